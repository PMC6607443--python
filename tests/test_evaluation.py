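"""LOO scoring, ROC/AUC, grid search and confusion metrics."""

import numpy as np
import pytest

from lc8motif.datasets import TrainingSet
from lc8motif.evaluation import (
    ConfusionSummary,
    LOODegeneracyError,
    calibrate_thresholds,
    confusion_metrics,
    grid_search_weights,
    loo_matrix_sums,
    loo_scores,
    roc_auc,
)
from lc8motif.matrices import build_all_matrices
from lc8motif.scoring import MatrixSet, ScorePair
from lc8motif.synthetic import MotifModel, generate_motifs


def mann_whitney_auc(scores, labels):
    """Brute-force concordant-pair fraction (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ranking(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)

    def test_constant_scores_are_uninformative(self):
        assert roc_auc([1, 1, 1, 1], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_matches_concordance_oracle_on_seeded_inputs(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            scores = rng.integers(0, 5, size=10).astype(float)  # many ties
            labels = rng.integers(0, 2, size=10)
            if labels.sum() in (0, 10):
                continue
            got = roc_auc(scores, labels).auc
            assert got == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-9)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores) + 5, labels).auc
        assert a == pytest.approx(b)

    def test_negated_scores_complement_auc(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=25)
        labels = np.r_[np.ones(10, int), np.zeros(15, int)]
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_points_are_monotone_and_trapezoid_area_matches(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        curve = roc_auc(scores, labels)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert curve.auc == pytest.approx(float(np.trapezoid(curve.tpr, curve.fpr)))


class TestLOO:
    def test_one_score_pair_per_motif_in_input_order(self, training, background, fitted):
        pairs = fitted.loo_pairs_
        assert len(pairs) == 111
        labels = [l for l, _ in pairs]
        assert labels == ["binder"] * 79 + ["nonbinder"] * 32

    def test_degenerate_class_rejected(self, background):
        with pytest.raises(LOODegeneracyError):
            loo_matrix_sums(["CDKSTQTP"], ["AEFSTQTP", "RSIDTQTP"], background)

    def test_loo_removes_exactly_one_copy_of_a_duplicated_motif(self, background):
        # LOO drops one occurrence by position, never every copy: holding
        # out either duplicate must leave the twin in the training counts,
        # so both copies get the same score, equal to scoring against
        # matrices trained with exactly one copy removed.
        model = MotifModel(separation=1.0, seed=5)
        binders = generate_motifs(10, "binder_like", model, seed=5)
        nonbinders = generate_motifs(8, "nonbinder_like", model, seed=6)
        binders.append(binders[0])  # duplicate at the end
        sums, labels, motifs = loo_matrix_sums(binders, nonbinders, background)
        reduced = build_all_matrices((binders[1:], nonbinders), background)
        from lc8motif.matrices import MATRIX_KEYS
        twin = len(binders) - 1  # index of the appended duplicate
        for j, key in enumerate(MATRIX_KEYS):
            assert sums[0, j] == pytest.approx(reduced[key].score(binders[0]), abs=1e-9)
            assert sums[0, j] == pytest.approx(sums[twin, j], abs=1e-9)

    def test_separated_classes_give_unit_auc(self, background):
        model = MotifModel(separation=1.0, seed=2)
        binders = generate_motifs(25, "binder_like", model, seed=21)
        nonbinders = generate_motifs(25, "nonbinder_like", model, seed=22)
        weights, aucs = grid_search_weights((binders, nonbinders), background)
        assert aucs["auc_aa"] == pytest.approx(1.0)
        assert aucs["auc_vp"] == pytest.approx(1.0)

    def test_label_permutation_gives_chance_auc(self, background):
        model = MotifModel(separation=1.0, seed=3)
        aucs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            motifs = generate_motifs(80, "binder_like", model, seed=seed + 50)
            perm = rng.permutation(80)
            binders = [motifs[i] for i in perm[:40]]
            nonbinders = [motifs[i] for i in perm[40:]]
            sums, labels, _ = loo_matrix_sums(binders, nonbinders, background)
            from lc8motif.evaluation import _auc_rank
            s = sums[:, 0]  # identity-background matrix score
            aucs.append(float(_auc_rank(s[None, :], labels)[0]))
        assert abs(np.mean(aucs) - 0.5) < 0.1


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, background):
        model = MotifModel(separation=1.0, seed=7)
        b = generate_motifs(6, "binder_like", model, seed=71)
        nb = generate_motifs(6, "nonbinder_like", model, seed=72)
        weights, _ = grid_search_weights((b, nb), background, grid=[0.7])
        assert all(w == 0.7 for w in weights.values())

    def test_empty_grid_rejected(self, background):
        with pytest.raises(ValueError):
            grid_search_weights((["CDKSTQTP", "AEFSTQTP"], ["TPTGTQTP", "PSSSTQTS"]),
                                background, grid=[])

    def test_returned_weights_are_grid_members(self, fitted):
        from lc8motif.evaluation import DEFAULT_WEIGHT_GRID
        assert all(w in DEFAULT_WEIGHT_GRID for w in fitted.weights_.values())

    def test_uninformative_matrix_weight_driven_to_grid_minimum(self, background):
        # classes differing only in residue identity within the same bins:
        # L vs I at -3 (both "large", both nonpolar) is invisible to the
        # binned matrices, so the informative signal is identity-level only.
        binders = ["KDLSTQTP", "KDLSSQTP", "KDLTTQTP", "RDLSTQTP", "KNLSTQTP"]
        nonbinders = ["KDISTQTP", "KDISSQTP", "KDITTQTP", "RDISTQTP", "KNISTQTP"]
        weights, aucs = grid_search_weights((binders, nonbinders), background,
                                            grid=[0.0, 0.5, 1.0])
        assert aucs["auc_aa"] == pytest.approx(1.0)
        # no binned matrix can separate the classes: chance AUC, and the
        # lexicographic tie-break drives every S_vp weight to the minimum
        assert aucs["auc_vp"] == pytest.approx(0.5)
        assert all(weights[k] == 0.0 for k in ("volume_bg", "volume_nb", "polarity_nb"))


class TestConfusion:
    def test_hand_built_two_by_two(self):
        c = ConfusionSummary(tp=3, fp=1, tn=7, fn=2)
        assert c.tpr == pytest.approx(0.6)
        assert c.tnr == pytest.approx(0.875)
        assert c.accuracy == pytest.approx(10 / 13)

    def test_all_correct(self):
        c = ConfusionSummary(tp=5, fp=0, tn=5, fn=0)
        assert c.accuracy == 1.0
        assert c.fpr == 0.0

    def test_counts_partition_the_classes(self, fitted):
        c = fitted.confusion_
        assert c.tp + c.fn == 79
        assert c.tn + c.fp == 32

    def test_high_confidence_counts_as_predicted_positive(self, mset):
        pairs = [("binder", ScorePair(s_aa=-100.0, s_vp=mset.theta_hc + 1, s_aa_norm=0, s_vp_norm=0))]
        c = confusion_metrics(pairs, mset)
        assert (c.tp, c.fn) == (1, 0)


class TestCalibration:
    def test_hc_threshold_zeroes_false_positives(self, fitted, mset):
        nb_vp = [p.s_vp for l, p in fitted.loo_pairs_ if l == "nonbinder"]
        assert all(v < mset.theta_hc for v in nb_vp)
        # smallest such threshold: some observed score sits just below it
        b_vp = [p.s_vp for l, p in fitted.loo_pairs_ if l == "binder"]
        assert mset.theta_hc in b_vp or mset.theta_hc == pytest.approx(max(nb_vp + b_vp) + 1)

    def test_calibration_recovers_a_constructed_operating_point(self):
        rng = np.random.default_rng(77)
        pairs = []
        for i in range(40):
            pairs.append(("binder", ScorePair(10 + rng.normal(), 5 + rng.normal(), 0, 0)))
        for i in range(20):
            pairs.append(("nonbinder", ScorePair(rng.normal(), rng.normal(), 0, 0)))
        thetas = calibrate_thresholds(pairs, target_fp=0, target_fn=0)
        fp = sum(
            1 for l, p in pairs
            if l == "nonbinder" and (
                p.s_vp >= thetas["theta_hc"]
                or (p.s_aa >= thetas["theta_aa"] and p.s_vp >= thetas["theta_vp"])
            )
        )
        fn = sum(
            1 for l, p in pairs
            if l == "binder" and not (
                p.s_vp >= thetas["theta_hc"]
                or (p.s_aa >= thetas["theta_aa"] and p.s_vp >= thetas["theta_vp"])
            )
        )
        assert (fp, fn) == (0, 0)
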