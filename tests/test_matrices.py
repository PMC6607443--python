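"""Frequency tables and the six log-ratio matrices."""

import math
from collections import Counter

import numpy as np
import pytest

from lc8motif.alphabet import AMINO_ACIDS, IDENTITY, POLARITY, SCHEMES, VOLUME
from lc8motif.datasets import BackgroundFrequencies
from lc8motif.matrices import (
    PSSM,
    NormalizationError,
    TrainingError,
    bin_background,
    bin_motif,
    build_all_matrices,
    build_background_pssm,
    build_nonbinder_pssm,
    position_frequencies,
)

from .conftest import random_motif


def uniform_background():
    return BackgroundFrequencies({a: 0.05 for a in AMINO_ACIDS})


class TestPositionFrequencies:
    def test_all_mass_on_one_symbol_without_pseudocount(self):
        ft = position_frequencies(["AAAATQTA", "CCCCTQTC"], IDENTITY, alpha=0)
        assert ft.freq("T", -1) == 1.0
        assert ft.freq("Q", 0) == 1.0

    def test_pseudocount_algebra_for_absent_symbol(self):
        n = 7
        ft = position_frequencies(["AAAATQTA"] * n, IDENTITY, alpha=1)
        assert ft.freq("W", -5) == pytest.approx(1 / (n + 20))
        assert ft.freq("A", -5) == pytest.approx((n + 1) / (n + 20))

    @pytest.mark.parametrize("scheme", SCHEMES.values(), ids=lambda s: s.name)
    def test_matches_hand_tally_oracle(self, scheme):
        rng = np.random.default_rng(11)
        motifs = [random_motif(rng) for _ in range(5)]
        alpha = 0.5
        ft = position_frequencies(motifs, scheme, alpha)
        for p in range(8):
            tally = Counter(scheme.mapping[m[p]] for m in motifs)
            for cat in scheme.categories:
                expected = (tally[cat] + alpha) / (5 + alpha * scheme.n_categories)
                assert ft.freq(cat, p - 5) == pytest.approx(expected)

    @pytest.mark.parametrize("scheme", SCHEMES.values(), ids=lambda s: s.name)
    def test_columns_sum_to_one(self, scheme):
        rng = np.random.default_rng(7)
        ft = position_frequencies([random_motif(rng) for _ in range(13)], scheme, 1.0)
        assert np.allclose(ft.freqs.sum(axis=0), 1.0, atol=1e-9)

    def test_binned_counts_equal_collapsed_identity_counts(self):
        rng = np.random.default_rng(3)
        motifs = [random_motif(rng) for _ in range(40)]
        ident = position_frequencies(motifs, IDENTITY, alpha=0)
        for scheme in (POLARITY, VOLUME):
            binned = position_frequencies(motifs, scheme, alpha=0)
            for ci, cat in enumerate(scheme.categories):
                rows = [AMINO_ACIDS.index(a) for a in scheme.residues_in(cat)]
                assert np.array_equal(ident.counts[rows].sum(axis=0), binned.counts[ci])


class TestBackgroundPSSM:
    def test_identical_frequencies_give_zero_matrix(self):
        ft = position_frequencies(["AAAATQTA"], IDENTITY, alpha=1)
        bg = BackgroundFrequencies(
            {a: float(f) for a, f in zip(AMINO_ACIDS, ft.freqs[:, 0])}
        )
        # column 0 of the table equals the background exactly
        pssm = build_background_pssm(ft, bg)
        assert np.allclose(pssm.weights[:, 0], 0.0)

    def test_log2_of_twenty_fold_enrichment(self):
        # f_bind(Q, 0) = 0.9 against a background of 0.045 is a 20x ratio
        ft = position_frequencies(["AAAAAQAA"], IDENTITY, alpha=0)
        object.__setattr__(ft, "freqs", np.where(ft.freqs > 0, 0.9, 0.1 / 19))
        bg = BackgroundFrequencies({a: 0.045 if a == "Q" else 0.955 / 19 for a in AMINO_ACIDS})
        pssm = build_background_pssm(ft, bg)
        assert pssm.weight("Q", 0) == pytest.approx(math.log2(20), abs=1e-9)

    def test_sign_tracks_enrichment_vs_background(self):
        rng = np.random.default_rng(5)
        ft = position_frequencies([random_motif(rng) for _ in range(30)], IDENTITY, 1.0)
        bg = uniform_background()
        pssm = build_background_pssm(ft, bg)
        assert np.array_equal(pssm.weights > 0, ft.freqs > 0.05)

    def test_zero_background_rejected(self):
        ft = position_frequencies(["AAAATQTA"], POLARITY, alpha=1)
        with pytest.raises(NormalizationError):
            build_background_pssm(ft, {c: 0.0 for c in POLARITY.categories})

    def test_binned_background_sums_within_category(self):
        bg = uniform_background()
        collapsed = bin_background(bg, POLARITY)
        assert collapsed["positive"] == pytest.approx(0.10)
        assert collapsed["nonpolar"] == pytest.approx(0.45)
        assert sum(collapsed.values()) == pytest.approx(1.0)


class TestNonbinderPSSM:
    def test_anchor_columns_are_exactly_zero(self):
        rng = np.random.default_rng(9)
        fb = position_frequencies([random_motif(rng) for _ in range(10)], IDENTITY, 1)
        fn = position_frequencies([random_motif(rng) for _ in range(10)], IDENTITY, 1)
        pssm = build_nonbinder_pssm(fb, fn)
        assert pssm.anchor_masked
        assert np.all(pssm.weights[:, 4:7] == 0.0)

    def test_log_ratio_matches_brute_force_oracle_off_anchor(self):
        rng = np.random.default_rng(21)
        fb = position_frequencies([random_motif(rng) for _ in range(12)], VOLUME, 1)
        fn = position_frequencies([random_motif(rng) for _ in range(9)], VOLUME, 1)
        pssm = build_nonbinder_pssm(fb, fn)
        for ci, cat in enumerate(VOLUME.categories):
            for p in (-5, -4, -3, -2, 2):
                expected = math.log2(fb.freq(cat, p) / fn.freq(cat, p))
                assert pssm.weight(cat, p) == pytest.approx(expected)

    def test_equal_frequencies_zero_the_column(self):
        fb = position_frequencies(["AAAATQTA", "CAAATQTA"], IDENTITY, 1)
        pssm = build_nonbinder_pssm(fb, fb)
        assert np.allclose(pssm.weights, 0.0)


class TestBuildAllMatrices:
    def test_six_matrices_with_expected_masking(self, training, background):
        mats = build_all_matrices(training, background)
        assert set(mats) == {
            "identity_bg", "identity_nb", "polarity_bg", "polarity_nb",
            "volume_bg", "volume_nb",
        }
        for key, pssm in mats.items():
            assert pssm.anchor_masked == key.endswith("_nb")
            assert np.all(np.isfinite(pssm.weights))

    def test_identical_classes_zero_the_nonbinder_matrices(self, background):
        motifs = ["CDKSTQTP", "AEFSTQTP", "RSIDTQTP"]
        mats = build_all_matrices((motifs, motifs), background)
        assert np.allclose(mats["identity_nb"].weights, 0.0)
        assert np.allclose(mats["volume_nb"].weights, 0.0)

    def test_empty_class_is_a_training_error(self, background):
        with pytest.raises(TrainingError):
            build_all_matrices(([], ["CDKSTQTP"]), background)

    def test_single_binder_background_column_matches_oracle(self, background):
        motif = "CDKSTQTP"
        mats = build_all_matrices(([motif], [motif, "AEFSTQTP"]), background, alpha=1.0)
        pssm = mats["identity_bg"]
        for p, a in enumerate(motif):
            expected = math.log2(((1 + 1) / (1 + 20)) / background[a])
            assert pssm.weight(a, p - 5) == pytest.approx(expected)


class TestSerialization:
    def test_tsv_round_trip_is_bit_exact(self, mset):
        for key, pssm in mset.matrices.items():
            back = PSSM.from_tsv(pssm.to_tsv())
            assert back.scheme.name == pssm.scheme.name
            assert back.normalization == pssm.normalization
            assert back.anchor_masked == pssm.anchor_masked
            assert np.array_equal(back.weights, pssm.weights)


def test_bin_motif_polarity_example():
    assert bin_motif("CDKSTQTP", POLARITY) == (
        "polar", "negative", "positive", "polar", "polar", "polar", "polar", "nonpolar"
    )
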