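"""Leave-one-out evaluation, ROC/AUC, weight grid search, calibration.

The training set is small (79 binders, 32 nonbinders), so every motif is
scored by matrices rebuilt with that motif removed from its class
(leave-one-out, LOO).  Combination weights for ``S_aa`` and ``S_vp`` are
chosen by a grid search maximizing the LOO ROC area, and the operating
thresholds are calibrated on the LOO score cloud.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .datasets import BackgroundFrequencies, TrainingSet
from .matrices import DEFAULT_PSEUDOCOUNT, MATRIX_KEYS, build_all_matrices
from .scoring import (
    AA_WEIGHT_KEYS,
    VP_WEIGHT_KEYS,
    MatrixSet,
    ScorePair,
    classify,
    is_predicted_binder,
)

#: Default candidate values for every combination weight: 0.0 .. 2.0 by 0.1.
DEFAULT_WEIGHT_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(21))

#: The operating point printed for the original training data, used as the
#: calibration target for the rebuilt score scale.
TARGET_FP = 4
TARGET_FN = 20


class LOODegeneracyError(ValueError):
    """Leave-one-out is undefined for a class of size 1."""


@dataclass(frozen=True)
class ROCCurve:
    """Tie-grouped ROC points and their trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.n_positives + self.n_negatives)

    @property
    def tpr(self) -> float:
        return self.tp / self.n_positives if self.n_positives else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / self.n_negatives if self.n_negatives else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / self.n_negatives if self.n_negatives else float("nan")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC over unique score thresholds with ties grouped; trapezoidal AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Tie-aware AUC for each row of ``scores`` (Mann-Whitney identity)."""
    scores = np.atleast_2d(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores, axis=1)
    pos_rank_sum = ranks[:, labels == 1].sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def loo_matrix_sums(
    binders: Sequence[str],
    nonbinders: Sequence[str],
    background: BackgroundFrequencies,
    alpha: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-matrix LOO score sums for every training motif.

    Returns ``(sums, labels, motifs)`` where ``sums[i, j]`` is the raw
    (unweighted) per-position sum of motif ``i`` on matrix ``MATRIX_KEYS[j]``
    rebuilt without that motif, and ``labels[i]`` is 1 for binders.
    """
    if len(binders) < 2 or len(nonbinders) < 2:
        raise LOODegeneracyError("leave-one-out needs >= 2 motifs per class")
    motifs = list(binders) + list(nonbinders)
    labels = np.array([1] * len(binders) + [0] * len(nonbinders))
    sums = np.zeros((len(motifs), len(MATRIX_KEYS)))
    for i, motif in enumerate(motifs):
        if labels[i] == 1:
            b = [m for k, m in enumerate(binders) if k != i]
            nb = list(nonbinders)
        else:
            b = list(binders)
            j = i - len(binders)
            nb = [m for k, m in enumerate(nonbinders) if k != j]
        mats = build_all_matrices((b, nb), background, alpha)
        for jm, key in enumerate(MATRIX_KEYS):
            sums[i, jm] = mats[key].score(motif)
    return sums, labels, motifs


def _combine(sums: np.ndarray, weights: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Weighted S_aa and S_vp for every row of per-matrix sums."""
    key_idx = {k: i for i, k in enumerate(MATRIX_KEYS)}
    s_aa = sum(weights[k] * sums[:, key_idx[k]] for k in AA_WEIGHT_KEYS)
    s_vp = sum(weights[k] * sums[:, key_idx[k]] for k in VP_WEIGHT_KEYS)
    return np.asarray(s_aa, dtype=float), np.asarray(s_vp, dtype=float)


def loo_scores(
    training: TrainingSet,
    background: BackgroundFrequencies,
    alpha: float = DEFAULT_PSEUDOCOUNT,
    weights: Mapping[str, float] | None = None,
    mset: MatrixSet | None = None,
) -> list[tuple[str, ScorePair]]:
    """LOO (label, ScorePair) for every training motif, in input order.

    Normalized scores are relative to the per-position-optimal motif of the
    full-training matrix set (``mset`` when given), so that LOO points are
    directly comparable to sliding-window scan scores.
    """
    if weights is None and mset is None:
        raise ValueError("provide weights or a fitted MatrixSet")
    if weights is None:
        weights = mset.weights
    sums, labels, _ = loo_matrix_sums(
        training.binder_motifs, training.nonbinder_motifs, background, alpha
    )
    s_aa, s_vp = _combine(sums, weights)
    if mset is None:
        mats = build_all_matrices(training, background, alpha)
        mset = MatrixSet(matrices=mats, weights=dict(weights))
    out = []
    for i, lab in enumerate(labels):
        pair = ScorePair(
            s_aa=float(s_aa[i]),
            s_vp=float(s_vp[i]),
            s_aa_norm=float(s_aa[i] / mset.max_s_aa) if mset.max_s_aa > 0 else 0.0,
            s_vp_norm=float(s_vp[i] / mset.max_s_vp) if mset.max_s_vp > 0 else 0.0,
        )
        out.append(("binder" if lab == 1 else "nonbinder", pair))
    return out


def grid_search_weights(
    training: TrainingSet | tuple[Sequence[str], Sequence[str]],
    background: BackgroundFrequencies,
    alpha: float = DEFAULT_PSEUDOCOUNT,
    grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
    loo_sums: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Maximize LOO AUC over a joint weight grid.

    The two ``S_aa`` weights and the three ``S_vp`` weights are searched
    independently (the scores are evaluated separately).  Ties are broken
    toward the lexicographically smallest weight vector.  Returns
    ``(weights, {"auc_aa": ..., "auc_vp": ...})``.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("empty weight grid")
    if loo_sums is None:
        if isinstance(training, TrainingSet):
            b, nb = training.binder_motifs, training.nonbinder_motifs
        else:
            b, nb = training
        sums, labels, _ = loo_matrix_sums(b, nb, background, alpha)
    else:
        sums, labels = loo_sums
    key_idx = {k: i for i, k in enumerate(MATRIX_KEYS)}

    def best_combo(keys: tuple[str, ...]) -> tuple[tuple[float, ...], float]:
        cols = sums[:, [key_idx[k] for k in keys]]  # (n, len(keys))
        mesh = np.meshgrid(*([grid] * len(keys)), indexing="ij")
        combos = np.stack([m.ravel() for m in mesh], axis=1)  # lexicographic order
        scores = combos @ cols.T  # (n_combos, n)
        aucs = _auc_rank(scores, labels)
        best = aucs.max()
        idx = int(np.nonzero(aucs >= best - 1e-12)[0][0])
        return tuple(float(w) for w in combos[idx]), float(aucs[idx])

    aa_w, auc_aa = best_combo(AA_WEIGHT_KEYS)
    vp_w, auc_vp = best_combo(VP_WEIGHT_KEYS)
    weights = dict(zip(AA_WEIGHT_KEYS, aa_w)) | dict(zip(VP_WEIGHT_KEYS, vp_w))
    return weights, {"auc_aa": auc_aa, "auc_vp": auc_vp}


def confusion_metrics(
    pairs: Sequence[tuple[str, ScorePair]], mset: MatrixSet
) -> ConfusionSummary:
    """Confusion counts of LOO score pairs at the matrix-set thresholds.

    Binder and high-confidence tiers both count as predicted-positive.
    """
    tp = fp = tn = fn = 0
    for label, pair in pairs:
        predicted = is_predicted_binder(classify(pair, mset))
        if label == "binder":
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def calibrate_thresholds(
    pairs: Sequence[tuple[str, ScorePair]],
    target_fp: int = TARGET_FP,
    target_fn: int = TARGET_FN,
) -> dict[str, float]:
    """Recover the published operating point on the rebuilt score scale.

    ``theta_hc`` is the smallest ``S_vp`` threshold with zero LOO false
    positives.  ``(theta_aa, theta_vp)`` are then chosen by scanning every
    candidate pair of observed score values and picking the pair whose LOO
    confusion counts best match ``(target_fp, target_fn)`` (ties toward the
    smaller absolute count error on false positives, then toward the most
    stringent — largest — thresholds achieving those counts).
    """
    labels = np.array([1 if lab == "binder" else 0 for lab, _ in pairs])
    s_aa = np.array([p.s_aa for _, p in pairs])
    s_vp = np.array([p.s_vp for _, p in pairs])
    nb_vp = s_vp[labels == 0]

    candidates_vp = np.unique(np.concatenate([s_vp, [s_vp.max() + 1.0]]))
    theta_hc = float(candidates_vp[candidates_vp > nb_vp.max()][0])

    cand_aa = np.unique(np.concatenate([s_aa, [s_aa.max() + 1.0]]))
    cand_vp = candidates_vp
    hc = s_vp >= theta_hc
    # pred[i, j, k]: sample k predicted positive at (theta_aa_i, theta_vp_j)
    A = s_aa[None, :] >= cand_aa[:, None]
    B = s_vp[None, :] >= cand_vp[:, None]
    pred = hc[None, None, :] | (A[:, None, :] & B[None, :, :])
    fp = (pred & (labels == 0)[None, None, :]).sum(axis=2)
    fn = ((~pred) & (labels == 1)[None, None, :]).sum(axis=2)
    cost = np.abs(fp - target_fp) + np.abs(fn - target_fn)
    tie = np.abs(fp - target_fp)
    order = np.lexsort(
        (
            -np.repeat(cand_aa, len(cand_vp)),
            -np.tile(cand_vp, len(cand_aa)),
            tie.ravel(),
            cost.ravel(),
        )
    )
    best = order[0]
    i, j = divmod(best, len(cand_vp))
    return {
        "theta_aa": float(cand_aa[i]),
        "theta_vp": float(cand_vp[j]),
        "theta_hc": theta_hc,
    }
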