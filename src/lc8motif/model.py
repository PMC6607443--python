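"""Scikit-learn-style estimator wrapping the full training pipeline.

``MotifBindingClassifier.fit`` builds the six position-specific matrices,
grid-searches the score combination weights by leave-one-out ROC area and
calibrates the decision thresholds on the LOO score cloud.  The fitted
object scores and classifies 8-mer motifs and composes with scikit-learn
model-selection utilities (``get_params`` / ``set_params`` / ``clone``).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import BackgroundFrequencies, load_packaged_background
from .evaluation import (
    DEFAULT_WEIGHT_GRID,
    TARGET_FP,
    TARGET_FN,
    ConfusionSummary,
    _combine,
    calibrate_thresholds,
    confusion_metrics,
    grid_search_weights,
    loo_matrix_sums,
)
from .matrices import DEFAULT_PSEUDOCOUNT, build_all_matrices
from .scoring import MatrixSet, ScorePair, classify, score_motif


class MotifBindingClassifier(BaseEstimator, ClassifierMixin):
    """Classify 8-residue LC8-motif candidates as binders or nonbinders.

    Parameters
    ----------
    alpha :
        Add-alpha pseudocount per category when estimating positional
        frequencies.
    background :
        Residue background for disordered regions; the packaged table is
        used when ``None``.
    weights :
        Fixed score-combination weights.  When ``None`` they are chosen by
        a leave-one-out grid search during :meth:`fit`.
    weight_grid :
        Candidate values per weight for the grid search.
    thresholds :
        Fixed ``(theta_aa, theta_vp, theta_hc)`` mapping.  When ``None``
        the thresholds are calibrated on the LOO score cloud to the
        published operating point (``target_fp`` false positives,
        ``target_fn`` false negatives; ``theta_hc`` is the smallest S_vp
        threshold with zero LOO false positives).
    target_fp, target_fn :
        Calibration target counts.

    Attributes
    ----------
    matrix_set_ : MatrixSet
        The six matrices with fitted weights and thresholds.
    weights_ : dict
        Fitted combination weights.
    loo_pairs_ : list of (label, ScorePair)
        Leave-one-out scores of the training motifs.
    auc_aa_, auc_vp_ : float
        LOO ROC areas of the two combined scores at the fitted weights.
    confusion_ : ConfusionSummary
        LOO confusion at the fitted thresholds.
    classes_ : ndarray
        ``["nonbinder", "binder"]``.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_PSEUDOCOUNT,
        background: BackgroundFrequencies | None = None,
        weights: Mapping[str, float] | None = None,
        weight_grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
        thresholds: Mapping[str, float] | None = None,
        target_fp: int = TARGET_FP,
        target_fn: int = TARGET_FN,
    ):
        self.alpha = alpha
        self.background = background
        self.weights = weights
        self.weight_grid = weight_grid
        self.thresholds = thresholds
        self.target_fp = target_fp
        self.target_fn = target_fn

    # ------------------------------------------------------------------

    @staticmethod
    def _split_classes(X: Sequence[str], y: Sequence) -> tuple[list[str], list[str]]:
        X = list(X)
        y_arr = np.asarray(y)
        if y_arr.dtype.kind in "US":
            pos = y_arr == "binder"
        else:
            pos = y_arr.astype(int) == 1
        binders = [m for m, p in zip(X, pos) if p]
        nonbinders = [m for m, p in zip(X, pos) if not p]
        return binders, nonbinders

    def fit(self, X: Sequence[str], y: Sequence) -> "MotifBindingClassifier":
        """Fit from 8-mer motifs ``X`` and labels ``y`` (1/"binder" = binder)."""
        binders, nonbinders = self._split_classes(X, y)
        if not binders or not nonbinders:
            raise ValueError("fit needs motifs from both classes")
        background = self.background or load_packaged_background()

        sums, labels, _ = loo_matrix_sums(binders, nonbinders, background, self.alpha)
        if self.weights is None:
            weights, aucs = grid_search_weights(
                (binders, nonbinders), background, self.alpha,
                grid=self.weight_grid, loo_sums=(sums, labels),
            )
        else:
            weights = dict(self.weights)
            from .evaluation import _auc_rank
            s_aa, s_vp = _combine(sums, weights)
            aucs = {
                "auc_aa": float(_auc_rank(s_aa[None, :], labels)[0]),
                "auc_vp": float(_auc_rank(s_vp[None, :], labels)[0]),
            }

        matrices = build_all_matrices((binders, nonbinders), background, self.alpha)
        mset = MatrixSet(matrices=matrices, weights=weights)

        s_aa, s_vp = _combine(sums, weights)
        pairs = []
        for i in range(len(labels)):
            pair = ScorePair(
                s_aa=float(s_aa[i]), s_vp=float(s_vp[i]),
                s_aa_norm=float(s_aa[i] / mset.max_s_aa) if mset.max_s_aa > 0 else 0.0,
                s_vp_norm=float(s_vp[i] / mset.max_s_vp) if mset.max_s_vp > 0 else 0.0,
            )
            pairs.append(("binder" if labels[i] == 1 else "nonbinder", pair))

        if self.thresholds is None:
            thetas = calibrate_thresholds(pairs, self.target_fp, self.target_fn)
        else:
            thetas = dict(self.thresholds)
        mset = mset.with_thresholds(
            thetas["theta_aa"], thetas["theta_vp"], thetas["theta_hc"]
        )

        self.background_ = background
        self.weights_ = weights
        self.thresholds_ = thetas
        self.matrix_set_ = mset
        self.loo_pairs_ = pairs
        self.auc_aa_ = aucs["auc_aa"]
        self.auc_vp_ = aucs["auc_vp"]
        self.confusion_ = confusion_metrics(pairs, mset)
        self.classes_ = np.array(["nonbinder", "binder"])
        return self

    # ------------------------------------------------------------------

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        """(n, 2) array of raw ``(S_aa, S_vp)`` per motif."""
        check_is_fitted(self, "matrix_set_")
        pairs = [score_motif(m, self.matrix_set_) for m in X]
        return np.array([[p.s_aa, p.s_vp] for p in pairs])

    def score_pairs(self, X: Sequence[str]) -> list[ScorePair]:
        check_is_fitted(self, "matrix_set_")
        return [score_motif(m, self.matrix_set_) for m in X]

    def predict_tier(self, X: Sequence[str]) -> list[str]:
        """Three-way tier per motif: nonbinder / binder / high_confidence."""
        check_is_fitted(self, "matrix_set_")
        return [classify(score_motif(m, self.matrix_set_), self.matrix_set_) for m in X]

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Binary call; the high-confidence tier counts as ``binder``."""
        tiers = self.predict_tier(X)
        return np.array(["binder" if t != "nonbinder" else "nonbinder" for t in tiers])

    def score(self, X: Sequence[str], y: Sequence, sample_weight=None) -> float:
        y_arr = np.asarray(y)
        if y_arr.dtype.kind not in "US":
            y_arr = np.where(y_arr.astype(int) == 1, "binder", "nonbinder")
        return float(np.mean(self.predict(X) == y_arr))
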