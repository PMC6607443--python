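"""Combined motif scores and thresholded classification.

Two scores summarize the six matrices: ``S_aa`` combines the two
single-residue matrices and ``S_vp`` combines the volume and polarity
matrices.  The binder-only (background-normalized) polarity matrix is
excluded from ``S_vp`` by construction — dropping it maximized the
leave-one-out ROC area — so ``S_vp`` is a weighted sum of three matrices.

Classification is tiered: a window is a *binder* when both scores clear
their thresholds, and *high-confidence* when ``S_vp`` alone clears a
stricter threshold chosen for perfect specificity on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property
from typing import Mapping

import numpy as np

from .alphabet import AMINO_ACIDS, MOTIF_LENGTH, validate_motif
from .matrices import MATRIX_KEYS, PSSM

#: Operating point printed for the authors' score scale: minimum S_aa and
#: S_vp for the binder call, and the stand-alone S_vp threshold for the
#: high-confidence call.
PUBLISHED_THRESHOLDS = {"theta_aa": 12.9, "theta_vp": 0.1, "theta_hc": 2.7}

#: S_aa weight keys and S_vp weight keys, in canonical order.
AA_WEIGHT_KEYS = ("identity_bg", "identity_nb")
VP_WEIGHT_KEYS = ("volume_bg", "volume_nb", "polarity_nb")

TIERS = ("nonbinder", "binder", "high_confidence")


@dataclass(frozen=True)
class ScorePair:
    """Raw and normalized combined scores for one 8-mer window."""

    s_aa: float
    s_vp: float
    s_aa_norm: float
    s_vp_norm: float


@dataclass(frozen=True)
class MatrixSet:
    """The six trained matrices plus combination weights and thresholds."""

    matrices: Mapping[str, PSSM]
    weights: Mapping[str, float]
    theta_aa: float = PUBLISHED_THRESHOLDS["theta_aa"]
    theta_vp: float = PUBLISHED_THRESHOLDS["theta_vp"]
    theta_hc: float = PUBLISHED_THRESHOLDS["theta_hc"]

    def __post_init__(self) -> None:
        missing = set(MATRIX_KEYS) - set(self.matrices)
        if missing:
            raise ValueError(f"matrix set misses {sorted(missing)}")
        if set(self.weights) != set(AA_WEIGHT_KEYS + VP_WEIGHT_KEYS):
            raise ValueError(
                "weights must cover exactly "
                f"{AA_WEIGHT_KEYS + VP_WEIGHT_KEYS}; the binder-only polarity "
                "matrix carries no weight"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("combination weights must be >= 0")

    # -- per-residue score tables -----------------------------------------

    def _residue_table(self, keys: tuple[str, ...]) -> np.ndarray:
        """(20, 8) combined weighted score of each residue at each position."""
        table = np.zeros((len(AMINO_ACIDS), MOTIF_LENGTH))
        for key in keys:
            pssm = self.matrices[key]
            w = self.weights[key]
            if w == 0:
                continue
            cat_idx = {c: i for i, c in enumerate(pssm.scheme.categories)}
            rows = [cat_idx[pssm.scheme.mapping[a]] for a in AMINO_ACIDS]
            table += w * pssm.weights[rows, :]
        return table

    @cached_property
    def aa_table(self) -> np.ndarray:
        return self._residue_table(AA_WEIGHT_KEYS)

    @cached_property
    def vp_table(self) -> np.ndarray:
        return self._residue_table(VP_WEIGHT_KEYS)

    @cached_property
    def max_s_aa(self) -> float:
        """S_aa of the per-position-optimal motif."""
        return float(self.aa_table.max(axis=0).sum())

    @cached_property
    def max_s_vp(self) -> float:
        return float(self.vp_table.max(axis=0).sum())

    def ideal_motif(self, which: str = "vp") -> str:
        """The 8-mer taking the argmax residue at every position."""
        table = self.aa_table if which == "aa" else self.vp_table
        return "".join(AMINO_ACIDS[i] for i in table.argmax(axis=0))

    def with_thresholds(self, theta_aa: float, theta_vp: float, theta_hc: float) -> "MatrixSet":
        return replace(self, theta_aa=theta_aa, theta_vp=theta_vp, theta_hc=theta_hc)


def _normalize(raw: float, maximum: float) -> float:
    # The per-position-optimal motif defines 1.0; degenerate all-zero
    # matrices normalize to 0 by convention.
    return raw / maximum if maximum > 0 else 0.0


def score_motif(motif: str, mset: MatrixSet) -> ScorePair:
    """Score one 8-mer: weighted per-position sums over the matrices."""
    validate_motif(motif)
    idx = [AMINO_ACIDS.index(a) for a in motif]
    cols = np.arange(MOTIF_LENGTH)
    s_aa = float(mset.aa_table[idx, cols].sum())
    s_vp = float(mset.vp_table[idx, cols].sum())
    return ScorePair(
        s_aa=s_aa,
        s_vp=s_vp,
        s_aa_norm=_normalize(s_aa, mset.max_s_aa),
        s_vp_norm=_normalize(s_vp, mset.max_s_vp),
    )


def classify(scores: ScorePair, mset: MatrixSet) -> str:
    """Tier a window: thresholds are inclusive (a score at the threshold
    passes); the high-confidence call uses ``S_vp`` alone."""
    if scores.s_vp >= mset.theta_hc:
        return "high_confidence"
    if scores.s_aa >= mset.theta_aa and scores.s_vp >= mset.theta_vp:
        return "binder"
    return "nonbinder"


def is_predicted_binder(tier: str) -> bool:
    """Binder and high-confidence tiers both count as predicted-positive."""
    return tier in ("binder", "high_confidence")
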