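"""Seeded synthetic motif sets and proteomes with known ground truth.

The generator emulates the positional preferences of LC8-binding motifs:
an invariant glutamine slot (position 0) flanked by serine/threonine at
-1/+1, an H-bond-capable -4 (often aspartate), a large or positively
charged -3, and a strand-breaking +2 (proline/aspartate/glutamate).  The
nonbinder-like class is likewise anchored — real nonbinder peptides were
selected for an anchor triplet — but its flank preferences are inverted
(hydrophobic -4/+2, small -3, bulky aromatic -2, acidic -5).

A single ``separation`` knob interpolates both classes between a shared
anchored-background model (separation 0, classes indistinguishable) and
the full class preferences (separation 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, MOTIF_LENGTH, POSITIONS
from .datasets import BackgroundFrequencies, load_packaged_background

CLASSES = ("binder_like", "nonbinder_like", "background")

#: Flank preference distributions per position (residue -> probability).
#: The two classes use disjoint residue sets at every flank position, so at
#: full separation the classes are perfectly separable by construction.
_BINDER_PREFS: dict[int, dict[str, float]] = {
    -5: {"K": 0.5, "R": 0.5},
    -4: {"D": 0.4, "S": 0.2, "T": 0.2, "N": 0.2},
    -3: {"K": 0.3, "R": 0.2, "I": 0.15, "L": 0.15, "M": 0.1, "V": 0.1},
    -2: {"S": 0.25, "T": 0.25, "A": 0.2, "G": 0.15, "V": 0.15},
    2: {"P": 0.4, "D": 0.3, "E": 0.3},
}

_NONBINDER_PREFS: dict[int, dict[str, float]] = {
    -5: {"D": 0.5, "E": 0.5},
    -4: {"L": 0.3, "V": 0.3, "I": 0.2, "F": 0.2},
    -3: {"A": 0.4, "G": 0.3, "H": 0.3},
    -2: {"F": 0.3, "W": 0.2, "Y": 0.3, "P": 0.2},
    2: {"V": 0.3, "I": 0.3, "L": 0.2, "F": 0.2},
}

#: Anchor distributions: shared baseline and the binder-class preference.
_ANCHOR_BASE = {-1: {"T": 0.6, "S": 0.4}, 0: {"Q": 1.0}, 1: {"T": 0.6, "S": 0.4}}
_ANCHOR_BINDER = {
    -1: {"T": 0.75, "S": 0.20, "I": 0.03, "V": 0.02},
    0: {"Q": 1.0},
    1: {"T": 0.80, "S": 0.15, "I": 0.03, "V": 0.02},
}


def _as_vector(dist: Mapping[str, float]) -> np.ndarray:
    v = np.zeros(len(AMINO_ACIDS))
    for a, p in dist.items():
        v[AMINO_ACIDS.index(a)] = p
    return v


@dataclass(frozen=True)
class MotifModel:
    """Positional residue models for anchored binder/nonbinder-like 8-mers.

    ``separation`` in [0, 1] scales the class-specific flank and anchor
    preferences; at 0 the two classes share one anchored-background model.
    """

    separation: float = 1.0
    seed: int = 0
    background: BackgroundFrequencies | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")

    @property
    def _bg(self) -> BackgroundFrequencies:
        return self.background or load_packaged_background()

    def position_distribution(self, klass: str, position: int) -> np.ndarray:
        """Length-20 residue probabilities for one motif position."""
        bg = _as_vector(self._bg.freq)
        lam = self.separation
        if klass == "background":
            return bg
        if position in _ANCHOR_BASE:
            base = _as_vector(_ANCHOR_BASE[position])
            if klass == "binder_like":
                pref = _as_vector(_ANCHOR_BINDER[position])
                return lam * pref + (1 - lam) * base
            return base
        prefs = _BINDER_PREFS if klass == "binder_like" else _NONBINDER_PREFS
        pref = _as_vector(prefs[position])
        return lam * pref + (1 - lam) * bg

    def probability_matrix(self, klass: str) -> np.ndarray:
        """(20, 8) per-position residue probabilities for a class."""
        if klass not in CLASSES:
            raise ValueError(f"unknown class {klass!r}")
        return np.stack(
            [self.position_distribution(klass, p) for p in POSITIONS], axis=1
        )


def generate_motifs(
    n: int, klass: str, model: MotifModel, seed: int | None = None
) -> list[str]:
    """Draw ``n`` independent anchored 8-mers from a class model.

    ``background`` draws every position i.i.d. from the background with no
    anchor constraint.  The stream is fully determined by the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    probs = model.probability_matrix(klass)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    out = []
    for _ in range(n):
        letters = [
            AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=probs[:, j])]
            for j in range(MOTIF_LENGTH)
        ]
        out.append("".join(letters))
    return out


def generate_proteome(
    n_proteins: int,
    lengths: Sequence[int] | int,
    planted: Sequence[tuple[int, int, str]],
    model: MotifModel,
    seed: int | None = None,
) -> tuple[str, list[dict]]:
    """Background proteins with motifs planted at known coordinates.

    ``planted`` lists ``(protein_index, start, motif)`` with ``start`` the
    1-based position of the first motif residue; the implied anchor
    coordinate in the truth table is ``q_position = start + 5``.  Returns
    ``(fasta_text, truth_table)`` where the truth table rows carry
    ``protein_id``, ``q_position``, ``motif`` and ``klass``.
    """
    if isinstance(lengths, int):
        lengths = [lengths] * n_proteins
    if len(lengths) != n_proteins:
        raise ValueError("lengths must match n_proteins")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    bg = _as_vector((model.background or load_packaged_background()).freq)

    occupied: dict[int, set[int]] = {i: set() for i in range(n_proteins)}
    for idx, start, motif in planted:
        if not 0 <= idx < n_proteins:
            raise ValueError(f"planted protein index {idx} out of range")
        if start < 1 or start + MOTIF_LENGTH - 1 > lengths[idx]:
            raise ValueError(
                f"planted motif at {start} does not fit in protein {idx} "
                f"(length {lengths[idx]})"
            )
        span = set(range(start, start + MOTIF_LENGTH))
        if occupied[idx] & span:
            raise ValueError(f"overlapping planted motifs in protein {idx}")
        occupied[idx] |= span

    sequences = []
    for i in range(n_proteins):
        letters = rng.choice(len(AMINO_ACIDS), size=lengths[i], p=bg)
        sequences.append([AMINO_ACIDS[j] for j in letters])
    truth: list[dict] = []
    for idx, start, motif in planted:
        if len(motif) != MOTIF_LENGTH:
            raise ValueError(f"planted motif {motif!r} is not 8 residues")
        sequences[idx][start - 1 : start - 1 + MOTIF_LENGTH] = list(motif)
        truth.append(
            {
                "protein_id": f"synth{idx:03d}",
                "q_position": start + 5,
                "motif": motif,
                "klass": "planted",
            }
        )
    fasta = "".join(
        f">synth{i:03d}\n" + "\n".join(_wrap("".join(sequences[i]))) + "\n"
        for i in range(n_proteins)
    )
    return fasta, truth


def truth_table_tsv(truth: Sequence[dict]) -> str:
    lines = ["protein_id\tq_position\tmotif\tklass"]
    lines += [f"{t['protein_id']}\t{t['q_position']}\t{t['motif']}\t{t['klass']}" for t in truth]
    return "\n".join(lines) + "\n"


def _wrap(seq: str, width: int = 60) -> list[str]:
    return [seq[i : i + width] for i in range(0, len(seq), width)] or [""]
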