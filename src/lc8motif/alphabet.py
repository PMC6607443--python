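"""Amino-acid alphabet and physicochemical bin schemes.

The LC8 recognition motif is scored both at single-residue resolution and
after collapsing the 20 standard residues into four physicochemical
categories.  Two binnings are used: side-chain *polarity* (positively
charged, negatively charged, polar-uncharged, nonpolar) and side-chain
*volume* (four ranges chosen to keep the within-bin volume spread small).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Mean residue volumes (Zamyatnin, cubic angstroms).
RESIDUE_VOLUMES: dict[str, float] = {
    "G": 60.1, "A": 88.6, "S": 89.0, "C": 108.5, "D": 111.1,
    "P": 112.7, "N": 114.1, "T": 116.1, "E": 138.4, "V": 140.0,
    "Q": 143.8, "H": 153.2, "M": 162.9, "I": 166.7, "L": 166.7,
    "K": 168.6, "R": 173.4, "F": 189.9, "Y": 193.6, "W": 227.8,
}

#: Motif position labels: eight residues numbered -5..+2 with the anchor
#: glutamine slot at 0 and the flanking threonines at -1/+1.
POSITIONS: tuple[int, ...] = (-5, -4, -3, -2, -1, 0, 1, 2)

MOTIF_LENGTH = 8
ANCHOR_POSITIONS: tuple[int, ...] = (-1, 0, 1)


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the 20 standard residues."""


@dataclass(frozen=True)
class BinScheme:
    """A mapping from residues to category labels.

    Parameters
    ----------
    name :
        ``identity``, ``polarity`` or ``volume`` for the built-in schemes;
        custom schemes may use any name.
    mapping :
        residue -> category label, covering all 20 standard residues.
    categories :
        Ordered category labels (rows of the matrix serialization).
    """

    name: str
    mapping: Mapping[str, str]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [a for a in AMINO_ACIDS if a not in self.mapping]
        if missing:
            raise ValueError(f"bin scheme {self.name!r} misses residues {missing}")
        extra = set(self.mapping.values()) - set(self.categories)
        if extra:
            raise ValueError(f"bin scheme {self.name!r} maps to unlisted categories {extra}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def bin_residue(self, residue: str) -> str:
        try:
            return self.mapping[residue]
        except KeyError:
            raise AlphabetError(f"nonstandard residue {residue!r}") from None

    def bin_motif(self, motif: str) -> tuple[str, ...]:
        """Substitute every residue of an 8-mer by its category label."""
        if len(motif) != MOTIF_LENGTH:
            raise ValueError(f"motif must have length {MOTIF_LENGTH}, got {len(motif)}")
        return tuple(self.bin_residue(a) for a in motif)

    def residues_in(self, category: str) -> tuple[str, ...]:
        return tuple(a for a in AMINO_ACIDS if self.mapping[a] == category)


def _identity_scheme() -> BinScheme:
    return BinScheme(
        name="identity",
        mapping={a: a for a in AMINO_ACIDS},
        categories=tuple(AMINO_ACIDS),
    )


def _polarity_scheme() -> BinScheme:
    # H with polar-uncharged: side-chain pKa ~6, mostly neutral at pH 7.5.
    groups = {
        "positive": "KR",
        "negative": "DE",
        "polar": "STNQCYH",
        "nonpolar": "AVLIMFWPG",
    }
    mapping = {a: cat for cat, members in groups.items() for a in members}
    return BinScheme(
        name="polarity",
        mapping=mapping,
        categories=("positive", "negative", "polar", "nonpolar"),
    )

#: Volume range edges (A^3) for the four volume bins.  The printed ranges
#: (<106, 122-142, 155-171, >200) leave gaps; residues whose tabulated
#: volume falls in a gap are assigned to the nearest range boundary.
VOLUME_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 106.0),
    (122.0, 142.0),
    (155.0, 171.0),
    (200.0, float("inf")),
)

VOLUME_CATEGORIES: tuple[str, ...] = ("small", "medium", "large", "very_large")


def _volume_bin_of(volume: float) -> str:
    best, best_dist = None, float("inf")
    for cat, (lo, hi) in zip(VOLUME_CATEGORIES, VOLUME_RANGES):
        if lo <= volume <= hi:
            return cat
        dist = min(abs(volume - lo), abs(volume - hi) if hi != float("inf") else float("inf"))
        if dist < best_dist:
            best, best_dist = cat, dist
    assert best is not None
    return best


def _volume_scheme() -> BinScheme:
    mapping = {a: _volume_bin_of(v) for a, v in RESIDUE_VOLUMES.items()}
    return BinScheme(name="volume", mapping=mapping, categories=VOLUME_CATEGORIES)


IDENTITY: BinScheme = _identity_scheme()
POLARITY: BinScheme = _polarity_scheme()
VOLUME: BinScheme = _volume_scheme()

SCHEMES: dict[str, BinScheme] = {s.name: s for s in (IDENTITY, POLARITY, VOLUME)}


def validate_motif(motif: str) -> str:
    """Check an 8-mer over the standard alphabet; return it unchanged."""
    if len(motif) != MOTIF_LENGTH:
        raise ValueError(f"motif must have length {MOTIF_LENGTH}, got {motif!r}")
    bad = [a for a in motif if a not in AMINO_ACIDS]
    if bad:
        raise AlphabetError(f"nonstandard residue(s) {bad} in motif {motif!r}")
    return motif
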