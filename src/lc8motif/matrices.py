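"""Position-specific scoring matrices for the LC8 recognition motif.

Six log2-ratio matrices are trained: for each bin scheme (single residues,
polarity categories, volume categories) one matrix normalizes binder
frequencies to a disordered-proteome background and one to the nonbinder
frequencies.  Because nonbinder peptides were selected to contain an anchor
triplet, the anchor columns (-1, 0, +1) carry no discriminative signal in
the nonbinder-normalized matrices and are masked to zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import (
    ANCHOR_POSITIONS,
    MOTIF_LENGTH,
    POSITIONS,
    SCHEMES,
    AlphabetError,
    BinScheme,
    validate_motif,
)
from .datasets import BackgroundFrequencies, TrainingSet

DEFAULT_PSEUDOCOUNT = 1.0


class TrainingError(ValueError):
    """Matrix training was asked for with an empty class."""


class NormalizationError(ValueError):
    """A background or reference frequency is zero."""


def bin_motif(motif: str, scheme: BinScheme) -> tuple[str, ...]:
    """Per-residue category substitution of an 8-mer under ``scheme``."""
    return scheme.bin_motif(validate_motif(motif))


@dataclass(frozen=True)
class FrequencyTable:
    """Pseudocounted per-position category frequencies of a motif set.

    ``counts[c, p]`` are raw occurrence counts and ``freqs[c, p]`` the
    add-alpha frequencies ``(count + alpha) / (n + alpha * K)`` where ``K``
    is the number of categories.  Columns index positions -5..+2.
    """

    scheme: BinScheme
    counts: np.ndarray
    freqs: np.ndarray
    pseudocount: float
    n_motifs: int

    def freq(self, category: str, position: int) -> float:
        return float(self.freqs[self.scheme.categories.index(category), POSITIONS.index(position)])


def position_frequencies(
    motifs: Sequence[str], scheme: BinScheme, alpha: float = DEFAULT_PSEUDOCOUNT
) -> FrequencyTable:
    """Count category occurrences per motif position and normalize."""
    if alpha < 0:
        raise ValueError("pseudocount must be >= 0")
    k = scheme.n_categories
    index = {c: i for i, c in enumerate(scheme.categories)}
    counts = np.zeros((k, MOTIF_LENGTH))
    for m in motifs:
        for p, cat in enumerate(bin_motif(m, scheme)):
            counts[index[cat], p] += 1
    n = len(motifs)
    freqs = (counts + alpha) / (n + alpha * k)
    return FrequencyTable(scheme=scheme, counts=counts, freqs=freqs,
                          pseudocount=alpha, n_motifs=n)


@dataclass(frozen=True)
class PSSM:
    """A log2 weight per (category, motif position).

    ``normalization`` records the denominator of the log-ratio:
    ``background`` (disordered-proteome frequencies) or ``nonbinder``
    (anchor-containing nonbinder frequencies, with the anchor columns
    -1..+1 masked to zero).
    """

    scheme: BinScheme
    normalization: str
    weights: np.ndarray  # (n_categories, 8), log2 units
    anchor_masked: bool

    def __post_init__(self) -> None:
        if self.weights.shape != (self.scheme.n_categories, MOTIF_LENGTH):
            raise ValueError("weight matrix shape does not match scheme")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PSSM weights must be finite")
        if self.anchor_masked:
            cols = [POSITIONS.index(p) for p in ANCHOR_POSITIONS]
            if not np.allclose(self.weights[:, cols], 0.0):
                raise ValueError("anchor-masked PSSM has nonzero anchor columns")

    def weight(self, category: str, position: int) -> float:
        return float(
            self.weights[self.scheme.categories.index(category), POSITIONS.index(position)]
        )

    def score(self, motif: str) -> float:
        """Sum of per-position weights for an 8-mer."""
        idx = {c: i for i, c in enumerate(self.scheme.categories)}
        cats = bin_motif(motif, self.scheme)
        return float(sum(self.weights[idx[c], p] for p, c in enumerate(cats)))

    def max_column_weights(self) -> np.ndarray:
        """Per-position maximum weight over categories (length 8)."""
        return self.weights.max(axis=0)

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# scheme\t{self.scheme.name}\n")
        buf.write(f"# normalization\t{self.normalization}\n")
        buf.write(f"# anchor_masked\t{self.anchor_masked}\n")
        buf.write("# log_base\t2\n")
        buf.write("category\t" + "\t".join(str(p) for p in POSITIONS) + "\n")
        for i, cat in enumerate(self.scheme.categories):
            row = "\t".join(np.format_float_positional(w, trim="-") for w in self.weights[i])
            buf.write(f"{cat}\t{row}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "PSSM":
        meta: dict[str, str] = {}
        rows: list[tuple[str, list[float]]] = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, value = line.lstrip("# ").split("\t", 1)
                meta[key.strip()] = value.strip()
            elif line.startswith("category") or not line.strip():
                continue
            else:
                fields = line.split("\t")
                rows.append((fields[0], [float(x) for x in fields[1:]]))
        scheme = SCHEMES[meta["scheme"]]
        # rows may arrive in any order; realign to scheme category order
        aligned = np.zeros((scheme.n_categories, MOTIF_LENGTH))
        for (cat, vals) in rows:
            aligned[scheme.categories.index(cat)] = vals
        return cls(
            scheme=scheme,
            normalization=meta["normalization"],
            weights=aligned,
            anchor_masked=meta["anchor_masked"] == "True",
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    @classmethod
    def read(cls, path: str | Path) -> "PSSM":
        return cls.from_tsv(Path(path).read_text())


def bin_background(
    background: BackgroundFrequencies, scheme: BinScheme
) -> dict[str, float]:
    """Collapse the 20 residue background frequencies by category."""
    out = {c: 0.0 for c in scheme.categories}
    for a, f in background.freq.items():
        out[scheme.mapping[a]] += f
    return out


def build_background_pssm(
    binder_freqs: FrequencyTable,
    background: BackgroundFrequencies | Mapping[str, float],
) -> PSSM:
    """log2( f_bind(c, p) / f_bg(c) ), all eight positions live."""
    scheme = binder_freqs.scheme
    if isinstance(background, BackgroundFrequencies):
        bg = bin_background(background, scheme)
    else:
        bg = dict(background)
    if set(bg) != set(scheme.categories):
        raise ValueError("background categories do not match the bin scheme")
    bg_vec = np.array([bg[c] for c in scheme.categories])
    if np.any(bg_vec <= 0):
        raise NormalizationError("background frequencies must be positive")
    weights = np.log2(binder_freqs.freqs / bg_vec[:, None])
    return PSSM(scheme=scheme, normalization="background", weights=weights,
                anchor_masked=False)


def build_nonbinder_pssm(
    binder_freqs: FrequencyTable, nonbinder_freqs: FrequencyTable
) -> PSSM:
    """log2( f_bind / f_nonbind ) with anchor columns -1..+1 zeroed."""
    if binder_freqs.scheme.name != nonbinder_freqs.scheme.name:
        raise ValueError("binder and nonbinder tables use different schemes")
    if np.any(nonbinder_freqs.freqs <= 0):
        raise NormalizationError(
            "nonbinder frequencies contain zeros; use a positive pseudocount"
        )
    weights = np.log2(binder_freqs.freqs / nonbinder_freqs.freqs)
    for p in ANCHOR_POSITIONS:
        weights[:, POSITIONS.index(p)] = 0.0
    return PSSM(scheme=binder_freqs.scheme, normalization="nonbinder",
                weights=weights, anchor_masked=True)


#: Keys of the six trained matrices.
MATRIX_KEYS = (
    "identity_bg", "identity_nb",
    "polarity_bg", "polarity_nb",
    "volume_bg", "volume_nb",
)


def build_all_matrices(
    training: TrainingSet | tuple[Sequence[str], Sequence[str]],
    background: BackgroundFrequencies,
    alpha: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, PSSM]:
    """Train all six matrices from binder and nonbinder motif sets.

    ``training`` may be a :class:`TrainingSet` or a plain
    ``(binder_motifs, nonbinder_motifs)`` pair.
    """
    if isinstance(training, TrainingSet):
        binders, nonbinders = training.binder_motifs, training.nonbinder_motifs
    else:
        binders, nonbinders = (list(training[0]), list(training[1]))
    if not binders or not nonbinders:
        raise TrainingError("both binder and nonbinder classes must be nonempty")
    out: dict[str, PSSM] = {}
    for scheme_name in ("identity", "polarity", "volume"):
        scheme = SCHEMES[scheme_name]
        fb = position_frequencies(binders, scheme, alpha)
        fn = position_frequencies(nonbinders, scheme, alpha)
        out[f"{scheme_name}_bg"] = build_background_pssm(fb, background)
        out[f"{scheme_name}_nb"] = build_nonbinder_pssm(fb, fn)
    return out
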