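"""Curated motif tables: loading, validation, anchor location.

LC8-binding motifs are eight residues long, numbered -5..+2 with the
anchor glutamine slot at position 0.  The training data are two classes of
labelled peptides: binders (direct interaction data, dissociation constant
at or below 25 uM where measured) and anchor-containing nonbinders
(peptides carrying a TQT-like triplet that showed no binding by ITC).

Tables are plain TSV with columns
``protein_id  gene  peptide  q_index  label  kd_um  source``; ``q_index``
is the 1-based position of the anchor glutamine slot within ``peptide``.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .alphabet import AMINO_ACIDS, AlphabetError, MOTIF_LENGTH

LABELS = ("binder", "weak_binder", "nonbinder")
SOURCES = ("Table1", "Table2", "TableS4", "LC8Hub", "user")

#: Default anchor triplet: [ST]Q[ST] spanning motif positions -1..+1.
DEFAULT_ANCHOR = r"[ST]Q[ST]"
#: Extended pattern admitting the documented variants: I/V at the
#: flanking positions and M in the glutamine slot (the Myosin Va "TMT").
EXTENDED_ANCHOR = r"[STIV][QM][STIV]"

KD_CUTOFF_UM = 25.0


class ParseError(ValueError):
    """A fixture row could not be parsed; message names file and line."""


class ConsistencyError(ValueError):
    """The same motif appears in conflicting classes."""


class FlankError(ValueError):
    """A peptide is too short on one side of the anchor for a full motif."""


@dataclass(frozen=True)
class MotifRecord:
    """One labelled 8-residue motif with its peptide context."""

    protein_id: str
    gene: str
    peptide: str
    q_index: int  # 1-based position of the anchor glutamine slot
    label: str
    kd_um: float | None = None
    source: str = "user"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.kd_um is not None and not self.kd_um > 0:
            raise ValueError(f"kd_um must be positive, got {self.kd_um}")
        bad = [a for a in self.peptide if a not in AMINO_ACIDS]
        if bad:
            raise AlphabetError(f"nonstandard residue(s) {bad} in {self.protein_id}")
        # raises FlankError if the peptide is short on either side
        extract_motif(self.peptide, self.q_index)

    @property
    def motif(self) -> str:
        """The 8-mer covering positions -5..+2."""
        return extract_motif(self.peptide, self.q_index)


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Residue background probabilities for disordered regions."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        if sorted(self.freq) != sorted(AMINO_ACIDS):
            raise ValueError("background table must cover exactly the 20 standard residues")
        if any(not 0.0 < f < 1.0 for f in self.freq.values()):
            raise ValueError("background frequencies must lie in (0, 1)")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")

    def __getitem__(self, residue: str) -> float:
        return self.freq[residue]


class TrainingSet:
    """Binder and anchor-containing nonbinder records.

    ``binders``/``nonbinders`` keep every loaded record (duplicates from
    independently synthesized peptides included); ``binder_motifs`` /
    ``nonbinder_motifs`` are the deduplicated motif lists used to build
    matrices, where no (protein_id, motif) pair repeats within a class.
    Records labelled ``weak_binder`` are retained for reporting only and
    enter neither class.
    """

    def __init__(self, records: Iterable[MotifRecord]):
        self.records: list[MotifRecord] = list(records)
        self.binders = [r for r in self.records if r.label == "binder"]
        self.weak_binders = [r for r in self.records if r.label == "weak_binder"]
        self.nonbinders = [r for r in self.records if r.label == "nonbinder"]
        motif_class: dict[str, str] = {}
        for r in self.binders + self.nonbinders:
            prev = motif_class.setdefault(r.motif, r.label)
            if prev != r.label:
                raise ConsistencyError(
                    f"motif {r.motif!r} ({r.protein_id}) appears as both {prev} and {r.label}"
                )

    @staticmethod
    def _dedup(records: Sequence[MotifRecord]) -> list[MotifRecord]:
        seen: set[tuple[str, str]] = set()
        out = []
        for r in records:
            key = (r.protein_id, r.motif)
            if key in seen:
                continue
            seen.add(key)
            out.append(r)
        return out

    @property
    def binder_records(self) -> list[MotifRecord]:
        return self._dedup(self.binders)

    @property
    def nonbinder_records(self) -> list[MotifRecord]:
        return self._dedup(self.nonbinders)

    @property
    def binder_motifs(self) -> list[str]:
        return [r.motif for r in self.binder_records]

    @property
    def nonbinder_motifs(self) -> list[str]:
        return [r.motif for r in self.nonbinder_records]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TrainingSet({len(self.binders)} binders, {len(self.weak_binders)} weak, "
            f"{len(self.nonbinders)} nonbinders)"
        )


def find_anchor(peptide: str, pattern: str = DEFAULT_ANCHOR) -> list[int]:
    """1-based positions of the anchor glutamine slot in ``peptide``.

    A position ``q`` is reported when the triplet ``peptide[q-1 .. q+1]``
    matches ``pattern`` (a three-residue regular expression).  Overlapping
    matches are all reported; an empty list is a valid result.
    """
    if len(peptide) < 3:
        raise ValueError("peptide must have length >= 3")
    rx = re.compile(pattern)
    hits = []
    for i in range(len(peptide) - 2):
        if rx.fullmatch(peptide[i : i + 3]):
            hits.append(i + 2)  # 1-based position of the middle residue
    return hits


def extract_motif(peptide: str, q_index: int) -> str:
    """Slice the 8-mer at positions ``q_index-5 .. q_index+2`` (1-based)."""
    if q_index - 5 < 1:
        raise FlankError(
            f"N-terminal flank too short: need 5 residues before position {q_index}"
        )
    if q_index + 2 > len(peptide):
        raise FlankError(
            f"C-terminal flank too short: need 2 residues after position {q_index} "
            f"in a peptide of length {len(peptide)}"
        )
    motif = peptide[q_index - 6 : q_index + 2]
    assert len(motif) == MOTIF_LENGTH
    return motif


def filter_by_affinity(
    records: Sequence[MotifRecord], max_kd_um: float = KD_CUTOFF_UM
) -> list[MotifRecord]:
    """Drop records whose dissociation constant exceeds ``max_kd_um``.

    The boundary is inclusive (a record at exactly the cutoff is kept) and
    records without a measured K_d are retained.
    """
    return [r for r in records if r.kd_um is None or r.kd_um <= max_kd_um]


def _parse_row(row: dict, path: str, lineno: int) -> MotifRecord:
    try:
        kd_raw = (row.get("kd_um") or "").strip()
        return MotifRecord(
            protein_id=row["protein_id"].strip(),
            gene=row["gene"].strip(),
            peptide=row["peptide"].strip(),
            q_index=int(row["q_index"]),
            label=row["label"].strip(),
            kd_um=float(kd_raw) if kd_raw else None,
            source=row["source"].strip(),
        )
    except (KeyError, TypeError, ValueError, AlphabetError, FlankError) as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def load_motif_table(path: str | Path) -> list[MotifRecord]:
    """Read one TSV motif table; ``#`` lines are comments."""
    path = Path(path)
    records: list[MotifRecord] = []
    with open(path, newline="") as fh:
        lines = [(i + 1, ln) for i, ln in enumerate(fh) if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    reader = csv.DictReader((ln for _, ln in lines), delimiter="\t")
    if reader.fieldnames is None or "peptide" not in reader.fieldnames:
        raise ParseError(f"{path}: missing header row")
    linenos = iter(no for no, _ in lines[1:])
    for row in reader:
        records.append(_parse_row(row, str(path), next(linenos)))
    if not records:
        raise ParseError(f"{path}: no data rows")
    return records


def load_training_tables(paths: Sequence[str | Path]) -> TrainingSet:
    """Load and merge motif tables into a validated :class:`TrainingSet`."""
    records: list[MotifRecord] = []
    for p in paths:
        records.extend(load_motif_table(p))
    training = TrainingSet(records)
    over = [r for r in training.binders if r.kd_um is not None and r.kd_um > KD_CUTOFF_UM]
    if over:
        warnings.warn(
            f"{len(over)} binder record(s) exceed the {KD_CUTOFF_UM} uM inclusion "
            "cutoff and should be relabelled weak_binder",
            stacklevel=2,
        )
    return training


# ---------------------------------------------------------------------------
# Packaged fixtures

def _data_path(name: str) -> Path:
    return Path(resources.files("lc8motif.data") / name)


def load_packaged_training() -> TrainingSet:
    """The packaged training table: 79 binder and 32 nonbinder motifs."""
    return load_training_tables([_data_path("training_table_synthetic.tsv")])


def load_packaged_background() -> BackgroundFrequencies:
    """The packaged disordered-region residue background."""
    return load_background(_data_path("background_disorder_synthetic.tsv"))


def load_background(path: str | Path) -> BackgroundFrequencies:
    """Read a two-column (residue, frequency) TSV background table."""
    freq: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("residue"):
                continue
            try:
                residue, value = line.split("\t")
                freq[residue] = float(value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return BackgroundFrequencies(freq)
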