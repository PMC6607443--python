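"""Sliding-window scanning of protein sequences.

Every 8-residue window of a sequence is scored and tiered; the reported
coordinate is the 1-based position of the window's anchor-glutamine slot
(motif position 0, i.e. window offset + 5).  Hits inside ordered regions
can be removed with an external per-residue disorder-propensity track.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .alphabet import AMINO_ACIDS, MOTIF_LENGTH
from .scoring import MatrixSet, classify, is_predicted_binder, score_motif

logger = logging.getLogger(__name__)

#: Windows whose mean disorder propensity falls below this are considered
#: ordered and removed by the default disorder filter.
DEFAULT_DISORDER_THRESHOLD = 0.5

REPORT_COLUMNS = (
    "sequence_id", "q_position", "window",
    "s_aa", "s_vp", "s_aa_norm", "s_vp_norm", "tier", "mean_disorder",
)


@dataclass(frozen=True)
class ScanHit:
    """One scored sliding-window position."""

    sequence_id: str
    q_position: int  # 1-based position of motif position 0 in the sequence
    window: str
    s_aa: float
    s_vp: float
    s_aa_norm: float
    s_vp_norm: float
    tier: str
    mean_disorder: float | None = None

    def to_row(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "q_position": self.q_position,
            "window": self.window,
            "s_aa": f"{self.s_aa:.4f}",
            "s_vp": f"{self.s_vp:.4f}",
            "s_aa_norm": f"{self.s_aa_norm:.4f}",
            "s_vp_norm": f"{self.s_vp_norm:.4f}",
            "tier": self.tier,
            "mean_disorder": "" if self.mean_disorder is None else f"{self.mean_disorder:.4f}",
        }


def scan_sequence(
    seq: str,
    mset: MatrixSet,
    sequence_id: str = "seq",
    report: str = "all",
) -> list[ScanHit]:
    """Score every full 8-mer window of ``seq``.

    Windows containing a nonstandard symbol (X, U, B, Z, ...) are skipped —
    a zero score would be a statement about the sequence, a skip is not —
    and the skip count is logged.  In ``above_threshold`` mode only windows
    tiered ``binder`` or ``high_confidence`` are returned.
    """
    if report not in ("all", "above_threshold"):
        raise ValueError(f"unknown report mode {report!r}")
    hits: list[ScanHit] = []
    skipped = 0
    for offset in range(len(seq) - MOTIF_LENGTH + 1):
        window = seq[offset : offset + MOTIF_LENGTH]
        if any(a not in AMINO_ACIDS for a in window):
            skipped += 1
            continue
        pair = score_motif(window, mset)
        tier = classify(pair, mset)
        if report == "above_threshold" and not is_predicted_binder(tier):
            continue
        hits.append(
            ScanHit(
                sequence_id=sequence_id,
                q_position=offset + 6,  # window offset (0-based) + position of Q slot
                window=window,
                s_aa=pair.s_aa,
                s_vp=pair.s_vp,
                s_aa_norm=pair.s_aa_norm,
                s_vp_norm=pair.s_vp_norm,
                tier=tier,
            )
        )
    if skipped:
        logger.info("%s: skipped %d window(s) with nonstandard symbols", sequence_id, skipped)
    return hits


def window_mean_disorder(hit: ScanHit, disorder: Sequence[float]) -> float:
    """Mean disorder propensity over the hit's 8 window residues."""
    start = hit.q_position - 6  # 0-based window start
    values = disorder[start : start + MOTIF_LENGTH]
    return float(sum(values)) / MOTIF_LENGTH


def apply_disorder_filter(
    hits: Sequence[ScanHit],
    disorder: Sequence[float],
    theta_dis: float = DEFAULT_DISORDER_THRESHOLD,
    sequence_length: int | None = None,
) -> list[ScanHit]:
    """Remove hits whose window mean disorder falls below ``theta_dis``.

    ``disorder`` is a per-residue track aligned to the scanned sequence;
    its length must equal the sequence length when that is known.  The
    window mean is recorded on every hit (survivors and, via the returned
    annotated list's complement, removals).
    """
    if sequence_length is not None and len(disorder) != sequence_length:
        raise ValueError(
            f"disorder track length {len(disorder)} != sequence length {sequence_length}"
        )
    annotated = [
        replace(h, mean_disorder=window_mean_disorder(h, disorder)) for h in hits
    ]
    for h in annotated:
        if h.q_position + 2 > len(disorder):
            raise ValueError(
                f"disorder track too short for hit at q_position {h.q_position}"
            )
    return [h for h in annotated if h.mean_disorder >= theta_dis]


def annotate_disorder(hits: Sequence[ScanHit], disorder: Sequence[float]) -> list[ScanHit]:
    """Record each hit's window mean disorder without filtering."""
    return [replace(h, mean_disorder=window_mean_disorder(h, disorder)) for h in hits]


def load_disorder_track(path: str | Path) -> dict[str, list[float]]:
    """Read a per-residue disorder TSV with columns (id, position, value)."""
    tracks: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "id":
                continue
            seq_id, pos, value = row[0], int(row[1]), float(row[2])
            tracks.setdefault(seq_id, {})[pos] = value
    out: dict[str, list[float]] = {}
    for seq_id, values in tracks.items():
        n = max(values)
        if sorted(values) != list(range(1, n + 1)):
            raise ValueError(f"disorder track for {seq_id!r} has gaps in positions")
        out[seq_id] = [values[i] for i in range(1, n + 1)]
    return out


def scan_fasta(
    fasta_path: str | Path,
    mset: MatrixSet,
    out_path: str | Path,
    report: str = "above_threshold",
    disorder_tracks: Mapping[str, Sequence[float]] | None = None,
    theta_dis: float = DEFAULT_DISORDER_THRESHOLD,
) -> Path:
    """Scan every record of a FASTA file and write a TSV hit report."""
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise IOError(f"{fasta_path}: no FASTA records")
    seen: set[str] = set()
    all_hits: list[ScanHit] = []
    n_scanned = 0
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{fasta_path}: duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("%s: empty sequence record %r skipped", fasta_path, rec.id)
            continue
        n_scanned += 1
        hits = scan_sequence(seq, mset, sequence_id=rec.id, report=report)
        if disorder_tracks is not None and rec.id in disorder_tracks:
            track = disorder_tracks[rec.id]
            if len(track) != len(seq):
                raise ValueError(
                    f"disorder track length {len(track)} != length of {rec.id!r} ({len(seq)})"
                )
            hits = apply_disorder_filter(hits, track, theta_dis, sequence_length=len(seq))
        all_hits.extend(hits)
    out_path = Path(out_path)
    with open(out_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, delimiter="\t")
        writer.writeheader()
        for h in all_hits:
            writer.writerow(h.to_row())
    logger.info(
        "scanned %d sequence(s): %d reported window(s)", n_scanned, len(all_hits)
    )
    return out_path
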