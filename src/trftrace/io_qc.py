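"""FASTA/FASTQ input/output and the small-RNA quality-control pipeline.

The QC stages run in a fixed order — quality filter, residual-adapter
removal, background (medium) subtraction, length filter, end trimming —
mirroring how co-culture small RNA-seq datasets are cleaned before any
genome matching: reads must be mostly high-quality bases, free of leftover
sequencing adapters, absent from the growth-medium control, 16-50 nt long,
and finally trimmed by 1 nt at the 5' end and 3 nt at the 3' end to strip
ligation and polyadenylation artifacts (yielding 12-46 nt cores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ReadRecord, ReadSet

__all__ = [
    "QcParams",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "quality_filter",
    "strip_residual_adapters",
    "subtract_background",
    "length_filter",
    "trim_ends",
    "run_qc",
]

logger = logging.getLogger(__name__)

#: Phred score written out when a read carries no quality model ('I' = Q40).
DEFAULT_QUALITY = 40


class ParseError(ValueError):
    """A malformed FASTA/FASTQ record, reported with its 0-based index."""


@dataclass
class QcParams:
    """Thresholds of the QC pipeline.

    quality_cutoff / min_fraction_at_cutoff: keep a read only if at least
    this fraction of its bases reach the Phred cutoff (defaults: >=90% of
    bases at Q20).
    adapter_min_match: a read is discarded when any ``adapter_min_match``
    consecutive nucleotides of an adapter occur in it (default 13 nt).
    length_min/length_max: inclusive read-length window after filtering.
    trim5/trim3: bases removed from the 5' and 3' ends after all filters.
    """

    quality_cutoff: int = 20
    min_fraction_at_cutoff: float = 0.90
    adapter_seqs: list[str] = field(default_factory=list)
    adapter_min_match: int = 13
    length_min: int = 16
    length_max: int = 50
    trim5: int = 1
    trim3: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction_at_cutoff <= 1):
            raise ValueError("min_fraction_at_cutoff must be in (0, 1]")
        if self.adapter_min_match < 1:
            raise ValueError("adapter_min_match must be >= 1")
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trims must be nonnegative")


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, provenance: str = "cellular") -> ReadSet:
    reads: ReadSet = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            reads.append(ReadRecord(rec.id, str(rec.seq), provenance=provenance))
        except ValueError as exc:
            raise ParseError(f"record {i}: {exc}") from exc
    return reads


def read_fastq(path: str | Path, provenance: str = "cellular") -> ReadSet:
    reads: ReadSet = []
    it = SeqIO.parse(str(path), "fastq")
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except ValueError as exc:  # Biopython: seq/quality length mismatch etc.
            raise ParseError(f"record {i}: {exc}") from exc
        quals = list(rec.letter_annotations["phred_quality"])
        try:
            reads.append(ReadRecord(rec.id, str(rec.seq), quals, provenance))
        except ValueError as exc:
            raise ParseError(f"record {i}: {exc}") from exc
        i += 1
    return reads


def _to_seqrecord(r: ReadRecord, with_quality: bool) -> SeqRecord:
    rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
    if with_quality:
        quals = r.qualities if r.qualities is not None else [DEFAULT_QUALITY] * len(r)
        rec.letter_annotations["phred_quality"] = quals
    return rec


def write_fasta(reads: ReadSet, path: str | Path) -> None:
    SeqIO.write((_to_seqrecord(r, False) for r in reads), str(path), "fasta")


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    SeqIO.write((_to_seqrecord(r, True) for r in reads), str(path), "fastq")


# ---------------------------------------------------------------------------
# Filters


def quality_filter(reads: ReadSet, p: QcParams) -> ReadSet:
    """Keep reads whose fraction of bases at >= quality_cutoff meets the bar."""
    out: ReadSet = []
    for r in reads:
        if r.qualities is None:
            raise ValueError(f"read {r.id!r}: quality filter requires Phred qualities")
        good = sum(q >= p.quality_cutoff for q in r.qualities)
        if good / len(r) >= p.min_fraction_at_cutoff:
            out.append(r)
    return out


def _adapter_windows(p: QcParams) -> set[str]:
    windows: set[str] = set()
    for ad in p.adapter_seqs:
        ad = ad.upper()
        if len(ad) < p.adapter_min_match:
            raise ValueError(
                f"adapter {ad!r} shorter than adapter_min_match={p.adapter_min_match}"
            )
        windows.update(
            ad[i : i + p.adapter_min_match]
            for i in range(len(ad) - p.adapter_min_match + 1)
        )
    return windows

def _first_adapter_pos(seq: str, windows: set[str], w: int) -> int:
    for i in range(len(seq) - w + 1):
        if seq[i : i + w] in windows:
            return i
    return -1


def strip_residual_adapters(reads: ReadSet, p: QcParams, clip: bool = False) -> ReadSet:
    """Drop (default) or clip reads containing a residual adapter stretch.

    A match is any run of ``adapter_min_match`` consecutive adapter
    nucleotides found exactly in the read; a run of >= that length always
    contains such a window, so only windows of exactly that size are
    scanned. With ``clip=True`` the read is truncated at the leftmost match
    instead of removed (and dropped only if nothing remains).
    """
    if not p.adapter_seqs:
        raise ValueError("adapter_seqs must be non-empty")
    windows = _adapter_windows(p)
    w = p.adapter_min_match
    out: ReadSet = []
    for r in reads:
        pos = _first_adapter_pos(r.sequence, windows, w)
        if pos < 0:
            out.append(r)
        elif clip and pos > 0:
            out.append(
                ReadRecord(
                    r.id,
                    r.sequence[:pos],
                    r.qualities[:pos] if r.qualities is not None else None,
                    r.provenance,
                )
            )
    return out


def subtract_background(reads: ReadSet, control: ReadSet) -> ReadSet:
    """Remove reads whose sequence occurs verbatim in the control set."""
    control_seqs = {c.sequence for c in control}
    return [r for r in reads if r.sequence not in control_seqs]


def length_filter(reads: ReadSet, min_nt: int, max_nt: int) -> ReadSet:
    return [r for r in reads if min_nt <= len(r) <= max_nt]


def trim_ends(reads: ReadSet, trim5: int, trim3: int) -> ReadSet:
    """Remove trim5 leading and trim3 trailing bases (qualities in lockstep).

    Reads too short to survive trimming are dropped and counted in the log,
    not raised.
    """
    out: ReadSet = []
    dropped = 0
    for r in reads:
        if len(r) <= trim5 + trim3:
            dropped += 1
            continue
        stop = len(r) - trim3
        quals = r.qualities[trim5:stop] if r.qualities is not None else None
        out.append(ReadRecord(r.id, r.sequence[trim5:stop], quals, r.provenance))
    if dropped:
        logger.info("trim_ends: dropped %d reads shorter than trims", dropped)
    return out


def run_qc(
    reads: ReadSet,
    p: QcParams,
    control: ReadSet | None = None,
    clip: bool = False,
) -> tuple[ReadSet, pd.DataFrame]:
    """Full pipeline: quality -> adapter -> background -> length -> trim.

    Returns the surviving reads and a per-stage report (stage, reads_in,
    reads_out). Stages without configuration (no qualities needed / no
    adapters / no control) are recorded as pass-through.
    """
    stages: list[tuple[str, int, int]] = []

    def step(name, func, current):
        after = func(current)
        stages.append((name, len(current), len(after)))
        return after

    cur = reads
    if reads and reads[0].qualities is not None:
        cur = step("quality", lambda rs: quality_filter(rs, p), cur)
    else:
        stages.append(("quality", len(cur), len(cur)))
    if p.adapter_seqs:
        cur = step("adapter", lambda rs: strip_residual_adapters(rs, p, clip), cur)
    else:
        stages.append(("adapter", len(cur), len(cur)))
    if control is not None:
        cur = step("background", lambda rs: subtract_background(rs, control), cur)
    else:
        stages.append(("background", len(cur), len(cur)))
    cur = step("length", lambda rs: length_filter(rs, p.length_min, p.length_max), cur)
    cur = step("trim", lambda rs: trim_ends(rs, p.trim5, p.trim3), cur)

    report = pd.DataFrame(stages, columns=["stage", "reads_in", "reads_out"])
    logger.info("qc pipeline:\n%s", report.to_string(index=False))
    return cur, report
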