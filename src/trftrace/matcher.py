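"""Exhaustive k-mismatch matching of short reads against genomes.

A read "matches" a genome when some window on either strand is within a
bounded Hamming distance (0-3 mismatches) of it. Reads from a co-culture
experiment are classified exclusively as HOST_ONLY / ALIEN_ONLY / COMMON /
UNMATCHED by whether they match the host genome, the cohabitant ("alien")
genome, both, or neither. Matching is exhaustive: every window on both
strands is scanned, so the hit list is complete by construction.

Bottom-strand hits are located by comparing the reverse complement of the
read against top-strand windows, so positions are always top-strand
0-based coordinates of the leftmost matched base.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import Genome, ReadSet, encode_read, revcomp

__all__ = [
    "Category",
    "MatchHit",
    "ClassificationResult",
    "match_read",
    "has_match",
    "classify_reads",
    "remove_host_like",
]

logger = logging.getLogger(__name__)

MAX_MISMATCH_LIMIT = 3


class Category(str, Enum):
    HOST_ONLY = "HOST_ONLY"
    ALIEN_ONLY = "ALIEN_ONLY"
    COMMON = "COMMON"
    UNMATCHED = "UNMATCHED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MatchHit:
    """One placement of a read on a genome within the mismatch budget."""

    genome_id: str
    position: int  # 0-based, leftmost matched base, top strand
    strand: str  # "+" or "-"
    mismatches: int


def _check_max_mismatch(max_mismatch: int) -> None:
    if not (0 <= max_mismatch <= MAX_MISMATCH_LIMIT):
        raise ValueError(f"max_mismatch must be in [0, {MAX_MISMATCH_LIMIT}]")


def _window_mismatches(read_arr: np.ndarray, genome: Genome) -> np.ndarray:
    """Hamming distance of the read to every genome window (vector of length
    L - l + 1)."""
    windows = sliding_window_view(genome.arr, len(read_arr))
    return (windows != read_arr).sum(axis=1)


def match_read(read: str, genome: Genome, max_mismatch: int) -> list[MatchHit]:
    """Every position on either strand within `max_mismatch` of the read.

    N in the read or genome always counts as a mismatch. A read longer than
    the genome yields an empty list with a warning.
    """
    _check_max_mismatch(max_mismatch)
    if len(read) > len(genome):
        warnings.warn(
            f"read of length {len(read)} longer than genome {genome.id!r}; no hits",
            stacklevel=2,
        )
        return []
    hits: list[MatchHit] = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        mm = _window_mismatches(encode_read(seq), genome)
        for pos in np.flatnonzero(mm <= max_mismatch):
            hits.append(MatchHit(genome.id, int(pos), strand, int(mm[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def min_mismatches(read: str, genome: Genome) -> int:
    """Smallest Hamming distance of the read to any window on either strand
    (len(read) + 1, i.e. worse than any budget, if the read is too long).

    Exact occurrences are resolved by substring search before any distance
    is computed; inexact reads fall back to an offset-accumulation scan
    (one vectorized pass per read offset over all windows).
    """
    if len(read) > len(genome):
        return len(read) + 1
    if "N" not in read and (read in genome.seq or read in genome.rc_seq):
        return 0
    best = len(read) + 1
    n = len(genome) - len(read) + 1
    for seq in (read, revcomp(read)):
        r = encode_read(seq)
        acc = np.zeros(n, dtype=np.int32)
        for j in range(len(r)):
            acc += genome.arr[j : j + n] != r[j]
        best = min(best, int(acc.min()))
    return best


def has_match(read: str, genome: Genome, max_mismatch: int) -> bool:
    _check_max_mismatch(max_mismatch)
    return min_mismatches(read, genome) <= max_mismatch


@dataclass
class ClassificationResult:
    """Exclusive partition of a read set against a (host, alien) genome pair."""

    read_ids: list[str]
    categories: list[Category]
    max_mismatch: int
    host_id: str
    alien_id: str

    @property
    def denominator(self) -> int:
        return len(self.categories)

    @property
    def counts(self) -> dict[Category, int]:
        c = {cat: 0 for cat in Category}
        for cat in self.categories:
            c[cat] += 1
        return c

    @property
    def percentages(self) -> dict[Category, float]:
        n = self.denominator
        return {cat: (100.0 * k / n if n else float("nan")) for cat, k in self.counts.items()}

    def per_read_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"read_id": self.read_ids, "category": [c.value for c in self.categories]}
        )

    def summary_frame(self) -> pd.DataFrame:
        counts, pcts = self.counts, self.percentages
        return pd.DataFrame(
            {
                "category": [c.value for c in Category],
                "count": [counts[c] for c in Category],
                "percent": [pcts[c] for c in Category],
            }
        )


def classify_reads(
    reads: ReadSet, host: Genome, alien: Genome, max_mismatch: int
) -> ClassificationResult:
    """Sort reads into HOST_ONLY / ALIEN_ONLY / COMMON / UNMATCHED.

    The same mismatch budget applies to both genomes; run
    :func:`remove_host_like` separately for the asymmetric host-removal
    step used when hunting imported RNAs.
    """
    _check_max_mismatch(max_mismatch)
    cats: list[Category] = []
    for r in reads:
        in_host = has_match(r.sequence, host, max_mismatch)
        in_alien = has_match(r.sequence, alien, max_mismatch)
        if in_host and in_alien:
            cats.append(Category.COMMON)
        elif in_host:
            cats.append(Category.HOST_ONLY)
        elif in_alien:
            cats.append(Category.ALIEN_ONLY)
        else:
            cats.append(Category.UNMATCHED)
    return ClassificationResult([r.id for r in reads], cats, max_mismatch, host.id, alien.id)


def remove_host_like(reads: ReadSet, host: Genome, max_mismatch: int = 1) -> ReadSet:
    """Drop every read placeable on the host genome within `max_mismatch`.

    Survivors are candidates for alien origin or permutation analysis; the
    default budget of 1 also removes the background of sequencing errors
    and single-nucleotide polymorphisms over host sequences.
    """
    _check_max_mismatch(max_mismatch)
    return [r for r in reads if not has_match(r.sequence, host, max_mismatch)]
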