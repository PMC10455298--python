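"""Marker-12-mer tRF read collection and 5'/3'-end profiling.

To trace fragments of a specific tRNA in a read pool dominated by host
sequences, the tRF's sequence context is decomposed into k-mers (k = 12 by
default) and only those absent from the host genome on both strands are
kept as markers. Any read containing a marker is attributed to the tRF.
The positional distribution of the 5'- and 3'-ends of those reads along
the reference then distinguishes endonucleolytic processing (sharp fixed
ends) from exonucleolytic decay (smeared ends).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Genome, ReadSet, kmer_set

__all__ = [
    "MarkerSet",
    "EndProfile",
    "derive_markers",
    "collect_trf_reads",
    "profile_ends",
    "compare_profiles",
    "ProfileComparison",
]


@dataclass(frozen=True)
class MarkerSet:
    """k-mers unique to a tRF context (absent from the excluded genome)."""

    trf_id: str
    k: int
    markers: frozenset[str]

    def __post_init__(self) -> None:
        if any(len(m) != self.k for m in self.markers):
            raise ValueError("all markers must have length k")


def derive_markers(
    trf_context: str, excluded: Genome, k: int = 12, trf_id: str = "trf"
) -> MarkerSet:
    """k-mers of the tRF context occurring nowhere in `excluded` (either strand).

    Emits a warning (the tRF is untraceable) when no marker survives.
    """
    trf_context = trf_context.upper()
    if len(trf_context) < k:
        raise ValueError(f"tRF context shorter than k={k}")
    context_kmers = kmer_set(trf_context, k)
    genome_kmers = kmer_set(excluded.seq, k, both_strands=True)
    markers = frozenset(context_kmers - genome_kmers)
    if not markers:
        warnings.warn(
            f"tRF {trf_id!r}: no unique {k}-mer versus genome {excluded.id!r}; untraceable",
            stacklevel=2,
        )
    return MarkerSet(trf_id, k, markers)


def collect_trf_reads(reads: ReadSet, markers: MarkerSet) -> ReadSet:
    """Retain reads containing at least one marker k-mer as a substring."""
    if not markers.markers:
        raise ValueError(f"marker set for {markers.trf_id!r} is empty")
    k = markers.k
    mset = markers.markers
    out = []
    for r in reads:
        s = r.sequence
        if any(s[i : i + k] in mset for i in range(len(s) - k + 1)):
            out.append(r)
    return out


@dataclass
class EndProfile:
    """Counts of read 5'- and 3'-ends per reference position (0-based).

    The 3' coordinate is the last base of the read (closed), so a
    full-length read contributes counts5[0] and counts3[L-1]. Reads not
    found verbatim in the reference, or outside the length window, are
    tallied in `n_unplaced` and excluded from the profile denominators.
    """

    trf_id: str
    reference: str
    counts5: np.ndarray
    counts3: np.ndarray
    n_reads: int
    n_unplaced: int = 0
    n_ambiguous: int = 0

    @property
    def pct5(self) -> np.ndarray:
        return 100.0 * self.counts5 / self.n_reads if self.n_reads else self.counts5 * np.nan

    @property
    def pct3(self) -> np.ndarray:
        return 100.0 * self.counts3 / self.n_reads if self.n_reads else self.counts3 * np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.reference)),
                "base": list(self.reference),
                "count5": self.counts5,
                "pct5": self.pct5,
                "count3": self.counts3,
                "pct3": self.pct3,
            }
        )


def profile_ends(
    trf_reads: ReadSet,
    reference: str,
    min_len: int = 12,
    max_len: int = 50,
    trf_id: str = "trf",
) -> EndProfile:
    """Place each read at its leftmost exact occurrence in the reference and
    count its end positions.

    Reads with multiple exact occurrences (repeats) are placed leftmost and
    counted in `n_ambiguous` as well. The default 12-50 nt window spans the
    39 length groups a small-RNA experiment retains after trimming.
    """
    reference = reference.upper()
    L = len(reference)
    counts5 = np.zeros(L, dtype=int)
    counts3 = np.zeros(L, dtype=int)
    n_reads = n_unplaced = n_ambiguous = 0
    for r in trf_reads:
        ell = len(r)
        if not (min_len <= ell <= max_len):
            n_unplaced += 1
            continue
        start = reference.find(r.sequence)
        if start < 0:
            n_unplaced += 1
            continue
        if reference.find(r.sequence, start + 1) >= 0:
            n_ambiguous += 1
        counts5[start] += 1
        counts3[start + ell - 1] += 1
        n_reads += 1
    return EndProfile(trf_id, reference, counts5, counts3, n_reads, n_unplaced, n_ambiguous)


@dataclass
class ProfileComparison:
    """Per-position percentage differences between two end profiles."""

    deltas: pd.DataFrame  # position, d5, d3, flagged5, flagged3
    peaks: pd.DataFrame  # profile, end, position, pct


def _peaks(pct: np.ndarray, min_pct: float) -> list[int]:
    """Local maxima at or above min_pct (plateaus report their left edge)."""
    out = []
    for i, v in enumerate(pct):
        if v < min_pct:
            continue
        left = pct[i - 1] if i > 0 else -np.inf
        right = pct[i + 1] if i + 1 < len(pct) else -np.inf
        if v > left and v >= right:
            out.append(i)
    return out


def compare_profiles(
    a: EndProfile, b: EndProfile, threshold: float = 5.0, min_peak_pct: float = 5.0
) -> ProfileComparison:
    """Positions where two profiles disagree by more than `threshold`
    percentage points, plus the peak table of both."""
    if a.reference != b.reference:
        raise ValueError("profiles are over different references")
    d5 = a.pct5 - b.pct5
    d3 = a.pct3 - b.pct3
    deltas = pd.DataFrame(
        {
            "position": np.arange(len(a.reference)),
            "d5": d5,
            "d3": d3,
            "flagged5": np.abs(d5) > threshold,
            "flagged3": np.abs(d3) > threshold,
        }
    )
    rows = []
    for label, prof in (("a", a), ("b", b)):
        for end, pct in (("5p", prof.pct5), ("3p", prof.pct3)):
            for pos in _peaks(np.asarray(pct, dtype=float), min_peak_pct):
                rows.append((label, end, pos, float(pct[pos])))
    peaks = pd.DataFrame(rows, columns=["profile", "end", "position", "pct"])
    return ProfileComparison(deltas, peaks)
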