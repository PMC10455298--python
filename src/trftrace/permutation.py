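"""Detection of circularly permuted reads (rotations of genomic segments).

A linear RNA fragment that circularizes and is re-cleaved at a new site
yields a read whose sequence is a rotation of a contiguous genomic
segment: read = segment[c:] + segment[:c]. Such reads fail exact genome
matching but can be recognized in two steps:

1. remove every read occurring verbatim in any genome (either strand);
   the survivor count is the "unmapped" denominator;
2. for each survivor, anchor its first 12-mer on the genome, extend the
   match greedily to the maximal prefix length m, and test whether the
   remaining suffix (the relocated segment, s = len - m nt) matches the
   genome immediately upstream of the anchor. The bottom strand is
   scanned by applying the same test to the reverse complement of the
   read, with coordinates reported on the top strand. Reads deviating
   from the genome anywhere besides the single junction are ignored.

The junction coordinate (anchor p, where the relocated segment abuts the
matched prefix) is the ligation site (LS); the locus left border p - s is
emitted alongside, since both borders describe the permuted locus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from .core import Genome, ReadSet, revcomp

__all__ = [
    "PermutationHit",
    "PermutationSummary",
    "remove_exact_matches",
    "find_permutation",
    "detect_permutations",
    "permutation_frequency",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 12
DEFAULT_MIN_TRANSFER = 5  # study setting; the algorithm itself allows 4
MIN_TRANSFER_FLOOR = 4


@dataclass(frozen=True)
class PermutationHit:
    """One read explained as a rotation of a contiguous genomic segment.

    For the oriented read (reverse complement when strand is '-'):
    ``oriented == g[anchor : anchor+matched_prefix] + g[anchor-relocated_len : anchor]``.
    The locus [locus_start, locus_end) is the contiguous segment whose
    rotation equals the read; ligation_site is the anchor coordinate.
    """

    read_id: str
    read_seq: str
    genome_id: str
    strand: str  # "+" or "-"
    anchor: int  # p: top-strand coordinate of the oriented read's first base
    matched_prefix: int  # m
    relocated_len: int  # s
    locus_start: int  # p - s
    locus_end: int  # p + m
    ligation_site: int  # = anchor
    copies: int = 1

    def __post_init__(self) -> None:
        if self.matched_prefix + self.relocated_len != len(self.read_seq):
            raise ValueError("m + s must equal read length")
        if self.locus_end - self.locus_start != len(self.read_seq):
            raise ValueError("locus length must equal read length")


@dataclass
class PermutationSummary:
    """Dataset-level tally of permuted reads among unmapped reads.

    frequency = deduplicated permuted-read count / unmapped-read count;
    display_scale is that frequency as a percentage multiplied by a further
    100 (i.e. frequency x 10,000), the conventional plotting scale for
    these rare events. Identical read sequences hitting several loci
    (paralogous genes) count once in read-level tallies.
    """

    n_unmapped: int
    n_permuted_reads: int
    n_unique_oligos: int
    length_distribution: dict[int, int] = field(default_factory=dict)
    locus_table: pd.DataFrame | None = None

    @property
    def frequency(self) -> float | None:
        if self.n_unmapped == 0:
            return None  # undefined; reported as missing
        return self.n_permuted_reads / self.n_unmapped

    @property
    def percent(self) -> float | None:
        f = self.frequency
        return None if f is None else 100.0 * f

    @property
    def display_scale(self) -> float | None:
        p = self.percent
        return None if p is None else 100.0 * p


def remove_exact_matches(reads: ReadSet, genomes: list[Genome]) -> ReadSet:
    """Drop reads occurring verbatim in any genome on either strand."""
    texts = [(g.seq, g.rc_seq) for g in genomes]
    out = []
    for r in reads:
        s = r.sequence
        if any(s in fwd or s in rc for fwd, rc in texts):
            continue
        out.append(r)
    return out


def _scan_arm(
    oriented: str,
    genome: Genome,
    strand: str,
    read_id: str,
    read_seq: str,
    k: int,
    min_transfer: int,
) -> list[PermutationHit]:
    """All junctions for one orientation of the read against the top strand."""
    g = genome.seq
    L = len(g)
    ell = len(oriented)
    anchor12 = oriented[:k]
    hits: list[PermutationHit] = []
    p = g.find(anchor12)
    while p >= 0:
        # maximal greedy prefix extension: a junction at any shorter m would
        # imply a deviation from the genome at position m, which is excluded
        m = k
        while m < ell and p + m < L and oriented[m] == g[p + m]:
            m += 1
        s = ell - m
        if s >= min_transfer and p >= s and oriented[m:] == g[p - s : p]:
            hit = PermutationHit(
                read_id=read_id,
                read_seq=read_seq,
                genome_id=genome.id,
                strand=strand,
                anchor=p,
                matched_prefix=m,
                relocated_len=s,
                locus_start=p - s,
                locus_end=p + m,
                ligation_site=p,
            )
            # reconstruction invariant, checked on every emitted hit
            assert g[p : p + m] + g[p - s : p] == oriented
            hits.append(hit)
        p = g.find(anchor12, p + 1)
    return hits


def find_permutation(
    read_seq: str,
    genome: Genome,
    k: int = DEFAULT_K,
    min_transfer: int = DEFAULT_MIN_TRANSFER,
    read_id: str = "read",
) -> list[PermutationHit]:
    """All loci on either strand whose rotation exactly equals the read.

    Returns an empty list when the read carries any deviation from the
    genome besides the single junction, or is shorter than k + min_transfer
    (logged as a skip). Several qualifying anchors (paralogous loci) are
    all returned; read-level deduplication happens downstream.
    """
    if min_transfer < MIN_TRANSFER_FLOOR:
        raise ValueError(f"min_transfer must be >= {MIN_TRANSFER_FLOOR}")
    read_seq = read_seq.upper()
    if len(read_seq) < k + min_transfer:
        logger.debug("read %s shorter than k+min_transfer; skipped", read_id)
        return []
    hits = _scan_arm(read_seq, genome, "+", read_id, read_seq, k, min_transfer)
    hits += _scan_arm(revcomp(read_seq), genome, "-", read_id, read_seq, k, min_transfer)
    return hits


def permutation_frequency(
    n_permuted_reads: int,
    n_unmapped: int,
    n_unique_oligos: int | None = None,
    length_distribution: dict[int, int] | None = None,
    locus_table: pd.DataFrame | None = None,
) -> PermutationSummary:
    """Assemble a summary; frequency is permuted reads / unmapped reads."""
    return PermutationSummary(
        n_unmapped=n_unmapped,
        n_permuted_reads=n_permuted_reads,
        n_unique_oligos=n_unique_oligos if n_unique_oligos is not None else n_permuted_reads,
        length_distribution=length_distribution or {},
        locus_table=locus_table,
    )


def detect_permutations(
    reads: ReadSet,
    genomes: list[Genome],
    k: int = DEFAULT_K,
    min_transfer: int = DEFAULT_MIN_TRANSFER,
) -> tuple[list[PermutationHit], PermutationSummary]:
    """Two-step pipeline over a read set and one or more genomes.

    Returns one hit per (read sequence, locus) with `copies` set to the
    number of identical read instances supporting it, plus the summary.
    Identical sequences hitting multiple loci are counted once per instance
    in read-level tallies while every locus stays listed.
    """
    unmapped = remove_exact_matches(reads, genomes)
    n_unmapped = len(unmapped)

    # scan unique sequences once; fan counts back out over instances
    instances: Counter[str] = Counter(r.sequence for r in unmapped)
    first_id = {}
    for r in unmapped:
        first_id.setdefault(r.sequence, r.id)

    all_hits: list[PermutationHit] = []
    n_permuted_reads = 0
    n_unique_oligos = 0
    length_distribution: Counter[int] = Counter()
    for seq, n_copies in instances.items():
        seq_hits: list[PermutationHit] = []
        for genome in genomes:
            seq_hits.extend(
                find_permutation(seq, genome, k, min_transfer, read_id=first_id[seq])
            )
        if not seq_hits:
            continue
        n_unique_oligos += 1
        n_permuted_reads += n_copies
        length_distribution[len(seq)] += n_copies
        all_hits.extend(replace(h, copies=n_copies) for h in seq_hits)

    locus_rows = [
        (
            h.genome_id,
            h.ligation_site,
            h.locus_start,
            h.locus_end,
            h.strand,
            h.read_id,
            h.read_seq,
            h.matched_prefix,
            h.relocated_len,
            h.copies,
        )
        for h in all_hits
    ]
    locus_table = pd.DataFrame(
        locus_rows,
        columns=[
            "genome_id",
            "LS",
            "locus_start",
            "locus_end",
            "strand",
            "read_id",
            "read_seq",
            "matched_prefix",
            "relocated_len",
            "copies",
        ],
    )
    summary = permutation_frequency(
        n_permuted_reads,
        n_unmapped,
        n_unique_oligos,
        dict(length_distribution),
        locus_table,
    )
    return all_hits, summary


def hits_to_bed(hits: list[PermutationHit]) -> pd.DataFrame:
    """BED6 rows (0-based, half-open) for permuted loci; score = copies."""
    return pd.DataFrame(
        [
            (h.genome_id, h.locus_start, h.locus_end, h.read_id, h.copies, h.strand)
            for h in hits
        ],
        columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )
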