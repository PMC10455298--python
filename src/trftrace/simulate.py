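"""Synthetic genomes and read sets with ground truth.

The generator emulates the statistical structure of co-culture small
RNA-seq: two random genomes sharing planted orthology blocks (and no other
12-mer, enforced by targeted resampling), reads drawn from host-unique,
alien-unique and shared regions, endonuclease-style fragmentation of tRF
references with fixed cut sites, low-rate 3' exonuclease trimming,
per-base substitution errors, 5' ligation and 3' poly(A)-like extension
artifacts, spike-in mixtures at a known molar fraction, and a controlled
fraction of circularly permuted reads with exact truth records.

Every function is deterministic under a fixed seed; ground-truth labels
ride in read ids after a '|' so they survive FASTA/FASTQ round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ALPHABET, Genome, ReadRecord, ReadSet, random_dna, revcomp
from .permutation import MIN_TRANSFER_FLOOR, PermutationHit

__all__ = [
    "SimConfig",
    "CutModel",
    "SharedBlock",
    "make_toy_genomes",
    "simulate_trf_fragments",
    "inject_permuted_reads",
    "simulate_mixture",
    "simulate_spikein",
    "simulate_experiment",
    "truth_frame",
    "write_genomes_fasta",
]

MARKER_K = 12  # anchor/marker size shared with the matcher and detector


@dataclass
class SimConfig:
    """Parameters of one simulated co-culture experiment.

    Fractions are of the total read count; frac_alien + frac_common <= 1
    and the remainder is host-unique. error_rate is the per-base
    substitution probability (sequencing error + SNP background).
    polya_ext_len appends a literal poly(A) stretch at the 3' end;
    lig_ext_len prepends random bases modelling 5' ligation artifacts.
    """

    seed: int = 0
    host_length: int = 5000
    alien_length: int = 5000
    n_shared_blocks: int = 2
    shared_block_length: int = 100
    n_reads: int = 10_000
    read_length_range: tuple[int, int] = (16, 50)
    error_rate: float = 0.005
    frac_alien: float = 0.01
    frac_common: float = 0.05
    frac_permuted: float = 0.0
    exo_trim_prob: float = 0.1
    polya_ext_len: int = 0
    lig_ext_len: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "frac_alien", "frac_common", "frac_permuted", "exo_trim_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_alien + self.frac_common > 1.0:
            raise ValueError("frac_alien + frac_common must be <= 1")
        lo, hi = self.read_length_range
        if not (12 <= lo <= hi <= 50):
            raise ValueError("read_length_range must lie within [12, 50]")
        if min(self.host_length, self.alien_length) <= 0:
            raise ValueError("genome lengths must be positive")
        if self.n_shared_blocks < 0 or self.shared_block_length <= 0:
            raise ValueError("invalid shared-block sizing")
        if self.n_shared_blocks * self.shared_block_length > min(
            self.host_length, self.alien_length
        ):
            raise ValueError("shared blocks exceed genome length")
        if self.polya_ext_len < 0 or self.lig_ext_len < 0:
            raise ValueError("extension lengths must be nonnegative")


@dataclass
class CutModel:
    """Endonuclease cut-site model on a reference tRF.

    Sites are (0-based position, weight) pairs; the 3' position is the
    (closed) coordinate of a fragment's last base. Weights must be
    nonnegative and sum to 1 per end, and at least one 5' site must lie
    strictly before some 3' site so a fragment can exist.
    """

    five_prime_sites: list[tuple[int, float]]
    three_prime_sites: list[tuple[int, float]]

    def validate(self, ref_len: int) -> None:
        for name, sites in (
            ("five_prime_sites", self.five_prime_sites),
            ("three_prime_sites", self.three_prime_sites),
        ):
            if not sites:
                raise ValueError(f"{name} must be non-empty")
            pos, w = zip(*sites)
            if any(p < 0 or p >= ref_len for p in pos):
                raise ValueError(f"{name}: position outside reference of length {ref_len}")
            if any(x < 0 for x in w):
                raise ValueError(f"{name}: negative weight")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{name}: weights must sum to 1")
        if not any(
            f < t
            for f, _ in self.five_prime_sites
            for t, _ in self.three_prime_sites
        ):
            raise ValueError("all 5'/3' site pairs inverted: no fragment possible")


@dataclass(frozen=True)
class SharedBlock:
    """One orthology block planted verbatim in both genomes."""

    host_start: int
    host_end: int  # half-open
    alien_start: int
    alien_end: int


def _place_blocks(rng: np.random.Generator, L: int, n: int, bl: int) -> list[tuple[int, int]]:
    """n non-overlapping [start, end) intervals of length bl in [0, L)."""
    free = L - n * bl
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    return [(int(offsets[i] + i * bl), int(offsets[i] + (i + 1) * bl)) for i in range(n)]


def _fully_inside(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= start and end <= e for s, e in intervals)


def _kmers_outside_blocks(
    seq: str, intervals: list[tuple[int, int]], k: int
) -> dict[str, list[int]]:
    """Top-strand k-mer windows not fully inside any interval, with starts."""
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        if _fully_inside(i, i + k, intervals):
            continue
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def _both_strand_closure(kmers: set[str]) -> set[str]:
    return kmers | {revcomp(m) for m in kmers}


def make_toy_genomes(cfg: SimConfig) -> tuple[Genome, Genome, list[SharedBlock]]:
    """Two random genomes sharing exactly the planted orthology blocks.

    Outside the shared blocks the genomes share no 12-mer on either
    strand (offending windows are locally resampled until true), so a
    read sampled outside a block can never be COMMON by accident.
    """
    rng = np.random.default_rng(cfg.seed)
    k = MARKER_K
    host = list(random_dna(rng, cfg.host_length))
    alien = list(random_dna(rng, cfg.alien_length))
    host_iv = _place_blocks(rng, cfg.host_length, cfg.n_shared_blocks, cfg.shared_block_length)
    alien_iv = _place_blocks(rng, cfg.alien_length, cfg.n_shared_blocks, cfg.shared_block_length)
    blocks = [
        SharedBlock(hs, he, as_, ae)
        for (hs, he), (as_, ae) in zip(host_iv, alien_iv)
    ]
    block_seqs = []
    for b in blocks:
        content = random_dna(rng, cfg.shared_block_length)
        block_seqs.append(content)
        host[b.host_start : b.host_end] = content
        alien[b.alien_start : b.alien_end] = content

    letters = list(ALPHABET)
    for _ in range(500):  # targeted repair until no off-block 12-mer is shared
        hseq, aseq = "".join(host), "".join(alien)
        block_kmers = _both_strand_closure(
            {s[i : i + k] for s in block_seqs for i in range(len(s) - k + 1)}
        )
        host_out = _kmers_outside_blocks(hseq, host_iv, k)
        alien_out = _kmers_outside_blocks(aseq, alien_iv, k)
        host_set = _both_strand_closure(set(host_out))
        alien_set = _both_strand_closure(set(alien_out))
        bad_host = {m for m in host_out if m in (alien_set | block_kmers)}
        bad_alien = {m for m in alien_out if m in (host_set | block_kmers)}
        if not bad_host and not bad_alien:
            return (
                Genome("host", hseq),
                Genome("alien", aseq),
                blocks,
            )
        for genome_chars, intervals, bad, table in (
            (host, host_iv, bad_host, host_out),
            (alien, alien_iv, bad_alien, alien_out),
        ):
            for m in sorted(bad):
                for start in table[m]:
                    mutable = [
                        j
                        for j in range(start, start + k)
                        if not any(s <= j < e for s, e in intervals)
                    ]
                    j = int(rng.choice(mutable))
                    genome_chars[j] = str(
                        rng.choice([c for c in letters if c != genome_chars[j]])
                    )
    raise RuntimeError("could not separate genome 12-mer content; genomes too small")


def simulate_trf_fragments(
    trf: str,
    cuts: CutModel,
    n: int,
    exo_trim_prob: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Fragments of a reference tRF cut at sampled 5'/3' sites.

    Each read is trf[f : t+1] for a weighted 5' site f and (closed) 3'
    site t, with probability exo_trim_prob of one extra 1-nt 3'
    truncation (exonuclease nibble). Inverted pairs (f >= t) are
    resampled; CutModel.validate guarantees at least one valid pair.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    trf = trf.upper()
    cuts.validate(len(trf))
    rng = np.random.default_rng(seed)
    f_pos, f_w = zip(*cuts.five_prime_sites)
    t_pos, t_w = zip(*cuts.three_prime_sites)
    reads: ReadSet = []
    for i in range(n):
        while True:
            f = int(rng.choice(f_pos, p=f_w))
            t = int(rng.choice(t_pos, p=t_w))
            if f < t:
                break
        frag = trf[f : t + 1]
        if exo_trim_prob > 0 and rng.random() < exo_trim_prob:
            frag = frag[:-1]
        reads.append(
            ReadRecord(f"frag_{i:06d}|{f}-{t}", frag, provenance="synthetic")
        )
    return reads


def inject_permuted_reads(
    genome: Genome,
    n: int,
    total_len_range: tuple[int, int] = (17, 50),
    relocated_len_range: tuple[int, int] = (5, 16),
    strand_mix: float = 0.5,
    seed: int = 0,
) -> tuple[ReadSet, list[PermutationHit]]:
    """Reads that are rotations of contiguous genome segments, with truth.

    Each read equals segment[s:] + segment[:s] (reverse-complemented for a
    bottom-strand fraction of strand_mix); segments are resampled until the
    read occurs nowhere verbatim in the genome (it would be removed at the
    exact-match step) and the truth split is the maximal one the detector
    reports (the base before the segment differs from the base after it).
    """
    lmin, lmax = total_len_range
    smin, smax = relocated_len_range
    if smax >= lmin:
        raise ValueError("relocated max must be < total min")
    if lmax > 50:
        raise ValueError("total max must be <= 50")
    if smin < MIN_TRANSFER_FLOOR:
        raise ValueError(f"relocated min must be >= {MIN_TRANSFER_FLOOR}")
    if lmin < smin + MARKER_K:
        raise ValueError(f"total min must be >= relocated min + {MARKER_K} (anchor size)")
    if not (0.0 <= strand_mix <= 1.0):
        raise ValueError("strand_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = genome.seq
    L = len(g)
    rc = genome.rc_seq
    reads: ReadSet = []
    truth: list[PermutationHit] = []
    for i in range(n):
        while True:
            ell = int(rng.integers(lmin, lmax + 1))
            s = int(rng.integers(smin, min(smax, ell - MARKER_K) + 1))
            a = int(rng.integers(0, L - ell + 1))
            # maximality of the split: prefix extension from the anchor must
            # stop exactly at the junction
            if a + ell < L and g[a] == g[a + ell]:
                continue
            seg = g[a : a + ell]
            oriented = seg[s:] + seg[:s]
            bottom = rng.random() < strand_mix
            read_seq = revcomp(oriented) if bottom else oriented
            if oriented in g or oriented in rc:
                continue
            break
        rid = f"perm_{i:06d}|permuted"
        reads.append(ReadRecord(rid, read_seq, provenance="synthetic"))
        truth.append(
            PermutationHit(
                read_id=rid,
                read_seq=read_seq,
                genome_id=genome.id,
                strand="-" if bottom else "+",
                anchor=a + s,
                matched_prefix=ell - s,
                relocated_len=s,
                locus_start=a,
                locus_end=a + ell,
                ligation_site=a + s,
            )
        )
    return reads, truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for j in hits:
        chars[j] = str(rng.choice([c for c in ALPHABET if c != chars[j]]))
    return "".join(chars)


def simulate_mixture(
    host: Genome,
    alien: Genome,
    shared_blocks: list[SharedBlock],
    cfg: SimConfig,
) -> ReadSet:
    """Reads from host-unique, alien-unique and shared regions in the
    configured proportions, with errors and end artifacts.

    Reads are drawn from both strands. A host/alien read may straddle a
    block border but never lies fully inside one; a common read lies fully
    inside a block. The truth origin (host/alien/common) is encoded in the
    read id.
    """
    rng = np.random.default_rng(cfg.seed)
    lmin, lmax = cfg.read_length_range
    host_iv = [(b.host_start, b.host_end) for b in shared_blocks]
    alien_iv = [(b.alien_start, b.alien_end) for b in shared_blocks]
    if cfg.frac_common > 0 and not shared_blocks:
        raise ValueError("frac_common > 0 requires shared blocks")
    p_host = 1.0 - cfg.frac_alien - cfg.frac_common
    reads: ReadSet = []
    for i in range(cfg.n_reads):
        u = rng.random()
        if u < p_host:
            origin, g, iv = "host", host, host_iv
        elif u < p_host + cfg.frac_alien:
            origin, g, iv = "alien", alien, alien_iv
        else:
            origin, g, iv = "common", host, host_iv
        if origin == "common":
            b = shared_blocks[int(rng.integers(0, len(shared_blocks)))]
            bs, be = b.host_start, b.host_end
            ell = int(rng.integers(lmin, min(lmax, be - bs) + 1))
            start = int(rng.integers(bs, be - ell + 1))
        else:
            while True:
                ell = int(rng.integers(lmin, lmax + 1))
                start = int(rng.integers(0, len(g) - ell + 1))
                if not _fully_inside(start, start + ell, iv):
                    break
        window = g.seq[start : start + ell]
        if rng.random() < 0.5:
            window = revcomp(window)
        seq = _apply_errors(rng, window, cfg.error_rate)
        if cfg.lig_ext_len:
            seq = random_dna(rng, cfg.lig_ext_len) + seq
        if cfg.polya_ext_len:
            seq = seq + "A" * cfg.polya_ext_len
        reads.append(ReadRecord(f"mix_{i:06d}|{origin}", seq, provenance="cellular"))
    return reads


def simulate_spikein(
    background: ReadSet,
    spike_seqs: list[str],
    spike_molar_fraction: float,
    n: int,
    seed: int = 0,
) -> ReadSet:
    """Mixture of spike-oligo reads (at the given molar fraction) and
    background reads resampled with replacement; truth label in the id."""
    if not spike_seqs:
        raise ValueError("spike_seqs must be non-empty")
    if not (0.0 <= spike_molar_fraction < 1.0):
        raise ValueError("spike_molar_fraction must be in [0, 1)")
    if not background:
        raise ValueError("background read set is empty")
    rng = np.random.default_rng(seed)
    reads: ReadSet = []
    for i in range(n):
        if rng.random() < spike_molar_fraction:
            seq = spike_seqs[int(rng.integers(0, len(spike_seqs)))]
            reads.append(ReadRecord(f"spk_{i:06d}|spike", seq, provenance="synthetic"))
        else:
            src = background[int(rng.integers(0, len(background)))]
            reads.append(
                ReadRecord(f"bg_{i:06d}|background", src.sequence, src.qualities, src.provenance)
            )
    return reads


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[Genome, Genome, list[SharedBlock], ReadSet, list[PermutationHit]]:
    """One full synthetic experiment: genomes, mixture reads, and a
    frac_permuted fraction of additional rotated host-genome reads."""
    host, alien, blocks = make_toy_genomes(cfg)
    reads = simulate_mixture(host, alien, blocks, cfg)
    truth: list[PermutationHit] = []
    n_perm = round(cfg.frac_permuted * cfg.n_reads)
    if n_perm:
        lmin = max(cfg.read_length_range[0], 17)
        lmax = max(cfg.read_length_range[1], lmin)
        perm_reads, truth = inject_permuted_reads(
            host,
            n_perm,
            total_len_range=(lmin, lmax),
            seed=cfg.seed + 1,
        )
        reads = reads + perm_reads
    return host, alien, blocks, reads, truth


def truth_frame(reads: ReadSet, truth: list[PermutationHit] | None = None) -> pd.DataFrame:
    """TSV-ready truth table: read_id, origin, and permutation fields."""
    perm = {h.read_id: h for h in truth or []}
    rows = []
    for r in reads:
        h = perm.get(r.id)
        rows.append(
            (
                r.id,
                r.origin or "",
                "permuted" if h else "linear",
                h.strand if h else "",
                h.anchor if h else "",
                h.matched_prefix if h else "",
                h.relocated_len if h else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "origin", "category", "strand", "anchor", "matched_prefix", "relocated_len"],
    )


def write_genomes_fasta(genomes: list[Genome], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes),
        str(path),
        "fasta",
    )
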