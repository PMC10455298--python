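import numpy as np
import pytest

from oracles import occurs_exact, rc, rotation_hits
from trftrace.core import Genome, ReadRecord, random_dna
from trftrace.permutation import (
    detect_permutations,
    find_permutation,
    permutation_frequency,
    remove_exact_matches,
)
from trftrace.simulate import inject_permuted_reads


def _planted_rotation(rng, L=300, a=10, ell=30, s=12):
    """Genome plus the rotation of g[a:a+ell] with relocated length s,
    resampled until the configuration is unambiguous (read absent verbatim,
    junction at the maximal split)."""
    while True:
        g = random_dna(rng, L)
        read = g[a + s : a + ell] + g[a : a + s]
        if g[a] != g[a + ell] and not occurs_exact(read, g):
            return Genome("g", g), read


def test_planted_rotation_is_found_with_exact_fields(rng):
    genome, read = _planted_rotation(rng, a=10, ell=30, s=12)
    (hit,) = find_permutation(read, genome)
    assert (hit.strand, hit.anchor, hit.matched_prefix, hit.relocated_len) == ("+", 22, 18, 12)
    assert (hit.locus_start, hit.locus_end, hit.ligation_site) == (10, 40, 22)
    # reconstruction from the genome reproduces the read
    g = genome.seq
    assert g[hit.anchor : hit.anchor + hit.matched_prefix] + g[hit.locus_start : hit.anchor] == read


def test_substitution_in_relocated_segment_kills_the_hit(rng):
    genome, read = _planted_rotation(rng)
    broken = list(read)
    broken[-3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[broken[-3]]
    assert find_permutation("".join(broken), genome) == []


def test_bottom_strand_read_reported_in_top_coordinates(rng):
    genome, read = _planted_rotation(rng, a=50, ell=28, s=9)
    (hit,) = find_permutation(rc(read), genome)
    assert hit.strand == "-"
    assert (hit.anchor, hit.matched_prefix, hit.relocated_len) == (59, 19, 9)
    assert (hit.locus_start, hit.locus_end) == (50, 78)


def test_min_transfer_boundary_four_versus_five(rng):
    genome, read = _planted_rotation(rng, a=40, ell=25, s=4)
    hits4 = find_permutation(read, genome, min_transfer=4)
    assert [(h.anchor, h.relocated_len) for h in hits4] == [(44, 4)]
    assert find_permutation(read, genome, min_transfer=5) == []


def test_min_transfer_below_program_floor_rejected(rng):
    genome, read = _planted_rotation(rng)
    with pytest.raises(ValueError, match=">= 4"):
        find_permutation(read, genome, min_transfer=3)


def test_short_reads_are_skipped(rng):
    genome = Genome("g", random_dna(rng, 100))
    assert find_permutation(random_dna(rng, 16), genome) == []  # < k + min_transfer


def test_remove_exact_matches_equals_substring_scan(rng):
    genomes = [Genome("g1", random_dna(rng, 500)), Genome("g2", random_dna(rng, 500))]
    reads = []
    for i in range(60):
        if i % 3 == 0:
            g = genomes[i % 2].seq
            start = int(rng.integers(0, 480))
            seq = g[start : start + 20]
            if i % 6 == 0:
                seq = rc(seq)
            reads.append(ReadRecord(f"m{i}", seq))
        else:
            reads.append(ReadRecord(f"r{i}", random_dna(rng, 20)))
    survivors = {r.id for r in remove_exact_matches(reads, genomes)}
    expected = {
        r.id
        for r in reads
        if not any(occurs_exact(r.sequence, g.seq) for g in genomes)
    }
    assert survivors == expected


def test_decisions_match_rotation_enumeration_oracle(rng):
    genome = Genome("g", random_dna(rng, 2000))
    reads = [random_dna(rng, int(rng.integers(17, 51))) for _ in range(300)]
    injected, _ = inject_permuted_reads(genome, 50, seed=77)
    reads += [r.sequence for r in injected]
    for seq in reads:
        if occurs_exact(seq, genome.seq):
            continue
        got = {
            (h.strand, h.anchor, h.matched_prefix, h.relocated_len)
            for h in find_permutation(seq, genome)
        }
        assert got == rotation_hits(seq, genome.seq)


def test_injected_truth_recovered_through_full_pipeline(rng):
    genome = Genome("g", random_dna(rng, 2000))
    reads, truth = inject_permuted_reads(genome, 200, seed=5)
    hits, summary = detect_permutations(reads, [genome])
    assert summary.n_unmapped == 200
    assert summary.n_permuted_reads == 200
    got = {(h.read_seq, h.strand, h.anchor, h.matched_prefix, h.relocated_len) for h in hits}
    for t in truth:
        assert (t.read_seq, t.strand, t.anchor, t.matched_prefix, t.relocated_len) in got


def test_paralogous_loci_listed_but_counted_once(rng):
    # same segment planted twice -> one counted read, two listed loci
    while True:
        core = random_dna(rng, 30)
        spacer1, spacer2, tail = random_dna(rng, 40), random_dna(rng, 40), random_dna(rng, 40)
        g = spacer1 + core + spacer2 + core + tail
        read = core[12:] + core[:12]
        if (
            not occurs_exact(read, g)
            and g[40] != g[70]
            and g[110] != g[140]
        ):
            break
    genome = Genome("g", g)
    hits, summary = detect_permutations(
        [ReadRecord("p1", read), ReadRecord("p2", read)], [genome]
    )
    assert summary.n_unmapped == 2
    assert summary.n_unique_oligos == 1
    assert summary.n_permuted_reads == 2  # two instances of one oligo
    anchors = sorted(h.anchor for h in hits)
    assert len(anchors) >= 2 and all(h.copies == 2 for h in hits)


def test_strand_symmetry_on_mirrored_genome(rng):
    genome = Genome("g", random_dna(rng, 1500))
    L = len(genome)
    reads, truth = inject_permuted_reads(
        genome,
        60,
        total_len_range=(30, 40),
        relocated_len_range=(13, 16),
        strand_mix=0.0,
        seed=9,
    )
    mirror = Genome("g", rc(genome.seq))
    for r, t in zip(reads, truth):
        # mirror symmetry needs the junction to stay maximal after reflection
        a, e = t.locus_start, t.locus_end
        if a > 0 and genome.seq[a - 1] == genome.seq[e - 1]:
            continue
        fwd = find_permutation(r.sequence, genome)
        bwd = find_permutation(r.sequence, mirror)
        mapped = {
            (h.strand, L - h.locus_end, L - h.locus_start)
            for h in bwd
        }
        assert {("-" if h.strand == "+" else "+", h.locus_start, h.locus_end) for h in fwd} <= mapped


def test_no_hit_ever_leaves_the_genome_bounds(rng):
    genome = Genome("g", random_dna(rng, 800))
    reads, _ = inject_permuted_reads(genome, 100, seed=3)
    hits, _ = detect_permutations(reads, [genome])
    for h in hits:
        assert 0 <= h.locus_start < h.locus_end <= len(genome)
        assert h.anchor - h.relocated_len >= 0
        assert h.anchor + h.matched_prefix <= len(genome)


def test_frequency_arithmetic_and_display_scale():
    s = permutation_frequency(5, 1000)
    assert s.frequency == 0.005
    assert s.percent == 0.5
    assert s.display_scale == 50.0
    z = permutation_frequency(0, 1000)
    assert z.frequency == 0.0 and z.display_scale == 0.0
    undef = permutation_frequency(0, 0)
    assert undef.frequency is None and undef.display_scale is None
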