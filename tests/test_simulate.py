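import numpy as np
import pytest

from oracles import binomial_3sd, occurs_exact, rc
from trftrace.core import kmer_set
from trftrace.io_qc import read_fastq, write_fastq
from trftrace.matcher import Category, classify_reads
from trftrace.simulate import (
    CutModel,
    SimConfig,
    inject_permuted_reads,
    make_toy_genomes,
    simulate_mixture,
    simulate_spikein,
    simulate_trf_fragments,
    write_genomes_fasta,
)


def test_config_validation():
    with pytest.raises(ValueError, match="<= 1"):
        SimConfig(frac_alien=0.6, frac_common=0.6)
    with pytest.raises(ValueError, match="read_length_range"):
        SimConfig(read_length_range=(10, 50))
    with pytest.raises(ValueError, match="exceed genome length"):
        SimConfig(host_length=150, n_shared_blocks=2, shared_block_length=100)


def test_genomes_share_no_offblock_12mer_and_blocks_are_verbatim():
    cfg = SimConfig(seed=3, host_length=3000, alien_length=3000, n_shared_blocks=2,
                    shared_block_length=100)
    host, alien, blocks = make_toy_genomes(cfg)
    assert len(blocks) == 2
    block_kmers = set()
    for b in blocks:
        hseq = host.seq[b.host_start : b.host_end]
        aseq = alien.seq[b.alien_start : b.alien_end]
        assert hseq == aseq and len(hseq) == 100
        block_kmers |= kmer_set(hseq, 12, both_strands=True)
    shared = kmer_set(host.seq, 12, both_strands=True) & kmer_set(alien.seq, 12, both_strands=True)
    assert shared <= block_kmers


def test_disjoint_genomes_share_no_12mer_at_all():
    cfg = SimConfig(seed=4, host_length=2000, alien_length=2000, n_shared_blocks=0,
                    frac_common=0.0)
    host, alien, _ = make_toy_genomes(cfg)
    assert not (
        kmer_set(host.seq, 12, both_strands=True)
        & kmer_set(alien.seq, 12, both_strands=True)
    )


def test_fixed_seed_gives_byte_identical_fasta(tmp_path):
    cfg = SimConfig(seed=9, host_length=1500, alien_length=1500)
    for name in ("a", "b"):
        host, alien, _ = make_toy_genomes(cfg)
        write_genomes_fasta([host, alien], tmp_path / f"{name}.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_single_cut_sites_reproduce_reference(rng):
    from trftrace.core import random_dna

    trf = random_dna(rng, 30)
    cuts = CutModel([(0, 1.0)], [(29, 1.0)])
    reads = simulate_trf_fragments(trf, cuts, n=20, exo_trim_prob=0.0, seed=1)
    assert all(r.sequence == trf for r in reads)
    trimmed = simulate_trf_fragments(trf, cuts, n=20, exo_trim_prob=1.0, seed=1)
    assert all(r.sequence == trf[:-1] for r in trimmed)


def test_inverted_cut_model_is_rejected():
    with pytest.raises(ValueError, match="inverted"):
        CutModel([(20, 1.0)], [(5, 1.0)]).validate(30)
    with pytest.raises(ValueError, match="sum to 1"):
        CutModel([(0, 0.5)], [(29, 1.0)]).validate(30)


def test_cut_site_frequencies_converge_to_weights(rng):
    from trftrace.core import random_dna

    trf = random_dna(rng, 40)
    cuts = CutModel([(0, 0.6), (5, 0.3), (10, 0.1)], [(39, 1.0)])
    n = 10_000
    reads = simulate_trf_fragments(trf, cuts, n=n, seed=2)
    lengths = np.array([len(r) for r in reads])
    for site, w in [(0, 0.6), (5, 0.3), (10, 0.1)]:
        frac = float((lengths == 40 - site).mean())
        assert abs(frac - w) <= binomial_3sd(w, n)


def test_mixture_without_noise_is_verbatim_host(rng):
    cfg = SimConfig(seed=5, n_reads=300, error_rate=0.0, frac_alien=0.0, frac_common=0.0,
                    host_length=2000, alien_length=2000)
    host, alien, blocks = make_toy_genomes(cfg)
    reads = simulate_mixture(host, alien, blocks, cfg)
    assert len(reads) == 300
    assert all(occurs_exact(r.sequence, host.seq) for r in reads)


def test_mixture_truth_labels_agree_with_classifier_when_noiseless():
    cfg = SimConfig(seed=6, n_reads=400, error_rate=0.0, frac_alien=0.2, frac_common=0.2,
                    host_length=2000, alien_length=2000)
    host, alien, blocks = make_toy_genomes(cfg)
    reads = simulate_mixture(host, alien, blocks, cfg)
    res = classify_reads(reads, host, alien, 0)
    label_map = {"host": Category.HOST_ONLY, "alien": Category.ALIEN_ONLY,
                 "common": Category.COMMON}
    for r, cat in zip(reads, res.categories):
        assert cat is label_map[r.origin]


def test_mixture_composition_matches_configured_fractions():
    cfg = SimConfig(seed=7, n_reads=10_000, frac_alien=0.1, frac_common=0.15)
    host, alien, blocks = make_toy_genomes(cfg)
    reads = simulate_mixture(host, alien, blocks, cfg)
    origins = [r.origin for r in reads]
    for label, p in [("host", 0.75), ("alien", 0.1), ("common", 0.15)]:
        frac = origins.count(label) / len(origins)
        assert abs(frac - p) <= binomial_3sd(p, len(origins))


def test_mixture_extensions_change_read_ends():
    cfg = SimConfig(seed=8, n_reads=50, error_rate=0.0, frac_alien=0.0, frac_common=0.0,
                    polya_ext_len=3, lig_ext_len=2, host_length=1500, alien_length=1500)
    host, alien, blocks = make_toy_genomes(cfg)
    reads = simulate_mixture(host, alien, blocks, cfg)
    assert all(r.sequence.endswith("AAA") for r in reads)
    assert all(len(r) >= cfg.read_length_range[0] + 5 for r in reads)


def test_injected_reads_never_match_genome_verbatim(rng):
    from trftrace.core import Genome, random_dna

    genome = Genome("g", random_dna(rng, 2000))
    reads, truth = inject_permuted_reads(genome, 100, seed=1)
    assert len(reads) == len(truth) == 100
    for r, t in zip(reads, truth):
        assert not occurs_exact(r.sequence, genome.seq)
        # read reconstructs as segment[s:] + segment[:s]
        seg = genome.seq[t.locus_start : t.locus_end]
        oriented = seg[t.relocated_len :] + seg[: t.relocated_len]
        assert r.sequence == (oriented if t.strand == "+" else rc(oriented))


def test_inject_strand_mix_zero_is_all_top(rng):
    from trftrace.core import Genome, random_dna

    genome = Genome("g", random_dna(rng, 1000))
    _, truth = inject_permuted_reads(genome, 40, strand_mix=0.0, seed=2)
    assert {t.strand for t in truth} == {"+"}


def test_inject_parameter_validation(rng):
    from trftrace.core import Genome, random_dna

    genome = Genome("g", random_dna(rng, 500))
    with pytest.raises(ValueError, match="< total min"):
        inject_permuted_reads(genome, 5, total_len_range=(17, 30), relocated_len_range=(5, 17))
    with pytest.raises(ValueError, match="<= 50"):
        inject_permuted_reads(genome, 5, total_len_range=(17, 60))


def test_spikein_fraction_and_label_roundtrip(tmp_path, rng):
    from trftrace.core import ReadRecord, random_dna

    background = [ReadRecord(f"b{i}", random_dna(rng, 20)) for i in range(100)]
    spikes = [random_dna(rng, 25) for _ in range(4)]
    n = 10_000
    mixed = simulate_spikein(background, spikes, 0.5, n, seed=4)
    n_spike = sum(1 for r in mixed if r.origin == "spike")
    assert abs(n_spike / n - 0.5) <= binomial_3sd(0.5, n)
    none = simulate_spikein(background, spikes, 0.0, 100, seed=4)
    assert all(r.origin == "background" for r in none)
    with pytest.raises(ValueError, match="non-empty"):
        simulate_spikein(background, [], 0.5, 10)
    path = tmp_path / "s.fastq"
    write_fastq(mixed[:50], path)
    assert [r.origin for r in read_fastq(path)] == [r.origin for r in mixed[:50]]
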