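# Methods

This note documents the models behind `trftrace`, the parameters that
matter, the numerical choices, and what the synthetic-data generator does
and does not emulate.

## Read QC

Stages run in a fixed order — quality → adapter → background → length →
trim — and each is idempotent, so the surviving set is independent of read
order and of re-application.

- **Quality filter.** A read is kept iff at least `min_fraction_at_cutoff`
  (default 0.90) of its bases have Phred ≥ `quality_cutoff` (default 20).
  The comparison is per read, not per window.
- **Residual adapters.** A read is *dropped* when any
  `adapter_min_match` (default 13) consecutive nucleotides of an adapter
  occur in it exactly. Matching is exact (no mismatches): the threshold is a
  length, and any ≥ 13-nt match necessarily contains a 13-nt window, so only
  windows of exactly that size are scanned. A `clip` mode truncates at the
  leftmost match instead; dropping is the default because residual-adapter
  reads are unreliable end to end.
- **Background subtraction.** Exact sequence identity against the
  growth-medium control set; no mismatch tolerance, since medium-derived
  sequences are compared within a single sequencing technology.
- **Length and trimming.** The 16–50 nt window is applied before trimming
  1 nt from the 5′ end and 3 nt from the 3′ end, so trimmed cores span
  12–46 nt. Trimming removes the positions most affected by ligation
  artifacts (5′) and polyadenylation-like extensions (3′). Reads shorter
  than the trims are dropped and counted, not raised.

## k-mismatch classification

A read matches a genome if some window on either strand is within Hamming
distance `max_mismatch` (0–3) of it; `N` counts as a mismatch against
everything, including `N`. Bottom-strand hits are found by comparing the
read's reverse complement against top-strand windows, so all coordinates are
0-based top-strand positions of the leftmost matched base. Categories are
exclusive: COMMON iff hits in both genomes, HOST_ONLY / ALIEN_ONLY iff hits
in exactly one, UNMATCHED otherwise; the same budget applies to both genomes.
The asymmetric step used when hunting imported RNAs — removing every read
within 1 mismatch of the host genome, which absorbs the sequencing-error and
SNP background — is a separate call (`remove_host_like`).

Implementation: `match_read` materializes every window comparison
(sliding-window view) because its contract is the exhaustive hit list;
existence checks (`classify_reads`, `remove_host_like`) first try exact
substring search and fall back to an offset-accumulation scan (one
vectorized pass per read offset). Multi-replicon FASTA inputs are scanned
record by record, never concatenated, so no phantom junction matches arise.

## tRF markers and end profiles

Markers are the 12-mers of a tRF's sequence context absent from the excluded
genome on both strands; a read containing any marker is attributed to the
tRF. k = 12 balances specificity (a random 12-mer has ~1.7 × 10⁷
possibilities, so a megabase-scale genome leaves most tRF 12-mers unique)
against sensitivity for 12-nt reads.

End profiles place each collected read at its leftmost exact occurrence in
the reference and count 5′ starts and 3′ ends per position; the 3′
coordinate is the last base (closed), so a full-length read contributes at
positions 0 and L−1. Reads with repeats in the reference are placed leftmost
and flagged ambiguous; reads not found verbatim (errors, chimeras) or
outside the 12–50 nt window are counted as unplaced and excluded from the
denominators. Exact placement replaces multiple alignment deliberately:
profiled reads are exact subfragments of the reference by selection, and
exactness keeps the counts auditable. Σ counts5 = Σ counts3 = n_reads holds
for every profile.

## Permutation detection

Anchor size k = 12 and `min_transfer` (minimum relocated-segment length)
default 5, floor 4: four is the smallest transfer the junction test can
support without drowning in coincidences, five is the conservative working
setting. The prefix extension is maximal-greedy and the junction is only
accepted at the maximal m: accepting a shorter split would assert a genome
deviation at position m, which the method excludes. A consequence worth
knowing: the rotation representation of a read is not always unique (if the
base before a segment equals the base after it, the locus can slide), and
the detector reports the maximal-split representative. The synthetic
injector plants only maximal-split configurations so truth fields match
detector output exactly.

The ligation site is reported as the anchor coordinate p (where the
relocated segment abuts the matched prefix); the locus left border p − s is
emitted as a first-class column too, since either border may be the
coordinate of interest when comparing loci across experiments. Summaries key
on the anchor.

Genome ends are linear: no hit may extend past either end (p − s ≥ 0,
p + m ≤ L), and origin-spanning loci of circular replicons are out of scope.
Detection is *not* exactly symmetric under reverse-complementing the genome:
the anchor-12 requirement and the maximal-extension rule are oriented, so a
hit whose relocated segment is shorter than 12 nt, or whose mirrored
junction is no longer maximal, can change fields under reflection. The
property test for strand symmetry therefore checks configurations with both
arms ≥ 12 nt and maximality preserved on both sides.

Frequency is the deduplicated permuted-read count over the unmapped-read
count (reads surviving exact-match removal). Identical sequences hitting
several loci count once per read instance; distinct sequences are tallied as
unique oligos. The display scale multiplies the percentage by a further 100
(frequency × 10⁴), convenient for plotting rare events.

## Derived quantities

- **Penetration efficiency** = 100 · n_inside / (n_inside + n_outside);
  undefined (NaN) at 0/0. Scale-invariant by construction.
- **Spike-in concentration** = spike_total_conc · (n_total − n_spike) /
  n_spike, under molar proportionality of read counts — the simplest model
  consistent with treating synthetic oligos of known concentration (four
  oligos at 1 µM, 4 µM total, configurable) as calibration spikes. It
  ignores ligation/length biases; see limitations.
- **Aggregation**: mean ± SEM (sample sd / √n); a single replicate reports
  the mean with SEM missing.
- **Two-group comparison**: Welch's t-test by default because replicate
  counts are small and variances unknown; `equal_var=True` restores the
  pooled test. Bonferroni: p_adj = min(1, p · m). Degenerate inputs (both
  groups constant) give p = 1 for equal means, else p = 0, by convention.
- **Growth AUC**: trapezoid rule with linear interpolation at interval
  endpoints; exact for the piecewise-linear curve through the samples, and
  additive over adjacent intervals.

## The synthetic-data generator

What it emulates, and the defaults:

- **Genomes** are uniform-random over {A,C,G,T} (no Ns), default 5 kb each,
  with 2 planted 100-bp orthology blocks copied verbatim into both. Outside
  the blocks the genomes share **no 12-mer on either strand**. For 5-kb
  genomes roughly half a dozen chance 12-mer collisions are expected, so
  this is enforced by targeted repair — re-randomizing one base inside each
  offending off-block window until the intersection is empty — rather than
  resampling whole genomes, which would rarely terminate. The postcondition
  makes truth labels and the classifier provably consistent at error rate 0.
- **Mixture reads** (default 10,000) are drawn from both strands with
  configured origin fractions (defaults: 1 % alien, 5 % common, remainder
  host — a co-culture-like regime scaled up to be measurable at desk-scale
  read counts), lengths uniform in 16–50 nt, and per-base substitution
  errors at `error_rate` (default 0.005; the source datasets do not pin an
  empirical error/SNP rate, and 0.5 % is a realistic combined figure for
  single-pass short reads over a polymorphic population). 5′ ligation
  artifacts prepend `lig_ext_len` random bases; 3′ extensions append a
  literal poly(A) run of `polya_ext_len` bases (bacterial polyadenylation is
  adenine-dominated; a literal run keeps truth deterministic).
- **tRF fragments** are cut at weighted 5′/3′ sites (endonuclease model:
  fixed ends, sharp profile peaks); inverted site pairs are resampled, and a
  cut model in which no 5′ site precedes any 3′ site is rejected outright.
  `exo_trim_prob` (default 0.1) applies a single 1-nt 3′ truncation —
  low-rate exonuclease nibbling.
- **Permuted reads** are rotations of genome segments, lengths 17–50 nt,
  relocated segments ≥ 5 nt (and ≤ ℓ − 12 so the anchor exists), resampled
  until absent verbatim from the genome and until the split is maximal, so
  detection recovers every truth field exactly at error rate 0.
- **Spike-ins** replace a background read with a spike sequence with
  probability equal to the spike molar fraction — read counts proportional
  to molar abundance, matching the estimator's assumption.

Everything is deterministic under a fixed seed (numpy `default_rng`), and
truth labels are carried in read ids so they survive FASTA/FASTQ round
trips.

What it does **not** emulate — and hence what passing tests do not show
about real data: homopolymer indel errors typical of semiconductor
sequencing (substitutions only), quality-score correlation along reads
(simulated FASTQ is uniform-quality unless a model is supplied), transcript
abundance structure (reads are drawn uniformly from genome regions, not from
an expression model), RNA modifications that stall reverse transcription,
ligation biases in library construction, and real orthology (shared blocks
are exact copies; real orthologs diverge). Results on real data additionally
depend on genome completeness and strain-level SNPs, which the toy genomes
idealize away.

## Problem sizes

The verification suite runs at desk scale, chosen so every stage is checked
against an exhaustive oracle or planted truth while the whole suite stays
interactive: 2-kb genomes and ~1,000-read pools for exhaustive permutation
oracles, two 5-kb genomes and 10,000 reads for classifier oracle and truth
agreement, 50,000-read pools for frequency recovery, 10⁵ reads for spike-in
recovery, and 10⁴ replicates for Monte-Carlo calibration of the t-test.
Binomial 3-SD bands are used wherever an estimate is compared with its
generating parameter.

## Known limitations

- The detector rejects permuted reads with any additional deviation
  (mismatch, indel, non-template nucleotide at the junction); sensitivity on
  real data is bounded by sequencing accuracy.
- Marker-based tRF attribution requires the tRF context to contain at least
  one 12-mer absent from the excluded genome; tRFs fully shared with the
  host are untraceable (a warning is emitted).
- The spike-in estimator assumes count–molarity proportionality; systematic
  length or ligation biases shift the estimate multiplicatively.
- Linear genome model: loci spanning the origin of a circular replicon are
  not detected.
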