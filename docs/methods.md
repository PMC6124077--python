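# Methods

This note records the models, rules and numerical choices behind
`flukeprint`, and what the simulator does and does not emulate.

## Pipeline model

The pipeline assumes a single-locus, taxon-specific amplicon (here a ~450 bp
segment of the hypervariable 5′ mitochondrial control region) sequenced as
paired-end reads long enough to overlap (2·read_length − amplicon ≥ 50 bp).
Each water sample is treated independently; the unit flowing through the
pipeline is the *unique sequence*: an exactly dereplicated merged contig
with a per-sample read count and frequency. Because mitochondrial DNA is
haploid and maternally inherited, each accepted haplotype in a sample is
interpreted as (at least) one contributing animal.

### Trimming

Adapters, then primers, are stripped from either read end by simple flush
matching with ≤ 10 % mismatching positions; read-through (staggered)
trimming is out of scope since the amplicon is longer than the reads.
3′ quality trimming uses the BWA/cutadapt running-sum rule: keep `seq[:c]`
for the cut `c` maximizing Σ_{i≥c}(Q_t − q_i) over the removed suffix
(no cut if no suffix scores positive; ties keep the longest read), with
Q_t = 20. Each mate is filtered separately. Malformed records are dropped
and counted, never fatal.

### Merging

Mate 2 is reverse-complemented and every overlap length from 50 up to the
shorter mate is scored as matches − mismatches (N never matches); ties go
to the longest overlap, and the winner is rejected if its mismatch fraction
exceeds 0.1 (the tool the protocol is modelled on leaves this unspecified,
so it is a configurable parameter). At overlap mismatches the
higher-quality base wins (mate 1 on ties, N always loses) with quality
|q₁ − q₂|; at matches, max(q₁, q₂). Read conservation is exact at every
stage: pairs in = merged + merge-rejected + trim-dropped.

### Dereplication and the denominator

Merged contigs shorter than 379 bp are dropped, the rest are grouped by
exact string identity (upper-cased) and sorted by count, ties broken
lexicographically. "Processed reads" — the denominator for all frequencies
— is the count of reads surviving merge *and* length filter. The merged
contig count is also reported, since depth criteria can reasonably be
expressed against either; the threshold stage takes frequencies, so the
convention enters only through `UniqueSequence.frequency`.

### Chimera removal

A deliberately simplified, deterministic variant of de-novo chimera
detection (not a clone of the chunked UCHIME heuristic): processing unique
sequences in descending abundance, a candidate is chimeric iff two
earlier-accepted parents exist, each ≥ 2× its count, some single breakpoint
reproduces the candidate exactly as parentA-prefix + parentB-suffix, and
the candidate differs from each parent by ≥ 2 substitutions. The perfect
crossover model is exactly verifiable against brute-force enumeration and
is adequate at amplicon scale, where true chimeras are single-breakpoint
PCR artefacts of the sample's own dominant templates. Flagged sequences are
removed regardless of frequency and never serve as parents. Note the
at-least-two-diffs rule means single-substitution error reads can never be
flagged, and a candidate whose every variant site is absent from all
parents (i.e. genuine sequencing error) cannot be reproduced by any
crossover.

### Error calibration and threshold

Positive controls are libraries built from tissue DNA of known haplotype.
Per control, the error rate is the frequency of the most abundant unique
sequence *not identical* (exact string comparison, consistent with
dereplicated sequence space) to the known haplotype. The filter threshold
is a pluggable rounding of the maximum rate across controls; the default
rounds up to the next whole percent (e.g. a 1.70 % maximum yields a 2 %
threshold), mirroring how such thresholds are applied in practice; a
raw-max rule is available. The threshold is applied per sample to
per-sample frequencies, retaining sequences with frequency ≥ threshold.
Pipeline order is chimera → calibration → threshold; calibration on
chimera-cleaned controls makes the measured rate reflect point errors
rather than removable artefacts.

### Haplotype calling

Retained sequences are aligned globally (match +1, mismatch −1, gap open
−2, gap extend −1; both strands) against the reference panel; identity is
matching columns over alignment columns, ties resolved to the smallest
haplotype id. Decision rules: identity 1.0 → known; identity ∈ [0.98, 1)
and fraction ≥ 0.20 → provisional novel haplotype; identity ≥ 0.98 with
lower fraction → rejected (insufficient evidence); identity < 0.98 →
rejected non-target. The 0.98 floor separates plausible conspecific
variants (a one-substitution variant of a 379 bp haplotype has identity
0.9974) from non-target amplification, and is configurable. The ≥ 20 %
novel-evidence rule is applied to primary as well as secondary sequences —
a symmetric evidence requirement. Novel calls are provisional by
construction: confirmation requires resequencing or recurrence, which is
why cohort-level novel ids are assigned deterministically (first-seen
order, shared across samples with identical sequences). A sample with no
accepted sequence yields a single `failed_sample` record carrying its best
evidence.

## Differentiation statistics

Φ_ST comes from AMOVA on squared pairwise nucleotide differences between
the haplotypes of observations (see README for the component formulas).
Each accepted call — including secondary haplotypes — contributes one
observation, since each reflects a distinct contributing animal; a
primary-only mode is available. Significance is by permuting stratum labels
over observations with a seeded generator, p = (1 + #{Φ ≥ Φ_obs})/(n_perm
+ 1), which keeps p > 0 and counts ties conservatively. The χ² homogeneity
test uses cells with positive expectation, df = (H−1)(K−1), and both
asymptotic and permutation p-values.

Degenerate inputs: all-zero distances return a `monomorphic` status with
Φ = 0, p = 1; single-stratum or single-haplotype tables raise. Note that
exactly mirrored stratum compositions give Φ_ST < 0, not 0 — among-stratum
sums of squares then fall below their panmictic expectation (two strata
both {A, B} give Φ = −1). Zero holds in expectation under label
exchangeability, which is what the type-I tests exercise; negative point
estimates on small panmictic datasets are expected behaviour of the
estimator, not an error.

## qPCR quantification

The relative standard curve is OLS of Ct on log₁₀(concentration) over a
1:10 dilution series (default 1.3 → 1.3×10⁻⁵ ng/µl, six points); replicate
wells are averaged on the Ct scale before fitting and conversion (standard
practice where the protocol is silent). Efficiency is 10^(−1/slope) − 1
(slope −3.3219 ↔ 100 %). Unknowns convert as conc = 10^((Ct −
intercept)/slope); wells undetermined or beyond the 45-cycle detection
cutoff (configurable; instruments are often run longer) are reported
undetected and excluded from cohort summaries. Fewer than three usable
standards is an error; a non-negative slope flags the curve invalid.

## Simulator

The generator emulates the emitting process of such a survey, with every
stochastic choice derived from one integer seed (byte-identical reruns):

- **Reference panel** — n haplotypes (default 58) of equal length (450 bp),
  each 1–30 substitutions from a common random ancestor, pairwise distinct,
  ids CR001…
- **Cohort** — two strata of water samples; per-stratum haplotype
  frequencies are Dirichlet draws over 8 circulating haplotypes unless
  supplied; 10 % of samples mix a second haplotype at 20–45 % (so every
  true minor haplotype satisfies the ≥ 20 % evidence rule by construction);
  4 positive controls of known haplotype; negative controls emit zero
  reads (their real-world counterparts are not sequenced).
- **Reads** — template = forward primer + haplotype + revcomp(reverse
  primer), using the assay's primer pair; the forward read is the first 300
  bases, the reverse read the reverse complement of the last 300;
  substitution errors hit each mate independently at 0.3 %/base, qualities
  are the matching constant Phred score (Q25 at 0.3 %), capped at Q40.
  Defaults: 10,000 read pairs/sample — a deliberate scale choice an order
  of magnitude below real MiSeq depth that preserves every frequency ratio
  the pipeline consumes.
- **Artefacts** — 2 % of reads are single-breakpoint two-parent chimeras
  (breakpoint uniform on [50, L−50], so both parent segments are
  detectable); 1 % are copies of one random non-target sequence (< 70 %
  identity to every reference), emulating environmental contamination;
  both rates are free parameters with realistic defaults, as true artefact
  rates are assay-dependent.
- **qPCR plate** — Ct = slope·log₁₀(conc) + intercept + N(0, σ), defaults
  slope −3.32, intercept 24, σ 0.2 cycles; eDNA concentrations are
  log-normal around a 0.0033 ng/µl median.

What it does *not* model — and therefore what passing tests cannot show:
indel sequencing errors and homopolymer artefacts; quality-score decay
along MiSeq reads (quality trimming is exercised, but not against realistic
quality profiles); PCR amplification bias between templates; eDNA
degradation, transport or field-sampling dropout (simulated samples never
fail for lack of target DNA, so simulated success rates sit at the
pipeline's ceiling rather than a field survey's); index hopping or
cross-sample contamination.

## Problem sizes and numerical choices

The test suite runs cohorts of 3–8 samples at 800–5,000 read pairs; the
calibration-recovery check and the acceptance script use the full default
conditions (20–36 samples, 10,000 pairs, 4 controls). Permutation tests use
500–1,000 permutations with explicit seeds. Floating-point tie handling in
permutation counts uses a 1e-12 tolerance so exact ties count as ≥.
Thresholding is inclusive (frequency ≥ threshold retained). The ceil-to-
percent rounding guards against float noise (1e-9) so a rate of exactly
2 % rounds to 2 %, not 3 %. Alignment identity ties break to the smallest
haplotype id; dereplication ties break lexicographically; batch merging is
bit-identical to single-pair merging (property-tested).

## Known limitations

- The chimera model misses multi-breakpoint or error-bearing chimeras;
  these fall to the frequency threshold instead.
- Exact-match calling means a known haplotype observed with even one
  residual error base is *not* "known"; it is only callable as novel if it
  clears the 20 % evidence bar. At realistic thresholds this is the
  intended conservative behaviour.
- Φ_ST/χ² treat observations as independent; two haplotypes from one water
  sample are correlated in space and time, and sample-level permutation is
  available but not the default.
- The qPCR module quantifies relative to a tissue-derived standard; it does
  not model amplification-curve processing or absolute copy number.
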