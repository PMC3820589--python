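# Methods

This note documents the models, parameter choices and numerical
conventions behind `poolseqval`, and what the synthetic-data tests do
and do not demonstrate about real data.

## The generative model

**Genotypes.** Each population is an independent random-mating unit at
Hardy–Weinberg equilibrium: individual major-allele dosage at SNP *j* in
population *p* is Binomial(ploidy, q_pj), loci independent (no
linkage). HWE is the natural neutral stand-in for samples of an
outcrossing species; departures (inbreeding, structure) can be injected
by constructing a `GenotypeMatrix` directly.

**True frequency spectrum.** Where a frequency matrix is not supplied,
per-population major-allele frequencies are drawn i.i.d. Uniform(0.02,
0.98) and alleles are relabelled per SNP so the across-population mean
is ≥ 0.5. This spans near-fixed, singleton-scale and intermediate
frequencies while keeping every SNP biallelic in expectation. It is
*broader* than the spectrum of a panel of pre-selected, highly
differentiated SNPs, whose per-population frequencies cluster near 0
and 1; consequences are noted under "Resampling" below.

**Pools.** One library per population. Each individual contributes a
DNA weight drawn from a gamma distribution with mean 1 and coefficient
of variation `pipetting_cv` (gamma guarantees positivity; CV 0 — the
default, i.e. perfectly equimolar pooling — bypasses sampling
entirely). One weight per individual per pool, shared across loci, as a
pipetting error physically is. The pool's true frequency of base *b* is
the weight-weighted mean allele dosage divided by ploidy. Coverage is
drawn from the configured sampler (default: uniform integers on
[55, 284], spanning the coverage range of the emulated study's two
mapping strategies). Read counts are multinomial over the six pileup
categories with per-base probability
`f_b (1 − e) + (1 − f_b) e/3`, scaled by `1 − n_rate − del_rate`; a
sequencing error substitutes uniformly among the three other bases. N
and deletion rates default to 0, matching base-quality-filtered
pileups. The default error rate at the CLI is 1% — the upper bound a
Phred-20-filtered short-read dataset should stay below. `error_rate`
must be < 0.25, where base identity carries no signal.

`count_mode="expected"` replaces the multinomial draw by deterministic
largest-remainder rounding of the expected counts. It exists for
exactness checks (e.g. at coverage 200 every multiple of 1/40 is
resolved exactly, so a noise-free run reproduces the 1:1 line to
machine precision); it is not a model of any sequencing process.

**Individual genotyping.** Calls are exact when they succeed and are
independently lost with probability `failure_rate` (CLI default 22/540
≈ 4.1%, the emulated assay-failure rate). Real assay failures cluster
by locus and by template quality; independence spreads the missing
values over more SNP × population pairs than clustered failure would,
which makes the complete-only subset smaller and is the conservative
choice for studying the effect of missingness.

## SNP calling

A site is retained iff (a) every pool's coverage — always the
four-nucleotide sum; N and deletion counts never enter coverage or any
frequency denominator — lies within `[min_coverage, max_coverage]`
(defaults 20 and 400), and (b) at least two nucleotides are present in
the combined counts and the second most frequent reaches
`min_minor_count` (default 4). The minor-count rule is applied to
counts combined across pools, matching how joint SNP identification
across populations works; a stricter per-pool variant is available via
`FilterParams(minor_scope="per_pool")`. Major/minor are the top two
bases of the combined counts with ties broken in fixed order
A < C < G < T. Sites with a third segregating base are retained when
the top-two rule passes; the extra counts are kept in the record but
excluded from the biallelic frequency denominator
`n_major / (n_major + n_minor)`, and a warning is logged (with a 1%
error rate at 150–300× such stray third-base reads are routine).
Counts and frequencies stay integer/rational (`fractions.Fraction`)
until serialization, so filter decisions and reported frequencies never
depend on float rounding.

`pool_frequency` called without a minor base uses the full four-base
denominator (the marginal read frequency); `call_snps` uses the
biallelic form. The two agree exactly at strictly biallelic sites.

## Validation statistics

One comparison record per called SNP × population: pooled MAF,
individual MAF (allele counting over non-missing individuals — pairwise
deletion), the pool's coverage, and a completeness flag. The regression
is ordinary least squares with the pooled frequency as predictor and
the individual frequency as response; raw frequencies for slope,
intercept and R² (the question is deviation from the 1:1 line, which a
transform would distort), arcsin√f on *both* variables for the
regression p-value and for the paired t-test (variance stabilization
for proportions; the asymptotic variance 1/(4c) is frequency-free).
All p-values are two-sided; SE of the mean uses the n−1 sample SD.
Degenerate inputs are explicit: a zero-variance predictor raises, a
paired test with identical vectors returns (t=0, p=1), a constant
non-zero difference returns signed infinity with p=0 and a warning, and
a subset with fewer than 3 records yields a report that names the gap
instead of statistics.

Both variants ("all", "complete_only") are always emitted; when nothing
is missing they are identical.

## Resampling

Reads are re-drawn *without replacement* (multivariate hypergeometric)
from each record's observed base counts at every target coverage in the
configured range — hence the range cap at the minimum observed
coverage; a draw can never exceed what a pool actually has, and asking
for more is an error rather than a silent with-replacement fallback. At
each coverage, each iteration recomputes all frequencies
(`n_major / c`, full-draw denominator), the mean absolute difference to
the individual-based frequencies, and the R² of the untransformed
regression; the curve reports across-iteration means and SDs (ddof 1;
exactly 0 when every iteration is an exhaustive identical draw). An
iteration whose resampled frequencies are all equal — possible at 1× —
has no explanatory power and scores R² = 0. Records are processed in
sorted (snp, population) order from a single seeded generator, so a
fixed config yields a bit-identical curve on any platform.

The per-iteration "mean frequency difference" averages *absolute*
differences; signed differences would average toward 0 and could not
reproduce a positive, declining accuracy curve.

Because the default synthetic spectrum is broad (much of the mass at
intermediate frequencies, where binomial noise √(pq/c) is maximal), the
coverage at which the mean difference crosses 5% lands higher (≈35–40×)
than it would for an extreme-frequency SNP panel (≈10–25×). The
*shape* of the curve — monotone decline of |Δf|, monotone rise of R²,
vanishing iteration spread as c approaches the observed coverage — is
spectrum-independent and is what the tests assert; the crossing
coverages are reported, not asserted.

## Problem sizes and reproducibility

The test suite runs the full emulated design (3 pools × 20 diploids ×
9 SNPs) end to end; parameter recovery uses 200 independent seeds
(slope within [0.9, 1.1], R² ≥ 0.9, Kolmogorov–Smirnov uniformity of
the paired-t p-value across seeds), and the resampling checks use 1000
iterations across 1–55×, matching the analysis the package implements.
Oracle tests compare the SNP filter against a brute-force transcription
of its three rules on 1000 random count tables, the hypergeometric
downsampler against the exact marginal pmf (χ² goodness of fit, 10⁴
draws), and every regression/t/correlation statistic against
closed-form normal-equation arithmetic on small datasets at 1e−12.

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; the three simulation stages draw from child
streams spawned off one `SeedSequence`, so each stage is independently
reproducible. Output floats are serialized with `repr`, making every
artifact byte-stable under a fixed seed.

## Limitations

- No read-level simulation: no quality scores, mapping bias, duplicate
  reads, indels, or linkage between loci; pooled counts are exchangeable
  reads, which real mapped data only approximate.
- The dropout model is independent per call; real assay failure is
  clustered (see above).
- Sequencing error is uniform across bases and sites; real error is
  context-dependent and strand-biased. The mean induced frequency bias
  `E[f̂] = f(1−e) + (1−f)e/3` is modelled exactly, but error
  overdispersion is not.
- The validation statistics treat all SNP × population comparisons as
  independent detection events; biologically they are not (the same
  pool underlies several records), so p-values are calibrated for the
  technical question only.
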