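# Methods

This note documents the models behind `genclock`, the defaults of the
synthetic-data generator, the numerical choices, and what the tests do and
do not establish about real data.

## The two clocks

**Recombination clock.** Archaic ancestry along a chromosome is modelled as
a two-state Markov process in genetic distance (the Markovian, or
exponential-tract, approximation to the ancestral recombination graph):
g generations after an admixture pulse of fraction α, archaic tract lengths
are Exp(mean 1/(g(1−α)) Morgans), gaps Exp(mean 1/(gα)), stationary archaic
fraction α.  The estimator `estimate_generations` inverts the mean:
ĝ = 100/(mean cM × (1−α)).  The approximation ignores coalescent
correlations between lineages and genetic drift in tract frequency; it is
accurate for the tract-length *mean* at the g ≈ 1,000–2,000 scale relevant
here, which is all the downstream statistics use.  Generations accrue
piecewise over lineage epochs: from the sampling time back to the
population split at the group's own mean parental age, and beyond the split
at the shared ancestral mean age (default 29 years, the conventional human
generation time).

**Mutation clock.** Trio-sequencing regressions give per-generation
transmitted mutation counts μ̂_f,g = 6.05 + 1.51·a_f (paternal) and
μ̂_m,g = 3.61 + 0.37·a_m (maternal); these four coefficients are parameters
(`PedigreeRegressionParams`) with those values as defaults.  With equal
parental ages the yearly rate is μ̂_y(a) = 9.66/a + 1.88, strictly
decreasing in a, which makes the derived-allele accumulation ratio of two
populations since their split invertible for the unknown age
(`estimate_parental_age`).  An excess measured over the whole
post-Out-of-Africa period is first multiplied by t_ooa/t_split
(`excess_scaling`); because the rates are linear this scaling composes
exactly with the inversion when the reference population's age also ruled
the shared epoch.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline is tested
under; they are fixed once and shared by every stage through named RNG
substreams of a single seed (one substream per individual × chromosome ×
purpose, so extending a cohort never perturbs existing draws; identical
seed and config are byte-identical).

* **Demography.** One Neanderthal pulse (default 55 kya, α = 0.02) into the
  common ancestor; population split 40 kya; Out-of-Africa horizon 60 kya
  for mutation accumulation.  Options: a second, private pulse to one group
  (younger, hence longer, tracts layered independently) and dilution
  (admixture from an archaic-free population), implemented as per-tract
  Bernoulli thinning, which reduces total archaic sequence but provably
  leaves the length distribution untouched.
* **Genome.** Two 50 Mb autosomes, a 30 Mb X, a 10 Mb Y by default —
  minutes-scale, large enough for thousands of tracts.  Tract boundaries
  snap to the 1 kb window grid so truth and HMM calls are comparable
  without off-by-one ambiguity.  Each individual's archaic ancestry is one
  haploid mosaic layer: called fragments on a diploid genome are
  effectively the union track, and a single layer keeps the exponential
  length law exact (a diploid union would lengthen ~2α of tracts by
  merging).
* **Recombination maps.** Piecewise-constant per group, default a single
  1.2 cM/Mb block (roughly the genome average); block count and lognormal
  rate jitter are configurable.  Morgan↔bp conversion uses the map's
  cumulative genetic position.
* **Mutations.** Per chromosome, derived-allele counts are Poisson with
  mean = Σ_epochs T · 2(w_f·μ̂_f,g(a_f)/a_f + w_m·μ̂_m,g(a_m)/a_m) ×
  copies/2 × callable_bp/genome_ref_bp × count_scale, where the sex-exposure
  weights (w_f, w_m) are (1/2, 1/2) for autosomes, (1/3, 2/3) for X and
  (1, 0) for Y.  Each lineage converts its per-generation rate to a yearly
  rate by its *own* parental age; with a_f = a_m this reduces to the
  (T/ā)·μ̂_g form the generation-time equations invert, and with unequal
  ages it yields the expected directional behaviour of the X-to-A ratio
  (older fathers / younger mothers at fixed mean age raise it).
  genome_ref_bp = 2.9 Gb maps the genome-wide pedigree counts onto the
  small synthetic genome; `count_scale` multiplies counts for
  precision-hungry experiments.
* **Spectrum.** Eight disjoint categories (the six pyrimidine base changes
  with C>T split into CpG>TpG / TCC>TTC / C>T′); fractions are linear in
  mean parental age around a human-polymorphism-like base composition at
  29 years, with slopes summing to zero (defaults: TCC>TTC −0.0008/yr,
  CpG>TpG flat, T>C +0.0008/yr, small terms elsewhere).  Each variant gets
  a concrete (ancestral, derived, 5′, 3′) context drawn uniformly from the
  contexts consistent with its category and is recorded on a random strand,
  so classification must strand-collapse correctly to recover the truth.
* **Clustered-DNM regions.** 10% of autosomal 1 Mb windows are flagged
  cDNM cohort-wide; inside them the C>G fraction is inflated by
  1 + 0.05·(a_m − 20), a maternal-age-increasing factor (slope 0 restores
  the null exactly).
* **Window tracks.** Per 1 kb window: callability ~ Beta(18, 2) (mean 0.9),
  with 2% of windows dropped to near-zero callability to emulate coverage
  dips; mutation-rate scale ~ Gamma with mean 1, CV 0.2; private-SNP count
  ~ Poisson(λ_state × callability × scale) with λ_background = 0.02 and
  λ_archaic = 0.4 per window (the ~20× contrast typical of outgroup-
  ascertained private-SNP densities).
* **Trio table.** Proband parental ages ~ Normal(31, 4.5²) paternal /
  Normal(28, 4.5²) maternal (clipped to [16, 60]); total DNM per proband
  ~ Poisson(μ̂_f,g + μ̂_m,g); type split multinomial from the age-linear
  spectrum.

What the generator does **not** emulate: sequencing error, reference bias,
selection against introgressed sequence, gene conversion, coalescent
correlation between individuals, linkage between variants, or realistic
fine-scale recombination maps.  Passing tests therefore establish the
*internal consistency and calibration* of the estimators under their own
model assumptions — not robustness to those real-data complications.

## Fragment calling (window HMM)

Two states (background / archaic), Poisson emissions scaled per window by
callability × mutrate_scale, fitted by Baum–Welch EM over all tracks as
independent chains sharing one parameter set.  Numerical choices: scaled
(not log-space) forward–backward with per-window max-shifted emissions,
accelerated with numba; λ initialised from the 50th and 99th percentiles of
count/exposure (floored at 10⁻³); tolerance 10⁻⁶ on the log-likelihood,
max 500 iterations; windows with callability < 0.05 are treated as missing
(no emission term, transitions still apply), which keeps calls from
breaking at coverage dips; after each M-step states are relabelled so the
archaic state is the denser one; an all-zero track collapses λ̂ to 0 and is
flagged rather than raised.  Decoding takes maximal runs of windows with
archaic posterior > 0.5 and annotates each fragment with its mean
posterior; "high-confidence" means mean posterior ≥ 0.8 by default — a
configurable convention, not an externally fixed value.

## Interval semantics

0-based half-open BED coordinates throughout.  Merging coalesces
overlapping *and* book-ended intervals (the merge tool's default);
intersection and shared/private classification use strict ≥1 bp overlap
(book-ended is not overlap).  Window frequency tiles the joined set into
1 kb segments and counts *distinct individuals* per window — the quantity
interpreted as archaic frequency — with raw overlap-event counting
available as an option (the two coincide when fragments are at least
window-sized).  Group comparisons can downsample the larger group by a
seeded uniform choice to balance discovery.

## Resampling inference

Bootstrap CIs follow the normal-approximation construction: bootstrap-
distribution mean ± z·(bootstrap sd), with percentile intervals as an
option.  Permutation tests compare the observed statistic to label
permutations: difference of means doubled for two tails, one-way F
one-tailed; "as extreme or more extreme" is an exact ≥ comparison (ties
count as extreme, no epsilon); when no permutation qualifies the fraction
is floored at 1/n_perm and the result flagged as an upper bound, with the
floor applied before doubling.  Library defaults are 100,000 resamples;
tests and the pipeline default to scaled-down 999/2,000, which the
calibration tests show is already well inside the stated tolerance bands.
All-identical data defines F = 0.

## Recombination-map rescaling

Populations' maps assign different total genetic lengths per chromosome;
before comparing genetic fragment lengths, every population's rates on a
chromosome are multiplied by l_qc/l_pc so all equal the shortest
population's length (idempotent).  The reciprocal factor (which inflates
all maps to agreement ratios rather than equalising them) is available as
`mode="printed"` for replication experiments with that alternative
convention.  HapMap-style text positions are read as 1-based and converted
to 0-based half-open internally; the last row of each chromosome closes
the extent and its rate is unused.

## Design choices that were genuinely open

* Trio aggregation groups probands by mean parental age rounded to 1
  decimal (grouping by "equal" real-valued ages needs a precision;
  configurable), discards groups of fewer than 2 probands, and computes
  fractions from summed counts, not averaged per-proband fractions.
* All nine spectrum fractions share one denominator — the total over the
  six base types — so the three C>T subtypes are not double-counted.
* cDNM p̄ is the unweighted mean of per-window p over each window class;
  windows with zero non-C>G count are skipped and reported; a
  count-weighted mean is available.
* The Y-chromosome sensitivity statistic is the relative derivative of the
  paternal yearly rate, (6.05/a²)/(6.05/a + 1.51)×100 — about 0.45%/year
  at a = 28 — as the most direct reading of a per-year paternal-rate
  sensitivity.
* Reported ages are rounded to 2 decimals only at the presentation layer.

## Problem sizes

Test and demo runs use 8–50 Mb chromosomes, 4–150 individuals per group,
999 permutations / 2,000 bootstrap resamples, and ~200,000 HMM windows for
recovery benchmarks — sizes chosen so the whole suite runs in minutes while
leaving every Monte-Carlo comparison enough precision for its 3-SE or
rate-band assertion.  All CLI defaults remain at the full 100,000-resample
scale.

## Known limitations

Uncertainty from fragment-length CIs is not propagated into age estimates
(point conversions only); the HMM does not attribute fragments to a source
population; no parametric tests are provided (the inference is
deliberately resampling-based); the X-to-A exposure model treats the male
X as carrying the population-averaged 1/3:2/3 history rather than tracking
transmission explicitly.
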