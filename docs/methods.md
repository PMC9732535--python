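# Methods

## The question and the model

A mouse heterozygous for *n* Robertsonian (Rb) fusions carries *n*
metacentric chromosomes, each of which pairs at meiosis I with its two
homologous telocentrics to form a trivalent. Under alternate segregation
each trivalent independently delivers either the metacentric or the two
telocentrics to a gamete. If segregation is Mendelian, the number of
metacentrics *X* an offspring inherits from the heterozygous parent is

    X ~ Binomial(n, 1/2),      P(X = k) = C(n, k) (1/2)^n.

Meiotic drive — transmission-ratio distortion — means the per-trivalent
transmission probability deviates from 1/2. When the probabilities
p_1..p_n differ across trivalents, X follows the Poisson-binomial
distribution, which `transmission_pmf` computes by iterative convolution
of the per-trivalent Bernoulli pmfs: exact, O(n²), no sampling. The
homogeneous case reduces to the binomial, and the implementation is
cross-checked in the tests against exhaustive enumeration of all 2^n
gamete outcomes up to n = 12 (agreement to 1e-12).

The cross design analysed by the bundled fixtures has n = 8 trivalents
and an all-telocentric base diploid number of 40, so an offspring with
k metacentrics has 2n = 40 − k. `telocentric_base` is a parameter
everywhere so the package is not hard-wired to this cross.

## Inference

**Goodness of fit.** `gof_test` compares the observed offspring
distribution over k = 0..n with N·pmf. The `asymptotic` mode is the
textbook chi-square with df = bins − 1. With N ≈ 56–83 the expected
tail counts fall below 1, where the chi-square reference distribution is
anti-conservative; the asymptotic mode without pooling is retained
because it is what a desk reanalysis of the reference dataset needs to
reproduce, and two defensible alternatives are provided: `pool_below=x`
merges tail bins inward until each pooled tail expectation reaches x,
and `method="monte_carlo"` draws multinomial(N, pmf) resamples and
reports the add-one p-value (1 + b)/(1 + B), which can never be exactly
zero. Monte-Carlo p-values are bit-reproducible given a seed. The
Monte-Carlo mode is validated against exact multinomial enumeration on
a reduced case (n = 3, N = 10) and its type-I error at nominal 0.05 is
checked to lie in (0.03, 0.07) over 2000 simulated null cohorts.

**Proportion tests.** `proportion_test` implements the one-sample
binomial test two ways: a normal approximation with null standard error
sqrt(p0(1−p0)/N) and no continuity correction (the two-sided p is by
convention twice the smaller one-sided p), and exact binomial tail sums.
The attached 95% interval is always the Wilson score interval, whose
coverage near boundary proportions is verified by simulation. With 5 of
6 offspring exceeding a reference, the one-sided normal p is 0.0512
(z = 1.633) while the exact tail is 7/64 = 0.1094 — the normal
approximation at N = 6 is optimistic, and both numbers are reported so
the reader can see the method dependence.

**Transmission estimates.** `estimate_transmission` treats the n·N
trivalent segregations behind a cohort as independent Bernoulli trials
and estimates p = Σk·counts[k]/(n·N) with a Wilson interval. This
independence assumption (across trivalents and across littermates) is
stated on the result object rather than silently assumed.
`compare_transmission` tests two cohorts with the pooled two-proportion
z-test on the aggregated trivalent outcomes, two-sided. For the bundled
cohorts (256/664 maternal vs 228/448 paternal) the pooled estimate is
484/1112 ≈ 43.5% and |z| ≈ 4.07.

**Dispersion.** A distribution can keep a near-Mendelian mean while
being the wrong shape. `dispersion_test` reports the ratio of the sample
variance of k to the binomial variance n·p̂(1−p̂) at the fitted mean
fraction, with a two-sided Monte-Carlo p under Binomial(n, p̂)
resampling (p̂ refitted per resample). A ratio above 1 is
overdispersion — mass pushed into the tails relative to any binomial
with the same mean.

**Multiple testing.** None is applied; raw p-values are reported, each
tagged with the method (and seed, when stochastic) that produced it.

## Pericentromeric morphometry

Chromosome compaction varies from metaphase plate to plate, so raw pixel
lengths are not comparable. The compaction-robust statistic is the
pericentromeric length CL divided by the chromosome total length TL,
times 100, with TL the mean of the two measured sister chromatid
lengths. TL-as-mean (rather than sum) was chosen because the bundled
per-animal summaries (~21–26%) are on the per-chromatid scale; the ratio
is exactly invariant to any uniform rescaling of all three lengths,
which the tests assert as a property. Exceedance of a parental reference
uses strict inequality, and "more than half the offspring exceed the
parent" is tested with the one-sided proportion test above.

## The synthetic-data generator

`simulate_offspring` draws each offspring's inherited count from a
distribution proportional to PoissonBinomial(k; drive) × viability[k]:

* **drive** — per-trivalent transmission probabilities (gametic
  mechanism);
* **viability** — relative survival weights over the genotype classes
  k = 0..n (post-zygotic mechanism). Selection acts on the class, not on
  individual gamete identity: this is the minimal mechanism that
  produces a distorted distribution shape with a near-Mendelian mean,
  the pattern the inference modules are designed to detect. These data
  cannot identify gametic drive versus viability selection — the
  simulator exposes both knobs, and the inference modules make no
  identifiability claim.

Offspring are grouped into litters of truncated-Poisson size (default
mean 4.4, matching the maternal crosses of the reference design);
litter membership is encoded in the animal id but deliberately ignored
by inference, which pools littermates. Plate counts replicate the true
count over 10 plates with an optional per-plate miscount rate.
`simulate_measurements` emulates the 20-plate measurement design: one
lognormal plate-level compaction factor (unit mean, configurable CV)
scales all lengths jointly, then each length receives independent
multiplicative lognormal measurement noise. With measurement CV m the
ratio estimator acquires a small positive bias of order 0.5·m²·ratio,
which the recovery tests budget for.

What the generator does **not** emulate: litter-level random effects in
the inference sense, chromosome-specific identities (the data collapse
all metacentrics into a count), unbalanced gametes from adjacent
segregation, or embryonic-lethality timing. Passing tests therefore
show the estimators are correct under the stated independence
assumptions, not that real cohorts satisfy those assumptions.

All randomness flows through NumPy's `default_rng` (PCG64); a given
seed reproduces a dataset exactly on any platform, and seeds are
explicit arguments throughout.

## Numerical and formatting choices

* Printed means/percentages use 2 decimals and p-values 4 decimals,
  half-up rounding (so 3.125% prints as 3.13), making table reproduction
  byte-stable; `rbdrive.io.fmt` is the single shared formatter.
* Reducing 10 plate counts to one karyotype call takes the mode and
  raises `AmbiguousKaryotypeError` on a tie — silent tie-breaking would
  fabricate a karyotype.
* A chi-square bin with zero expectation and non-zero observation under
  the asymptotic method raises rather than returning infinity.
* Degenerate inputs (empty cohorts, all offspring in one class, all-zero
  viability after masking) raise with specific messages.

## Known inconsistencies in the bundled reference data

Two internal inconsistencies of the source tables are documented and
warned about at fixture-load time: the maternal expected-frequency
column of the source is consistent with N = 84 although the cohort size
is 83 (this package computes expectations from the actual N = 83; both
choices give a p-value that rounds to 0.0000), and one descendant's mean
ratio is printed as 25.61 and 26.61 in different places (the fixture
uses 25.61; the exceedance count of 5 is unaffected either way). The
source also prints 50.7% for the paternal mean fraction where 228/448 =
50.89%; the package reports the recomputed value.

## Problem sizes used in the test suite

The statistical property checks run at desk scale: 2000 null cohorts of
N = 56 with 1000 resamples each for Monte-Carlo calibration, 200
replicates of N = 500 for estimator recovery, and 500 replicates of
N = 83 for the viability-detection power check. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.
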