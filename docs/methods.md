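# Methods

## Study design being modelled

The package analyzes city-level overweight prevalence among Chinese adults
aged 45+ against urban air pollution. Individual height/weight records are
converted to BMI = weight(kg)/height(m)² and categorized by the Chinese
national standard with lower-inclusive, half-open intervals —
underweight (0, 18.5), normal [18.5, 24), overweight [24, 28),
obese [28, ∞). "Overweight prevalence" counts BMI ≥ 24 (overweight plus
obese), matching the BMI < 24 / ≥ 24 dichotomy customary for this
population; `include_obese=False` restricts to [24, 28). Ages are split at
60: middle-aged [45, 60), elderly [60, ∞); 60 itself is elderly. Records
under 45 are excluded with a logged count. Prevalence is the per-city,
per-age-group fraction, and cells with zero members are omitted rather
than reported as zero, since an absent cell and a zero prevalence are
different facts.

Note on the source definition: the survey literature this emulates
occasionally misprints BMI as height divided by weight squared; the
universal weight/height² is what is implemented.

## Spatial weights

Cities are represented by centroids, so the default neighborhood is
k-nearest-neighbor (k = 5) under great-circle (haversine) distance,
row-standardized. k-NN guarantees no isolates and behaves sanely with the
very uneven city density of a China-scale lattice; a fixed distance band
and polygon contiguity (via shapely) are available when they fit the data
better. Exact distance ties fall back to unit-id order and are logged.
Weights round-trip through GAL (topology only).

## Moran's I

The global statistic is the classical double-sum ratio with population
S²; E(I) = −1/(n−1). The printed sources this emulates give Z without a
variance formula, so the standard Cliff–Ord moments are provided under
both the normality and the randomization assumption (default:
randomization), plus a conditional permutation test. The permutation p is
two-sided and symmetric about E(I): p = (1 + #{|I⁽ᵖ⁾ − E(I)| ≥ |I −
E(I)|}) / (n_perm + 1). Permutation draws are vectorized (one matrix
product per batch), which keeps 1000-simulation calibration runs cheap.
Constant inputs (S² = 0) raise rather than return a value.

## Getis-Ord Gi*/Gi

The raw statistic is the value-mass ratio Σⱼ wᵢⱼxⱼ / Σⱼ xⱼ, which lies in
[0, 1] for nonnegative values with binary or row-standardized weights.
Inference uses the exact Ord–Getis first two moments: the self-inclusive
Gi* variant (default, `include_self=True`) uses global mean/variance and
n; Gi excludes unit i from its own mean and variance, which makes its
analytic null identical to the conditional permutation null (the tests
exploit this). When a weights matrix without self-weights is supplied for
Gi*, the unit is treated as one more neighbor: its self-weight is the
row's largest neighbor weight, re-standardized if the input was. Z-scores
map to classes at |z| ≥ 1.645 / 1.96 / 2.576 (90/95/99%), sign deciding
hot vs cold.

## Geodetector

**Discretization.** Exposures become ordinal strata by quantile (default,
L = 5), equal-interval, or Fisher–Jenks natural breaks (exact dynamic
program, O(L·n²), written in-package since no installed library provides
it). Duplicate quantile breaks merge; the effective L′ ≤ L is recorded and
warned about. Values equal to a break go to the lower stratum.

**Factor detector.** q = 1 − SSW/SST with population (÷N_h) variances —
the only convention under which q equals ANOVA η² exactly and stays in
[0, 1]; sample variances would break both. Singleton strata contribute
zero within-variance, consistent with the formula, but are flagged
because they mechanically inflate q. Constant responses raise.

**Significance.** F = ((N−L)/(L−1))·q/(1−q) referred to a noncentral
F(L−1, N−L; λ) with λ = (1/σ²)[Σ_h Ȳ_h² − (Σ_h √N_h Ȳ_h)²/N], the
published q-test for this statistic. A stratum-label permutation
alternative is provided (vectorized: SSW reduces to one matrix product
because Σy² is permutation-invariant). Both calibrate to nominal size in
the test suite (rejection rate ∈ [0.03, 0.07] at α = 0.05 over 1000 null
simulations at n = 200, L = 5). q = 1 reports p = 0 flagged as an
infimum. Significance markers `a`/`b` are emitted at 0.05/0.01.

**Interaction detector.** Overlay zones are the non-empty cells of the
cross-classification; q₁₂ is the factor q on that partition. Because the
overlay refines both marginals, SSW cannot increase, so q₁₂ ≥ max(q₁, q₂)
up to floating point — the two weakening categories can only arise for
externally supplied q triples, and the classifier still implements all
five for that use. Independence (q₁₂ = q₁ + q₂) is tested within
tol = 1e-9, since exact equality never occurs in floating point. An
all-singleton overlay returns q₁₂ = 1 with a degenerate-overlay warning.

## Synthetic study generator

The generator reproduces the *conditions* of the emulated study, not any
particular realization:

* **Lattice.** 122 cities uniform over (74–134°E, 18–53°N); region =
  north iff latitude ≥ 33°N, a flat-latitude proxy for the
  Qinling–Huaihe line (region enters the analysis only as a label, so the
  GIS boundary is not needed).
* **Pollutants.** Five fields with region-specific target means/sds taken
  from the published region-wise summaries (e.g. PM2.5 56.21 north /
  43.50 south µg/m³); sds are back-solved from the 5–95% spans under
  normality, (q95−q5)/3.29. Each field is a standard Gaussian process
  with exponential correlogram exp(−d/range) (default range 500 km,
  Cholesky-sampled) pushed through a moment-matched lognormal, so values
  are positive, spatially autocorrelated, and mean-calibrated. range = 0
  gives iid fields.
* **Individuals.** 16,171 records; 49.1% middle-aged, 53.7% female
  (published shares); ages uniform within group; height Gaussian by sex;
  BMI Gaussian per age group (middle-aged mean 24.0, elderly 23.4, sd
  3.5 — chosen so the overall BMI ≥ 24 share is ≈46%, the published
  individual-level rate), plus a regional shift (north +0.7, south −0.7,
  sized to reproduce the reported ≈55% vs ≈39% regional contrast) and an
  optional pollutant coupling: the chosen pollutant's quantile strata
  shift the city's BMI mean, which is how end-to-end runs acquire a
  detectable q with known provenance. Weight is derived from BMI and
  height. Allocation to cities is equal-count by default (multinomial
  optional); the emulated study never published per-city sample sizes.
* **Stratified responses.** `generate_response` draws city-level values
  as stratum mean + iid N(0, σ_w²) noise, so the theoretical
  q = Var_between/(Var_between + σ_w²) is exact (Var_between is the
  stratum-size-weighted population variance of the configured means);
  `strata_means_for_q` inverts this for equal strata. Clipping to [0, 1]
  is off by default because it biases q; when enabled the flag and
  clipped count are recorded.
* **Determinism.** One integer seed; every generator draws from a named
  `SeedSequence` substream (`[seed, crc32(name)]`), so identical
  (config, seed) reproduces identical tables byte-for-byte and modules
  can be regenerated independently.

What the generator does **not** emulate: survey sampling design, weights
and nonresponse; within-city spatial structure; measurement error in
anthropometrics; temporal pollution dynamics. Passing tests therefore
demonstrate the statistical machinery on data with the study's marginal
and covariance structure, not epidemiological conclusions about real
populations.

A known internal tension in the emulated tables — city-mean prevalences
near 67%/57% versus an overall individual-level rate of 46% — cannot be
resolved from the published material; the generator targets the
individual-level rate and the regional contrast, and treats the city-mean
table only as a shape reference.

## Pipeline and reporting

`run_full` chains simulate → prevalence → Moran/Gi* (national, per age
group) → Geodetector (per region × age group, all five pollutants, all 10
pairs), writing CSV/GeoJSON/GAL artifacts and a JSON manifest (config,
seed, library versions, stage log, collected warnings) sufficient to
reproduce every number. Prevalence summaries use linear-interpolation
percentiles and city-unweighted means (the emulated tables do not state
either choice). Reruns with identical config are byte-identical; this is
tested.

## Problem sizes in the calibration experiments

The acceptance experiments use n = 200–500 units, 200 replicates for
recovery, and 1000 simulations for null calibration with 199-draw
permutation tests — sizes at which the Monte-Carlo standard error of a
rejection rate (≈0.007) and of a mean q (≈0.001) is well inside the
asserted tolerances, chosen to keep the whole suite comfortably fast.

## Known limitations

* Gi* analytic z-scores use the total-randomization moments; for heavily
  skewed values at small n their normal tail is approximate (the Gi
  variant is exact against conditional permutation and is what the
  agreement test checks).
* The noncentral-F q-test estimates λ from the data, as the published
  test specifies; for tiny strata (N_h < 5) its size can drift and the
  permutation variant is preferable.
* GeoJSON output is points-only; no choropleth/cartographic rendering.
* Fisher–Jenks is exact but quadratic in n; for n ≫ 10⁴ use quantile
  breaks.
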