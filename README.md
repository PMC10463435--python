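# stratq

Spatial stratified-heterogeneity analysis of overweight prevalence versus
air pollution, for spatial epidemiologists working with city-level survey
aggregates.

Middle-aged (45–60) and elderly (60+) adults are classified by the Chinese
BMI standard (overweight: BMI ≥ 24 kg/m²), aggregated to city-level
prevalence, and analyzed in three stages:

1. **Spatial pattern.** Global Moran's I over a k-nearest-neighbor
   great-circle weights matrix,

       I = Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / (S² Σᵢⱼ wᵢⱼ),   S² = (1/n) Σᵢ (xᵢ−x̄)²,

   with E(I) = −1/(n−1), analytic (normality / randomization) or
   permutation inference; and local Getis-Ord Gi* hot/cold-spot classes at
   the 90/95/99% levels.

2. **Factor detector.** Each pollutant (PM2.5, PM10, SO2, O3, NO2) is cut
   into L ordinal strata (quantile, equal-interval or Fisher–Jenks) and its
   explanatory power for prevalence is the Geodetector q-statistic

       q = 1 − SSW/SST,   SSW = Σ_h N_h σ²_h,   SST = N σ²,

   identically the one-way ANOVA η², with a noncentral-F or permutation
   significance test.

3. **Interaction detector.** q is recomputed on the overlay of two
   stratifications and the triple (q₁, q₂, q₁₂) is classified into
   nonlinear/univariate weakening, bivariate or nonlinear enhancement, or
   independence.

A synthetic-study generator reproduces the analysis conditions — ~122
cities split north/south at 33°N, ~16,000 individuals, pollutant fields
with configurable spatial correlation and region-specific marginals, and
stratified responses whose **theoretical q is known in closed form** — so
the full pipeline is testable end to end without restricted survey data.

## Worked example

```python
import stratq as sq

cfg = sq.RunConfig(
    synthetic=sq.SyntheticConfig(seed=7, coupling=sq.Coupling()),  # SO2-coupled
    seed=7, out_dir="demo_out")
bundle = sq.run_full(cfg)
print(bundle.moran[["age_group", "I", "z"]].round(3).to_string(index=False))
print(bundle.factor_q.query("region == 'north' and age_group == 'elderly'")
      [["factor", "q", "significance"]].round(3).to_string(index=False))
```

prints

```
  age_group     I      z
middle_aged 0.369  7.082
    elderly 0.559 10.637

factor     q significance
  pm25 0.044
  pm10 0.084
   so2 0.619            b
    o3 0.005
   no2 0.041
```

Both age groups show strong positive spatial autocorrelation of prevalence
(I ≈ 0.37–0.56, z ≫ 2), as built into the generator through the regional
BMI contrast and the spatially correlated pollutant coupling; the factor
detector attributes the stratified heterogeneity to SO2 (q ≈ 0.62,
significant at the 1% level, marker `b`), the pollutant the synthetic
coupling actually used, while the uncoupled pollutants stay near q ≈ 0.

The same pipeline runs from a shell:

```sh
stratq full --seed 7 --out demo_out          # or simulate|prevalence|autocorr|detect
```

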