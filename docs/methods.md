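# Methods

This note records the models, conventions, and numerical choices behind
`kelpwave`, and what the synthetic-data tests do and do not demonstrate.

## Temperature metrics

**Inputs.** Daily, per-zone SST (°C) emulating a 5-km nighttime foundation-SST
satellite product. Dates must be unique and increasing; gaps are allowed.
Values outside [−5, 40] °C trigger a warning, not an error.

**Day-of-year mapping.** All climatology arithmetic uses a 365-day calendar:
February 29 maps to day 59 (sharing February 28), so March 1 is day 60 in
every year. This keeps the seasonal phase aligned across leap years.

**Climatology.** For each day-of-year *d*, the climatology is the mean of all
reference-year observations whose day-of-year falls within
*d* ± `smoothing_halfwidth` (circular across the year boundary). The default
halfwidth is 15 days (a centred 31-day window), standard practice for daily
SST climatologies; halfwidth 0 gives the plain per-day mean and is used where
tests need bit-level exactness. A pre-computed climatology (e.g. a satellite
product's own) can be supplied instead via `climatology.csv`. A day-of-year
with no pooled observations is an error; under 50% of the expected count is a
warning.

**Water-year windows.** The exposure window for survey year *Y* is
1 September *Y*−1 through 31 August *Y*, inclusive — the year preceding the
(summer) canopy survey.

**The three annual metrics.**

- *Warmest-month mean SST*: maximum over the window's calendar months of the
  monthly mean daily SST. Ties break to the earliest month (Sept → Aug
  order).
- *Maximum monthly SSTA*: maximum over months of the monthly mean of daily
  anomalies. Calendar months are used, not sliding 30-day blocks.
- *Days with SSTA > 0 °C*: strictly positive anomalies only; a day at exactly
  0 °C does not count, and missing days never count.

Months with no observations are flagged missing and excluded; a window with
fewer than 80% of its calendar days present is logged but still summarised.
Zones sharing a satellite grid cell (via `zone_cells.csv`) receive identical
metric rows, computed once per cell.

A note on exactness: the strict `> 0` day count is sensitive at the last bit.
A day-of-year mean of *k* identical floating-point values can differ from
them by one ulp, so "anomaly of a series against its own rebuilt climatology"
is zero only to machine tolerance (~1e-15 °C). Exact-count constructions in
the tests therefore pair the noise-free simulator with its closed-form
climatology (`expected_climatology`), which is bit-identical by construction.

## Canopy statistics

Canopy area (ha) is tracked per zone, sub-region, year, and species; species
are summed before sub-region aggregation. Conventions:

- Baseline = mean ± sample (n−1) s.d. over the baseline years present
  (default 2011–2013); at least two years are required.
- Percent of baseline = 100·(area − mean)/mean.
- Fold difference = max/min annual area, reported to one decimal; maximum
  loss = 100·(mean − window minimum)/mean, reported to the nearest integer
  percent. Full precision is retained internally; rounding applies only to
  reported tables.
- Recovery: threshold = mean − 1·s.d. The decline year is the first year at or
  after the heatwave onset (default 2014) below the threshold; the recovery
  year is the first later year at or above it. A symmetric variant
  (|area − mean| < s.d., so a large overshoot does not count as recovered) is
  available via `symmetric=True`. Absence of decline or recovery is encoded
  as `None`, not an error. Note the one-sided recovery year is monotone in
  the threshold only while the decline year stays fixed; if raising the
  threshold also moves the decline earlier, recovery can legitimately move
  earlier too.
- Scaling for regression: per zone and species, area divided by the maximum
  over the configured analysis period; exact 0 → 0.01 and exact 1 → 0.99 so
  responses are strictly inside (0, 1). Missing survey years are skipped, not
  interpolated.

## Beta regression

The response y ∈ (0,1) is Beta(μφ, (1−μ)φ): E[y] = μ, Var[y] = μ(1−μ)/(1+φ).
The mean submodel is g(μ) = β₀ + β₁x with g the Cauchy quantile function
tan(π(μ−½)) by default (logit and probit are available); its heavy tails let
fitted means saturate toward 0/1 slowly, which suits canopy fractions that
pile up near the zone maximum. The precision is either constant
(φ = exp γ₀) or log-linear in the covariate (φ = exp(γ₀ + γ₁x)).

Fitting is maximum likelihood: starting values from least squares of g(y) on
x, with a delta-method method-of-moments φ from the residual variance; BFGS
on the analytic score, with a Nelder–Mead polish if the maximum-gradient
criterion (‖score‖∞ < 1e-3 for the convergence flag; the optimizer itself
targets 1e-8) is not met. Standard errors come from the observed information
(central finite differences of the analytic score, relative step 1e-5);
p-values are two-sided Wald z. When the information matrix is singular (for
instance a constant covariate), a pseudo-inverse is used so the identifiable
directions remain usable. AIC = −2ℓ + 2k with k = 3 (constant φ) or 4.

- *Pseudo-R²* = squared Pearson correlation between the fitted linear
  predictor η̂ and g(y), with g the same link as the fit; defined as 0 when η̂
  has no variance.
- *Precision misspecification*: LR statistic 2(ℓ_full − ℓ_reduced) clamped at
  0, df = 1, p from χ². Non-converged fits are refused.
- *Model comparison*: fits on the same observations ranked by AIC; fits
  within 1 of the minimum are reported as co-best.

The test suite cross-checks the logit-link path against an independent
maximum-likelihood implementation (statsmodels' beta model) and the
Cauchy-link path against a dense grid search; correctness of the likelihood
itself is checked against the closed-form beta density.

## Diagnostics

- **Breusch–Pagan**: OLS of the response on the covariates, auxiliary OLS of
  squared residuals on the same design; studentized (Koenker) statistic
  n·R²_aux ~ χ²_k by default, classical ESS/(2σ̂⁴) behind a flag. Applied in
  the pipeline to the link-transformed response, since the test is defined
  for a linear model.
- **Moran's I** on inverse-Euclidean-distance weights between zone centroids
  (any consistent planar projection; zero diagonal, no row standardization).
  Expectation −1/(n−1); the two-sided normal p-value uses the Cliff–Ord
  randomization variance, which requires n ≥ 4 — with exactly 3 zones the
  statistic is returned with p = NaN, and the pipeline skips sub-regions with
  fewer than 4 located zones.
- **Wilcoxon rank-sum**: W = #{(a,b): a > b} + ½·ties (the Mann–Whitney U of
  the first group, the same quantity R prints as W). Exact distribution when
  min(n) ≤ 10 and there are no ties; otherwise normal approximation with tie
  and continuity corrections.
- **Levene**: one-way ANOVA F on absolute deviations from the group centre;
  median centring (Brown–Forsythe) by default, mean centring selectable.

## Synthetic data

`simulate_sst` builds sst(t) = mean + A·cos(2π(doy(t) − peak)/365) + AR(1)
noise + Σ boxcar events. The cosine is evaluated on the same 365-day
day-of-year index the climatology uses, so a noise-free series equals its own
halfwidth-0 climatology exactly. AR(1) innovations are Gaussian with
innovation s.d. = noise_sd·√(1 − ρ²), making `noise_sd` the stationary
marginal s.d. Defaults (10 °C mean, ±4 °C seasonal range peaking at day 227,
ρ = 0.8, 0.4 °C marginal noise) describe a cool temperate sea.

`simulate_canopy` z-scores the chosen metric across the zone-year rows, sets
μ = Cauchy⁻¹-link(β₀ + β₁z), draws y ~ Beta(μφ, (1−μ)φ), and scales by a
baseline area; the generating parameters are returned as a truth record.

`make_fixture` assembles six sub-regions × 10 zones across 1989–2021 with a
heatwave block starting mid-September 2014 whose intensity (1.0 → 3.5 °C) and
duration (180 → 940 days) escalate inland, mean SST also increasing inland,
and canopy driven by the maximum monthly SSTA with β₁ = −1.5, φ = 60 — a
signal strong enough that the qualitative outcomes (coincident declines,
later recovery inland, negative fitted slopes) are stable across seeds.

What the generator does **not** emulate: spatially correlated noise fields,
nutrient or biotic covariates, species-specific dynamics, observation error in
aerial delineation, or serial dependence of canopy on its own past. Passing
tests therefore demonstrate that the estimators and classifiers recover known
structure of this idealized form — not that temperature explains any
particular share of real canopy variance. The published regression tables
themselves depend on the real survey and satellite records and are out of
reach of desk-scale simulation; the end-to-end fixture covers their
qualitative content (sign and ordering) only.

## Problem sizes and the acceptance script

`scripts/acceptance.py --seed S --out f.json` recomputes, at sizes chosen to
keep a single-CPU run in minutes:

- fold differences and maximum losses from the published sub-region canopy
  summaries (deterministic; the printed minima/maxima/baselines are inputs);
- slope bias and 95% Wald coverage over 100 replicates of n = 500
  observations from (β₀ = 0.3, β₁ = −0.8, φ = 20) with the Cauchy link;
- Breusch–Pagan and Levene rejection rates at α = 0.05 over 1000 Gaussian
  homoscedastic null simulations each (n = 50; 3 × 30);
- the full synthetic-study pipeline (fraction of negative fitted slopes,
  Spearman correlation of injected anomaly duration with recovery year, the
  recovery lag of the innermost vs the coastal sub-region, and the smallest
  Moran's I p-value).

The test suite additionally runs 200-replicate parameter recovery, a
500-simulation uniformity check of the precision-LR p-values, and exhaustive
small-sample Wilcoxon/Moran oracle comparisons.
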