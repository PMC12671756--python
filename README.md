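# kelpwave

Tools for relating annual floating-kelp canopy area to marine-heatwave (MHW)
temperature exposure, built around the 2014–2016 Northeast Pacific MHW and the
bull kelp (*Nereocystis luetkeana*) / giant kelp (*Macrocystis pyrifera*)
canopies of Washington State, USA. The package turns daily sea-surface
temperature (SST) and annual aerial canopy surveys into:

1. **Annual temperature metrics** per zone over September–August "water
   years": mean daily SST of the warmest month, maximum monthly SST anomaly
   (SSTA, relative to a day-of-year climatology), and the count of days with
   SSTA > 0 °C — proxies for peak temperature, anomaly magnitude, and
   accumulated thermal stress.
2. **Canopy baseline and recovery statistics**: pre-MHW baseline mean ± s.d.
   (2011–2013 by default), percent-of-baseline trajectories, fold differences
   (max/min canopy area), maximum loss during the heatwave window, and the
   recovery year — the first post-decline year at or above mean − 1 s.d.
3. **Beta regression** of scaled canopy area (fraction of the zone maximum,
   clamped into (0.01, 0.99)) on a temperature metric, with a **Cauchy mean
   link** g(μ) = tan(π(μ − ½)) and the mean–precision parameterization
   y ~ Beta(μφ, (1−μ)φ), fitted by maximum likelihood with analytic score.
   Models per sub-region × metric are compared by AIC (ties within 1 ΔAIC),
   with pseudo-R² = corr(η̂, g(y))².
4. **Diagnostics**: Breusch–Pagan (studentized by default), a likelihood-ratio
   test for covariate-dependent precision φ, Moran's I on inverse-distance
   weights for spatial autocorrelation among zones, Wilcoxon rank-sum and
   Levene tests for species comparisons.
5. **A synthetic-data generator** (seasonal cycle + AR(1) noise + boxcar
   heatwave events; canopy drawn from a known beta-regression truth) so the
   entire pipeline is testable without satellite or survey downloads.

## Worked example

```python
import numpy as np
from kelpwave import beta_regression as br, canopy_response as cr
from kelpwave import sst_metrics as sm, synthetic_data as sd

# fold difference and max loss from published sub-region summaries
print(cr.fold_difference(215.0, 441.0))   # 2.1   (open coast, 2011-2018)
base = cr.BaselineStats("open_coast", (2011, 2012, 2013), mean_ha=361.0, sd_ha=63.0)
print(cr.max_loss({2015: 215.0}, base, range(2014, 2017)))  # 40  (% of baseline)

# a noise-free series with a 30-day +2 °C heatwave filling June
params = sd.SstSimParams(noise_sd=0.0,
                         heatwave_events=(("2003-06-01", 30, 2.0),),
                         years=(2001, 2003))
series = sd.simulate_sst(params)["Z1"]
anoms = sm.anomaly_series(series, sd.expected_climatology(params))
w = sm.WaterYearWindow(2003)          # Sept 2002 - Aug 2003
print(sm.metric_days_positive(anoms, w))      # 30
print(sm.metric_max_monthly_ssta(anoms, w))   # 2.0

# recover a known temperature-canopy relationship
rng = np.random.default_rng(1)
x = rng.normal(size=500)
mu = br.inverse_cauchy_link(0.3 - 0.8 * x)
y = rng.beta(mu * 20, (1 - mu) * 20)
fit = br.fit_betareg(y, x)
print(np.round(fit.beta, 2))          # [ 0.28 -0.81]  (truth: 0.3, -0.8)
```

The first two numbers say the open-coast canopy varied 2.1-fold over
2011–2018 and lost at most 40% of its pre-heatwave baseline during 2014–2016.
The metric block shows the injected event is recovered exactly by the anomaly
machinery. The final fit recovers the generating slope well within sampling
error.

## Command line

```bash
kelpwave simulate --seed 42 --out-dir fixtures/
kelpwave metrics  --sst fixtures/sst.csv --reference-years 1989-1995 \
                  --years 2011-2018 --out metrics.csv
kelpwave response --canopy fixtures/canopy.csv --out-dir results/
kelpwave regress  --scaled results/scaled.csv --metrics metrics.csv \
                  --sub-region Coast --metric max_monthly_ssta --out fit.json
kelpwave run      --config run.yaml
```

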