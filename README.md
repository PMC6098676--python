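# rhinopfc

Tools for computing and interpreting the **proportion of females calving
(PFC)** — annual births divided by the number of females that were adult
during any part of that year — as a population-level reproductive indicator
for megaherbivores, built around the demographic history of a closed,
reintroduced black rhinoceros (*Diceros bicornis minor*) population monitored
individually over 1986–2008.

PFC is attractive for monitoring because it needs far less data than
individual-level measures (inter-birthing intervals, age at first
reproduction). But for asynchronous breeders whose inter-birthing interval
(IBI, here 29.0 months) exceeds a year, a PFC time series is autocorrelated
by construction — a female calving this year is unlikely to calve next year —
and fluctuates strongly through demographic stochasticity and founding
effects. This package implements the full analysis chain for such data, plus
an individual-based simulator to quantify how much PFC variation arises with
*no* environmental or density driver at all.

## What it computes

1. **Life-history registry** (`rhinopfc.life_history`): dated individual
   records (births, imports, exports, deaths, calvings) with validation
   (calving spacing ≥ 15-month gestation), stage classification (a female is
   adult once she has calved or reaches age 7), annual PFC with the
   part-year denominator rule, end-of-year census tables, and du Toit's
   benchmark bands (<0.29 very poor–poor, 0.29–0.33 poor–mod, 0.33–0.40
   mod–good, >0.40 good–excellent).
2. **Transforms** (`rhinopfc.transforms`): the standard arcsine-square-root
   transform and the modified count-based version
   `transPFC = ½[asin√(x/(n+1)) + asin√((x+1)/(n+1))]`, covariate
   construction (density as prior-end-of-year total over the 220 km² area,
   calendar-year and prior-year rainfall), standardization, trailing moving
   averages with dispersion summaries, and ACF/PACF correlograms.
3. **Model selection** (`rhinopfc.model_selection`): the Gaussian AR(2)
   regression

   `transPFC_t = b₀ + b₁·transPFC_{t−1} + b₂·transPFC_{t−2} + c₁·density + c₂·rain + c₃·rain₁ + ε,  ε ~ N(0, σ²)`

   fitted by conditional maximum likelihood for **all 2⁵ = 32 covariate
   subsets** on one common response window, ranked by AICc; Akaike weights,
   the 0.95 confidence set, natural model averaging with unconditional SEs,
   and per-term relative importance. Exposed as scikit-learn style
   estimators (`GaussianMLRegressor`, `ARXModelSelector`).
4. **Simulator** (`rhinopfc.simulate`): a monthly individual-based model of
   the reintroduced population (staged imports, gamma-distributed conception
   waits calibrated to IBI 29.0 ± 7.9 months, stage-specific survival,
   optional log-linear density/rainfall effects on conception) driving the
   false-signal and PFC-variance experiments.

## Worked example

The packaged census table (the study population's 1986–2008 demographic
history) ships with the package:

```
$ rhinopfc reproduce --out-dir out/
NOTICE: rainfall series not supplied (it is not part of the published table);
rain-dependent results are unavailable and the ranking covers the 8 rain-free models.
                    computed  published  tolerance status
quantity
PFC mean            0.397205      0.400     0.0050   PASS
PFC SD              0.241740      0.240     0.0050   PASS
MA(3) mean          0.400993      0.400     0.0050   PASS
MA(3) SD            0.063116      0.063     0.0005   PASS
MA(11) SD           0.015839      0.016     0.0005   PASS
density lag-1 corr  0.991047      0.990     0.0050   PASS
dAICc lag1-only     0.482451      0.070     0.5000   PASS
dAICc null          5.229210      5.390     0.5000   PASS
dAICc lags+density  3.608393      3.470     0.5000   PASS
```

Reading the numbers: the 22 annual PFC values average 0.40 (SD 0.24) — on
average "mod–good" by du Toit's bands, but with single years as low as 0.08
and as high as 1.0; a 3-year moving average keeps the mean and cuts the
dispersion to 0.063 (26 % of the raw SD). The best AICc model regresses
transPFC on its own two lags with *negative* coefficients (the 29-month IBI
echo), the intercept-only model sits ~5.2 AICc units behind, and adding
density costs ~3.6 units — the growing population's density carries no PFC
signal. Density is collinear with its own lag (r = 0.99), which is why the
lagged copy is dropped from the candidate set.

Simulation, from Python:

```python
from rhinopfc import SimulationConfig, simulate, false_signal_experiment

out = simulate(SimulationConfig(seed=1))
print(out.summary)
# {'realized_growth_rate': 0.082, 'realized_ibi_mean_months': 27.4, ...,
#  'pfc_mean': 0.415, 'pfc_sd': 0.219, 'final_population': 93}

fs = false_signal_experiment(SimulationConfig(seed=11), replicates=100)
print(fs["ci_exclusion_rate"])   # how often a null covariate "signals"
# density 0.01, rain 0.05, rain_1 0.09
```

Subcommands: `pfc`, `census`, `transform`, `correlogram`, `fit-rank`,
`moving-average`, `benchmark`, `simulate`, `false-signal`, `reproduce`
(see `rhinopfc --help`). Every stochastic run writes a manifest with its
seed; `fit-rank --rainfall rain.csv` (columns `year,rain_mm`) switches from
the 8 rain-free models to the full 32.

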