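# Methods

## The indicator

For calendar year *y*, PFC(*y*) = (births in *y*) / (number of females adult
during any part of *y*). Adulthood is conferred by a first calving or by
reaching seven years, and is never revoked; the denominator therefore counts
females who matured, died or were exported mid-year. A year with no adult
female has no defined PFC and the computation refuses to emit 0 or NaN for
it. Births are counted from mothers' calving dates, so a registry whose
calves are individually registered stays consistent automatically.

Stage classification beyond the adult rule is census convention only:
calf/subadult at 3.5 years and male adulthood at 7 are configurable defaults
(`StageConfig`) that never affect PFC. Imported animals of unknown age get a
nominal age at entry (calf 1.75 y, subadult 5.25 y, adult 10 y — stage
midpoints, with adults placed comfortably past the threshold) so later
transitions are well defined; such ages are recognizable via
`LifeHistoryRecord.is_import` with `birth_date=None`. Census rows are
end-of-calendar-year compositions, which is what makes the packaged table's
totals monotone. Dates are whole calendar days; ages use exact year
fractions (365.25 d/y).

The packaged census ships the published demographic history 1986–2008
(22 PFC years, totals 3→110, adult females 1→29, 23 surviving imports, 5
exports in 2006). The published source text says "four" founders while its
own table row for 1986 sums to 3; the package follows the table. Integer
birth counts are recovered from the rounded PFC column as
x = round(pfc·n_adult_females), asserting |pfc − x/n| < 0.5/n. For a few
years (e.g. 1998, 2005) the published proportion was evidently computed on a
part-year denominator one larger than the end-of-year adult-female column;
the recovered counts remain uniquely determined and consistent.

## Transforms and summaries

The modified arcsine transform
½[asin√(x/(n+1)) + asin√((x+1)/(n+1))] operates on the recovered counts,
not the rounded proportion, lies strictly inside (0, π/2) and is strictly
increasing in x — boundary years (PFC 0 or 1) stay ordered and finite, which
the standard asin√p does not guarantee. Both transforms are computed; the
modified one ("transPFC") is the modelling response.

Moving averages are trailing, full-window only, aligned to the last year of
the window; the value set (hence any dispersion summary) is
alignment-invariant. The headline dispersion is the population SD
(divisor n) of the window-mean series — on the packaged data this reproduces
the published 0.063 for window 3 and 0.016 for window 11, where the
sample-SD alternative (also reported) gives 0.065/0.017. One nuance: the
window-3…11 SD sequence is *nearly* but not strictly monotone — it rises by
~0.0008 at windows 7→8 and ~0.0004 at 9→10 (0.0631, 0.0508, 0.0465, 0.0329,
0.0306, 0.0314, 0.0195, 0.0198, 0.0158). The published description of a
monotone decrease holds only as a broad trend; the corresponding regression
test records the discrepancy rather than hiding it.

ACF uses the standard biased sample estimator; PACF uses the
Durbin–Levinson recursion on the same autocovariances (statsmodels
`pacf(method="ldb")`), so PACF(1) ≡ ACF(1). Significance bounds are the
flat ±1.96/√n.

Covariates: density(y) = end-of-year total of y−1 over 220 km²; rain(y) and
rain_1(y) = rain(y−1) when a rainfall series is supplied. The one-year
lagged density is computed only as a diagnostic — in this monotonically
growing population it correlates with density at 0.99 and is excluded from
the candidate set. Covariates are standardized (sample SD) over the
modelling window; the lagged responses are not standardized.

## Model selection

Likelihood: conditional Gaussian ML. The printed global model is a
regression with i.i.d. Gaussian errors, so the lagged responses are treated
as observed regressors; coefficients solve the normal equations,
σ̂² = RSS/n, logLik = −(n/2)(log 2πσ̂² + 1). Coefficient SEs use the
unbiased divisor n−p. An exact state-space likelihood would handle the
initial lags differently; this is the known source of small AICc
discrepancies (≲0.5) against ranking tables produced with state-space
software, and why the ranking comparisons carry a ±0.5 tolerance.

All 2^m submodels are fitted on the **same** response window — years where
the response, both lags and every candidate covariate exist (1989–2008,
n = 20, on the packaged data). Per-model windows would make information
criteria incomparable. AICc = −2logLik + 2k + 2k(k+1)/(n−k−1) with k
counting intercept, slopes and σ². Ties in the ranking break deterministically
toward fewer terms, then canonical term order. Weights are normalized
exp(−Δ/2); the confidence set is the smallest top prefix with cumulative
weight ≥ 0.95; model averaging is "natural" (over models containing the
term, renormalized weights) with unconditional
SE = Σᵢ wᵢ√(seᵢ² + (bᵢ − b̄)²); relative importance sums weights over all
2^m models. A term absent from every confidence-set model is flagged
absent, never silently zeroed. Without a rainfall series the candidate set
is {lag1, lag2, density} (8 models) and the CLI says so explicitly; the
published rainfall series is not part of the published table, so
rain-dependent results (all-32 relative importances, the 46 % global-model
variance explained) require the user to supply one.

An interpolating (zero-residual) fit returns its coefficients but has
σ̂² = 0 and infinite log-likelihood; information criteria are deliberately
unavailable on that path.

## Simulator

Monthly time step (gestation and IBI are month-scale quantities). Each
female, once eligible, draws a required conception wait
W = (ibi_min − gestation) + Gamma(shape, scale), with the gamma solved from
the configured IBI mean 29.0 and SD 7.9 months (SD back-computed from the
published SE 0.9 at n = 77; the gamma family is a modelling choice — only
the first two moments are constrained by the study). Covariate effects
multiply the monthly wait work-off rate by exp(c_d·density + c_r·z_rain),
so zero slopes reproduce the configured IBI exactly and a negative density
slope stretches intervals as the population grows. Conception occurs in the
month the accumulated rate-weighted exposure crosses W, with a half-month
starting credit to centre the discretization; no exposure accrues in the
calving month itself, enforcing the post-partum minimum. Gestation then runs
exactly 15 months. Nulliparous females start the same waiting process at
age afr·12 − ibi_mean months, so the expected age at first calving equals
the configured 7 years. Deaths are monthly Bernoulli draws from
stage-specific annual survival; sexes at birth are Bernoulli(0.5).

Within one female, calvings share a fixed per-female day-of-month, so the
≥15-month spacing invariant holds by construction for any month gap ≥ 16
(the configuration requires ibi_min ≥ gestation + 1); other event days
jitter uniformly. Every simulated registry passes full life-history
validation.

Defaults are the study conditions: the 23-animal staged import schedule
(1986–1997, dominated by the 1997 subadult-female pulse), the 2006 removal
of five subadults, 220 km², 23-year horizon. Annual rainfall is a
stationary AR(1) with mean 550 mm, SD 120 mm and autocorrelation 0 (the
study's two rain measures correlated at −0.06). Stage survivals
{calf 0.95, subadult 0.97, adult 0.97} are calibration constants, not
measured values, chosen for the growth-rate target. Under these defaults,
across replicates: realized mean IBI ≈ 28.2 months (the 0.8-month deficit
from 29.0 is end-of-study censoring — long intervals in progress at the
horizon are never observed — plus residual discretization), realized
post-import exponential growth ≈ 0.073/yr (within the 0.10 ± 0.03
calibration band; the band's width reflects that the study's 0.102 was
fitted to a census trajectory that includes import pulses), mean age at
first calving ≈ 6.9 y, and mean simulated PFC ≈ 0.39 — consistent with the
12/29 ≈ 0.41 back-of-envelope for an expanding population.

What the simulator does **not** emulate: spatial structure, poaching or
environment-driven mortality, senescence, maternal effects, imperfect
detection. Passing tests therefore show that the analysis chain behaves
correctly under idealized closed-population demography with known dates —
not that real monitoring data are this clean.

## Experiments

*False signal*: with zero injected effects, each replicate simulates a
population, computes PFC, transforms it, and runs the full 32-model ranking
with its own density and simulated rainfall; a covariate "signals" when its
model-averaged 95 % CI (±1.96 unconditional SE) excludes zero. The observed
null-rain signal rate is ≈ 0.09 at 500 replicates — near, and below, the
0.10 bound used in testing. Injected rainfall effects on conception surface
predominantly in the *prior-year* rain covariate of the birth year, because
gestation displaces conception-time causes by 15 months — a structural
lesson for interpreting such regressions.

*PFC variance*: replicate distributions of annual PFC and of
moving-average SDs by window; the window-11 SD falls below the window-3 SD
in ≥95 % of replicates.

## Problem sizes and determinism

Test and acceptance-script replicate counts (500 for the false-signal and
CI-coverage checks where those are the stated conditions; 60–100 for
calibration means, whose replicate-mean standard errors are already ≲0.1
month for IBI and ≲0.002 for growth) are chosen so the whole suite runs in
a couple of minutes on one core. Replicate seeds derive from one master
seed via `numpy.random.SeedSequence`; identical seeds give bitwise-identical
registries.

## Known limitations

- Conditional (not exact state-space) likelihood; AICc values match
  state-space fits only to ≈0.5.
- Count recovery from rounded proportions assumes the published
  adult-female column is the PFC denominator; for part-year denominators
  the transform's n is then off by one in a few years (negligible at these
  magnitudes but documented).
- The simulator's survival rates are calibration constants; its realized
  growth sits in the lower half of the calibration band.
- Moving-average dispersion is not strictly monotone in window size on the
  packaged data (see above).
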