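"""Proportion transforms, covariate construction, moving averages, correlograms.

Proportions are variance-unstable near 0 and 1, so the PFC series is mapped
through the arcsine-square-root transform before autoregressive modelling.
Two variants are provided: the standard ``asin(sqrt(p))`` and a modified
count-based version,

    transPFC = 1/2 * [ asin(sqrt(x / (n + 1))) + asin(sqrt((x + 1) / (n + 1))) ]

which behaves better for proportions at or near the boundaries and is the
headline transform.  The modified form needs the integer counts (x births out
of n adult females), which are recovered from rounded published PFC values
via :func:`rhinopfc.life_history.births_from_census`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .life_history import births_from_census, census_totals

#: Study-site area, km^2 (fenced section of the Great Fish River Reserve).
DEFAULT_AREA_KM2 = 220.0


class DegenerateSeriesError(ValueError):
    """A computation requires variation the series does not have."""


def arcsine_sqrt(p):
    """Standard arcsine-square-root transform, radians in [0, pi/2]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportion outside [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def zar_transform(x, n):
    """Modified arcsine transform on counts (x successes of n trials).

    Strictly inside (0, pi/2) and strictly increasing in ``x`` at fixed
    ``n``, so years with PFC of exactly 0 or 1 remain distinguishable from
    near-boundary years.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any((x < 0) | (x > n)):
        raise ValueError("x outside [0, n]")
    out = 0.5 * (
        np.arcsin(np.sqrt(x / (n + 1.0))) + np.arcsin(np.sqrt((x + 1.0) / (n + 1.0)))
    )
    return float(out) if out.ndim == 0 else out


def transform_pfc(pfc_series: pd.Series, n_adult_females: pd.Series) -> pd.DataFrame:
    """Per-year transformed PFC table.

    Recovers integer birth counts from (possibly rounded) proportions and the
    adult-female counts, then returns columns ``births``, ``n``, ``transPFC``
    (modified transform) and ``arcsine`` (standard transform) indexed by year.
    """
    idx = pfc_series.index
    n = n_adult_females.loc[idx].astype(int)
    births = pd.Series(
        [births_from_census(p, m) for p, m in zip(pfc_series, n)], index=idx
    )
    return pd.DataFrame(
        {
            "births": births,
            "n": n,
            "transPFC": zar_transform(births.to_numpy(), n.to_numpy()),
            "arcsine": arcsine_sqrt(pfc_series.to_numpy()),
        }
    )


def standardize(series, ddof: int = 1):
    """Centre to mean 0 and scale to SD 1 (sample SD by default)."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise DegenerateSeriesError("standardize needs >= 2 distinct values")
    out = (arr - arr.mean()) / arr.std(ddof=ddof)
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def moving_average(series, window: int):
    """Trailing full-window moving average.

    Returns the ``len(series) - window + 1`` complete-window means.  With a
    pandas input the result is aligned to the last year of each window; the
    set of values (hence any dispersion summary) is alignment-invariant.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(series, dtype=float)
    if window > arr.size:
        raise ValueError(f"window {window} exceeds series length {arr.size}")
    out = np.convolve(arr, np.ones(window) / window, mode="valid")
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index[window - 1 :], name=series.name)
    return out


def moving_average_summary(series, windows=range(3, 12)) -> pd.DataFrame:
    """Mean and dispersion of the moving-average series per window.

    ``sd`` is the population SD (divisor n) of the window means — the
    headline dispersion; ``sd_sample`` (divisor n-1) is reported alongside.
    """
    rows = []
    for w in windows:
        ma = np.asarray(moving_average(series, w), dtype=float)
        rows.append((w, ma.size, ma.mean(), ma.std(ddof=0), ma.std(ddof=1)))
    return pd.DataFrame(
        rows, columns=["window", "n_windows", "mean", "sd", "sd_sample"]
    ).set_index("window")


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample ACF/PACF with the flat 95% significance bound +/-1.96/sqrt(n)."""

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    significance_bound: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lags, "acf": self.acf, "pacf": self.pacf}
        ).set_index("lag")


def correlogram(series, max_lag: int) -> CorrelogramResult:
    """Sample autocorrelations and partial autocorrelations.

    PACF uses the Durbin-Levinson recursion on biased autocovariances, so
    the lag-1 partial autocorrelation equals the lag-1 autocorrelation
    exactly.  The lag-0 entries are both 1.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if np.ptp(arr) == 0:
        raise DegenerateSeriesError("constant series has no correlogram")
    r = _sm_acf(arr, nlags=max_lag, fft=False)
    phi = _sm_pacf(arr, nlags=max_lag, method="ldb")
    return CorrelogramResult(
        lags=np.arange(max_lag + 1),
        acf=r,
        pacf=phi,
        significance_bound=1.96 / np.sqrt(arr.size),
        n=arr.size,
    )


def build_covariates(
    census: pd.DataFrame,
    rainfall: pd.Series | None = None,
    area_km2: float = DEFAULT_AREA_KM2,
) -> pd.DataFrame:
    """Per-year physical covariates for the PFC regression.

    density(y) is the population density (animals/km^2) at the beginning of
    year y, i.e. the end-of-year total of y-1 divided by the area;
    density_lag(y) is density one further year back (kept only for the
    collinearity diagnostic — in this monotonically growing population the
    two are correlated at ~0.99, so the lag is discarded from modelling).
    rain(y) is the calendar-year rainfall total (mm) and rain_1(y) the
    prior year's; both require a supplied rainfall series.
    """
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    totals = census_totals(census)
    years = [y for y in census.index if y - 1 in totals.index]
    out = pd.DataFrame(index=pd.Index(years, name="year"))
    out["density"] = [totals.loc[y - 1] / area_km2 for y in years]
    out["density_lag"] = [
        totals.loc[y - 2] / area_km2 if y - 2 in totals.index else np.nan
        for y in years
    ]
    if rainfall is not None:
        missing = [y for y in years if y not in rainfall.index or y - 1 not in rainfall.index]
        if missing:
            raise ValueError(f"rainfall series missing years: {missing}")
        out["rain"] = [float(rainfall.loc[y]) for y in years]
        out["rain_1"] = [float(rainfall.loc[y - 1]) for y in years]
    return out


def add_standardized(covariates: pd.DataFrame, columns=None, ddof: int = 1) -> pd.DataFrame:
    """Append ``<col>_std`` columns standardized over the table's window."""
    out = covariates.copy()
    for col in columns or [c for c in covariates.columns if not c.endswith("_std")]:
        out[f"{col}_std"] = standardize(covariates[col].astype(float), ddof=ddof)
    return out


__all__ = [
    "arcsine_sqrt",
    "zar_transform",
    "transform_pfc",
    "standardize",
    "moving_average",
    "moving_average_summary",
    "correlogram",
    "CorrelogramResult",
    "build_covariates",
    "add_standardized",
    "DegenerateSeriesError",
    "DEFAULT_AREA_KM2",
]
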