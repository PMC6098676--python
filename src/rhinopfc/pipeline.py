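"""End-to-end analysis pipeline on a census table.

Chains the stages: PFC column -> integer birth counts -> modified arcsine
transform -> physical covariates -> all-subsets AR(2) AICc ranking, plus the
moving-average and correlogram summaries.  Rainfall is optional throughout:
without it the candidate covariate set shrinks to density and the ranking
covers the 8 rain-free models (2^3) instead of all 32.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_history import census_totals
from .model_selection import ARXModelSelector, rank_models
from .transforms import (
    CorrelogramResult,
    build_covariates,
    correlogram,
    moving_average_summary,
    transform_pfc,
    DEFAULT_AREA_KM2,
)


@dataclass
class StudyAnalysis:
    """All derived products of one census (plus optional rainfall) analysis."""

    pfc: pd.Series
    transformed: pd.DataFrame
    ma_summary: pd.DataFrame
    acf: CorrelogramResult
    covariates: pd.DataFrame
    selector: ARXModelSelector
    rain_available: bool

    @property
    def pfc_mean(self) -> float:
        return float(self.pfc.mean())

    @property
    def pfc_sd(self) -> float:
        """Population SD (divisor n) of the annual PFC values."""
        return float(self.pfc.std(ddof=0))

    def density_lag_correlation(self) -> float:
        """Pearson correlation of density with its one-year lag over the
        modelling window (the collinearity that disqualifies the lag)."""
        sub = self.covariates.loc[self.selector.window_]
        return float(np.corrcoef(sub["density"], sub["density_lag"])[0, 1])


def analyze_census(
    census: pd.DataFrame,
    rainfall: pd.Series | None = None,
    area_km2: float = DEFAULT_AREA_KM2,
    max_lag: int = 2,
    acf_max_lag: int = 10,
    confidence_level: float = 0.95,
) -> StudyAnalysis:
    """Run the full PFC analysis on a census table.

    The PFC series is taken from the census ``pfc`` column (years with a
    defined value); integer birth counts are recovered from the rounded
    proportions and the adult-female column.
    """
    pfc = census["pfc"].dropna().astype(float)
    transformed = transform_pfc(pfc, census["f_adult"])
    tp = transformed["transPFC"].rename("transPFC")
    cov = build_covariates(census, rainfall=rainfall, area_km2=area_km2)
    terms = ["density", "rain", "rain_1"] if rainfall is not None else ["density"]
    selector = rank_models(
        tp,
        cov[terms],
        max_lag=max_lag,
        confidence_level=confidence_level,
    )
    return StudyAnalysis(
        pfc=pfc,
        transformed=transformed,
        ma_summary=moving_average_summary(pfc.to_numpy(), windows=range(3, 12)),
        acf=correlogram(tp.to_numpy(), max_lag=acf_max_lag),
        covariates=cov,
        selector=selector,
        rain_available=rainfall is not None,
    )


def headline_summary(analysis: StudyAnalysis) -> dict:
    """The quantities a monitoring report leads with."""
    ranking = analysis.selector.ranking_
    census_years = analysis.pfc.index
    out = {
        "pfc_mean": analysis.pfc_mean,
        "pfc_sd": analysis.pfc_sd,
        "ma3_mean": float(analysis.ma_summary.loc[3, "mean"]),
        "ma3_sd": float(analysis.ma_summary.loc[3, "sd"]),
        "ma11_sd": float(analysis.ma_summary.loc[11, "sd"]),
        "n_years": int(len(census_years)),
        "n_models": int(len(ranking)),
        "best_model": ranking.index[0],
        "density_lag_correlation": analysis.density_lag_correlation(),
        "variance_explained_global": float(analysis.selector.variance_explained_),
    }
    for label, key in [
        ("transPFC_1", "daicc_lag1_only"),
        ("null", "daicc_null"),
        ("transPFC_1 + transPFC_2 + density", "daicc_lags_density"),
    ]:
        if label in ranking.index:
            out[key] = float(ranking.loc[label, "daicc"])
    return out


__all__ = ["StudyAnalysis", "analyze_census", "headline_summary"]
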