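"""AR(2) regression with exogenous covariates, AICc ranking and model averaging.

The global model for the transformed calving proportion is the Gaussian
autoregression

    transPFC_t = b0 + b1*transPFC_{t-1} + b2*transPFC_{t-2}
                 + c1*density_t + c2*rain_t + c3*rain_{t-1} + eps_t,
    eps_t ~ N(0, sigma^2) i.i.d.,

fitted by conditional maximum likelihood: the lagged responses are treated as
observed regressors, so the ML coefficients solve the least-squares normal
equations and sigma^2_hat = RSS/n.  All 2^m submodels (every subset of the m
candidate terms; the intercept is always included) are fitted on one common
response window so their AICc values are comparable.  Multi-model inference
follows the Akaike-weight formalism: Delta_i = AICc_i - min AICc, weights
w_i proportional to exp(-Delta_i/2), a 95% confidence set as the smallest
top-ranked prefix with cumulative weight >= 0.95, natural model averaging of
coefficients with unconditional standard errors, and per-term relative
importance as the sum of weights over models containing the term.

The two estimators follow scikit-learn conventions (``fit`` populates
trailing-underscore attributes; parameters are constructor arguments) and
compose with sklearn tooling.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .transforms import standardize

TERM_ORDER = ("transPFC_1", "transPFC_2", "density", "rain", "rain_1")


class RankDeficiencyError(ValueError):
    """The design matrix is collinear; coefficients are not identifiable."""


class SingularLikelihoodError(ValueError):
    """Residual variance is zero; the Gaussian likelihood is unbounded."""


class InsufficientDataError(ValueError):
    """Too few responses to fit the requested model (or its AICc)."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1); ``k`` counts all estimated
    parameters (intercept, slopes and sigma^2).
    """
    if n - k - 1 <= 0:
        raise InsufficientDataError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized exp(-Delta/2) model weights."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


class GaussianMLRegressor(RegressorMixin, BaseEstimator):
    """Linear regression by Gaussian maximum likelihood.

    Identical point estimates to ordinary least squares; the variance uses
    the ML divisor n (``sigma2_``) so that ``loglik_`` is the maximized
    Gaussian log-likelihood, while coefficient standard errors use the
    unbiased divisor n - p.

    A zero-residual (interpolating) fit takes the singular-variance guard
    path: coefficients are still returned, ``sigma2_`` is 0 and ``loglik_``
    is +inf; information criteria are then unavailable.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        n = y.size
        if X.shape[0] != n:
            raise ValueError("X and y have different numbers of rows")
        design = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        p = design.shape[1]
        if n <= p:
            raise InsufficientDataError(f"need n > {p} observations, got {n}")
        if np.linalg.matrix_rank(design) < p:
            raise RankDeficiencyError("collinear design matrix")
        params, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ params
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        scale = max(float(y @ y), 1.0)
        self.n_ = n
        self.k_ = p + 1  # + sigma^2
        self.df_resid_ = n - p
        self.rss_ = rss
        self.tss_ = tss
        if rss <= 1e-12 * scale:
            # interpolating fit: likelihood unbounded in sigma^2 -> guard path
            self.sigma2_ = 0.0
            self.loglik_ = math.inf
            self.se_ = np.zeros(p)
            self.aicc_ = None
        else:
            self.sigma2_ = rss / n
            self.loglik_ = -0.5 * n * (math.log(2.0 * math.pi * self.sigma2_) + 1.0)
            xtx_inv = np.linalg.inv(design.T @ design)
            self.se_ = np.sqrt(np.diag(xtx_inv) * rss / (n - p))
            self.aicc_ = (
                aicc(self.loglik_, self.k_, n) if n - self.k_ - 1 > 0 else None
            )
        if self.fit_intercept:
            self.intercept_ = float(params[0])
            self.coef_ = params[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = params
        self.params_ = params
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Normal-approximation confidence intervals for all mean parameters
        (intercept first when fitted), shape (p, 2)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.params_ - z * self.se_, self.params_ + z * self.se_]
        )

    def variance_explained(self) -> float:
        """1 - RSS/TSS on the fitted window."""
        if self.tss_ == 0:
            raise ValueError("response has zero variance")
        return 1.0 - self.rss_ / self.tss_


def fit_ml(X, y, fit_intercept: bool = True) -> GaussianMLRegressor:
    """Functional wrapper: fitted :class:`GaussianMLRegressor`."""
    return GaussianMLRegressor(fit_intercept=fit_intercept).fit(X, y)


def variance_explained(fit: GaussianMLRegressor) -> float:
    return fit.variance_explained()


def _canonical(terms) -> tuple[str, ...]:
    order = {t: i for i, t in enumerate(TERM_ORDER)}
    return tuple(sorted(terms, key=lambda t: (order.get(t, len(order)), t)))


def model_label(terms) -> str:
    return " + ".join(terms) if terms else "null"


def all_model_specs(terms) -> list[tuple[str, ...]]:
    """Every subset of ``terms`` (2^m specs) in deterministic order: fewer
    terms first, then canonical term order."""
    terms = _canonical(terms)
    specs = []
    for size in range(len(terms) + 1):
        specs.extend(itertools.combinations(terms, size))
    return specs


def assemble_design(
    transformed: pd.Series,
    covariates: pd.DataFrame | None,
    terms,
    max_lag: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and response on the common window.

    The window is the set of years for which the response, *all* ``max_lag``
    lagged responses, and every candidate covariate are defined — identical
    for every submodel, which is what makes their AICc values comparable.
    ``terms`` selects the columns of the returned design.
    """
    resp_name = transformed.name or "transPFC"
    frame = pd.DataFrame({resp_name: transformed.astype(float)})
    for i in range(1, max_lag + 1):
        frame[f"{resp_name}_{i}"] = transformed.shift(i)
    if covariates is not None:
        for col in covariates.columns:
            frame[col] = covariates[col].astype(float)
    frame = frame.dropna()
    missing = [t for t in terms if t not in frame.columns]
    if missing:
        raise KeyError(f"unknown model terms: {missing}")
    return frame[list(terms)], frame[resp_name]


class ARXModelSelector(BaseEstimator):
    """All-subsets AICc inference for the lagged-PFC regression.

    Parameters
    ----------
    max_lag : order of the autoregression (lagged-response terms built from
        the response series itself; default 2).
    confidence_level : cumulative-weight threshold of the confidence set.
    standardize_covariates : centre/scale (sample SD) the exogenous
        covariates over the common window before fitting.  Lagged responses
        are never standardized.

    After ``fit(X, y)`` (X: covariate DataFrame indexed by year, possibly
    empty; y: transformed PFC Series indexed by year):

    - ``ranking_``: one row per model, sorted by AICc, with k, logLik, AICc,
      dAICc, weight, cumulative weight and confidence-set membership;
    - ``fits_``: model label -> fitted :class:`GaussianMLRegressor`;
    - ``importance_``: per-term relative importance over all models;
    - ``averaged_``: per-term model-averaged coefficient and unconditional
      SE over the confidence set (natural averaging);
    - ``global_fit_``: the full model, and ``variance_explained_``.
    """

    def __init__(
        self,
        max_lag: int = 2,
        confidence_level: float = 0.95,
        standardize_covariates: bool = True,
    ):
        self.max_lag = max_lag
        self.confidence_level = confidence_level
        self.standardize_covariates = standardize_covariates

    def fit(self, X: pd.DataFrame | None, y: pd.Series):
        resp_name = y.name or "transPFC"
        lag_terms = [f"{resp_name}_{i}" for i in range(1, self.max_lag + 1)]
        cov_terms = [] if X is None else list(X.columns)
        terms = lag_terms + cov_terms
        design, response = assemble_design(y, X, terms, max_lag=self.max_lag)
        n = len(response)
        k_max = len(terms) + 2  # intercept + slopes + sigma^2
        if n - k_max - 1 <= 0:
            raise InsufficientDataError(
                f"window of {n} responses too short for the global model"
            )
        if self.standardize_covariates:
            for col in cov_terms:
                design[col] = standardize(design[col])
        self.terms_ = tuple(terms)
        self.window_ = response.index
        self.n_ = n
        self.design_ = design
        self.response_ = response

        rows, fits = [], {}
        for spec in all_model_specs(terms):
            label = model_label(spec)
            fit = GaussianMLRegressor().fit(
                design[list(spec)].to_numpy().reshape(n, len(spec)),
                response.to_numpy(),
            )
            if fit.aicc_ is None:
                raise SingularLikelihoodError(f"model {label!r} interpolates the data")
            fits[label] = fit
            rows.append((label, spec, fit.k_, fit.loglik_, fit.aicc_))
        ranking = pd.DataFrame(
            rows, columns=["model", "terms", "k", "loglik", "aicc"]
        )
        # stable sort => deterministic tie-break: fewer terms, canonical order
        ranking = ranking.sort_values("aicc", kind="stable").reset_index(drop=True)
        ranking["daicc"] = ranking["aicc"] - ranking["aicc"].iloc[0]
        ranking["weight"] = akaike_weights(ranking["aicc"])
        ranking["cumweight"] = ranking["weight"].cumsum()
        in_set = np.zeros(len(ranking), dtype=bool)
        cutoff = int(np.searchsorted(ranking["cumweight"], self.confidence_level))
        in_set[: cutoff + 1] = True
        ranking["in_confidence_set"] = in_set
        self.fits_ = fits
        self.ranking_ = ranking.set_index("model")
        self.confidence_set_ = list(ranking.loc[in_set, "model"])

        self.importance_ = pd.Series(
            {
                t: float(
                    ranking.loc[[t in tt for tt in ranking["terms"]], "weight"].sum()
                )
                for t in terms
            },
            name="relative_importance",
        )
        self.averaged_ = self._model_average()
        self.global_fit_ = fits[model_label(_canonical(terms))]
        self.variance_explained_ = self.global_fit_.variance_explained()
        return self

    def _model_average(self) -> pd.DataFrame:
        """Natural model averaging over the confidence set.

        For each term, weights of the confidence-set models containing it are
        renormalized; the unconditional SE folds between-model spread into
        the within-model SE: SE = sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2).
        Terms absent from every confidence-set model are flagged, not zeroed.
        """
        sub = self.ranking_[self.ranking_["in_confidence_set"]]
        rows = []
        for term in self.terms_:
            entries = []
            for label, row in sub.iterrows():
                if term not in row["terms"]:
                    continue
                fit = self.fits_[label]
                j = row["terms"].index(term)
                entries.append((row["weight"], fit.coef_[j], fit.se_[j + 1]))
            if not entries:
                rows.append((term, False, np.nan, np.nan, 0, self.importance_[term]))
                continue
            w = np.array([e[0] for e in entries])
            w = w / w.sum()
            b = np.array([e[1] for e in entries])
            se = np.array([e[2] for e in entries])
            bbar = float(w @ b)
            use = float(w @ np.sqrt(se**2 + (b - bbar) ** 2))
            rows.append((term, True, bbar, use, len(entries), self.importance_[term]))
        return pd.DataFrame(
            rows,
            columns=[
                "term",
                "in_confidence_set",
                "coefficient",
                "unconditional_se",
                "n_models",
                "relative_importance",
            ],
        ).set_index("term")


def rank_models(
    transformed: pd.Series,
    covariates: pd.DataFrame | None,
    max_lag: int = 2,
    confidence_level: float = 0.95,
    standardize_covariates: bool = True,
) -> ARXModelSelector:
    """Fit the all-subsets ranking; functional wrapper over the selector."""
    return ARXModelSelector(
        max_lag=max_lag,
        confidence_level=confidence_level,
        standardize_covariates=standardize_covariates,
    ).fit(covariates, transformed)


def simulate_arx(
    intercept: float,
    ar_coefs,
    sigma: float,
    n: int,
    rng: np.random.Generator,
    burn: int = 100,
) -> np.ndarray:
    """Simulate a Gaussian AR(p) series (used for parameter-recovery checks)."""
    ar = np.asarray(ar_coefs, dtype=float)
    p = ar.size
    total = n + burn + p
    y = np.zeros(total)
    eps = rng.normal(0.0, sigma, total)
    for t in range(p, total):
        y[t] = intercept + sum(ar[i] * y[t - 1 - i] for i in range(p)) + eps[t]
    return y[-n:]


__all__ = [
    "GaussianMLRegressor",
    "ARXModelSelector",
    "aicc",
    "akaike_weights",
    "all_model_specs",
    "assemble_design",
    "fit_ml",
    "model_label",
    "rank_models",
    "simulate_arx",
    "variance_explained",
    "RankDeficiencyError",
    "SingularLikelihoodError",
    "InsufficientDataError",
    "TERM_ORDER",
]
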