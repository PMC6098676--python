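"""Maximum-likelihood fitting, AICc ranking, weights, model averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhinopfc.model_selection import (
    ARXModelSelector,
    GaussianMLRegressor,
    InsufficientDataError,
    RankDeficiencyError,
    aicc,
    akaike_weights,
    all_model_specs,
    assemble_design,
    fit_ml,
    rank_models,
    simulate_arx,
)


def _oracle_normal_equations(X, y, intercept=True):
    """Independent oracle: solve X'X b = X'y directly."""
    A = np.column_stack([np.ones(len(y)), X]) if intercept else X
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestGaussianMLRegressor:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        fit = fit_ml(X, y)
        expected = _oracle_normal_equations(X, y)
        np.testing.assert_allclose(fit.params_, expected, atol=1e-8)

    def test_noiseless_interpolation_takes_guard_path(self):
        x = np.arange(10.0)
        fit = fit_ml(x, 2.0 * x + 1.0)
        assert fit.intercept_ == pytest.approx(1.0, abs=1e-8)
        assert fit.coef_[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.sigma2_ == 0.0 and fit.loglik_ == np.inf and fit.aicc_ is None

    def test_collinear_design_rejected(self):
        x = np.arange(12.0)
        with pytest.raises(RankDeficiencyError):
            fit_ml(np.column_stack([x, 2 * x]), np.sin(x))

    def test_loglik_is_gaussian_ml(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = X @ [1.0, -2.0] + rng.normal(size=40)
        fit = fit_ml(X, y)
        # direct evaluation of the Gaussian log density at the ML estimates
        resid = y - fit.intercept_ - X @ fit.coef_
        ll = np.sum(
            -0.5 * np.log(2 * np.pi * fit.sigma2_) - resid**2 / (2 * fit.sigma2_)
        )
        assert fit.loglik_ == pytest.approx(ll, rel=1e-10)

    def test_ar2_parameter_recovery_large_n(self):
        rng = np.random.default_rng(11)
        y = simulate_arx(1.0, [-0.5, -0.2], 0.2, 5000, rng)
        fit = fit_ml(np.column_stack([y[1:-1], y[:-2]]), y[2:])
        for est, truth, se in zip(fit.coef_, (-0.5, -0.2), fit.se_[1:]):
            assert abs(est - truth) < 3 * se

    def test_sklearn_param_interface(self):
        est = GaussianMLRegressor()
        assert est.get_params() == {"fit_intercept": True}
        est.set_params(fit_intercept=False)
        assert est.fit_intercept is False


class TestAICc:
    def test_direct_arithmetic(self):
        assert aicc(0.0, 4, 20) == pytest.approx(8 + 40 / 15)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(-10.0, 4, 10**7) == pytest.approx(20 + 8, abs=1e-4)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(InsufficientDataError):
            aicc(0.0, 4, 5)


class TestRanking:
    def test_two_model_weights_hand_computed(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_weights_sum_to_one(self, study_analysis):
        assert study_analysis.selector.ranking_["weight"].sum() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_all_subsets_enumerated(self):
        assert len(all_model_specs(["a", "b", "c", "d", "e"])) == 32
        assert all_model_specs(["a"])[0] == ()

    def test_common_window_n20_for_all_models(self, study_analysis):
        sel = study_analysis.selector
        assert sel.n_ == 20
        assert list(sel.window_) == list(range(1989, 2009))
        assert all(f.n_ == 20 for f in sel.fits_.values())

    def test_window_1987_1990_has_two_responses(self, study_analysis):
        tp = study_analysis.transformed["transPFC"].rename("transPFC")
        X, y = assemble_design(
            tp.loc[1987:1990], None, ["transPFC_1", "transPFC_2"], max_lag=2
        )
        assert len(y) == 2

    def test_ranking_invariant_to_covariate_rescaling(self, study_analysis):
        tp = study_analysis.transformed["transPFC"].rename("transPFC")
        cov = study_analysis.covariates[["density"]]
        a = rank_models(tp, cov)
        b = rank_models(tp, cov * 37.5)
        pd.testing.assert_series_equal(a.ranking_["aicc"], b.ranking_["aicc"])

    def test_null_vs_best_gap_is_large(self, study_analysis):
        # the PFC lags, not density, carry the signal
        daicc = study_analysis.selector.ranking_["daicc"]
        assert daicc.loc["null"] > 4.5
        assert study_analysis.selector.ranking_.index[0] == "transPFC_1 + transPFC_2"

    def test_insufficient_window_errors(self, study_analysis):
        tp = study_analysis.transformed["transPFC"].rename("transPFC")
        with pytest.raises(InsufficientDataError):
            rank_models(tp.loc[1987:1993], None)


class TestModelAverage:
    def test_single_model_set_returns_that_models_coefficients(self, study_analysis):
        tp = study_analysis.transformed["transPFC"].rename("transPFC")
        sel = ARXModelSelector(confidence_level=1e-9).fit(None, tp)
        best = sel.confidence_set_[0]
        assert len(sel.confidence_set_) == 1
        fit = sel.fits_[best]
        terms = sel.ranking_.loc[best, "terms"]
        for j, t in enumerate(terms):
            assert sel.averaged_.loc[t, "coefficient"] == pytest.approx(fit.coef_[j])
            assert sel.averaged_.loc[t, "unconditional_se"] == pytest.approx(
                fit.se_[j + 1]
            )

    def test_unconditional_se_hand_example(self):
        # two equal-weight models, coefficients 1 and 3 with zero variance:
        # average 2, unconditional SE = 0.5*|1-2| + 0.5*|3-2| = 1
        w = np.array([0.5, 0.5])
        b = np.array([1.0, 3.0])
        se = np.zeros(2)
        bbar = w @ b
        use = w @ np.sqrt(se**2 + (b - bbar) ** 2)
        assert bbar == pytest.approx(2.0) and use == pytest.approx(1.0)

    def test_importance_of_term_in_all_models_is_one(self, study_analysis):
        tp = study_analysis.transformed["transPFC"].rename("transPFC")
        sel = ARXModelSelector(max_lag=0).fit(
            study_analysis.covariates[["density"]], tp
        )
        # 2 models: null and density; importance(density) = weight(density model)
        wd = sel.ranking_.loc["density", "weight"]
        assert sel.importance_["density"] == pytest.approx(wd)

    def test_importance_bounded_by_best_containing_model(self, study_analysis):
        sel = study_analysis.selector
        for term in sel.terms_:
            best_w = max(
                row["weight"]
                for _, row in sel.ranking_.iterrows()
                if term in row["terms"]
            )
            assert 0 <= best_w <= sel.importance_[term] <= 1


class TestVarianceExplained:
    def test_perfect_fit_is_one(self):
        x = np.arange(20.0)
        y = 3 * x + np.sin(x)
        fit = fit_ml(np.column_stack([x, np.sin(x)]), y)
        assert fit.variance_explained() == pytest.approx(1.0, abs=1e-10)

    def test_intercept_only_is_zero(self):
        rng = np.random.default_rng(5)
        fit = fit_ml(np.empty((30, 0)), rng.normal(size=30))
        assert fit.variance_explained() == pytest.approx(0.0, abs=1e-10)

    def test_simulated_r2_half(self):
        rng = np.random.default_rng(9)
        n = 10_000
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)  # population R^2 = 0.5
        assert fit_ml(x, y).variance_explained() == pytest.approx(0.5, abs=0.02)
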