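"""Mixed-model machinery: scaling, families, AICc selection.

The Laplace-ML fits are cross-checked against independent estimators:
statsmodels MixedLM (Gaussian mixed model, exact case), GLM (Poisson
without random effect), and BetaModel (beta regression without random
effect).
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.othermod.betareg import BetaModel

from swarmnet.errors import ValidationError
from swarmnet.gradient_models import (
    GlmmSpec,
    LaplaceGLMM,
    aicc,
    aicc_select,
    fit_glmm,
    glmm_report,
    scale_predictors,
    squeeze_unit_interval,
)


class TestScaling:
    def test_z_score_small_column(self):
        df, params = scale_predictors(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), ["x"])
        # sample sd of {1,2,3} is exactly 1
        np.testing.assert_allclose(df["x"], [-1.0, 0.0, 1.0])
        assert params["x"].mean == 2.0
        assert params["x"].sd == 1.0

    def test_already_standardized_unchanged(self, rng):
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        df, _ = scale_predictors(pd.DataFrame({"x": x}), ["x"])
        np.testing.assert_allclose(df["x"], x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            scale_predictors(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])

    def test_squeeze_is_monotone_and_open(self):
        y = np.array([0.0, 0.2, 0.5, 1.0])
        s = squeeze_unit_interval(y, 50)
        assert (np.diff(s) > 0).all()
        assert (s > 0).all() and (s < 1).all()


class TestAicc:
    def test_monotone_in_k_at_fixed_likelihood(self):
        vals = [aicc(-100.0, k, 60) for k in range(2, 8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_reduces_to_aic_for_large_n(self):
        assert abs(aicc(-500.0, 4, 10_000) - (2 * 500 + 2 * 4)) < 0.1


class TestFamilyCrossChecks:
    def test_gaussian_mixed_model_matches_mixedlm_ml(self):
        rng = np.random.default_rng(3)
        J = 150
        g = np.repeat(np.arange(J), rng.integers(1, 4, J))
        n = g.size
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ np.array([1.0, -0.3, 0.2]) + rng.normal(0, 0.5, J)[g] + rng.normal(0, 0.8, n)
        params, sig_re, sig_eps, ll, *_ = LaplaceGLMM("gaussian").fit(
            X, y, g, term_names=["i", "x1", "x2"]
        )
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        np.testing.assert_allclose(params["estimate"], ref.fe_params, atol=1e-4)
        assert sig_re == pytest.approx(np.sqrt(np.asarray(ref.cov_re)[0, 0]), abs=1e-3)
        assert sig_eps == pytest.approx(np.sqrt(ref.scale), abs=1e-3)
        assert ll == pytest.approx(ref.llf, abs=1e-4)

    def test_poisson_without_random_effect_matches_glm(self):
        rng = np.random.default_rng(5)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(X @ np.array([1.2, -0.4]))).astype(float)
        params, *_ = LaplaceGLMM("poisson", random_intercept=False).fit(
            X, y, None, term_names=["i", "x"]
        )
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(params["estimate"], ref.params, atol=1e-5)

    def test_beta_without_random_effect_matches_betamodel(self):
        rng = np.random.default_rng(11)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = expit(X @ np.array([1.0, 0.5]))
        y = rng.beta(mu * 15.0, (1 - mu) * 15.0)
        params, _, phi, ll, *_ = LaplaceGLMM("beta", random_intercept=False).fit(
            X, y, None, term_names=["i", "x"]
        )
        ref = BetaModel(y, X).fit(disp=False)
        np.testing.assert_allclose(params["estimate"], ref.params[:2], atol=1e-4)
        assert np.log(phi) == pytest.approx(ref.params[2], abs=1e-3)
        assert ll == pytest.approx(ref.llf, abs=1e-3)

    def test_poisson_random_intercept_recovers_variance(self):
        rng = np.random.default_rng(21)
        J = 400
        g = np.repeat(np.arange(J), 3)
        n = g.size
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        b = rng.normal(0, 0.5, J)
        y = rng.poisson(np.exp(1.0 + 0.3 * X[:, 1] + b[g])).astype(float)
        params, sig_re, *_ = LaplaceGLMM("poisson").fit(X, y, g, term_names=["i", "x"])
        assert params["estimate"].iloc[1] == pytest.approx(0.3, abs=0.05)
        assert sig_re == pytest.approx(0.5, abs=0.1)


def _metric_frame(rng, n=120, response="size"):
    rain = rng.normal(size=n)
    suit = rng.normal(size=n)
    y = rng.poisson(np.exp(1.8 - 0.2 * rain)).astype(float)
    return pd.DataFrame(
        {
            response: y,
            "rainfall": rain * 200 + 2500,
            "suitability": expit(suit),
            "swarm_id": [f"sw{i//2}" for i in range(n)],
        }
    )


class TestFitGlmm:
    def test_listwise_drop_and_minimum_rows(self, rng):
        df = _metric_frame(rng, n=12)
        df.loc[:4, "size"] = np.nan
        with pytest.raises(ValidationError, match="usable rows"):
            fit_glmm(GlmmSpec(response="size", family="poisson"), df)

    def test_fit_reports_wald_cis_bracketing_estimate(self, rng):
        fit = fit_glmm(GlmmSpec(response="size", family="poisson"), _metric_frame(rng))
        p = fit.params
        assert ((p["ci_lo"] <= p["estimate"]) & (p["estimate"] <= p["ci_hi"])).all()
        assert fit.aicc > fit.aic

    def test_scaling_happens_inside(self, rng):
        """Coefficients are on the standardized scale regardless of raw units."""
        df = _metric_frame(rng, n=300)
        fit = fit_glmm(GlmmSpec(response="size", family="poisson"), df)
        df2 = df.copy()
        df2["rainfall"] = df2["rainfall"] * 10 + 1e5  # affine change of units
        fit2 = fit_glmm(GlmmSpec(response="size", family="poisson"), df2)
        assert fit.coef("rainfall") == pytest.approx(fit2.coef("rainfall"), abs=1e-5)


class TestAiccSelect:
    @staticmethod
    def _sim(rng, quad_coef, n=200):
        rain = rng.normal(size=n)
        suit = rng.normal(size=n)
        lam = np.exp(1.8 - 0.2 * rain + quad_coef * rain**2)
        return pd.DataFrame(
            {
                "size": rng.poisson(lam).astype(float),
                "rainfall": rain,
                "suitability": suit,
                "swarm_id": [f"sw{i}" for i in range(n)],
            }
        )

    def test_linear_truth_selects_linear_mostly(self):
        spec = GlmmSpec(response="size", family="poisson")
        wins = 0
        for rep in range(25):
            rng = np.random.default_rng(1000 + rep)
            fit, table = aicc_select(spec, self._sim(rng, 0.0))
            wins += not fit.spec.quadratic
        assert wins >= 20  # >= 80 % of replicates

    def test_quadratic_truth_selects_quadratic_mostly(self):
        spec = GlmmSpec(response="size", family="poisson")
        wins = 0
        for rep in range(25):
            rng = np.random.default_rng(2000 + rep)
            fit, _ = aicc_select(spec, self._sim(rng, 0.3))
            wins += fit.spec.quadratic
        assert wins >= 20

    def test_comparison_table_shape(self, rng):
        fit, table = aicc_select(
            GlmmSpec(response="size", family="poisson"), self._sim(rng, 0.0)
        )
        assert list(table["model"]) == ["linear", "quadratic"]
        assert table["chosen"].sum() == 1
        assert table.loc[table["chosen"], "aicc"].item() == min(table["aicc"])


class TestReport:
    def test_significance_flags(self, rng):
        fit = fit_glmm(
            GlmmSpec(response="size", family="poisson"), _metric_frame(rng, n=400)
        )
        rep = glmm_report({"size": fit})
        rain = rep[rep.term == "rainfall"].iloc[0]
        assert rain["significant"]  # strong generating effect
        assert rain["ci_hi"] < 0
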