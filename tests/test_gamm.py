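"""Additive mixed models: spline basis, REML core, shrinkage behavior.

The Gaussian REML core is cross-checked against statsmodels MixedLM
(pure random-intercept case) and the full shrinkage-smooth fit against
R's mgcv (the reference GAMM toolchain) on a frozen dataset.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from swarmnet.errors import ValidationError
from swarmnet.gradient_models import (
    AdditiveMixedModel,
    GammSpec,
    crs_basis,
    fit_gamm,
    gamm_report,
)


def make_pair_data(
    seed,
    *,
    n=1000,
    effect_rain=0.3,
    effect_suit=0.0,
    re_sd=0.3,
    noise=1.0,
    response="beta_st",
    beta_scale=False,
):
    """Pairwise-table lookalike with known linear effects on the z scale."""
    rng = np.random.default_rng(seed)
    sites = [f"S{i}" for i in range(1, 8)]
    rainfall = np.linspace(2100, 2860, 7)
    suit = rng.permutation(np.linspace(0.3, 0.99, 7))
    s1, s2 = rng.integers(0, 7, n), rng.integers(0, 7, n)
    dr = np.abs(rainfall[s1] - rainfall[s2])
    ds = np.abs(suit[s1] - suit[s2])
    zdr = (dr - dr.mean()) / dr.std(ddof=1)
    zds = (ds - ds.mean()) / ds.std(ddof=1)
    labels = [tuple(sorted((a, b))) for a, b in zip(s1, s2)]
    code = {u: i for i, u in enumerate(sorted(set(labels)))}
    u = rng.normal(0, re_sd, len(code))
    eta = effect_rain * zdr + effect_suit * zds + u[[code[l] for l in labels]]
    if beta_scale:
        mu = expit(1.5 + eta)
        y = rng.beta(mu * 20.0, (1 - mu) * 20.0)
    else:
        y = eta + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            response: y,
            "d_rainfall": dr,
            "d_suitability": ds,
            "site_1": [sites[i] for i in s1],
            "site_2": [sites[i] for i in s2],
        }
    )


class TestCrsBasis:
    def test_interpolation_at_knots(self):
        knots = np.array([0.0, 0.4, 1.0])
        X, S = crs_basis(knots, knots)
        np.testing.assert_allclose(X, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(S, S.T)
        assert (np.linalg.eigvalsh(S) > -1e-12).all()

    def test_linear_functions_have_zero_penalty(self):
        knots = np.array([0.0, 0.3, 1.0])
        x = np.linspace(0, 1, 50)
        X, S = crs_basis(x, knots)
        coefs = 2.0 * knots + 1.0  # values of a linear function at the knots
        np.testing.assert_allclose(X @ coefs, 2.0 * x + 1.0, atol=1e-10)
        assert coefs @ S @ coefs == pytest.approx(0.0, abs=1e-12)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValidationError):
            crs_basis(np.linspace(0, 1, 10), np.array([0.0, 1.0]))


class TestRemlCore:
    def test_random_intercept_only_matches_mixedlm_reml(self):
        rng = np.random.default_rng(9)
        J, reps = 30, 40
        g = np.repeat([f"g{j}" for j in range(J)], reps)
        n = g.size
        y = rng.normal(0, 0.6, J).repeat(reps) + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"y": y})
        model = AdditiveMixedModel()
        model.fit(y, df, [], np.asarray(g, dtype=object))
        ref = sm.MixedLM(y, np.ones((n, 1)), groups=g).fit(reml=True)
        tau2 = model.gamma_["site_pair"] * model.sigma2_
        assert model.sigma2_ == pytest.approx(ref.scale, rel=1e-3)
        assert tau2 == pytest.approx(np.asarray(ref.cov_re)[0, 0], rel=2e-2)

    def test_matches_mgcv_on_frozen_dataset(self, tmp_path):
        """e.d.f. of both shrinkage smooths agrees with mgcv's cs basis."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        df = make_pair_data(42, effect_rain=0.5)
        fit = fit_gamm(GammSpec(response="beta_st"), df)
        d = df.copy()
        d["zdr"] = (d.d_rainfall - d.d_rainfall.mean()) / d.d_rainfall.std(ddof=1)
        d["zds"] = (d.d_suitability - d.d_suitability.mean()) / d.d_suitability.std(ddof=1)
        d["y"] = (d.beta_st - d.beta_st.mean()) / d.beta_st.std(ddof=1)
        d["pair"] = [
            "_".join(sorted((a, b))) for a, b in zip(d.site_1, d.site_2)
        ]
        csv = tmp_path / "pairs.csv"
        d.to_csv(csv, index=False)
        script = f"""
        library(mgcv)
        d <- read.csv('{csv}'); d$pair <- factor(d$pair)
        m <- gam(y ~ s(zdr, bs='cs', k=3) + s(zds, bs='cs', k=3) + s(pair, bs='re'),
                 data=d, method='REML')
        cat(summary(m)$s.table[1:2, 1], sep=',')
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        edf_rain_ref, edf_suit_ref = map(float, out.stdout.strip().split(","))
        assert fit.edf["d_rainfall"] == pytest.approx(edf_rain_ref, abs=0.3)
        assert fit.edf["d_suitability"] == pytest.approx(edf_suit_ref, abs=0.3)


class TestGaussianGamm:
    def test_strong_effect_detected(self):
        fit = fit_gamm(GammSpec(response="beta_st"), make_pair_data(1, effect_rain=0.5))
        assert fit.pvalues["d_rainfall"] <= 0.001
        assert fit.edf["d_rainfall"] > 0.5

    def test_null_covariate_shrinks(self):
        fit = fit_gamm(GammSpec(response="beta_st"), make_pair_data(2, effect_rain=0.5))
        assert fit.edf["d_suitability"] < 0.3

    def test_edf_one_means_linear_fit_shape(self):
        """The fitted smooth of a linear-generated effect is itself ~linear."""
        fit = fit_gamm(GammSpec(response="beta_st"), make_pair_data(3, effect_rain=0.18))
        grid = np.linspace(-1.0, 2.0, 9)
        curve = fit.smooth_curve("d_rainfall", grid)
        slopes = np.diff(curve["fit"]) / np.diff(grid)
        assert np.ptp(slopes) < 0.35 * max(abs(slopes).max(), 1e-9)

    def test_minimum_rows_enforced(self):
        with pytest.raises(ValidationError, match=">= 50"):
            fit_gamm(GammSpec(response="beta_st"), make_pair_data(4, n=30))


class TestBetaGamm:
    def test_logit_linear_effect_detected(self):
        df = make_pair_data(7, effect_rain=0.4, response="beta_wn", beta_scale=True)
        fit = fit_gamm(GammSpec(response="beta_wn"), df)
        assert fit.converged
        assert fit.phi is not None and fit.phi > 1
        assert fit.pvalues["d_rainfall"] <= 0.01
        assert fit.pvalues["d_suitability"] > 0.05

    def test_report_layout(self):
        df = make_pair_data(8, effect_rain=0.4, response="beta_wn", beta_scale=True)
        fit = fit_gamm(GammSpec(response="beta_wn"), df)
        rep = gamm_report({"beta_wn": fit})
        assert set(rep.columns) == {"response", "term", "edf", "p", "significant"}
        assert len(rep) == 2
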