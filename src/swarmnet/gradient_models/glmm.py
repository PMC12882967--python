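"""Generalized linear mixed models with one random intercept.

Metric responses are modelled against standardized rainfall and habitat
suitability with a random intercept for swarm identity (the same swarm
can be followed on up to three consecutive days).  Families follow each
response's support: Poisson/log for network size, beta/logit for the
two proportion metrics (clustering, mean normalized degree), and
Gaussian/identity for mean weighted degree and skewness.

Estimation is maximum likelihood with a Laplace approximation to the
random-intercept integral.  Because the random effect is a scalar per
group, each group's integrand is maximized by a one-dimensional Newton
iteration, vectorized across groups; the Laplace correction is exact
for the Gaussian family.  Wald 95% CIs throughout; AICc counts every
estimated parameter (fixed effects plus variance/dispersion terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools import numdiff

from ..errors import ConvergenceError, ValidationError
from .scaling import scale_predictors, squeeze_unit_interval

_LOG_SIGMA_MIN = -6.0  # sigma ~ 2.5e-3: effectively no group variance
_LOG_SIGMA_MAX = 3.0


# ---------------------------------------------------------------------------
# Families: per-observation log-likelihood and its first two derivatives
# in the linear predictor eta.  ``aux`` is the extra scale parameter
# (None for Poisson, residual sd for Gaussian, precision phi for beta).

class _Poisson:
    name = "poisson"
    n_aux = 0

    @staticmethod
    def start_intercept(y):
        return float(np.log(max(np.mean(y), 1e-3)))

    @staticmethod
    def ll(y, eta, aux):
        eta = np.clip(eta, -30.0, 30.0)
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)

    @staticmethod
    def d1(y, eta, aux):
        return y - np.exp(np.clip(eta, -30.0, 30.0))

    @staticmethod
    def d2(y, eta, aux):
        return -np.exp(np.clip(eta, -30.0, 30.0))


class _Gaussian:
    name = "gaussian"
    n_aux = 1  # log residual sd

    @staticmethod
    def start_intercept(y):
        return float(np.mean(y))

    @staticmethod
    def start_aux(y):
        return float(np.log(max(np.std(y), 1e-3)))

    @staticmethod
    def ll(y, eta, aux):
        s2 = aux**2
        return -0.5 * np.log(2 * np.pi * s2) - (y - eta) ** 2 / (2 * s2)

    @staticmethod
    def d1(y, eta, aux):
        return (y - eta) / aux**2

    @staticmethod
    def d2(y, eta, aux):
        return -np.ones_like(eta) / aux**2


class _Beta:
    """Beta regression with logit link and precision phi (mean parameterization)."""

    name = "beta"
    n_aux = 1  # log phi

    @staticmethod
    def start_intercept(y):
        m = float(np.mean(y))
        m = min(max(m, 1e-4), 1 - 1e-4)
        return float(np.log(m / (1 - m)))

    @staticmethod
    def start_aux(y):
        # Method-of-moments phi from the marginal mean/variance.
        m, v = float(np.mean(y)), float(np.var(y))
        phi = max(m * (1 - m) / max(v, 1e-6) - 1, 1.0)
        return float(np.log(phi))

    @staticmethod
    def ll(y, eta, aux):
        phi = aux
        mu = special.expit(np.clip(eta, -30.0, 30.0))
        return (
            special.gammaln(phi)
            - special.gammaln(mu * phi)
            - special.gammaln((1 - mu) * phi)
            + (mu * phi - 1) * np.log(y)
            + ((1 - mu) * phi - 1) * np.log1p(-y)
        )

    @staticmethod
    def _dl_dmu(y, mu, phi):
        return phi * (
            np.log(y) - np.log1p(-y)
            - special.digamma(mu * phi)
            + special.digamma((1 - mu) * phi)
        )

    @classmethod
    def d1(cls, y, eta, aux):
        mu = special.expit(np.clip(eta, -30.0, 30.0))
        return cls._dl_dmu(y, mu, aux) * mu * (1 - mu)

    @classmethod
    def d2(cls, y, eta, aux):
        phi = aux
        mu = special.expit(np.clip(eta, -30.0, 30.0))
        w = mu * (1 - mu)
        d2l_dmu2 = -(phi**2) * (
            special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
        )
        return d2l_dmu2 * w**2 + cls._dl_dmu(y, mu, phi) * w * (1 - 2 * mu)


FAMILIES = {f.name: f for f in (_Poisson, _Gaussian, _Beta)}


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmmSpec:
    """Model specification for one metric response."""

    response: str
    family: str
    fixed: tuple[str, ...] = ("rainfall", "suitability")
    quadratic: bool = False  # add scaled-rainfall^2 term
    group: str = "swarm_id"

    def terms(self) -> list[str]:
        t = ["intercept", *self.fixed]
        if self.quadratic:
            t.append(f"{self.fixed[0]}_sq")
        return t


#: Family/link used for each network metric.
FAMILY_FOR_RESPONSE = {
    "size": "poisson",
    "mean_norm_degree": "beta",
    "clustering": "beta",
    "mean_weighted_degree": "gaussian",
    "skewness": "gaussian",
}


@dataclass
class GlmmFit:
    """Fitted GLMM: coefficient table, variance components, information criteria."""

    spec: GlmmSpec
    params: pd.DataFrame  # term, estimate, se, ci_lo, ci_hi, p
    sigma_re: float  # random-intercept sd
    aux: float | None  # residual sd (gaussian) or precision phi (beta)
    loglik: float
    aicc: float
    aic: float
    n: int
    k: int
    converged: bool
    n_groups: int = 0

    def coef(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "se"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.set_index("term").loc[term]
        return float(row["ci_lo"]), float(row["ci_hi"])


class LaplaceGLMM:
    """ML GLMM with a single scalar random intercept (Laplace approximation).

    Parameters are the fixed-effect vector, log random-intercept sd and,
    family permitting, one log scale/dispersion parameter; the joint
    likelihood is maximized with L-BFGS-B.
    """

    def __init__(self, family: str, *, random_intercept: bool = True, max_inner: int = 50):
        if family not in FAMILIES:
            raise ValidationError(f"unknown family {family!r}")
        self.family = FAMILIES[family]
        self.random_intercept = random_intercept
        self.max_inner = max_inner

    # -- inner Laplace step -------------------------------------------------
    def _modes(self, y, eta0, g, n_groups, sigma2, aux):
        """Per-group posterior modes of the random intercept (vectorized Newton)."""
        fam = self.family
        b = np.zeros(n_groups)
        for _ in range(self.max_inner):
            eta = eta0 + b[g]
            g1 = np.bincount(g, fam.d1(y, eta, aux), minlength=n_groups) - b / sigma2
            g2 = np.bincount(g, fam.d2(y, eta, aux), minlength=n_groups) - 1.0 / sigma2
            g2 = np.minimum(g2, -1e-10)
            step = g1 / g2
            step = np.clip(step, -3.0, 3.0)
            b = b - step
            if np.max(np.abs(g1)) < 1e-9:
                break
        eta = eta0 + b[g]
        curv = np.bincount(g, fam.d2(y, eta, aux), minlength=n_groups) - 1.0 / sigma2
        return b, np.minimum(curv, -1e-10)

    def _neg_loglik(self, theta, X, y, g, n_groups):
        fam = self.family
        p = X.shape[1]
        beta = theta[:p]
        idx = p
        if self.random_intercept:
            sigma2 = np.exp(2.0 * theta[idx])
            idx += 1
        aux = np.exp(theta[idx]) if fam.n_aux else None
        eta0 = X @ beta
        if not self.random_intercept:
            return -float(np.sum(fam.ll(y, eta0, aux)))
        b, curv = self._modes(y, eta0, g, n_groups, sigma2, aux)
        eta = eta0 + b[g]
        ll = (
            np.sum(fam.ll(y, eta, aux))
            - np.sum(b**2) / (2.0 * sigma2)
            - 0.5 * np.sum(np.log(sigma2 * (-curv)))
        )
        return -float(ll)

    # -- public fit ---------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray | None = None,
        *,
        term_names: Sequence[str] | None = None,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if self.random_intercept:
            if groups is None:
                raise ValidationError("groups required for a random-intercept model")
            codes, _ = pd.factorize(np.asarray(groups), sort=True)
            n_groups = int(codes.max()) + 1
        else:
            codes, n_groups = np.zeros(n, dtype=int), 1

        fam = self.family
        theta0 = np.zeros(p + (1 if self.random_intercept else 0) + fam.n_aux)
        theta0[0] = fam.start_intercept(y)
        bounds: list[tuple[float | None, float | None]] = [(None, None)] * p
        idx = p
        if self.random_intercept:
            theta0[idx] = -1.0
            bounds.append((_LOG_SIGMA_MIN, _LOG_SIGMA_MAX))
            idx += 1
        if fam.n_aux:
            theta0[idx] = fam.start_aux(y)
            bounds.append((-8.0, 10.0))

        obj = lambda th: self._neg_loglik(th, X, y, codes, n_groups)
        res = optimize.minimize(
            obj, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        if not res.success and grad_norm > 1e-2:
            raise ConvergenceError(
                f"GLMM ({fam.name}) did not converge: {res.message}",
                grad_norm=grad_norm, n_iter=int(res.nit),
            )

        theta = res.x
        hess = numdiff.approx_hess1(theta, obj)
        cov = np.linalg.pinv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        names = list(term_names) if term_names is not None else [f"x{i}" for i in range(p)]
        z = 1.959963984540054
        est = theta[:p]
        se = se_all[:p]
        with np.errstate(divide="ignore", invalid="ignore"):
            pvals = 2.0 * special.ndtr(-np.abs(np.where(se > 0, est / se, np.inf)))
        params = pd.DataFrame(
            {
                "term": names,
                "estimate": est,
                "se": se,
                "ci_lo": est - z * se,
                "ci_hi": est + z * se,
                "p": pvals,
            }
        )
        idx = p
        sigma_re = 0.0
        if self.random_intercept:
            sigma_re = float(np.exp(theta[idx]))
            if theta[idx] <= _LOG_SIGMA_MIN + 1e-6:
                sigma_re = 0.0  # at the boundary: no group variance
            idx += 1
        aux = float(np.exp(theta[idx])) if fam.n_aux else None

        k = len(theta)
        ll = -res.fun
        aic = -2 * ll + 2 * k
        aicc = aic + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf)
        return params, sigma_re, aux, ll, aic, aicc, n, k, n_groups


# ---------------------------------------------------------------------------
# DataFrame-level interface

def fit_glmm(spec: GlmmSpec, data: pd.DataFrame, *, prescaled: bool = False) -> GlmmFit:
    """Fit one metric's GLMM on a metrics table joined to site environments.

    Rows with an undefined (NaN) response or predictor are dropped
    listwise for this response only.  Predictors are standardized from
    the retained rows unless ``prescaled``.  Beta-family responses are
    squeezed off the boundary with (y(n−1)+1/2)/n.
    """
    cols = [spec.response, *spec.fixed, spec.group]
    d = data[cols].dropna().copy()
    n = len(d)
    if n < 10:
        raise ValidationError(
            f"response {spec.response!r}: only {n} usable rows (need >= 10)"
        )
    if not prescaled:
        d, _ = scale_predictors(d, list(spec.fixed))
    y = d[spec.response].to_numpy(dtype=float)
    if spec.family == "beta":
        y = squeeze_unit_interval(y, n)
    Xcols = [np.ones(n)] + [d[c].to_numpy(dtype=float) for c in spec.fixed]
    if spec.quadratic:
        Xcols.append(d[spec.fixed[0]].to_numpy(dtype=float) ** 2)
    X = np.column_stack(Xcols)

    model = LaplaceGLMM(spec.family)
    params, sigma_re, aux, ll, aic, aicc, n, k, n_groups = model.fit(
        X, y, d[spec.group].to_numpy(), term_names=spec.terms()
    )
    return GlmmFit(
        spec=spec, params=params, sigma_re=sigma_re, aux=aux,
        loglik=ll, aicc=aicc, aic=aic, n=n, k=k, converged=True,
        n_groups=n_groups,
    )


def aicc_select(
    spec: GlmmSpec, data: pd.DataFrame, **kwargs
) -> tuple[GlmmFit, pd.DataFrame]:
    """Compare the linear model with its quadratic-rainfall extension by AICc.

    Returns the lower-AICc fit (ties go to the model with fewer
    parameters) plus the comparison table.
    """
    lin = fit_glmm(GlmmSpec(**{**spec.__dict__, "quadratic": False}), data, **kwargs)
    try:
        quad = fit_glmm(GlmmSpec(**{**spec.__dict__, "quadratic": True}), data, **kwargs)
    except ConvergenceError as exc:
        raise ConvergenceError(f"quadratic candidate for {spec.response!r}: {exc}") from exc
    table = pd.DataFrame(
        {
            "model": ["linear", "quadratic"],
            "k": [lin.k, quad.k],
            "loglik": [lin.loglik, quad.loglik],
            "aicc": [lin.aicc, quad.aicc],
        }
    )
    chosen = quad if quad.aicc < lin.aicc else lin
    table["chosen"] = table["model"] == ("quadratic" if chosen is quad else "linear")
    return chosen, table


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: −2ℓ + 2k + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
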