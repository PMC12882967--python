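"""Generalized additive mixed models for pairwise network dissimilarity.

Each dissimilarity component is regressed on smooth functions of the
between-site differences in rainfall and habitat suitability, with a
random intercept for the unordered pair of sites (swarm-level pairs
within one site pair are not independent).

Smooths are cubic regression splines with at most three knots and a
shrinkage penalty: the penalty's null space (the linear part) receives
a small eigenvalue of its own, so smoothing can shrink a term all the
way to a flat line when the covariate carries no signal — the
effective degrees of freedom (e.d.f.) then drop below 1, while
e.d.f. = 1 denotes a linear effect and larger values increasing
nonlinearity.  Smoothing parameters and variance components are chosen
by REML on the Gaussian working model; the overall-dissimilarity
response (beta family, logit link) is handled by penalized
quasi-likelihood iterations around that Gaussian core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from ..errors import ConvergenceError, ValidationError
from .scaling import scale_predictors, squeeze_unit_interval

_SHRINK_FRACTION = 0.1  # null-space eigenvalue as a fraction of the smallest positive


# ---------------------------------------------------------------------------
# Cubic regression spline basis with derivative penalty (value-based
# parameterization: coefficients are the spline's values at the knots).

def crs_basis(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic regression spline basis and second-derivative penalty.

    Returns the n×k basis matrix and the k×k penalty S = D'B⁻¹D built
    from the knot spacings.  Evaluation outside the knot range
    extrapolates linearly (natural boundary conditions).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    if k < 3:
        raise ValidationError("cubic regression spline needs >= 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValidationError("knots must be strictly increasing")
    h = np.diff(knots)

    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv = np.linalg.inv(B)
    S = D.T @ Binv @ D
    # F maps knot values to second derivatives at the knots (natural BCs).
    F = np.vstack([np.zeros(k), Binv @ D, np.zeros(k)])

    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    dxm = xc - knots[j]
    dxp = knots[j + 1] - xc
    am, ap = dxp / hj, dxm / hj
    cm = (dxp**3 / hj - hj * dxp) / 6.0
    cp = (dxm**3 / hj - hj * dxm) / 6.0

    X = np.zeros((x.size, k))
    rows = np.arange(x.size)
    np.add.at(X, (rows, j), am)
    np.add.at(X, (rows, j + 1), ap)
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
    # Linear extrapolation beyond the boundary knots.
    below, above = x < knots[0], x > knots[-1]
    if below.any() or above.any():
        eps = 1e-6 * (knots[-1] - knots[0])
        for sel, x0 in ((below, knots[0]), (above, knots[-1])):
            if sel.any():
                b0, _ = crs_basis(np.array([x0]), knots)
                b1, _ = crs_basis(np.array([x0 + (eps if x0 == knots[0] else -eps)]), knots)
                slope = (b1 - b0) / (eps if x0 == knots[0] else -eps)
                X[sel] = b0 + (x[sel] - x0)[:, None] * slope
    return X, S


@dataclass
class _Smooth:
    """One shrinkage smooth term: basis transforms frozen at fit time."""

    name: str
    knots: np.ndarray
    center: np.ndarray  # column means absorbed by the sum-to-zero constraint
    Zc: np.ndarray  # k×(k−1) constraint null-space basis
    Linv_t: np.ndarray  # maps constrained coefs to iid-prior coordinates

    def design(self, x: np.ndarray) -> np.ndarray:
        X, _ = crs_basis(x, self.knots)
        return (X - self.center) @ self.Zc @ self.Linv_t


def _build_smooth(name: str, x: np.ndarray, n_knots: int) -> tuple[_Smooth, np.ndarray]:
    qs = np.linspace(0.0, 100.0, n_knots)
    knots = np.unique(np.percentile(x, qs))
    if knots.size < 3:
        raise ValidationError(
            f"covariate {name!r} has too few distinct values for a spline"
        )
    X, S = crs_basis(x, knots)
    center = X.mean(axis=0)
    # Sum-to-zero constraint: work in the null space of the column means.
    _, _, vt = np.linalg.svd(center[None, :])
    Zc = vt[1:].T
    Sc = Zc.T @ S @ Zc
    # Shrinkage ("cs"-style): give the penalty null space a small positive
    # eigenvalue so heavy smoothing can flatten the term entirely.
    w, U = np.linalg.eigh(Sc)
    pos = w > w.max() * 1e-9
    if not pos.any():
        raise ValidationError(f"degenerate penalty for smooth {name!r}")
    w[~pos] = _SHRINK_FRACTION * w[pos].min()
    S_shrunk = (U * w) @ U.T
    L = np.linalg.cholesky(S_shrunk)
    Linv_t = np.linalg.inv(L).T
    sm = _Smooth(name=name, knots=knots, center=center, Zc=Zc, Linv_t=Linv_t)
    return sm, (X - center) @ Zc @ Linv_t


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammSpec:
    """Specification for one dissimilarity response."""

    response: str  # beta_wn | beta_st | beta_os
    family: str = ""  # inferred from response when empty
    smooths: tuple[str, ...] = ("d_rainfall", "d_suitability")
    n_knots: int = 3
    scale_response: bool | None = None  # default: z-score Gaussian responses

    def resolved_family(self) -> str:
        if self.family:
            return self.family
        return "beta" if self.response == "beta_wn" else "gaussian"


@dataclass
class GammFit:
    spec: GammSpec
    edf: dict[str, float]
    pvalues: dict[str, float]
    sigma2: float  # working-scale residual variance
    gamma: dict[str, float]  # variance ratios (smooths + random intercept)
    phi: float | None  # beta precision (PQL), None for Gaussian
    n: int
    n_site_pairs: int
    converged: bool
    _smooths: list[_Smooth] = field(repr=False, default_factory=list)
    _beta_blocks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    _cov_blocks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    _intercept: float = 0.0

    def smooth_curve(self, name: str, x: np.ndarray) -> pd.DataFrame:
        """Fitted smooth (centered) with a 95% CI band over given covariate values."""
        sm = next(s for s in self._smooths if s.name == name)
        Xg = sm.design(np.asarray(x, dtype=float))
        fit = Xg @ self._beta_blocks[name]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, self._cov_blocks[name], Xg), 0))
        z = 1.959963984540054
        return pd.DataFrame(
            {"x": x, "fit": fit, "ci_lo": fit - z * se, "ci_hi": fit + z * se}
        )


class AdditiveMixedModel:
    """Gaussian additive mixed model: shrinkage smooths + one random intercept.

    The smooth coefficient blocks and the random intercept are treated
    as independent Gaussian blocks with variances γ_s σ²; the γ are
    chosen by minimizing the (profiled) REML criterion, computed through
    the low-rank Woodbury identity so each evaluation costs O(m³) in the
    total number of random coefficients m.
    """

    def __init__(self, n_knots: int = 3):
        self.n_knots = n_knots

    def _assemble(self, data: pd.DataFrame, smooths: Sequence[str], group: np.ndarray):
        self.smooths_: list[_Smooth] = []
        blocks: list[np.ndarray] = []
        self.block_names_: list[str] = []
        self.block_slices_: list[slice] = []
        start = 0
        for name in smooths:
            sm, Xs = _build_smooth(name, data[name].to_numpy(dtype=float), self.n_knots)
            self.smooths_.append(sm)
            blocks.append(Xs)
            self.block_names_.append(name)
            self.block_slices_.append(slice(start, start + Xs.shape[1]))
            start += Xs.shape[1]
        codes, uniques = pd.factorize(group, sort=True)
        q = len(uniques)
        Zg = np.zeros((len(codes), q))
        Zg[np.arange(len(codes)), codes] = 1.0
        blocks.append(Zg)
        self.block_names_.append("site_pair")
        self.block_slices_.append(slice(start, start + q))
        self.n_site_pairs_ = q
        return np.hstack(blocks)

    @staticmethod
    def _reml_pieces(XtX, Xty, ZtZ, ZtX, Zty, yty, n, p, gammas, sizes):
        gvec = np.concatenate([np.full(sz, g) for g, sz in zip(gammas, sizes)])
        m = gvec.size
        # Symmetric Woodbury core: I_m + G^{1/2} Z'Z G^{1/2}
        gs = np.sqrt(gvec)
        core = np.eye(m) + (gs[:, None] * ZtZ * gs[None, :])
        cf = linalg.cho_factor(core, lower=True)
        logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))

        def vinv_mult(AtB, ZtA, ZtB):
            # A' V⁻¹ B = A'B − (Z'A)' G^{1/2} core⁻¹ G^{1/2} (Z'B)
            tmp = linalg.cho_solve(cf, gs[:, None] * ZtB)
            return AtB - (gs[:, None] * ZtA).T @ tmp

        XtVinvX = vinv_mult(XtX, ZtX, ZtX)
        XtVinvy = vinv_mult(Xty[:, None], ZtX, Zty[:, None])[:, 0]
        ytVinvy = float(vinv_mult(np.array([[yty]]), Zty[:, None], Zty[:, None])[0, 0])
        cfx = linalg.cho_factor(XtVinvX)
        beta_gls = linalg.cho_solve(cfx, XtVinvy)
        ytPy = ytVinvy - XtVinvy @ beta_gls
        logdet_XVX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        return logdet_V, logdet_XVX, max(ytPy, 1e-12)

    def fit(
        self,
        y: np.ndarray,
        data: pd.DataFrame,
        smooths: Sequence[str],
        group: np.ndarray,
        *,
        weights: np.ndarray | None = None,
    ):
        y = np.asarray(y, dtype=float)
        n = y.size
        W = self._assemble(data, smooths, group)
        X = np.ones((n, 1))  # fixed part: intercept only
        if weights is not None:
            sw = np.sqrt(np.asarray(weights, dtype=float))
            yw, Xw, Ww = y * sw, X * sw[:, None], W * sw[:, None]
        else:
            yw, Xw, Ww = y, X, W
        p = Xw.shape[1]
        sizes = [s.stop - s.start for s in self.block_slices_]

        XtX, Xty, yty = Xw.T @ Xw, Xw.T @ yw, float(yw @ yw)
        ZtZ, ZtX, Zty = Ww.T @ Ww, Ww.T @ Xw, Ww.T @ yw

        def neg_reml(log_g):
            gammas = np.exp(np.clip(log_g, -18.0, 18.0))
            ld_v, ld_x, ytPy = self._reml_pieces(
                XtX, Xty, ZtZ, ZtX, Zty, yty, n, p, gammas, sizes
            )
            return (n - p) * np.log(ytPy) + ld_v + ld_x

        x0 = np.zeros(len(sizes))
        res = optimize.minimize(neg_reml, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000})
        if not res.success:
            raise ConvergenceError(f"GAMM REML search failed: {res.message}",
                                   n_iter=int(res.nit))
        gammas = np.exp(np.clip(res.x, -18.0, 18.0))

        # Final penalized fit at the selected smoothing parameters.
        gvec = np.concatenate([np.full(sz, g) for g, sz in zip(gammas, sizes)])
        C = np.hstack([Xw, Ww])
        pen = np.concatenate([np.zeros(p), 1.0 / gvec])
        A = C.T @ C + np.diag(pen)
        Ainv = np.linalg.inv(A)
        coefs = Ainv @ (C.T @ yw)
        resid = yw - C @ coefs
        ytPy = float(resid @ yw)  # = y'y − y'Cθ̂ for the penalized solution
        sigma2 = max(ytPy, 1e-12) / (n - p)

        E = Ainv @ (C.T @ C)  # hat-matrix trace decomposition
        edf = {}
        for name, sl in zip(self.block_names_, self.block_slices_):
            cols = slice(p + sl.start, p + sl.stop)
            edf[name] = float(np.trace(E[cols, cols]))

        Vb = sigma2 * Ainv  # Bayesian posterior covariance
        self.coefs_, self.cov_, self.sigma2_ = coefs, Vb, sigma2
        self.edf_ = edf
        self.gamma_ = dict(zip(self.block_names_, gammas))
        self.p_fixed_ = p
        self.n_ = n
        return self

    def block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.block_names_.index(name)
        sl = self.block_slices_[i]
        cols = slice(self.p_fixed_ + sl.start, self.p_fixed_ + sl.stop)
        return self.coefs_[cols], self.cov_[cols, cols]

    def smooth_pvalue(self, name: str) -> float:
        """Approximate Wald test of a smooth against zero, on e.d.f. degrees.

        mgcv-style: the statistic uses the posterior covariance of the
        smooth's coefficients and is referred to a chi-square with the
        term's effective degrees of freedom.
        """
        b, V = self.block(name)
        w, U = np.linalg.eigh(V)
        keep = w > max(w.max(), 1e-300) * 1e-10
        Vinv = (U[:, keep] / w[keep]) @ U[:, keep].T
        T = float(b @ Vinv @ b)
        df = max(self.edf_[name], 0.05)
        return float(stats.chi2.sf(T, df))


def _site_pair_labels(data: pd.DataFrame) -> np.ndarray:
    labels = [
        "|".join(sorted((str(a), str(b))))
        for a, b in zip(data["site_1"], data["site_2"])
    ]
    return np.asarray(labels, dtype=object)


def fit_gamm(spec: GammSpec, data: pd.DataFrame, *, prescaled: bool = False) -> GammFit:
    """Fit one dissimilarity GAMM on the pairwise table.

    Smooth covariates are standardized; Gaussian responses (turnover and
    rewiring components) are z-scored; the beta-family overall
    dissimilarity is squeezed off {0, 1} and fitted by PQL.
    """
    family = spec.resolved_family()
    need = [spec.response, *spec.smooths, "site_1", "site_2"]
    d = data[need].dropna().copy()
    n = len(d)
    if n < 50:
        raise ValidationError(f"need >= 50 pairwise rows, have {n}")
    if not prescaled:
        d, _ = scale_predictors(d, list(spec.smooths))
    y = d[spec.response].to_numpy(dtype=float)
    group = _site_pair_labels(d)

    scale_resp = spec.scale_response
    if scale_resp is None:
        scale_resp = family == "gaussian"

    model = AdditiveMixedModel(n_knots=spec.n_knots)
    phi = None
    if family == "gaussian":
        if scale_resp:
            sd = y.std(ddof=1)
            if not sd > 0:
                raise ValidationError("response has zero variance")
            y = (y - y.mean()) / sd
        model.fit(y, d, spec.smooths, group)
        converged = True
    elif family == "beta":
        y = squeeze_unit_interval(y, n)
        eta = np.log(y / (1 - y))
        phi = max(np.mean(y) * (1 - np.mean(y)) / max(np.var(y), 1e-8) - 1, 1.0)
        converged = False
        # PQL outer loop: tolerance 1e-3 on the linear predictor — smoothing
        # parameters are re-selected each cycle, which leaves a small limit
        # cycle well below any inferentially relevant scale.
        for _ in range(50):
            mu = special.expit(np.clip(eta, -15, 15))
            v = mu * (1 - mu)
            z = eta + (y - mu) / v
            w = v * (1 + phi)
            model.fit(z, d, spec.smooths, group, weights=w)
            # Rebuild the linear predictor from the fitted components.
            eta_new = np.full(n, model.coefs_[0])
            for sm in model.smooths_:
                b, _ = model.block(sm.name)
                eta_new += sm.design(d[sm.name].to_numpy(dtype=float)) @ b
            bg, _ = model.block("site_pair")
            codes, _ = pd.factorize(group, sort=True)
            eta_new += bg[codes]
            mu_new = special.expit(np.clip(eta_new, -15, 15))
            edf_tot = sum(model.edf_.values()) + 1
            pearson = float(np.sum((y - mu_new) ** 2 / (mu_new * (1 - mu_new))))
            phi = max((n - edf_tot) / max(pearson, 1e-10) - 1, 0.1)
            if np.max(np.abs(eta_new - eta)) < 1e-3:
                eta = eta_new
                converged = True
                break
            eta = eta_new
        if not converged:
            raise ConvergenceError("beta-family PQL iterations did not converge")
    else:
        raise ValidationError(f"unknown GAMM family {family!r}")

    edf = {k: v for k, v in model.edf_.items() if k != "site_pair"}
    pvals = {name: model.smooth_pvalue(name) for name in spec.smooths}
    beta_blocks, cov_blocks = {}, {}
    for name in spec.smooths:
        b, V = model.block(name)
        beta_blocks[name], cov_blocks[name] = b, V
    return GammFit(
        spec=spec,
        edf=edf,
        pvalues=pvals,
        sigma2=model.sigma2_,
        gamma=model.gamma_,
        phi=phi,
        n=n,
        n_site_pairs=model.n_site_pairs_,
        converged=converged,
        _smooths=model.smooths_,
        _beta_blocks=beta_blocks,
        _cov_blocks=cov_blocks,
        _intercept=float(model.coefs_[0]),
    )
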