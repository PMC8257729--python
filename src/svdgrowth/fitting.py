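"""Model fitting: quasi-Newton FIML estimation wrapped as an sklearn-style estimator.

:class:`StructuralEquationModel` follows the scikit-learn estimator contract
(``fit`` on a DataFrame, fitted attributes with trailing underscores,
``get_params``/``set_params``), so grids of models compose with ordinary
tooling.  The module-level :func:`fit` function is a thin wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .likelihood import (InadmissibleParameters, ModelData, implied_moments,
                         loglik_and_grad)
from .model import CompiledModel, ModelSpec

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class StdEstimate:
    est: float
    se: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        if self.se is None:
            return (np.nan, np.nan)
        return (self.est - 1.96 * self.se, self.est + 1.96 * self.se)

    @property
    def p(self) -> float:
        if self.se is None or self.se == 0:
            return np.nan
        return float(2.0 * norm.sf(abs(self.est / self.se)))


@dataclass
class FitResult:
    """Estimates, likelihood and diagnostics from one model fit."""

    spec: ModelSpec
    model: CompiledModel
    theta_t: np.ndarray
    loglik: float
    converged: bool
    gradient_norm: float
    n_used: int
    n_params: int
    n_nodes: int
    estimates: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    standardized: dict[str, StdEstimate] = field(default_factory=dict)
    n_starts_tried: int = 1

    def implied_moments(self):
        return implied_moments(self.model, self.theta_t)

    def to_json_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_used": self.n_used,
            "converged": bool(self.converged),
            "gradient_norm": self.gradient_norm,
            "estimates": self.estimates,
            "se": self.se,
            "standardized": {
                k: {"est": v.est, "se": v.se, "ci": list(v.ci), "p": v.p}
                for k, v in self.standardized.items()
            },
        }


class StructuralEquationModel(BaseEstimator):
    """FIML estimation of a structural equation model.

    Parameters
    ----------
    spec : ModelSpec
        The model to estimate.
    n_starts : int
        Number of optimisation starts: the spec's start values plus jittered
        perturbations; the best final likelihood wins.
    n_nodes : int
        Gauss-Hermite nodes for models with binary indicators.
    compute_se : bool
        Whether to compute observed-information standard errors and the
        delta-method standardized solution after fitting.
    gtol, ftol : float
        L-BFGS projected-gradient and relative function tolerances.
    jitter : float
        Standard deviation of the start perturbations (transformed scale).
    seed : int
        Seed for the start-value jitter stream.
    """

    def __init__(self, spec=None, n_starts=5, n_nodes=21, compute_se=True,
                 gtol=1e-5, ftol=1e-9, maxiter=3000, jitter=0.1, seed=0):
        self.spec = spec
        self.n_starts = n_starts
        self.n_nodes = n_nodes
        self.compute_se = compute_se
        self.gtol = gtol
        self.ftol = ftol
        self.maxiter = maxiter
        self.jitter = jitter
        self.seed = seed

    # -- scikit-learn interface -------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        model = self.spec.compile()
        data = ModelData(model, X)
        res = _optimize(model, data, n_starts=self.n_starts, n_nodes=self.n_nodes,
                        gtol=self.gtol, ftol=self.ftol, maxiter=self.maxiter,
                        jitter=self.jitter, seed=self.seed)
        if self.compute_se and res.converged:
            add_standard_errors(res, data)
        self.result_ = res
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.estimates_ = res.estimates
        self.se_ = res.se
        self.standardized_ = res.standardized
        self.n_used_ = res.n_used
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-subject log-likelihood of ``X`` under the fitted parameters."""
        model = self.result_.model
        data = ModelData(model, X)
        ll, _ = loglik_and_grad(model, data, self.result_.theta_t,
                                n_nodes=self.n_nodes, want_grad=False)
        return ll / max(data.n_used, 1)


def fit(spec: ModelSpec, cohort: pd.DataFrame, **opts) -> FitResult:
    """Fit ``spec`` to ``cohort`` by FIML; see :class:`StructuralEquationModel`."""
    est = StructuralEquationModel(spec=spec, **opts)
    return est.fit(cohort).result_


# ---------------------------------------------------------------------------

def _objective(model, data, n_nodes):
    state = {"last_ok": None}

    def f(theta):
        try:
            # wild probe points can overflow exp() before the admissibility
            # check rejects them; the non-finite guard below handles those
            with np.errstate(over="ignore", invalid="ignore"):
                ll, g = loglik_and_grad(model, data, theta, n_nodes=n_nodes)
            if not np.isfinite(ll) or not np.all(np.isfinite(g)):
                raise InadmissibleParameters("non-finite likelihood")
            state["last_ok"] = theta.copy()
            return -ll, -g
        except InadmissibleParameters:
            ref = state["last_ok"] if state["last_ok"] is not None else np.zeros_like(theta)
            d = theta - ref
            return 1e12 + 1e8 * float(d @ d), 2e8 * d

    return f


def _diag_precondition(f, x0, eps=1e-4):
    """One-shot diagonal-Hessian scaling: SEM parameters live on wildly
    different curvature scales (loadings vs latent covariances), which stalls
    L-BFGS; optimising in x = s*y with s ~ H_jj^(-1/2) fixes the conditioning."""
    _, g0 = f(x0)
    k = len(x0)
    d = np.ones(k)
    for j in range(k):
        xp = x0.copy()
        xp[j] += eps
        _, gp = f(xp)
        d[j] = (gp[j] - g0[j]) / eps
    pos = d[d > 1e-8]
    fallback = np.median(pos) if len(pos) else 1.0
    d = np.where(d > 1e-8, d, fallback)
    return 1.0 / np.sqrt(d)


def _optimize(model, data, n_starts, n_nodes, gtol, ftol, maxiter, jitter, seed):
    rng = np.random.default_rng(seed)
    f = _objective(model, data, n_nodes)
    theta0 = model.start_vector()
    scale = _diag_precondition(f, theta0)

    def f_scaled(y):
        fx, gx = f(scale * y)
        return fx, scale * gx

    best = None
    tried = 0
    for s in range(max(1, n_starts)):
        x0 = theta0 if s == 0 else theta0 + rng.normal(0.0, jitter, theta0.shape)
        res = optimize.minimize(
            f_scaled, x0 / scale, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 25},
        )
        res.x = scale * res.x
        tried += 1
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e11 and s == 0 and n_starts <= 1:
            break
    ll, g = loglik_and_grad(model, data, best.x, n_nodes=n_nodes)
    gnorm = float(np.max(np.abs(g)))
    converged = bool(np.isfinite(ll)) and best.fun < 1e11 and (
        best.success or gnorm < 100.0 * gtol * max(1.0, np.sqrt(data.n_used))
    )
    result = FitResult(
        spec=model.spec, model=model, theta_t=best.x, loglik=ll,
        converged=converged, gradient_norm=gnorm, n_used=data.n_used,
        n_params=model.n_free, n_nodes=n_nodes,
        estimates=model.estimates_dict(best.x), n_starts_tried=tried,
    )
    return result


# ---------------------------------------------------------------------------
# standard errors and the standardized solution

def _observed_information(model, data, theta_t, n_nodes, eps=1e-5):
    """Numerical Hessian of -loglik from central differences of the analytic gradient."""
    k = len(theta_t)
    H = np.zeros((k, k))
    for j in range(k):
        tp, tm = theta_t.copy(), theta_t.copy()
        tp[j] += eps
        tm[j] -= eps
        _, gp = loglik_and_grad(model, data, tp, n_nodes=n_nodes)
        _, gm = loglik_and_grad(model, data, tm, n_nodes=n_nodes)
        H[:, j] = -(gp - gm) / (2.0 * eps)
    return 0.5 * (H + H.T)


def standardized_solution(model: CompiledModel, theta_t: np.ndarray) -> dict[str, float]:
    """Standardized structural paths and loadings at ``theta_t``.

    Paths among latents are rescaled by model-implied total latent SDs;
    loadings by latent SD over observed SD.  Keys: ``"to~from"`` for paths,
    ``"obs=~lat"`` for loadings, ``"mean(lat)"`` for latent means (unscaled),
    ``"var(lat)"`` for total latent variances.
    """
    Lam, B, Psi, Th, nu, alpha, tau, Gam = model.matrices(theta_t)
    m = model.m
    M = linalg.solve(np.eye(m) - B, np.eye(m), check_finite=False)
    SigL = M @ Psi @ M.T
    sdL = np.sqrt(np.clip(np.diag(SigL), 1e-12, None))
    Sig = Lam[model.cont_rows] @ SigL @ Lam[model.cont_rows].T + \
        Th[np.ix_(model.cont_rows, model.cont_rows)]
    sdO = np.sqrt(np.clip(np.diag(Sig), 1e-12, None))
    sd_obs = {v: sdO[i] for i, v in enumerate(model.cont_vars)}
    out: dict[str, float] = {}
    spec = model.spec
    for (to, frm), e in spec.beta.items():
        i, j = model.lat_index[to], model.lat_index[frm]
        out[f"{to}~{frm}"] = B[i, j] * sdL[j] / sdL[i]
    for (obs, lat), e in spec.lambda_.items():
        i, j = model.obs_index[obs], model.lat_index[lat]
        denom = sd_obs.get(obs)
        if denom is None:  # binary: liability SD = sqrt(l^2 psi + 1)
            denom = np.sqrt(Lam[i, j] ** 2 * SigL[j, j] + 1.0)
        out[f"{obs}=~{lat}"] = Lam[i, j] * sdL[j] / denom
    for lat in spec.latents:
        j = model.lat_index[lat]
        out[f"var({lat})"] = SigL[j, j]
        out[f"mean({lat})"] = float((M @ alpha)[j])
    return out


def add_standard_errors(res: FitResult, data: ModelData) -> FitResult:
    """Attach observed-information SEs and the delta-method standardized block."""
    model, theta = res.model, res.theta_t
    with np.errstate(over="ignore", invalid="ignore"):
        H = _observed_information(model, data, theta, res.n_nodes)
    try:
        cov_t = linalg.inv(H)
    except linalg.LinAlgError:
        cov_t = linalg.pinvh(H)
    d = np.diag(cov_t).copy()
    bad = d < 0
    d[bad] = np.nan
    # natural-scale SEs via the chain rule through exp() for log-variances
    jac_nat = model.natural_jacobian_diag(theta)
    se_nat = np.sqrt(d) * np.abs(jac_nat)
    res.se = dict(zip(model.labels, se_nat.tolist()))

    keys = list(standardized_solution(model, theta).keys())
    s0 = np.array([standardized_solution(model, theta)[k] for k in keys])
    J = np.zeros((len(keys), len(theta)))
    eps = 1e-6
    for j in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        sp = standardized_solution(model, tp)
        sm = standardized_solution(model, tm)
        J[:, j] = [(sp[k] - sm[k]) / (2 * eps) for k in keys]
    var_s = np.einsum("ij,jk,ik->i", J, cov_t, J)
    var_s = np.where(var_s < 0, np.nan, var_s)
    res.standardized = {
        k: StdEstimate(float(v), float(np.sqrt(vs)) if np.isfinite(vs) else None)
        for k, v, vs in zip(keys, s0, var_s)
    }
    return res


def flip_factor_sign(res: FitResult, factor: str) -> None:
    """Negate a latent factor's direction in place (loadings, paths, covariances, mean).

    Used to canonicalise sign-indeterminate factors (unit-variance
    identification): the likelihood is invariant, interpretation is not.
    Requires each affected free parameter label to be tied only to entries
    that flip together.
    """
    model, spec = res.model, res.spec
    k = model.lat_index[factor]
    flip_labels = set()
    for (obs, lat), e in spec.lambda_.items():
        if lat == factor and e.free:
            flip_labels.add(e.label)
    for (to, frm), e in spec.beta.items():
        if (to == factor) != (frm == factor) and e.free:  # xor: one endpoint flips
            flip_labels.add(e.label)
    for (a, b), e in spec.psi.items():
        if (a == factor) != (b == factor) and e.free:
            flip_labels.add(e.label)
    if factor in spec.alpha and spec.alpha[factor].free:
        flip_labels.add(spec.alpha[factor].label)
    for j, (lab, is_log) in enumerate(zip(model.labels, model.log_scale)):
        if lab in flip_labels:
            if is_log:
                raise ValueError(f"cannot flip log-scale parameter {lab}")
            res.theta_t[j] = -res.theta_t[j]
    res.estimates = model.estimates_dict(res.theta_t)


# ---------------------------------------------------------------------------
# saturated and independence (baseline) models for fit indices

@dataclass
class MomentsResult:
    mu: np.ndarray
    sigma: np.ndarray
    loglik: float
    n_params: int
    columns: list[str]


def fit_saturated(df: pd.DataFrame, columns=None, tol=1e-9, max_iter=500) -> MomentsResult:
    """Unstructured-MVN FIML fit (mean vector and full covariance) via EM."""
    cols = list(columns) if columns is not None else list(df.columns)
    Y = df[cols].to_numpy(dtype=float)
    Y = Y[~np.isnan(Y).all(axis=1)]
    n, p = Y.shape
    obs = ~np.isnan(Y)
    mu = np.nanmean(Y, axis=0)
    sig = np.ma.cov(np.ma.masked_invalid(Y), rowvar=False, bias=True).filled(0.0)
    sig += np.eye(p) * (1e-6 + 1e-3 * np.trace(sig) / p)
    codes = np.packbits(obs, axis=1)
    _, first, inverse = np.unique(codes, axis=0, return_index=True, return_inverse=True)
    groups = [(np.where(obs[r0])[0], np.where(inverse == g)[0]) for g, r0 in enumerate(first)]

    last_ll = -np.inf
    for _ in range(max_iter):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        ll = 0.0
        for o, rows in groups:
            mIdx = np.setdiff1d(np.arange(p), o)
            Yo = Y[np.ix_(rows, o)]
            Soo = sig[np.ix_(o, o)]
            L = linalg.cholesky(Soo, lower=True, check_finite=False)
            R = Yo - mu[o]
            V = linalg.cho_solve((L, True), R.T, check_finite=False)
            ll += -0.5 * (len(rows) * (len(o) * _LOG2PI + 2 * np.log(np.diag(L)).sum())
                          + np.einsum("ij,ji->", R, V))
            Ey = np.tile(mu, (len(rows), 1))
            Ey[:, o] = Yo
            Cov = np.zeros((p, p))
            if len(mIdx):
                B = linalg.cho_solve((L, True), sig[np.ix_(o, mIdx)], check_finite=False)
                Ey[:, mIdx] = mu[mIdx] + R @ B
                Cov[np.ix_(mIdx, mIdx)] = sig[np.ix_(mIdx, mIdx)] - sig[np.ix_(mIdx, o)] @ B
            S1 += Ey.sum(axis=0)
            S2 += Ey.T @ Ey + len(rows) * Cov
        mu = S1 / n
        sig = S2 / n - np.outer(mu, mu)
        sig = 0.5 * (sig + sig.T)
        if abs(ll - last_ll) < tol * (1 + abs(ll)):
            last_ll = ll
            break
        last_ll = ll
    return MomentsResult(mu, sig, last_ll, p * (p + 3) // 2, cols)


def fit_baseline(df: pd.DataFrame, columns=None) -> MomentsResult:
    """Independence model: free means and variances, zero covariances (exact MLE)."""
    cols = list(columns) if columns is not None else list(df.columns)
    Y = df[cols].to_numpy(dtype=float)
    Y = Y[~np.isnan(Y).all(axis=1)]
    p = Y.shape[1]
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    ll = 0.0
    for j in range(p):
        y = Y[:, j]
        y = y[~np.isnan(y)]
        ll += -0.5 * (len(y) * (_LOG2PI + np.log(var[j])) + ((y - mu[j]) ** 2).sum() / var[j])
    return MomentsResult(mu, np.diag(var), ll, 2 * p, cols)
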