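"""Full-information maximum likelihood for SEMs with optional binary indicators.

Continuous models use the casewise multivariate-normal likelihood, grouped by
missing-data pattern.  Models with binary (probit-threshold) indicators use
one-dimensional adaptive Gauss–Hermite quadrature over the single latent the
binary variables load on: conditional on that latent, the continuous block is
multivariate normal and the binary indicators are independent probits.

Both paths return the log-likelihood together with its analytic gradient
(hand-written reverse-mode differentiation through the LISREL matrix algebra),
which is what makes the repeated model fits in the simulation studies cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, special
from scipy.stats import norm

from functools import lru_cache

from .model import CompiledModel, _LAMBDA, _BETA, _PSI, _THETA, _NU, _ALPHA, _TAU, _GAMMA

_LOG2PI = np.log(2.0 * np.pi)


@lru_cache(maxsize=None)
def _hermgauss(n_nodes: int):
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    return t, w, np.log(w)


class InadmissibleParameters(RuntimeError):
    """Raised when the implied covariance at a parameter point is not PD."""


class ModelData:
    """Cohort columns arranged for a compiled model, grouped by missingness pattern.

    Binary indicator columns and any exogenous-regressor column referenced by a
    nonzero Gamma row of an observed variable must be complete for the subjects
    contributing that variable; exogenous cells tied to missing outcomes may be
    missing and are zero-filled (they never enter the likelihood).
    """

    def __init__(self, model: CompiledModel, df: pd.DataFrame):
        self.model = model
        spec = model.spec
        missing_cols = [c for c in spec.observed + spec.exog if c not in df.columns]
        if missing_cols:
            raise KeyError(f"cohort is missing model columns: {missing_cols}")
        Yc = df[model.cont_vars].to_numpy(dtype=float)
        self.n_total = len(df)
        if model.bin_vars:
            D = df[model.bin_vars].to_numpy(dtype=float)
            if np.isnan(D).any():
                raise ValueError("binary indicator columns must be complete")
            bad = ~np.isin(D, (0.0, 1.0))
            if bad.any():
                raise ValueError("binary indicator columns must contain only 0/1")
            self.D = D
        else:
            self.D = np.zeros((self.n_total, 0))
        if spec.exog:
            X = df[spec.exog].to_numpy(dtype=float)
            X = np.where(np.isnan(X), 0.0, X)  # cells tied to missing outcomes only
        else:
            X = np.zeros((self.n_total, 0))
        self.X = X

        obs_mask = ~np.isnan(Yc)
        keep = obs_mask.any(axis=1) | (len(model.bin_vars) > 0)
        self.kept = np.where(keep)[0]
        self.n_used = int(keep.sum())
        Yc, obs_mask = Yc[keep], obs_mask[keep]
        self.D = self.D[keep]
        self.X = self.X[keep]
        # group rows by missingness pattern
        codes = np.packbits(obs_mask, axis=1)
        _, first, inverse = np.unique(codes, axis=0, return_index=True, return_inverse=True)
        self.patterns = []
        for g, row0 in enumerate(first):
            rows = np.where(inverse == g)[0]
            cols = np.where(obs_mask[row0])[0]
            self.patterns.append(
                {
                    "rows": rows,
                    "cols": cols,  # indices into model.cont_vars
                    "Y": np.ascontiguousarray(Yc[np.ix_(rows, cols)]),
                    "X": np.ascontiguousarray(self.X[rows]),
                    "D": np.ascontiguousarray(self.D[rows]),
                }
            )


def _chol_logdet(S):
    try:
        L = linalg.cholesky(S, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise InadmissibleParameters(str(exc)) from exc
    return L, 2.0 * np.log(np.diag(L)).sum()


def loglik_and_grad(model: CompiledModel, data: ModelData, theta_t: np.ndarray,
                    n_nodes: int = 21, want_grad: bool = True):
    """Log-likelihood and gradient (transformed scale) at ``theta_t``.

    Dispatches to the pure-continuous FIML path or the quadrature path
    depending on whether the model contains binary indicators.
    """
    if model.bin_vars:
        return _loglik_binary(model, data, theta_t, n_nodes, want_grad)
    return _loglik_continuous(model, data, theta_t, want_grad)


def loglik(model: CompiledModel, data: ModelData, theta_t, n_nodes: int = 21) -> float:
    return loglik_and_grad(model, data, theta_t, n_nodes, want_grad=False)[0]


def _common_forward(model, theta_t):
    Lam, B, Psi, Th, nu, alpha, tau, Gam = model.matrices(theta_t)
    m = model.m
    try:
        M = linalg.solve(np.eye(m) - B, np.eye(m), check_finite=False)
    except linalg.LinAlgError as exc:
        raise InadmissibleParameters("singular (I - Beta)") from exc
    SigL = M @ Psi @ M.T
    avec = M @ alpha
    cr = model.cont_rows
    LamC = Lam[cr]
    SigF = LamC @ SigL @ LamC.T + Th[np.ix_(cr, cr)]
    muC = nu[cr] + LamC @ avec
    GamC = Gam[cr] if model.q else None
    return dict(Lam=Lam, B=B, Psi=Psi, Th=Th, nu=nu, alpha=alpha, tau=tau, Gam=Gam,
                M=M, SigL=SigL, avec=avec, LamC=LamC, SigF=SigF, muC=muC, GamC=GamC)


def _finish_gradient(model, fw, SigBar, nuBarC, LamBarC_extra, GamBarC, alphaBar_extra,
                     LamBar_bin=None, tauBar=None, SigLBar_extra=None, theta_t=None):
    """Chain accumulated continuous-block adjoints back to the base matrices."""
    cr = model.cont_rows
    LamC, SigL, M, Psi, alpha, avec = (fw["LamC"], fw["SigL"], fw["M"], fw["Psi"],
                                       fw["alpha"], fw["avec"])
    p, mdim = model.p, model.m

    LamBar = np.zeros((p, mdim))
    ThBar = np.zeros((p, p))
    nuBar = np.zeros((p, 1))
    GamBar = np.zeros((p, max(model.q, 1)))

    SigBarS = 0.5 * (SigBar + SigBar.T)
    LamBar[cr] = 2.0 * SigBarS @ LamC @ SigL + LamBarC_extra
    SigLBar = LamC.T @ SigBar @ LamC
    if SigLBar_extra is not None:
        SigLBar = SigLBar + SigLBar_extra
    ThBar[np.ix_(cr, cr)] = SigBarS
    nuBar[cr, 0] = nuBarC
    if model.q and GamBarC is not None:
        GamBar[cr] = GamBarC

    # mu = nu + LamC @ (M alpha): mean part
    uC = nuBarC  # dL/d(muC) summed over subjects
    avecBar = LamC.T @ uC + (alphaBar_extra if alphaBar_extra is not None else 0.0)
    LamBar[cr] += np.outer(uC, avec)
    alphaBar = M.T @ avecBar
    MBar = np.outer(avecBar, alpha)

    # SigL = M Psi M^T
    PsiBar = M.T @ SigLBar @ M
    MBar += SigLBar @ M @ Psi.T + SigLBar.T @ M @ Psi
    BBar = M.T @ MBar @ M.T

    if LamBar_bin is not None:
        LamBar += LamBar_bin
    adjoints = {
        _LAMBDA: LamBar,
        _BETA: BBar,
        _PSI: PsiBar,
        _THETA: ThBar,
        _NU: nuBar,
        _ALPHA: alphaBar.reshape(-1, 1),
        _GAMMA: GamBar,
    }
    if tauBar is not None:
        adjoints[_TAU] = tauBar
    return model.gather_grad(theta_t, adjoints)


def _loglik_continuous(model, data, theta_t, want_grad):
    fw = _common_forward(model, theta_t)
    SigF, muC, GamC = fw["SigF"], fw["muC"], fw["GamC"]
    pall = len(model.cont_vars)

    ll = 0.0
    SigBar = np.zeros((pall, pall))
    nuBarC = np.zeros(pall)
    GamBarC = np.zeros((pall, model.q)) if model.q else None

    for pat in data.patterns:
        cols = pat["cols"]
        Y, X = pat["Y"], pat["X"]
        n_g, p_o = Y.shape
        So = SigF[np.ix_(cols, cols)]
        L, logdet = _chol_logdet(So)
        mu = muC[cols]
        if model.q:
            Mu = mu + X @ GamC[cols].T
            R = Y - Mu
        else:
            R = Y - mu
        V = linalg.cho_solve((L, True), R.T, check_finite=False)  # p_o x n_g
        quad = np.einsum("ij,ji->", R, V)
        ll += -0.5 * (n_g * (p_o * _LOG2PI + logdet) + quad)
        if want_grad:
            So_inv = linalg.cho_solve((L, True), np.eye(p_o), check_finite=False)
            A = -0.5 * (n_g * So_inv - V @ V.T)
            SigBar[np.ix_(cols, cols)] += A
            u = V.sum(axis=1)
            nuBarC[cols] += u
            if model.q:
                GamBarC[cols] += V @ X

    if not want_grad:
        return ll, None
    grad = _finish_gradient(model, fw, SigBar, nuBarC,
                            LamBarC_extra=np.zeros((pall, model.m)),
                            GamBarC=GamBarC, alphaBar_extra=None, theta_t=theta_t)
    return ll, grad


def _loglik_binary(model, data, theta_t, n_nodes, want_grad):
    fw = _common_forward(model, theta_t)
    SigF, muC, GamC, SigL, Lam, tau, avec = (fw["SigF"], fw["muC"], fw["GamC"],
                                             fw["SigL"], fw["Lam"], fw["tau"], fw["avec"])
    cr, br = model.cont_rows, model.bin_rows
    kF = model.int_latent_idx
    pall = len(model.cont_vars)
    nb = len(model.bin_vars)

    psiF = SigL[kF, kF]
    if psiF <= 0:
        raise InadmissibleParameters("non-positive variance of integration latent")
    sqp = np.sqrt(psiF)
    cfull = fw["LamC"] @ SigL[:, kF]          # Cov(continuous, eta)
    a_full = cfull / sqp                      # loading of continuous on z = (eta-mF)/sqrt(psi)
    mF = avec[kF]
    lb = Lam[br, kF]                          # binary loadings on eta
    beta_b = lb * sqp
    kappa_b = lb * mF - tau[br]

    # Gauss-Hermite nodes (physicists'); integral over z ~ N(0,1)
    tk, wk, log_wk = _hermgauss(n_nodes)

    ll = 0.0
    SigBar = np.zeros((pall, pall))
    nuBarC = np.zeros(pall)
    GamBarC = np.zeros((pall, model.q)) if model.q else None
    aBar = np.zeros(pall)       # adjoint of a_full (mean-shift + Sigc parts)
    psiBar = 0.0
    lbBar = np.zeros(nb)
    tauBarv = np.zeros(nb)
    mFBar = 0.0

    for pat in data.patterns:
        cols = pat["cols"]
        Y, X, D = pat["Y"], pat["X"], pat["D"]
        n_g, p_o = Y.shape
        sgn = 2.0 * D - 1.0  # n_g x nb

        if p_o:
            So = SigF[np.ix_(cols, cols)]
            a = a_full[cols]
            Sc = So - np.outer(a, a)
            L, logdet = _chol_logdet(Sc)
            mu = muC[cols]
            Mu = mu + X @ GamC[cols].T if model.q else mu
            R = Y - Mu
            V = linalg.cho_solve((L, True), R.T, check_finite=False)  # p_o x n_g
            h = linalg.cho_solve((L, True), a, check_finite=False)
            rq = np.einsum("ij,ji->i", R, V)
            q = R @ h                       # a' Sc^-1 r_i
            c0 = float(a @ h)
        else:  # subject contributes only through the binary indicators
            L, logdet = None, 0.0
            a = np.zeros(0)
            V, h = np.zeros((0, n_g)), np.zeros(0)
            rq, q, c0 = np.zeros(n_g), np.zeros(n_g), 0.0
        # adaptive centring from the Gaussian part of the posterior of z
        s_star = 1.0 / np.sqrt(1.0 + c0)
        m_i = q * s_star**2
        Z = m_i[:, None] + np.sqrt(2.0) * s_star * tk[None, :]   # n_g x K

        logint = (q[:, None] * Z - 0.5 * c0 * Z**2
                  - 0.5 * Z**2 - 0.5 * _LOG2PI)                   # + log phi(z)
        if nb:
            U = sgn[:, :, None] * (beta_b[None, :, None] * Z[:, None, :]
                                   + kappa_b[None, :, None])      # n_g x nb x K
            logint = logint + special.log_ndtr(U).sum(axis=1)
        const_i = -0.5 * (p_o * _LOG2PI + logdet) - 0.5 * rq
        logw = logint + (log_wk + tk**2)[None, :] + np.log(np.sqrt(2.0) * s_star)
        lse = special.logsumexp(logw, axis=1)
        ll += const_i.sum() + lse.sum()

        if not want_grad:
            continue
        P = np.exp(logw - lse[:, None])               # posterior node weights
        m1 = (P * Z).sum(axis=1)
        m2 = (P * Z**2).sum(axis=1)
        S1, S2 = m1.sum(), m2.sum()

        if p_o:
            So_inv = linalg.cho_solve((L, True), np.eye(p_o), check_finite=False)
            Vm1 = V @ m1
            # Sigc^-1 Wtilde Sigc^-1 where Wtilde = E[(r - a z)(r - a z)']
            mid = (V @ V.T) - np.outer(Vm1, h) - np.outer(h, Vm1) + S2 * np.outer(h, h)
            A_Sc = -0.5 * (n_g * So_inv - mid)
            SigBar[np.ix_(cols, cols)] += A_Sc
            # mean adjoint: sum_i Sc^-1 (r_i - a m1_i)
            u = V.sum(axis=1) - h * S1
            nuBarC[cols] += u
            if model.q:
                GamBarC[cols] += V @ X - np.outer(h, m1 @ X)
            # a adjoint: mean-shift part + through Sigc = So - a a'
            a_mean = Vm1 - h * S2
            A_ScS = 0.5 * (A_Sc + A_Sc.T)
            a_sig = -2.0 * A_ScS @ a
            aBar[cols] += a_mean + a_sig
        # binary parts
        if nb:
            G = sgn[:, :, None] * np.exp(-0.5 * U * U - 0.5 * _LOG2PI
                                         - special.log_ndtr(U))
            PG = P[:, None, :] * G
            kapBar = PG.sum(axis=(0, 2))
            betBar = (PG * Z[:, None, :]).sum(axis=(0, 2))
            lbBar += betBar * sqp + kapBar * mF
            psiBar += float(betBar @ lb) / (2.0 * sqp)
            mFBar += float(kapBar @ lb)
            tauBarv -= kapBar

    if not want_grad:
        return ll, None

    # a_full = cfull / sqrt(psiF); cfull = LamC SigL e_F; psiF = SigL[F,F]
    cBar = aBar / sqp
    psiBar += -0.5 * float(aBar @ a_full) / psiF
    LamBarC_extra = np.outer(cBar, SigL[:, kF])
    SigLBar_extra = np.outer(fw["LamC"].T @ cBar, _unit(model.m, kF))
    SigLBar_extra[kF, kF] += psiBar

    # mF = (M alpha)[kF]: fold into avec adjoint via extra term
    avec_extra = np.zeros(model.m)
    avec_extra[kF] = mFBar
    # binary loadings live in Lambda rows br, column kF
    LamBar_bin = np.zeros((model.p, model.m))
    LamBar_bin[model.bin_rows, kF] = lbBar
    tauBar = np.zeros((model.p, 1))
    tauBar[model.bin_rows, 0] = tauBarv

    grad = _finish_gradient(model, fw, SigBar, nuBarC,
                            LamBarC_extra=LamBarC_extra, GamBarC=GamBarC,
                            alphaBar_extra=None, LamBar_bin=LamBar_bin,
                            tauBar=tauBar, SigLBar_extra=SigLBar_extra,
                            theta_t=theta_t)
    # the avec-extra (mF) term was not passed through _finish_gradient; add it here
    M = fw["M"]
    alphaBar2 = M.T @ avec_extra
    MBar2 = np.outer(avec_extra, fw["alpha"])
    BBar2 = M.T @ MBar2 @ M.T
    grad += model.gather_grad(theta_t, {_ALPHA: alphaBar2.reshape(-1, 1), _BETA: BBar2})
    return ll, grad


def _unit(n, k):
    e = np.zeros(n)
    e[k] = 1.0
    return e


# ---------------------------------------------------------------------------
# public operation wrappers

def _theta_from(model: CompiledModel, params) -> np.ndarray:
    if params is None:
        return model.start_vector()
    if isinstance(params, dict):
        missing = [l for l in model.labels if l not in params]
        if missing:
            raise KeyError(f"missing parameter values for {missing[:5]}")
        return model.transform(np.array([params[l] for l in model.labels]))
    return np.asarray(params, dtype=float)


def fiml_loglik(cohort: pd.DataFrame, spec, params=None) -> float:
    """Casewise multivariate-normal FIML log-likelihood of an all-continuous model.

    ``params`` may be a dict of natural-scale values by label, a transformed
    parameter vector, or None for the spec's start values.
    """
    model = spec.compile() if not isinstance(spec, CompiledModel) else spec
    if model.bin_vars:
        raise ValueError("model contains binary indicators; use loglik_with_binary")
    data = ModelData(model, cohort)
    ll, _ = _loglik_continuous(model, data, _theta_from(model, params), want_grad=False)
    return ll


def loglik_with_binary(cohort: pd.DataFrame, spec, params=None, n_nodes: int = 21) -> float:
    """Marginal log-likelihood with probit indicators integrated out by
    adaptive Gauss-Hermite quadrature; equals :func:`fiml_loglik` when the
    model has no binary variables."""
    if n_nodes < 7:
        raise ValueError("use at least 7 quadrature nodes")
    model = spec.compile() if not isinstance(spec, CompiledModel) else spec
    data = ModelData(model, cohort)
    theta = _theta_from(model, params)
    if not model.bin_vars:
        ll, _ = _loglik_continuous(model, data, theta, want_grad=False)
        return ll
    ll, _ = _loglik_binary(model, data, theta, n_nodes, want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# public moment interface

def implied_moments(model: CompiledModel, theta_t: np.ndarray):
    """Model-implied covariance and mean of the continuous observed block.

    Returns ``(Sigma, mu)`` over the continuous observed variables in spec
    order (exogenous direct effects contribute per subject and are excluded).
    """
    fw = _common_forward(model, theta_t)
    Sig = fw["SigF"]
    Sig = 0.5 * (Sig + Sig.T)
    eig = np.linalg.eigvalsh(Sig)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise InadmissibleParameters("implied covariance is not PSD")
    return Sig, fw["muC"].copy()


def factor_scores(model: CompiledModel, data: ModelData, theta_t: np.ndarray,
                  latent: str, n_nodes: int = 21) -> np.ndarray:
    """Posterior mean E[eta | observed data] of one latent, per subject.

    For models with binary indicators the latent must be the integration
    latent; the posterior mean is computed from the quadrature weights.  For
    all-continuous models this is the regression-method factor score.
    Returns an array aligned with the rows passed to :class:`ModelData`
    (NaN for subjects with no observed data).
    """
    k = model.lat_index[latent]
    fw = _common_forward(model, theta_t)
    SigL, LamC, SigF, muC, GamC, avec = (fw["SigL"], fw["LamC"], fw["SigF"],
                                         fw["muC"], fw["GamC"], fw["avec"])
    out = np.full(data.n_total, np.nan)
    if model.bin_vars:
        if k != model.int_latent_idx:
            raise ValueError("with binary indicators, scores are available only "
                             "for the latent they load on")
        kF = k
        psiF = SigL[kF, kF]
        sqp = np.sqrt(psiF)
        a_full = LamC @ SigL[:, kF] / sqp
        mF = avec[kF]
        lb = fw["Lam"][model.bin_rows, kF]
        beta_b = lb * sqp
        kappa_b = lb * mF - fw["tau"][model.bin_rows]
        tk, wk, log_wk = _hermgauss(n_nodes)
        for pat in data.patterns:
            cols = pat["cols"]
            Y, X, D = pat["Y"], pat["X"], pat["D"]
            n_g, p_o = Y.shape
            sgn = 2.0 * D - 1.0
            if p_o:
                So = SigF[np.ix_(cols, cols)]
                a = a_full[cols]
                Sc = So - np.outer(a, a)
                L, _ = _chol_logdet(Sc)
                Mu = muC[cols] + (X @ GamC[cols].T if model.q else 0.0)
                R = Y - Mu
                h = linalg.cho_solve((L, True), a, check_finite=False)
                q = R @ h
                c0 = float(a @ h)
            else:
                q, c0 = np.zeros(n_g), 0.0
            s_star = 1.0 / np.sqrt(1.0 + c0)
            m_i = q * s_star**2
            Z = m_i[:, None] + np.sqrt(2.0) * s_star * tk[None, :]
            logint = q[:, None] * Z - 0.5 * (c0 + 1.0) * Z**2
            if len(model.bin_vars):
                U = sgn[:, :, None] * (beta_b[None, :, None] * Z[:, None, :]
                                       + kappa_b[None, :, None])
                logint = logint + special.log_ndtr(U).sum(axis=1)
            logw = logint + (log_wk + tk**2)[None, :]
            P = np.exp(logw - special.logsumexp(logw, axis=1)[:, None])
            m1 = (P * Z).sum(axis=1)
            out[data.kept[pat["rows"]]] = mF + sqp * m1
        return out
    # continuous: regression scores from the joint normal
    cov_k = LamC @ SigL[:, k]
    for pat in data.patterns:
        cols = pat["cols"]
        Y, X = pat["Y"], pat["X"]
        if Y.shape[1] == 0:
            continue
        So = SigF[np.ix_(cols, cols)]
        L, _ = _chol_logdet(So)
        Mu = muC[cols] + (X @ GamC[cols].T if model.q else 0.0)
        R = Y - Mu
        w = linalg.cho_solve((L, True), cov_k[cols], check_finite=False)
        out[data.kept[pat["rows"]]] = avec[k] + R @ w
    return out


def binary_marginal_prevalence(model: CompiledModel, theta_t: np.ndarray) -> dict[str, float]:
    """Marginal P(y=1) for each binary indicator: Phi((l*mF - tau)/sqrt(l^2 psi + 1))."""
    fw = _common_forward(model, theta_t)
    kF = model.int_latent_idx
    psiF = fw["SigL"][kF, kF]
    mF = fw["avec"][kF]
    out = {}
    for v, row in zip(model.bin_vars, model.bin_rows):
        l = fw["Lam"][row, kF]
        t = fw["tau"][row]
        out[v] = float(norm.cdf((l * mF - t) / np.sqrt(l * l * psiF + 1.0)))
    return out
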