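"""Model comparison, fit assessment, multiplicity control and effect summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .fitting import FitResult, MomentsResult
from .likelihood import implied_moments


@dataclass
class LRTestResult:
    """Likelihood-ratio comparison of a restricted model against a
    less-restrictive neighbour that nests it."""

    lr_stat: float
    df: int
    p: float


def lr_test(full: FitResult, neighbour: FitResult) -> LRTestResult:
    """LR = 2 * (loglik(neighbour) - loglik(full restricted model)).

    ``full`` is the hypothesized (more constrained) model; ``neighbour`` the
    less-restrictive model whose free parameters must be a superset of the
    full model's.  The statistic is referred to chi-square with df equal to
    the difference in free-parameter counts.
    """
    if not (full.converged and neighbour.converged):
        raise ValueError("both fits must have converged")
    full_labels = set(full.model.labels)
    nb_labels = set(neighbour.model.labels)
    if not full_labels <= nb_labels:
        raise ValueError("models are not nested: full model has parameters "
                         f"absent from the neighbour: {sorted(full_labels - nb_labels)[:5]}")
    df = neighbour.n_params - full.n_params
    lr = 2.0 * (neighbour.loglik - full.loglik)
    if lr < -1e-6 * max(1.0, abs(full.loglik)):
        raise ValueError(f"negative LR statistic ({lr:.3g}): optimizer failure")
    lr = max(lr, 0.0)
    p = 1.0 if df == 0 else float(chi2.sf(lr, df))
    return LRTestResult(float(lr), int(df), p)


@dataclass
class FitIndices:
    rmsea: float
    cfi: float
    tli: float
    srmr: float


def fit_indices(fit: FitResult, saturated: MomentsResult, baseline: MomentsResult,
                n: int) -> FitIndices:
    """RMSEA, CFI, TLI and SRMR for an all-continuous model.

    chi-square = 2*(loglik_saturated - loglik_model); the baseline is the
    free-means diagonal-covariance model.  Unavailable for models with binary
    indicators (no saturated likelihood under the probit formulation).
    """
    if fit.model.bin_vars:
        raise ValueError("absolute fit indices are unavailable for models with "
                         "binary indicators; use lr_test against a neighbour")
    if fit.model.q:
        raise ValueError("fit indices are implemented for models without "
                         "exogenous direct regressors")
    chi2_m = max(2.0 * (saturated.loglik - fit.loglik), 0.0)
    df_m = saturated.n_params - fit.n_params
    chi2_b = max(2.0 * (saturated.loglik - baseline.loglik), 0.0)
    df_b = saturated.n_params - baseline.n_params
    if df_m <= 0 or df_b <= 0:
        rmsea = 0.0
        cfi, tli = 1.0, 1.0
    else:
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
        num = max(chi2_m - df_m, 0.0)
        den = max(chi2_b - df_b, num)
        cfi = 1.0 - (num / den if den > 0 else 0.0)
        rb = chi2_b / df_b
        rm = chi2_m / df_m
        tli = (rb - rm) / (rb - 1.0) if rb > 1.0 else 1.0
    # SRMR over the model's observed block, standardized by saturated SDs
    sigma, _ = implied_moments(fit.model, fit.theta_t)
    cols = fit.model.cont_vars
    idx = [saturated.columns.index(c) for c in cols]
    S = saturated.sigma[np.ix_(idx, idx)]
    d = np.sqrt(np.diag(S))
    res = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices_from(res)
    srmr = float(np.sqrt(np.mean(res[iu] ** 2)))
    return FitIndices(rmsea=rmsea, cfi=float(min(cfi, 1.0)), tli=float(tli), srmr=srmr)


FDR_FAMILIES = ("foc_svd", "foc_wmh", "bifactor")


def fdr_adjust(pvals: pd.Series, families: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment within model families.

    ``families`` labels each p-value with its correction group (the three
    groups: SVD-predictor FoC models, WMH-predictor FoC models, bifactor
    models); adjustment is carried out separately per group.
    """
    pvals = pd.Series(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any() or pvals.isna().any():
        raise ValueError("p-values must be in [0, 1] and non-missing")
    families = pd.Series(families)
    if len(families) != len(pvals):
        raise ValueError("families must align with pvals")
    out = pd.Series(np.nan, index=pvals.index)
    for fam, idx in families.groupby(families).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty FDR family {fam!r}")
        out.loc[idx] = multipletests(pvals.loc[idx].to_numpy(), method="fdr_bh")[1]
    return out


def slope_r2(fit: FitResult, outcome: str = "G_s", predictor: str | None = None) -> float:
    """Share of the latent slope's variance attributable to the SVD/WMH path:
    the squared standardized path coefficient."""
    from .fitting import standardized_solution

    ss = standardized_solution(fit.model, fit.theta_t)
    if predictor is None:
        for cand in ("svd", "wmhp"):
            if f"{outcome}~{cand}" in ss:
                predictor = cand
                break
    key = f"{outcome}~{predictor}"
    if key not in ss:
        raise KeyError(f"no structural path {key} in the model")
    if ss.get(f"var({outcome})", 0.0) <= 0:
        raise ValueError(f"zero implied variance for {outcome}")
    return float(ss[key] ** 2)


@dataclass
class ResultRow:
    """One outcome-by-predictor association, one row of the results tables."""

    family: str            # foc_svd | foc_wmh | bifactor
    model: str             # e.g. 'general', 'speed', or 'bifactor'
    step: str              # covariate step name
    outcome: str           # e.g. 'slope(general)' or 'intercept(speed)'
    predictor: str         # 'svd' or 'wmh'
    beta_std: float
    se: float | None
    ci_lo: float
    ci_hi: float
    p: float
    p_fdr: float | None = None
    r2_slope: float | None = None
    converged: bool = True
    loglik: float = np.nan
    extra: dict = field(default_factory=dict)


def result_table(rows: list[ResultRow]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "family": r.family, "model": r.model, "step": r.step, "outcome": r.outcome,
        "predictor": r.predictor, "beta_std": r.beta_std, "se": r.se,
        "ci_lo": r.ci_lo, "ci_hi": r.ci_hi, "p": r.p, "p_fdr": r.p_fdr,
        "r2_slope": r.r2_slope, "converged": r.converged, "loglik": r.loglik,
    } for r in rows])
    return df


def attach_fdr(rows: list[ResultRow]) -> list[ResultRow]:
    """Grouped BH adjustment over converged rows, in place."""
    ok = [r for r in rows if r.converged and np.isfinite(r.p)]
    if not ok:
        return rows
    p = pd.Series([r.p for r in ok])
    fam = pd.Series([r.family for r in ok])
    adj = fdr_adjust(p, fam)
    for r, a in zip(ok, adj):
        r.p_fdr = float(a)
    return rows
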