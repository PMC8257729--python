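import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from svdgrowth.fitting import fit, fit_baseline, fit_saturated
from svdgrowth.model import CONTINUOUS, ModelSpec, fixed, free
from svdgrowth.stats import (FDR_FAMILIES, FitIndices, fdr_adjust, fit_indices,
                             lr_test, slope_r2)

from conftest import one_factor_spec, simulate_one_factor


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_stepup_bruteforce(p):
    """Literal step-up definition: p_(k) * m / k, monotonised from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_hand_case():
    p = pd.Series([0.01, 0.02, 0.03, 0.04])
    fam = pd.Series(["a"] * 4)
    np.testing.assert_allclose(fdr_adjust(p, fam), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged_and_all_ones():
    assert fdr_adjust(pd.Series([0.37]), pd.Series(["a"]))[0] == pytest.approx(0.37)
    np.testing.assert_allclose(
        fdr_adjust(pd.Series([1.0, 1.0, 1.0]), pd.Series(["a"] * 3)), 1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
       st.integers(min_value=1, max_value=3))
def test_bh_matches_stepup_definition(pvals, n_fam):
    fams = [FDR_FAMILIES[i % n_fam] for i in range(len(pvals))]
    out = fdr_adjust(pd.Series(pvals), pd.Series(fams))
    for fam in set(fams):
        idx = [i for i, f in enumerate(fams) if f == fam]
        expect = bh_stepup_bruteforce([pvals[i] for i in idx])
        np.testing.assert_allclose(out.iloc[idx], expect, atol=1e-12)
    # monotone in p within a family, never below raw p, never above 1
    assert (out.to_numpy() >= np.asarray(pvals) - 1e-12).all()
    assert (out.to_numpy() <= 1.0 + 1e-12).all()


def test_bh_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        fdr_adjust(pd.Series([0.5, 1.5]), pd.Series(["a", "a"]))
    with pytest.raises(ValueError):
        fdr_adjust(pd.Series([0.5, np.nan]), pd.Series(["a", "a"]))


# ---------------------------------------------------------------------------
# likelihood-ratio test

def test_lr_identical_models_zero_stat():
    df = simulate_one_factor(n=200, seed=31)
    res = fit(one_factor_spec(), df, n_starts=1, compute_se=False)
    out = lr_test(res, res)
    assert out.lr_stat == pytest.approx(0.0, abs=1e-9)
    assert out.df == 0
    assert out.p == 1.0


def test_lr_restricted_vs_free_loading():
    df = simulate_one_factor(n=300, seed=32)
    restricted = one_factor_spec()
    restricted.lambda_[("y2", "f")] = fixed(0.8)  # fix at truth
    r_fit = fit(restricted, df, n_starts=1, compute_se=False)
    f_fit = fit(one_factor_spec(), df, n_starts=1, compute_se=False)
    out = lr_test(r_fit, f_fit)
    assert out.df == 1
    assert out.lr_stat >= 0.0
    assert 0.0 <= out.p <= 1.0


def test_lr_non_nested_models_rejected():
    df = simulate_one_factor(n=200, seed=33)
    a = fit(one_factor_spec(), df, n_starts=1, compute_se=False)
    other = one_factor_spec()
    other.lambda_[("y2", "f")] = free("different_label", 0.8)
    b = fit(other, df, n_starts=1, compute_se=False)
    with pytest.raises(ValueError, match="not nested"):
        lr_test(b, a)


def test_lr_negative_stat_signals_failure():
    df = simulate_one_factor(n=200, seed=34)
    res = fit(one_factor_spec(), df, n_starts=1, compute_se=False)
    import dataclasses
    worse = dataclasses.replace(res, loglik=res.loglik - 5.0)
    better = dataclasses.replace(res, loglik=res.loglik)
    with pytest.raises(ValueError, match="negative LR"):
        lr_test(better, worse)


# ---------------------------------------------------------------------------
# fit indices

def test_fit_indices_saturated_target_is_perfect():
    from test_fitting import saturated_spec

    df = simulate_one_factor(n=300, seed=38)
    res = fit(saturated_spec(list(df.columns)), df, n_starts=1, compute_se=False)
    fi = fit_indices(res, fit_saturated(df), fit_baseline(df), n=len(df))
    assert fi.rmsea == pytest.approx(0.0, abs=1e-4)
    assert fi.cfi == pytest.approx(1.0, abs=1e-6)
    assert fi.srmr == pytest.approx(0.0, abs=1e-3)


def test_fit_indices_independence_target_gives_cfi_zero():
    df = simulate_one_factor(n=300, seed=39)
    indep = ModelSpec([(c, CONTINUOUS) for c in df.columns], ["dummy"])
    for c in df.columns:
        indep.set_loading(c, "dummy", fixed(0.0))
        indep.set_theta(c, c, free(f"v_{c}", 1.0))
        indep.set_intercept(c, free(f"m_{c}", 0.0))
    indep.set_psi("dummy", "dummy", fixed(1.0))
    res = fit(indep, df, n_starts=1, compute_se=False)
    fi = fit_indices(res, fit_saturated(df), fit_baseline(df), n=len(df))
    assert fi.cfi == pytest.approx(0.0, abs=1e-6)
    assert fi.tli == pytest.approx(0.0, abs=1e-6)


def test_fit_indices_on_correct_one_factor_model():
    df = simulate_one_factor(n=800, seed=35)
    res = fit(one_factor_spec(), df, n_starts=1, compute_se=False)
    sat = fit_saturated(df)
    base = fit_baseline(df)
    fi = fit_indices(res, sat, base, n=len(df))
    assert fi.rmsea < 0.06
    assert fi.cfi > 0.95
    assert fi.srmr < 0.08
    assert fi.tli <= 1.5


def test_fit_indices_hand_computed_three_variable_fixture():
    """Hand oracle: compute chi-square/df and the index formulas directly from
    the saturated and model logliks of a deliberately misspecified model."""
    rng = np.random.default_rng(36)
    n = 400
    f = rng.normal(0, 1, n)
    u = rng.normal(0, 1, n)
    df = pd.DataFrame({
        "y1": f + rng.normal(0, 0.6, n),
        "y2": 0.8 * f + rng.normal(0, 0.6, n),
        # correlated pair the single factor cannot absorb: overidentified misfit
        "y3": 0.5 * f + 0.7 * u + rng.normal(0, 0.5, n),
        "y4": 0.5 * f + 0.7 * u + rng.normal(0, 0.5, n),
    })
    spec = one_factor_spec(n_ind=4)
    res = fit(spec, df, n_starts=1, compute_se=False)
    sat = fit_saturated(df)
    base = fit_baseline(df)
    fi = fit_indices(res, sat, base, n=n)
    chi2_m = 2 * (sat.loglik - res.loglik)
    df_m = sat.n_params - res.n_params
    chi2_b = 2 * (sat.loglik - base.loglik)
    df_b = sat.n_params - base.n_params
    assert fi.rmsea == pytest.approx(
        np.sqrt(max(chi2_m - df_m, 0) / (df_m * (n - 1))), abs=1e-10)
    assert fi.cfi == pytest.approx(
        1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m), abs=1e-10)
    assert fi.tli == pytest.approx(
        ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1), abs=1e-10)


def test_fit_indices_refuse_binary_models():
    from conftest import mixed_factor_spec, simulate_mixed

    spec = mixed_factor_spec(with_exog=False)
    df = simulate_mixed(n=150, seed=37, missing=False, with_exog=False)
    res = fit(spec, df, n_starts=1, compute_se=False)
    sat = fit_saturated(df[["y1", "y2", "y3"]])
    base = fit_baseline(df[["y1", "y2", "y3"]])
    with pytest.raises(ValueError, match="binary"):
        fit_indices(res, sat, base, n=len(df))


# ---------------------------------------------------------------------------
# slope R^2

def test_slope_r2_is_squared_standardized_path(prepared_cohort):
    from svdgrowth.builders import foc_spec
    from svdgrowth.fitting import standardized_solution

    spec = foc_spec("speed", step="none", predictor="svd_latent", data=prepared_cohort)
    res = fit(spec, prepared_cohort, n_starts=1, compute_se=False)
    assert res.converged
    beta = standardized_solution(res.model, res.theta_t)["G_s~svd"]
    assert slope_r2(res) == pytest.approx(beta**2, abs=1e-12)
    assert 0.0 <= slope_r2(res) <= 1.0
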