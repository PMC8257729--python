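"""Oracle and property tests for the FIML engine.

The brute-force oracles here are deliberately independent of the engine:
per-subject multivariate-normal densities via scipy, hand matrix algebra for
implied moments, and closed-form probit marginalisation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svdgrowth.likelihood import (ModelData, fiml_loglik, implied_moments,
                                  binary_marginal_prevalence, factor_scores,
                                  loglik_and_grad, loglik_with_binary)
from svdgrowth.model import CONTINUOUS, BINARY, ModelSpec, fixed, free

from conftest import (mixed_factor_spec, one_factor_spec, simulate_mixed,
                      simulate_one_factor)


# ---------------------------------------------------------------------------
# implied moments

def test_implied_moments_zero_loadings_gives_theta():
    spec = ModelSpec([("y1", CONTINUOUS), ("y2", CONTINUOUS)], ["f"])
    spec.set_loading("y1", "f", fixed(0.0))
    spec.set_loading("y2", "f", fixed(0.0))
    spec.set_theta("y1", "y1", fixed(0.7))
    spec.set_theta("y2", "y2", fixed(0.3))
    spec.set_psi("f", "f", fixed(1.0))
    model = spec.compile()
    sigma, mu = implied_moments(model, model.start_vector())
    np.testing.assert_allclose(sigma, np.diag([0.7, 0.3]))
    np.testing.assert_allclose(mu, 0.0)


def test_implied_moments_one_factor_hand_algebra():
    # lambda = (1, .8, .6), psi = 1, theta = .5 I  =>  Sigma_12 = 0.8 etc.
    spec = one_factor_spec(n_ind=3)
    model = spec.compile()
    sigma, _ = implied_moments(model, model.start_vector())
    lam = np.array([1.0, 0.8, 0.6])
    expect = np.outer(lam, lam) + 0.5 * np.eye(3)
    np.testing.assert_allclose(sigma, expect, atol=1e-12)


def test_implied_moments_match_structural_simulation():
    """Monte-Carlo oracle: simulate the structural equations by hand at the
    spec's parameter values and compare empirical with implied moments."""
    spec = mixed_factor_spec(with_exog=False)
    model = spec.compile()
    sigma, mu = implied_moments(model, model.start_vector())
    df = simulate_mixed(n=200_000, seed=5, missing=False, with_exog=False)
    emp = df[["y1", "y2", "y3"]].cov().to_numpy()
    np.testing.assert_allclose(sigma, emp, atol=0.02)
    np.testing.assert_allclose(mu, df[["y1", "y2", "y3"]].mean(), atol=0.02)


def continuous_subspec(spec: ModelSpec) -> ModelSpec:
    """The same model restricted to its continuous observed block."""
    cont = ModelSpec.from_json(spec.to_json())
    cont.observed = cont.continuous_vars
    cont.kinds = {v: CONTINUOUS for v in cont.observed}
    cont.lambda_ = {k: v for k, v in cont.lambda_.items() if k[0] in cont.observed}
    cont.theta = {k: v for k, v in cont.theta.items() if k[0] in cont.observed}
    cont.tau = {}
    return cont


# ---------------------------------------------------------------------------
# continuous FIML

def test_complete_data_equals_full_mvn_loglik():
    spec = mixed_factor_spec(with_exog=False)
    df = simulate_mixed(n=150, seed=2, missing=False, with_exog=False)
    model = spec.compile()
    th = model.start_vector()
    sigma, mu = implied_moments(model, th)
    ours = fiml_loglik(df[["y1", "y2", "y3"]], continuous_subspec(spec))
    oracle = stats.multivariate_normal(mean=mu, cov=sigma).logpdf(
        df[["y1", "y2", "y3"]].to_numpy()).sum()
    assert ours == pytest.approx(oracle, rel=1e-10)


def test_single_standard_normal_observation_closed_form():
    spec = ModelSpec([("x", CONTINUOUS)], ["f"])
    spec.set_loading("x", "f", fixed(0.0))
    spec.set_theta("x", "x", fixed(1.0))
    spec.set_psi("f", "f", fixed(1.0))
    spec.set_intercept("x", fixed(0.0))
    df = pd.DataFrame({"x": [0.0]})
    assert fiml_loglik(df, spec) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_pattern_grouping_matches_per_subject_bruteforce():
    """30% MCAR mask: grouped FIML equals an ungrouped per-subject oracle."""
    spec = one_factor_spec(n_ind=4)
    rng = np.random.default_rng(3)
    df = simulate_one_factor(n=200, seed=3)
    mask = rng.random(df.shape) < 0.3
    df = df.mask(mask)
    df = df[df.notna().any(axis=1)]
    model = spec.compile()
    th = model.start_vector()
    sigma, mu = implied_moments(model, th)
    oracle = 0.0
    for _, row in df.iterrows():
        o = row.notna().to_numpy()
        oracle += stats.multivariate_normal(
            mean=mu[o], cov=sigma[np.ix_(o, o)]).logpdf(row.dropna().to_numpy())
    ours = fiml_loglik(df, spec)
    assert ours == pytest.approx(oracle, abs=1e-10 * abs(oracle))


# ---------------------------------------------------------------------------
# binary indicators and quadrature

def test_zero_binary_loadings_separate_into_bernoulli_terms():
    """With (numerically) zero loadings the joint likelihood factorises into
    the continuous FIML part plus independent Bernoulli probit terms."""
    spec = mixed_factor_spec(with_exog=False)
    spec.lambda_[("b1", "f")] = fixed(1e-12)
    spec.lambda_[("b2", "f")] = fixed(1e-12)
    df = simulate_mixed(n=120, seed=4, missing=True, with_exog=False)
    tau1, tau2 = 1.0, 0.5
    p1, p2 = stats.norm.cdf(-tau1), stats.norm.cdf(-tau2)
    bern = (df.b1 * np.log(p1) + (1 - df.b1) * np.log(1 - p1)
            + df.b2 * np.log(p2) + (1 - df.b2) * np.log(1 - p2)).sum()
    cont_ll = fiml_loglik(df[["y1", "y2", "y3"]], continuous_subspec(spec))
    full = loglik_with_binary(df, spec)
    assert full == pytest.approx(cont_ll + bern, rel=1e-9)


def test_binary_marginal_prevalence_formula_vs_simulation():
    """P(y=1) = Phi((l*mF - tau)/sqrt(l^2 psi + 1)), checked by Monte Carlo."""
    spec = mixed_factor_spec(with_exog=False)
    model = spec.compile()
    prev = binary_marginal_prevalence(model, model.start_vector())
    rng = np.random.default_rng(9)
    n = 400_000
    f = rng.normal(0, np.sqrt(0.9), n)
    emp1 = np.mean(0.7 * f + rng.normal(0, 1, n) > 1.0)
    emp2 = np.mean(0.5 * f + rng.normal(0, 1, n) > 0.5)
    assert prev["b1"] == pytest.approx(emp1, abs=0.003)
    assert prev["b2"] == pytest.approx(emp2, abs=0.003)


def test_quadrature_node_count_converged():
    """SVD-burden CFA: 15 vs 41 adaptive GH nodes agree to < 1e-6."""
    from svdgrowth.builders import svd_cfa_spec
    from svdgrowth.simulate import default_truth, simulate_cohort
    from svdgrowth.builders import prepare_analysis_frame

    truth = default_truth("paper_foC", seed=5)
    prep = prepare_analysis_frame(simulate_cohort(truth))
    spec = svd_cfa_spec()
    ll15 = loglik_with_binary(prep, spec, n_nodes=15)
    ll41 = loglik_with_binary(prep, spec, n_nodes=41)
    assert abs(ll15 - ll41) < 1e-6


def test_too_few_quadrature_nodes_rejected():
    spec = mixed_factor_spec(with_exog=False)
    df = simulate_mixed(n=50, seed=6, missing=False, with_exog=False)
    with pytest.raises(ValueError, match="at least 7"):
        loglik_with_binary(df, spec, n_nodes=5)


# ---------------------------------------------------------------------------
# analytic gradients

@pytest.mark.parametrize("with_binary", [True, False])
def test_analytic_gradient_matches_finite_differences(with_binary):
    spec = mixed_factor_spec(with_exog=True)
    df = simulate_mixed(n=120, seed=7, missing=True, with_exog=True)
    if not with_binary:
        spec = one_factor_spec(n_ind=4)
        df = simulate_one_factor(n=120, seed=7)
        df = df.mask(np.random.default_rng(0).random(df.shape) < 0.25)
        df = df[df.notna().any(axis=1)]
    model = spec.compile()
    data = ModelData(model, df)
    rng = np.random.default_rng(11)
    th = model.start_vector() + rng.normal(0, 0.05, model.n_free)
    ll, grad = loglik_and_grad(model, data, th)
    eps = 1e-6
    for j in range(model.n_free):
        tp, tm = th.copy(), th.copy()
        tp[j] += eps
        tm[j] -= eps
        lp, _ = loglik_and_grad(model, data, tp, want_grad=False)
        lm, _ = loglik_and_grad(model, data, tm, want_grad=False)
        num = (lp - lm) / (2 * eps)
        assert grad[j] == pytest.approx(num, rel=5e-5, abs=1e-7), model.labels[j]


# ---------------------------------------------------------------------------
# factor scores

def test_factor_scores_deterministic_and_aligned():
    spec = mixed_factor_spec(with_exog=False)
    df = simulate_mixed(n=200, seed=8, missing=True, with_exog=False)
    # duplicate a subject: identical rows must get identical scores
    df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    model = spec.compile()
    data = ModelData(model, df)
    s1 = factor_scores(model, data, model.start_vector(), "f")
    s2 = factor_scores(model, data, model.start_vector(), "f")
    np.testing.assert_array_equal(s1, s2)
    assert s1[0] == pytest.approx(s1[-1], abs=1e-12)
    assert len(s1) == len(df)


def test_factor_scores_track_generating_latent():
    rng = np.random.default_rng(12)
    n = 2000
    f = rng.normal(0, 1, n)
    loadings = (1.0, 0.8, 0.6, 0.9)
    df = pd.DataFrame({f"y{i}": lam * f + rng.normal(0, np.sqrt(0.5), n)
                       for i, lam in enumerate(loadings, 1)})
    spec = one_factor_spec(n_ind=4)
    model = spec.compile()
    data = ModelData(model, df)
    scores = factor_scores(model, data, model.start_vector(), "f")
    assert np.corrcoef(scores, f)[0, 1] > 0.85
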