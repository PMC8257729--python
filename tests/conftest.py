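import numpy as np
import pandas as pd
import pytest

from svdgrowth.model import BINARY, CONTINUOUS, ModelSpec, fixed, free


def mixed_factor_spec(with_exog: bool = True) -> ModelSpec:
    """Two-latent model: SVD-like factor with two binary indicators plus an
    endogenous outcome latent; optionally one exogenous direct regressor."""
    spec = ModelSpec(
        [("y1", CONTINUOUS), ("y2", CONTINUOUS), ("y3", CONTINUOUS),
         ("b1", BINARY), ("b2", BINARY)],
        ["f", "g"],
        exog=["x1"] if with_exog else (),
    )
    spec.set_loading("y1", "f", fixed(1.0))
    spec.set_loading("y2", "f", free("l2", 0.8))
    spec.set_loading("y3", "g", fixed(1.0))
    spec.set_loading("b1", "f", free("lb1", 0.7))
    spec.set_loading("b2", "f", free("lb2", 0.5))
    spec.set_path("g", "f", free("b_gf", 0.3))
    spec.set_psi("f", "f", free("psi_f", 0.9))
    spec.set_psi("g", "g", free("psi_g", 0.6))
    for v, s in [("y1", 0.5), ("y2", 0.4)]:
        spec.set_theta(v, v, free(f"th_{v}", s))
    # y3 is g's only indicator: fix its residual variance and intercept so
    # psi_g and alpha_g are identified
    spec.set_theta("y3", "y3", fixed(0.5))
    for v in ("y1", "y2"):
        spec.set_intercept(v, free(f"nu_{v}", 0.0))
    spec.set_intercept("y3", fixed(0.0))
    spec.set_theta("b1", "b1", fixed(1.0))
    spec.set_theta("b2", "b2", fixed(1.0))
    spec.set_mean("f", fixed(0.0))
    spec.set_mean("g", free("al_g", 0.2))
    spec.set_threshold("b1", free("tau1", 1.0))
    spec.set_threshold("b2", free("tau2", 0.5))
    if with_exog:
        spec.set_exog_path("y3", "x1", free("g31", 0.2))
        spec.set_exog_path("y1", "x1", free("g11", -0.1))
    return spec


def simulate_mixed(n=300, seed=0, missing=True, with_exog=True) -> pd.DataFrame:
    """Forward simulation matching ``mixed_factor_spec`` at its start values."""
    rng = np.random.default_rng(seed)
    f = rng.normal(0, np.sqrt(0.9), n)
    g = 0.2 + 0.3 * f + rng.normal(0, np.sqrt(0.6), n)
    x1 = rng.normal(0, 1, n) if with_exog else np.zeros(n)
    df = pd.DataFrame({
        "y1": f + rng.normal(0, np.sqrt(0.5), n) - 0.1 * x1,
        "y2": 0.8 * f + rng.normal(0, np.sqrt(0.4), n),
        "y3": g + 0.2 * x1 + rng.normal(0, np.sqrt(0.5), n),
        "b1": (0.7 * f + rng.normal(0, 1, n) > 1.0).astype(float),
        "b2": (0.5 * f + rng.normal(0, 1, n) > 0.5).astype(float),
    })
    if with_exog:
        df["x1"] = x1
    if missing:
        df.loc[rng.random(n) < 0.3, "y2"] = np.nan
        df.loc[rng.random(n) < 0.2, "y3"] = np.nan
    return df


def one_factor_spec(n_ind=4, psi=1.0, free_first=False) -> ModelSpec:
    """Plain one-factor CFA with continuous indicators."""
    obs = [(f"y{i}", CONTINUOUS) for i in range(1, n_ind + 1)]
    spec = ModelSpec(obs, ["f"])
    loadings = [1.0, 0.8, 0.6, 0.9, 0.7][:n_ind]
    for i, lam in enumerate(loadings, start=1):
        if i == 1 and not free_first:
            spec.set_loading(f"y{i}", "f", fixed(1.0))
        else:
            spec.set_loading(f"y{i}", "f", free(f"l{i}", lam))
        spec.set_theta(f"y{i}", f"y{i}", free(f"th{i}", 0.5))
        spec.set_intercept(f"y{i}", free(f"nu{i}", 0.0))
    spec.set_psi("f", "f", free("psi", psi) if not free_first else fixed(1.0))
    spec.set_mean("f", fixed(0.0))
    return spec


def simulate_one_factor(n=500, seed=0, loadings=(1.0, 0.8, 0.6, 0.9), psi=1.0,
                        theta=0.5) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    f = rng.normal(0, np.sqrt(psi), n)
    return pd.DataFrame({
        f"y{i}": lam * f + rng.normal(0, np.sqrt(theta), n)
        for i, lam in enumerate(loadings, start=1)
    })


@pytest.fixture(scope="session")
def mixed_spec():
    return mixed_factor_spec()


@pytest.fixture(scope="session")
def mixed_data():
    return simulate_mixed(n=300, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """One attrition-thinned synthetic cohort shared across tests."""
    from svdgrowth.simulate import apply_attrition, default_truth, simulate_cohort

    truth = default_truth("paper_foC", seed=7)
    return apply_attrition(simulate_cohort(truth), truth)


@pytest.fixture(scope="session")
def prepared_cohort(small_cohort):
    from svdgrowth.builders import prepare_analysis_frame

    return prepare_analysis_frame(small_cohort)
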