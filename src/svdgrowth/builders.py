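"""Builders translating the study's model structures into :class:`ModelSpec` objects.

Covers the SVD-burden measurement model (two continuous and two probit
indicators), the vascular-risk CFA with extracted factor scores, hierarchical
factor-of-curves (FoC) growth models per cognitive domain, and the
longitudinal bifactor growth model separating general from domain-specific
trajectories.

Conventions (applied by :func:`prepare_analysis_frame`): all cognitive tests
are oriented so higher = better (four-choice reaction time negated) and
z-scored against the baseline-wave observed mean/SD, so latent means and
slopes are in baseline-SD units; the WMH/intracranial-volume ratio is
log-transformed by default before standardization (it is strongly
right-skewed, and a linear factor loading is only plausible on the log
scale); per-wave age enters mean-centred as a direct exogenous predictor of
that wave's observed scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitResult, fit
from .likelihood import ModelData, factor_scores
from .model import BINARY, CONTINUOUS, ModelSpec, fixed, free
from .simulate import ALL_TESTS, DOMAINS, NEGATED_TESTS, TIME_LOADINGS, WAVES


@dataclass(frozen=True)
class GrowthStructure:
    """Fixed slope loadings (years since baseline) of the four waves."""

    wave_times: tuple[float, ...] = TIME_LOADINGS

    def __post_init__(self):
        wt = self.wave_times
        if len(wt) != len(WAVES) or wt[0] != 0.0 or any(b <= a for a, b in zip(wt, wt[1:])):
            raise ValueError("wave_times must start at 0 and strictly increase, one per wave")


#: nested covariate adjustment steps, in the order they are added
COVARIATE_STEPS = ("none", "age_sex", "vascular", "childhood")
STEP_LABELS = {
    "none": "unadjusted",
    "age_sex": "+ age + sex",
    "vascular": "+ age + sex + vascular risk",
    "childhood": "+ age + sex + vascular risk + childhood cognitive ability",
}

PREDICTORS = ("svd_latent", "wmh_ratio")

#: default domain membership (general = union of all tests)
DOMAIN_MAP = {k: list(v) for k, v in DOMAINS.items()}


def _step_rank(step: str) -> int:
    if step not in COVARIATE_STEPS:
        raise ValueError(f"unknown covariate step {step!r}")
    return COVARIATE_STEPS.index(step)


def domain_tests(domain: str, domain_map=None) -> list[str]:
    dm = domain_map or DOMAIN_MAP
    if domain == "general":
        return [t for tests in dm.values() for t in tests]
    if domain not in dm:
        raise ValueError(f"unknown domain {domain!r}")
    return list(dm[domain])


# ---------------------------------------------------------------------------
# cohort preparation

def prepare_analysis_frame(cohort: pd.DataFrame, wmh_transform: str = "log") -> pd.DataFrame:
    """Analysis-ready frame: oriented, baseline-z-scored, centred columns.

    Adds ``z_<test>_w<wave>``, ``z_wmh``, ``z_pvs``, ``z_mht``, z-scored
    continuous vascular indicators and ``cage_w<wave>`` (per-wave age centred
    at the wave's observed mean).  Raw columns are retained.
    """
    if wmh_transform not in ("log", "none"):
        raise ValueError("wmh_transform must be 'log' or 'none'")
    df = cohort.copy()
    base_wave = WAVES[0]
    for t in ALL_TESTS:
        sign = -1.0 if t in NEGATED_TESTS else 1.0
        base = sign * df[f"{t}_w{base_wave}"]
        mu, sd = base.mean(), base.std()
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize test {t}: degenerate baseline")
        for w in WAVES:
            df[f"z_{t}_w{w}"] = (sign * df[f"{t}_w{w}"] - mu) / sd
    wmh = df["wmh_ratio"].astype(float)
    wmh_t = np.log(wmh) if wmh_transform == "log" else wmh
    df["z_wmh"] = (wmh_t - wmh_t.mean()) / wmh_t.std()
    df["z_pvs"] = (df["pvs_count"] - df["pvs_count"].mean()) / df["pvs_count"].std()
    df["z_mht"] = (df["mht_age11"] - df["mht_age11"].mean()) / df["mht_age11"].std()
    for c, zc in [("hba1c", "z_hba1c"), ("cholesterol", "z_chol"),
                  ("sbp", "z_sbp"), ("dbp", "z_dbp")]:
        df[zc] = (df[c] - df[c].mean()) / df[c].std()
    for w in WAVES:
        age = df[f"age_w{w}"].astype(float)
        df[f"cage_w{w}"] = age - age.mean()
    return df


# ---------------------------------------------------------------------------
# measurement models

def svd_cfa_spec() -> ModelSpec:
    """One-factor model of total SVD burden: WMH ratio and PVS count as
    continuous indicators, lacunes and microbleeds as probit indicators.

    Scale set by fixing the WMH loading at 1; factor variance free.
    """
    spec = ModelSpec(
        [("z_wmh", CONTINUOUS), ("z_pvs", CONTINUOUS),
         ("lacunes", BINARY), ("microbleeds", BINARY)],
        ["svd"],
    )
    spec.set_loading("z_wmh", "svd", fixed(1.0))
    spec.set_loading("z_pvs", "svd", free("l_pvs", 0.5))
    spec.set_loading("lacunes", "svd", free("l_lac", 1.0))
    spec.set_loading("microbleeds", "svd", free("l_mb", 0.7))
    spec.set_psi("svd", "svd", free("psi_svd", 0.5))
    spec.set_theta("z_wmh", "z_wmh", free("th_wmh", 0.5))
    spec.set_theta("z_pvs", "z_pvs", free("th_pvs", 0.8))
    spec.set_theta("lacunes", "lacunes", fixed(1.0))
    spec.set_theta("microbleeds", "microbleeds", fixed(1.0))
    spec.set_intercept("z_wmh", free("nu_wmh", 0.0))
    spec.set_intercept("z_pvs", free("nu_pvs", 0.0))
    spec.set_mean("svd", fixed(0.0))
    spec.set_threshold("lacunes", free("tau_lac", 2.0))
    spec.set_threshold("microbleeds", free("tau_mb", 1.4))
    return spec


def vascular_cfa_spec() -> ModelSpec:
    """One-factor vascular-risk CFA: probit hypertension/diabetes/smoking,
    continuous HbA1c, cholesterol, systolic and diastolic blood pressure.

    Unit-variance factor with all loadings free (convenient for factor scores).
    """
    spec = ModelSpec(
        [("hypertension", BINARY), ("diabetes", BINARY), ("smoker", BINARY),
         ("z_hba1c", CONTINUOUS), ("z_chol", CONTINUOUS),
         ("z_sbp", CONTINUOUS), ("z_dbp", CONTINUOUS)],
        ["vasc"],
    )
    for v, start in [("hypertension", 0.7), ("diabetes", 0.6), ("smoker", 0.3)]:
        spec.set_loading(v, "vasc", free(f"l_{v}", start))
        spec.set_theta(v, v, fixed(1.0))
        spec.set_threshold(v, free(f"tau_{v}", 0.5 if v != "diabetes" else 1.4))
    for v, start in [("z_hba1c", 0.45), ("z_chol", 0.15), ("z_sbp", 0.5), ("z_dbp", 0.45)]:
        spec.set_loading(v, "vasc", free(f"l_{v}", start))
        spec.set_theta(v, v, free(f"th_{v}", 0.7))
        spec.set_intercept(v, free(f"nu_{v}", 0.0))
    spec.set_psi("vasc", "vasc", fixed(1.0))
    spec.set_mean("vasc", fixed(0.0))
    return spec


def vascular_factor_scores(prepared: pd.DataFrame, **fit_opts) -> tuple[pd.Series, FitResult]:
    """Fit the vascular CFA and return mean-zero posterior factor scores.

    Scores are posterior means E[eta | indicators] under the fitted model
    (the regression method generalised to the mixed probit/linear model),
    computed from each subject's observed indicator subset.
    """
    opts = {"n_starts": 2, "compute_se": False}
    opts.update(fit_opts)
    spec = vascular_cfa_spec()
    res = fit(spec, prepared, **opts)
    if not res.converged:
        raise RuntimeError("vascular-risk CFA did not converge")
    data = ModelData(res.model, prepared)
    scores = factor_scores(res.model, data, res.theta_t, "vasc")
    s = pd.Series(scores, index=prepared.index, name="vascular_score")
    return s - s.mean(), res


# ---------------------------------------------------------------------------
# growth models

def _add_growth_core(spec: ModelSpec, tests, growth: GrowthStructure):
    """First-order latent intercept/slope per test with fixed time loadings.

    Slope loadings are entered as the wave times divided by the total span,
    so the latent slope metric is 'decline over the full follow-up' - this
    keeps slope-related parameters on the same numerical scale as
    intercept-related ones (far better optimiser conditioning).  The span is
    recorded in ``spec.meta['slope_unit_years']``; per-year quantities are
    obtained by dividing by it.  Standardized estimates are invariant to the
    choice.
    """
    unit = growth.wave_times[-1]
    spec.meta["slope_unit_years"] = unit
    for t in tests:
        for w_idx, w in enumerate(WAVES):
            col = f"z_{t}_w{w}"
            spec.set_loading(col, f"i_{t}", fixed(1.0))
            spec.set_loading(col, f"s_{t}", fixed(growth.wave_times[w_idx] / unit))
            spec.set_theta(col, col, free(f"th_{t}", 0.36))
            spec.set_intercept(col, free(f"nu_{t}", 0.0))


def _add_covariates(spec: ModelSpec, step: str, outcome_factors, predictor_latent,
                    tests, with_imaging_age: bool):
    """Time-invariant covariates as single-indicator latents regressed into the
    second-order factors, plus per-wave age as a direct exogenous predictor."""
    rank = _step_rank(step)
    covs = []
    if rank >= 1:
        covs.append(("c_sex", "sex", 0.25))
    if rank >= 2:
        covs.append(("c_vr", "vascular_score", 1.0))
    if rank >= 3:
        covs.append(("c_mht", "z_mht", 1.0))
    for lat, col, var0 in covs:
        spec.set_loading(col, lat, fixed(1.0))
        spec.set_theta(col, col, fixed(0.0))
        spec.set_intercept(col, free(f"nu_{lat}", 0.0))
        spec.set_psi(lat, lat, free(f"psi_{lat}", var0))
        spec.set_mean(lat, fixed(0.0))
        for fac in outcome_factors:
            spec.set_path(fac, lat, free(f"b_{fac}_{lat}", 0.0))
        if predictor_latent is not None:
            spec.set_psi(lat, predictor_latent, free(f"cov_{lat}_pred", 0.0))
    for i, (lat_a, _, _) in enumerate(covs):
        for lat_b, _, _ in covs[i + 1:]:
            spec.set_psi(lat_a, lat_b, free(f"cov_{lat_a}_{lat_b}", 0.0))
    if rank >= 1:
        # mean-centred age at each wave predicts the same wave's observed scores
        # (one pooled coefficient; tests are on a common z metric)
        for t in tests:
            for w in WAVES:
                spec.set_exog_path(f"z_{t}_w{w}", f"cage_w{w}", free("g_age_cog", 0.0))
        if with_imaging_age:
            for col in ("z_wmh", "z_pvs"):
                if col in spec.observed and spec.theta.get((col, col), fixed(1.0)).value != 0.0:
                    spec.set_exog_path(col, "cage_w2", free("g_age_img", 0.0))


def _predictor_block(spec: ModelSpec, predictor: str):
    """Attach the SVD-burden factor or the observed-WMH single-indicator latent."""
    if predictor == "svd_latent":
        spec.set_loading("z_wmh", "svd", fixed(1.0))
        spec.set_loading("z_pvs", "svd", free("l_pvs", 0.5))
        spec.set_loading("lacunes", "svd", free("l_lac", 1.0))
        spec.set_loading("microbleeds", "svd", free("l_mb", 0.7))
        spec.set_psi("svd", "svd", free("psi_svd", 0.5))
        spec.set_theta("z_wmh", "z_wmh", free("th_wmh", 0.5))
        spec.set_theta("z_pvs", "z_pvs", free("th_pvs", 0.8))
        spec.set_theta("lacunes", "lacunes", fixed(1.0))
        spec.set_theta("microbleeds", "microbleeds", fixed(1.0))
        spec.set_intercept("z_wmh", free("nu_wmh", 0.0))
        spec.set_intercept("z_pvs", free("nu_pvs", 0.0))
        spec.set_mean("svd", fixed(0.0))
        spec.set_threshold("lacunes", free("tau_lac", 2.0))
        spec.set_threshold("microbleeds", free("tau_mb", 1.4))
        return "svd"
    if predictor == "wmh_ratio":
        spec.set_loading("z_wmh", "wmhp", fixed(1.0))
        spec.set_theta("z_wmh", "z_wmh", fixed(0.0))
        spec.set_intercept("z_wmh", free("nu_wmh", 0.0))
        spec.set_psi("wmhp", "wmhp", free("psi_wmhp", 1.0))
        spec.set_mean("wmhp", fixed(0.0))
        return "wmhp"
    raise ValueError(f"unknown predictor {predictor!r}")


def _observed_for(tests, step, predictor):
    obs = [(f"z_{t}_w{w}", CONTINUOUS) for t in tests for w in WAVES]
    if predictor == "svd_latent":
        obs += [("z_wmh", CONTINUOUS), ("z_pvs", CONTINUOUS),
                ("lacunes", BINARY), ("microbleeds", BINARY)]
    elif predictor == "wmh_ratio":
        obs += [("z_wmh", CONTINUOUS)]
    rank = _step_rank(step)
    if rank >= 1:
        obs.append(("sex", CONTINUOUS))
    if rank >= 2:
        obs.append(("vascular_score", CONTINUOUS))
    if rank >= 3:
        obs.append(("z_mht", CONTINUOUS))
    return obs


def _exog_for(step, predictor):
    if _step_rank(step) >= 1:
        return [f"cage_w{w}" for w in WAVES]
    return []


def _apply_growth_starts(spec: ModelSpec, prepared: pd.DataFrame, tests,
                         growth: GrowthStructure, bifactor: bool) -> None:
    """Heuristic data-driven start values for growth-model parameters.

    Moment-based: wave means give intercepts and slope means; lag-1
    autocovariance splits stable from occasion variance; baseline
    cross-covariances with the reference test give loading starts.  Purely a
    warm start for the optimiser - final estimates do not depend on it.
    """
    unit = growth.wave_times[-1]
    wt = np.asarray(growth.wave_times) / unit  # model's internal slope metric
    ref = tests[0]
    means = {t: np.array([prepared[f"z_{t}_w{w}"].mean() for w in WAVES]) for t in tests}
    des = np.column_stack([np.ones(4), wt])
    coefs = {t: np.linalg.lstsq(des, means[t], rcond=None)[0] for t in tests}
    slope_ref = coefs[ref][1] if abs(coefs[ref][1]) > 1e-6 else -1.0
    base = prepared[[f"z_{t}_w{WAVES[0]}" for t in tests]]
    cov0 = base.cov().to_numpy()
    cross = cov0[np.triu_indices_from(cov0, k=1)]
    psi_gi = float(np.clip(np.median(cross) if len(cross) else 0.5, 0.2, 0.9))
    lag = {
        t: float(pd.concat([prepared[f"z_{t}_w{WAVES[0]}"],
                            prepared[f"z_{t}_w{WAVES[1]}"]], axis=1).cov().iloc[0, 1])
        for t in tests
    }
    ref_col = tests.index(ref)

    # crude slope-variance start from per-subject OLS slopes of the reference test
    cols = [f"z_{ref}_w{w}" for w in WAVES]
    comp = prepared[cols].dropna()
    if len(comp) > 30:
        Yc = comp.to_numpy()
        H = np.linalg.lstsq(des, Yc.T, rcond=None)[0]
        psi_gs = float(np.clip(np.var(H[1]) * 0.5, 0.01, 4.0))
    else:
        psi_gs = 0.18

    def set_start(label, value):
        for coll in (spec.lambda_, spec.beta, spec.psi, spec.theta, spec.gamma):
            for e in coll.values():
                if e.free and e.label == label:
                    e.value = value
        for coll in (spec.nu, spec.alpha, spec.tau):
            for e in coll.values():
                if e.free and e.label == label:
                    e.value = value

    for t in tests:
        var_i = float(np.clip(lag[t], 0.1, 0.95))
        set_start(f"nu_{t}", float(coefs[t][0]))
        set_start(f"th_{t}", float(np.clip(1.0 - var_i, 0.05, 0.9)))
        li = float(np.clip(cov0[tests.index(t), ref_col] / psi_gi, 0.3, 1.6)) if t != ref else 1.0
        ls = float(np.clip(coefs[t][1] / slope_ref, 0.3, 1.6)) if t != ref else 1.0
        if bifactor:
            gi_load = li * np.sqrt(psi_gi)
            set_start(f"bg_i_{t}", 0.9 * gi_load)
            set_start(f"bd_i_{t}", 0.4 * gi_load)
            set_start(f"bg_s_{t}", 0.9 * ls * np.sqrt(psi_gs))
            set_start(f"bd_s_{t}", 0.4 * ls * np.sqrt(psi_gs))
            set_start(f"ui_{t}", float(np.clip(var_i - li**2 * psi_gi, 0.02, 0.5)) * 0.7)
        else:
            set_start(f"li_{t}", li)
            set_start(f"ls_{t}", ls)
            set_start(f"ui_{t}", float(np.clip(var_i - li**2 * psi_gi, 0.02, 0.5)))
        set_start(f"vs_{t}", 0.25 * psi_gs)
    if bifactor:
        set_start("alpha_g_s", float(slope_ref / (0.9 * np.sqrt(psi_gs))))
    else:
        set_start("psi_Gi", psi_gi)
        set_start("psi_Gs", psi_gs)
        set_start("psi_Gis", -0.1 * np.sqrt(psi_gi * psi_gs))
        set_start("alpha_slope", float(slope_ref))


def foc_spec(domain: str, growth: GrowthStructure | None = None, step: str = "none",
             predictor: str | None = "svd_latent", domain_map=None,
             data: pd.DataFrame | None = None) -> ModelSpec:
    """Hierarchical factor-of-curves model for one cognitive domain.

    Per-test latent intercepts and slopes (slope loadings fixed at the wave
    times) load on a second-order domain intercept and slope; the SVD-burden
    factor (or observed WMH ratio) predicts both; covariates are added
    stepwise.  ``predictor=None`` builds the covariate-free measurement model.

    The first test of the domain anchors the second-order factors (loading
    fixed at 1), so the second-order slope mean is in baseline-SD units of
    the reference test per year.
    """
    growth = growth or GrowthStructure()
    tests = domain_tests(domain, domain_map)
    pred_arg = predictor if predictor is not None else "none"
    obs = _observed_for(tests, step, predictor if predictor else "none")
    latents = [f"i_{t}" for t in tests] + [f"s_{t}" for t in tests] + ["G_i", "G_s"]
    if predictor == "svd_latent":
        latents.append("svd")
    elif predictor == "wmh_ratio":
        latents.append("wmhp")
    rank = _step_rank(step)
    if rank >= 1:
        latents.append("c_sex")
    if rank >= 2:
        latents.append("c_vr")
    if rank >= 3:
        latents.append("c_mht")
    spec = ModelSpec(obs, latents, exog=_exog_for(step, pred_arg))

    _add_growth_core(spec, tests, growth)
    for k, t in enumerate(tests):
        li = fixed(1.0) if k == 0 else free(f"li_{t}", 0.9)
        ls = fixed(1.0) if k == 0 else free(f"ls_{t}", 0.9)
        spec.set_path(f"i_{t}", "G_i", li)
        spec.set_path(f"s_{t}", "G_s", ls)
        spec.set_psi(f"i_{t}", f"i_{t}", free(f"ui_{t}", 0.16))
        spec.set_psi(f"s_{t}", f"s_{t}", free(f"vs_{t}", 0.04))
        spec.set_psi(f"i_{t}", f"s_{t}", free(f"uv_{t}", 0.0))
    spec.set_psi("G_i", "G_i", free("psi_Gi", 0.5))
    spec.set_psi("G_s", "G_s", free("psi_Gs", 0.18))
    spec.set_psi("G_i", "G_s", free("psi_Gis", -0.03))
    spec.set_mean("G_s", free("alpha_slope", -1.2))
    spec.set_mean("G_i", fixed(0.0))

    pred_lat = None
    if predictor is not None:
        pred_lat = _predictor_block(spec, predictor)
        spec.set_path("G_i", pred_lat, free("b_int_pred", -0.1))
        spec.set_path("G_s", pred_lat, free("b_slope_pred", -0.05))
    _add_covariates(spec, step, ["G_i", "G_s"], pred_lat, tests,
                    with_imaging_age=predictor is not None)
    if data is not None:
        _apply_growth_starts(spec, data, tests, growth, bifactor=False)
    return spec


BIFACTOR_FACTORS = ["g", "speed", "memory", "visuospatial"]


def bifactor_spec(growth: GrowthStructure | None = None, step: str = "none",
                  predictor: str | None = "svd_latent", domain_map=None,
                  data: pd.DataFrame | None = None) -> ModelSpec:
    """Longitudinal bifactor model: general and domain trajectories separated.

    Every test's latent intercept loads on the general intercept factor and
    its domain's intercept factor (same for slopes); all second-order factors
    are mutually orthogonal except the intercept-slope covariance within each
    factor, which stays free.  Second-order factors carry fixed unit residual
    variance with free loadings.  The SVD factor predicts all eight
    second-order factors simultaneously.
    """
    growth = growth or GrowthStructure()
    dm = domain_map or DOMAIN_MAP
    tests = [t for d in dm.values() for t in d]
    test_domain = {t: d for d, ts in dm.items() for t in ts}
    obs = _observed_for(tests, step, predictor if predictor else "none")
    second = [f"{f}_{io}" for f in BIFACTOR_FACTORS for io in ("i", "s")]
    latents = [f"i_{t}" for t in tests] + [f"s_{t}" for t in tests] + second
    if predictor == "svd_latent":
        latents.append("svd")
    elif predictor == "wmh_ratio":
        latents.append("wmhp")
    rank = _step_rank(step)
    latents += ["c_sex"] * (rank >= 1) + ["c_vr"] * (rank >= 2) + ["c_mht"] * (rank >= 3)
    spec = ModelSpec(obs, latents, exog=_exog_for(step, predictor or "none"))

    _add_growth_core(spec, tests, growth)
    for t in tests:
        d = test_domain[t]
        spec.set_path(f"i_{t}", "g_i", free(f"bg_i_{t}", 0.6))
        spec.set_path(f"s_{t}", "g_s", free(f"bg_s_{t}", 0.4))
        spec.set_path(f"i_{t}", f"{d}_i", free(f"bd_i_{t}", 0.25))
        spec.set_path(f"s_{t}", f"{d}_s", free(f"bd_s_{t}", 0.15))
        spec.set_psi(f"i_{t}", f"i_{t}", free(f"ui_{t}", 0.1))
        spec.set_psi(f"s_{t}", f"s_{t}", free(f"vs_{t}", 0.03))
        spec.set_psi(f"i_{t}", f"s_{t}", free(f"uv_{t}", 0.0))
    for f_ in BIFACTOR_FACTORS:
        spec.set_psi(f"{f_}_i", f"{f_}_i", fixed(1.0))
        spec.set_psi(f"{f_}_s", f"{f_}_s", fixed(1.0))
        spec.set_psi(f"{f_}_i", f"{f_}_s", free(f"psi_{f_}_is", -0.1))
        spec.set_mean(f"{f_}_i", fixed(0.0))
        spec.set_mean(f"{f_}_s", free(f"alpha_{f_}_s", -2.0 if f_ == "g" else 0.0))

    pred_lat = None
    if predictor is not None:
        pred_lat = _predictor_block(spec, predictor)
        for f_ in BIFACTOR_FACTORS:
            spec.set_path(f"{f_}_i", pred_lat, free(f"b_{f_}_i_pred", -0.05))
            spec.set_path(f"{f_}_s", pred_lat, free(f"b_{f_}_s_pred", -0.1))
    _add_covariates(spec, step, second, pred_lat, tests,
                    with_imaging_age=predictor is not None)
    if data is not None:
        _apply_growth_starts(spec, data, tests, growth, bifactor=True)
    return spec


def canonicalize_bifactor_signs(res: FitResult) -> FitResult:
    """Orient each unit-variance second-order factor so its summed loadings
    are positive (the likelihood is invariant under joint sign flips)."""
    from .fitting import flip_factor_sign

    spec = res.spec
    for f_ in BIFACTOR_FACTORS:
        for io in ("i", "s"):
            fac = f"{f_}_{io}"
            if fac not in spec.latents:
                continue
            total = sum(
                res.estimates[e.label]
                for (to, frm), e in spec.beta.items()
                if frm == fac and e.free and e.label in res.estimates
            )
            if total < 0:
                flip_factor_sign(res, fac)
    return res
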