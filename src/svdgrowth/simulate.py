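"""Synthetic longitudinal cohort generator with known ground truth.

Emulates a community-dwelling ageing cohort observed at four triennial waves
(mean ages ~72.5, 76.2, 79.5, 82): ten cognitive tests in three domains, a
latent small-vessel-disease (SVD) burden factor measured by WMH/intracranial
volume ratio, perivascular-space count and binary lacune/microbleed ratings,
vascular-risk indicators, childhood ability, and wave-on-wave attrition that
is selective on WMH burden and education.

The generating model is the same hierarchical growth structure the analysis
models estimate: per-test latent intercepts and slopes load on second-order
general (and, in the bifactor scenario, domain-specific) intercepts and
slopes; the SVD factor and covariates predict the second-order factors.
Structural coefficients are specified on the standardized scale and converted
to raw scale internally, so scenario truths can be set directly to
standardized effect sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

TIME_LOADINGS = (0.0, 3.78, 6.83, 9.55)
WAVES = (2, 3, 4, 5)

#: domain membership and orientation of the ten cognitive tests
DOMAINS = {
    "speed": ["digit_symbol", "symbol_search", "inspection_time", "choice_rt"],
    "memory": ["verbal_pairs", "logical_memory", "digit_span_back"],
    "visuospatial": ["block_design", "matrix_reasoning", "spatial_span"],
}
ALL_TESTS = [t for tests in DOMAINS.values() for t in tests]
#: tests whose raw scores run the "wrong way" (higher = worse) and are negated
NEGATED_TESTS = {"choice_rt"}

#: raw-score location/scale used to emit plausibly scaled test columns
TEST_SCALES = {
    "digit_symbol": (56.0, 12.0), "symbol_search": (24.5, 6.0),
    "inspection_time": (111.0, 11.5), "choice_rt": (0.64, 0.09),
    "verbal_pairs": (27.0, 9.5), "logical_memory": (74.0, 18.0),
    "digit_span_back": (7.8, 2.3), "block_design": (34.0, 10.0),
    "matrix_reasoning": (13.5, 5.0), "spatial_span": (7.4, 1.4),
}

BASE_AGE_MEAN, BASE_AGE_SD = 72.5, 0.5
AGE_JITTER_SD = 0.15
WMH_RATIO_MEAN, WMH_RATIO_CV = 0.0084, 1.05  # Mean and coefficient of variation
PVS_MEAN, PVS_SD = 258.7, 94.6
MHT_MEAN, MHT_SD = 50.2, 11.9
EDU_MEAN, EDU_SD = 10.9, 1.2
EDU_MHT_CORR = 0.35


@dataclass
class TestTruth:
    """Per-test measurement truth (z-score metric at baseline).

    ``resid_sd=None`` (the default) solves the occasion-noise SD so that the
    test's baseline variance is exactly 1, i.e. latent means and slopes are
    in baseline-SD units of the observed score.
    """

    lam_i_g: float     # intercept loading on the general intercept factor
    lam_s_g: float     # slope loading on the general slope factor
    lam_i_d: float     # loadings on the orthogonal domain factors
    lam_s_d: float
    u_sd: float        # test-specific intercept disturbance SD
    v_sd: float        # test-specific slope disturbance SD (per year)
    resid_sd: float | None = None  # occasion-specific noise SD


@dataclass
class AttritionTruth:
    base_rates: tuple[float, ...] = (0.143, 0.197, 0.194)
    b_wmh: float = 0.35        # log-odds per SD of log WMH ratio
    b_education: float = -0.25  # log-odds per SD of education


@dataclass
class SimTruth:
    """Complete generating parameter set for one synthetic cohort."""

    scenario: str
    n_subjects: int = 540
    seed: int = 1
    time_loadings: tuple[float, ...] = TIME_LOADINGS
    g_intercept_mean: float = 0.0
    g_intercept_sd: float = 0.75
    g_slope_mean: float = -0.13           # SD units per year
    g_slope_sd: float = 0.045
    intercept_slope_resid_corr: float = -0.2
    domain_intercept_sds: dict = field(default_factory=lambda: dict.fromkeys(DOMAINS, 0.0))
    domain_slope_sds: dict = field(default_factory=lambda: dict.fromkeys(DOMAINS, 0.0))
    #: per-year mean decline offset of each domain relative to g (enters as
    #: lam_s_g * (g_slope + offset) so domain means stay proportional to loadings)
    domain_slope_offsets: dict = field(default_factory=lambda: dict.fromkeys(DOMAINS, 0.0))
    #: correlation between a domain's intercept and slope factors (people with
    #: lower domain-specific level tend to show steeper domain-specific decline)
    domain_is_corr: float = -0.35
    tests: dict = field(default_factory=dict)
    #: standardized loadings of continuous markers / raw liability loadings of
    #: binary markers on the unit-variance SVD factor
    svd_loadings: dict = field(default_factory=lambda: {
        "wmh": 0.75, "pvs": 0.40, "lacunes": 0.75, "microbleeds": 0.55})
    svd_prevalences: dict = field(default_factory=lambda: {
        "lacunes": 0.051, "microbleeds": 0.120})
    #: standardized structural paths; predictor for slopes/intercepts is the
    #: SVD factor (or standardized log WMH in the wmh_only scenario)
    beta_svd_to_slopes: dict = field(default_factory=lambda: dict.fromkeys(
        ["g", *DOMAINS], 0.0))
    beta_svd_to_intercepts: dict = field(default_factory=lambda: dict.fromkeys(
        ["g", *DOMAINS], 0.0))
    covariate_effects: dict = field(default_factory=lambda: {
        "intercept": {"vascular": -0.10, "mht": 0.50, "sex": 0.05},
        "slope": {"vascular": -0.10, "mht": 0.0, "sex": 0.05},
    })
    #: modest predictor correlations; the SVD-vascular correlation is kept
    #: small because the published stepwise adjustment sequence moves the SVD
    #: path by only ~0.003 when vascular risk enters the model
    predictor_corr: dict = field(default_factory=lambda: {
        ("svd", "vascular"): 0.10, ("svd", "mht"): -0.15, ("vascular", "mht"): -0.10})
    age_direct: float = -0.02      # z-units per year of within-wave age deviation
    age_on_imaging: float = 0.03   # liability z-units per year of baseline age
    wmh_as_predictor: bool = False
    attrition: AttritionTruth = field(default_factory=AttritionTruth)
    female_prop: float = 0.467

    # -- derived ----------------------------------------------------------
    def svd_thresholds(self) -> dict:
        """Probit thresholds on the standardized total-liability scale."""
        return {k: float(norm.ppf(1.0 - p)) for k, p in self.svd_prevalences.items()}

    def liability_threshold(self, marker: str) -> float:
        """Threshold on the raw liability scale (residual variance 1)."""
        lam = self.svd_loadings[marker]
        return self.svd_thresholds()[marker] * np.sqrt(lam**2 + 1.0)

    def resolved_resid_sd(self, test: str) -> float:
        """Occasion-noise SD: explicit value, or solved for unit baseline variance."""
        tt = self.tests[test]
        if tt.resid_sd is not None:
            return tt.resid_sd
        dom = next(d for d, ts in DOMAINS.items() if test in ts)
        var_i = (tt.lam_i_g**2 * self.g_intercept_sd**2
                 + tt.lam_i_d**2 * self.domain_intercept_sds[dom]**2 + tt.u_sd**2)
        resid_var = 1.0 - var_i
        if resid_var <= 0:
            raise ValueError(
                f"test {test}: intercept variance {var_i:.3f} >= 1; cannot solve "
                "occasion noise for unit baseline variance")
        return float(np.sqrt(resid_var))

    def validate(self) -> None:
        for name, t in self.tests.items():
            if min(t.u_sd, t.v_sd) < 0 or (t.resid_sd is not None and t.resid_sd < 0):
                raise ValueError(f"negative SD in test truth {name}")
            self.resolved_resid_sd(name)
        tl = self.time_loadings
        if tl[0] != 0.0 or any(b <= a for a, b in zip(tl, tl[1:])):
            raise ValueError("time loadings must start at 0 and strictly increase")
        for k, p in self.svd_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {k} outside (0, 1)")
        for d in (self.beta_svd_to_slopes, self.beta_svd_to_intercepts):
            for k, b in d.items():
                if abs(b) >= 1.0:
                    raise ValueError(f"standardized path {k} must have |beta| < 1")
        if self.g_intercept_sd <= 0 or self.g_slope_sd <= 0:
            raise ValueError("factor SDs must be positive")

    def replace(self, **kw) -> "SimTruth":
        return dataclasses.replace(self, **kw)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        doc = dataclasses.asdict(self)
        doc["predictor_corr"] = {f"{a}|{b}": v for (a, b), v in self.predictor_corr.items()}
        return json.dumps(doc, indent=1, default=default)


def _default_tests(style: str = "hierarchical") -> dict[str, TestTruth]:
    # reference test of each domain has unit g loadings so that per-domain and
    # general fits (which fix the first loading at 1) recover factor means 1:1.
    # In the bifactor style, g- and domain-loading profiles are strongly
    # heterogeneous (some tests g-dominated, others domain-dominated), as in
    # real batteries; near-flat or proportional profiles would leave the
    # bifactor rotation empirically indeterminate, which real data do not
    # exhibit.  Hierarchical scenarios have no domain factors, so only their
    # g profile matters.
    if style == "bifactor":
        vals = {
            "digit_symbol":   (1.00, 1.00, 0.45, 0.45),
            "symbol_search":  (0.90, 0.85, 0.75, 0.75),
            "inspection_time": (0.50, 0.45, 1.10, 1.15),
            "choice_rt":      (0.55, 0.50, 1.20, 1.25),
            "verbal_pairs":   (1.00, 1.00, 0.90, 0.90),
            "logical_memory": (0.75, 0.75, 1.10, 1.10),
            "digit_span_back": (0.60, 0.55, 0.50, 0.55),
            "block_design":   (1.00, 1.00, 0.55, 0.55),
            "matrix_reasoning": (0.90, 0.90, 0.45, 0.40),
            "spatial_span":   (0.55, 0.50, 1.10, 1.15),
        }
    else:
        vals = {
            "digit_symbol":   (1.00, 1.00, 0.70, 0.70),
            "symbol_search":  (0.95, 0.90, 1.00, 1.00),
            "inspection_time": (0.70, 0.75, 1.05, 1.05),
            "choice_rt":      (0.85, 0.85, 1.20, 1.15),
            "verbal_pairs":   (1.00, 1.00, 1.15, 1.10),
            "logical_memory": (0.95, 0.90, 1.05, 1.00),
            "digit_span_back": (0.70, 0.70, 0.55, 0.60),
            "block_design":   (1.00, 1.00, 0.80, 0.85),
            "matrix_reasoning": (0.95, 0.90, 0.75, 0.70),
            "spatial_span":   (0.75, 0.80, 1.05, 1.10),
        }
    out = {}
    # bifactor style: most non-general slope variance belongs to the domain
    # factors rather than single tests, keeping the domain slope factors
    # empirically separable from g
    v_sd = 0.012 if style == "bifactor" else 0.018
    for name, (lig, lsg, lid, lsd) in vals.items():
        out[name] = TestTruth(lam_i_g=lig, lam_s_g=lsg, lam_i_d=lid, lam_s_d=lsd,
                              u_sd=0.40, v_sd=v_sd)
    return out


SCENARIOS = ("null_svd", "paper_foC", "paper_bifactor", "wmh_only")


def default_truth(scenario: str, **overrides) -> SimTruth:
    """Fully populated generating truth for a named scenario.

    Scenarios
    ---------
    ``null_svd``
        SVD burden unrelated to every cognitive intercept and slope.
    ``paper_foC``
        Hierarchical factor-of-curves truth: one general intercept/slope
        factor over all tests (no orthogonal domain variance), SVD effect on
        the general slope of -0.201 SD and intercept -0.25 SD; mean declines
        per year of -0.13 (general), -0.16 (speed), -0.005 (memory), -0.08
        (visuospatial) via proportional domain offsets.
    ``paper_bifactor``
        Bifactor truth: orthogonal general and domain intercept/slope
        factors; SVD affects only the general slope (-0.222 SD).
    ``wmh_only``
        Slopes depend on the observed (log) WMH ratio rather than the latent
        SVD factor, standardized effect -0.149 on the general slope.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    style = "bifactor" if scenario == "paper_bifactor" else "hierarchical"
    truth = SimTruth(scenario=scenario, tests=_default_tests(style))
    offsets = {"speed": -0.03, "memory": 0.125, "visuospatial": 0.05}
    truth.domain_slope_offsets.update(offsets)
    if scenario == "null_svd":
        pass
    elif scenario == "paper_foC":
        truth.beta_svd_to_slopes["g"] = -0.201
        truth.beta_svd_to_intercepts["g"] = -0.25
    elif scenario == "paper_bifactor":
        truth.beta_svd_to_slopes["g"] = -0.222
        truth.beta_svd_to_intercepts["g"] = -0.25
        # domain shares calibrated against the cohort's published decomposition
        # of decline variance (~50-70% shared across abilities): g carries
        # ~55-65% of per-test slope variance, domains most of the rest
        truth.domain_intercept_sds = {"speed": 0.45, "memory": 0.40, "visuospatial": 0.40}
        truth.domain_slope_sds = {"speed": 0.030, "memory": 0.026, "visuospatial": 0.028}
    elif scenario == "wmh_only":
        truth.wmh_as_predictor = True
        truth.beta_svd_to_slopes["g"] = -0.149
        truth.beta_svd_to_intercepts["g"] = -0.20
    truth = truth.replace(**overrides)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------

def _structural_draw(truth: SimTruth, preds: np.ndarray, R: np.ndarray, rng):
    """Draw (G_I, G_S) given standardized predictors ``preds`` (n x 4).

    Columns of ``preds``: svd-or-wmh, vascular, mht, sex (all unit variance).
    Raw coefficients are standardized betas times the outcome's total SD; the
    residual (co)variance is solved so total SDs match the specified values.
    """
    ce = truth.covariate_effects
    bI_std = np.array([truth.beta_svd_to_intercepts["g"], ce["intercept"]["vascular"],
                       ce["intercept"]["mht"], ce["intercept"]["sex"]])
    bS_std = np.array([truth.beta_svd_to_slopes["g"], ce["slope"]["vascular"],
                       ce["slope"]["mht"], ce["slope"]["sex"]])
    sdI, sdS = truth.g_intercept_sd, truth.g_slope_sd
    varI_resid = sdI**2 * (1.0 - bI_std @ R @ bI_std)
    varS_resid = sdS**2 * (1.0 - bS_std @ R @ bS_std)
    if min(varI_resid, varS_resid) <= 0:
        raise ValueError("standardized effects imply negative residual variance")
    cov_resid = truth.intercept_slope_resid_corr * np.sqrt(varI_resid * varS_resid)
    Z = rng.multivariate_normal(
        [0.0, 0.0], [[varI_resid, cov_resid], [cov_resid, varS_resid]], size=len(preds))
    GI = truth.g_intercept_mean + preds @ (bI_std * sdI) + Z[:, 0]
    GS = truth.g_slope_mean + preds @ (bS_std * sdS) + Z[:, 1]
    return GI, GS


def _predictor_corr_matrix(truth: SimTruth) -> np.ndarray:
    R = np.eye(4)
    idx = {"svd": 0, "vascular": 1, "mht": 2, "sex": 3}
    for (a, b), v in truth.predictor_corr.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = v
    return R


def simulate_cohort(truth: SimTruth) -> pd.DataFrame:
    """Forward-simulate a wide cohort table (no attrition) from ``truth``."""
    truth.validate()
    n = truth.n_subjects
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2718]))

    # --- correlated latents: SVD factor, vascular liability, childhood ability
    R3 = np.eye(3)
    pairs = {("svd", "vascular"): (0, 1), ("svd", "mht"): (0, 2), ("vascular", "mht"): (1, 2)}
    for key, (i, j) in pairs.items():
        R3[i, j] = R3[j, i] = truth.predictor_corr.get(key, 0.0)
    F, VR, MHTz = rng.multivariate_normal(np.zeros(3), R3, size=n).T
    sex = (rng.random(n) < truth.female_prop).astype(float)
    sex_z = (sex - truth.female_prop) / np.sqrt(truth.female_prop * (1 - truth.female_prop))

    # --- ages
    base_age = rng.normal(BASE_AGE_MEAN, BASE_AGE_SD, n)
    ages = np.empty((n, 4))
    for w in range(4):
        jit = 0.0 if w == 0 else rng.normal(0.0, AGE_JITTER_SD, n)
        ages[:, w] = base_age + truth.time_loadings[w] + jit
    ages.sort(axis=1)  # jitter is far smaller than wave gaps; keep monotone

    # --- imaging markers
    age_dev = base_age - BASE_AGE_MEAN
    lw = truth.svd_loadings["wmh"]
    wmh_liab = lw * F + np.sqrt(max(1 - lw**2, 1e-9)) * rng.normal(0, 1, n) \
        + truth.age_on_imaging * age_dev
    logsd = np.sqrt(np.log(1.0 + WMH_RATIO_CV**2))
    logmean = np.log(WMH_RATIO_MEAN) - 0.5 * logsd**2
    wmh_ratio = np.exp(logmean + logsd * wmh_liab)
    lp = truth.svd_loadings["pvs"]
    pvs_lat = lp * F + np.sqrt(max(1 - lp**2, 1e-9)) * rng.normal(0, 1, n) \
        + truth.age_on_imaging * age_dev
    pvs_count = np.clip(np.round(PVS_MEAN + PVS_SD * pvs_lat), 0, None)
    markers = {}
    for mk in ("lacunes", "microbleeds"):
        lam = truth.svd_loadings[mk]
        liab = lam * F + rng.normal(0, 1, n)
        markers[mk] = (liab > truth.liability_threshold(mk)).astype(float)

    # --- vascular-risk indicators
    def probit_item(loading, prev):
        thr = norm.ppf(1.0 - prev) * np.sqrt(loading**2 + 1.0)
        return (loading * VR + rng.normal(0, 1, n) > thr).astype(float)

    hypertension = probit_item(0.7, 0.48)
    diabetes = probit_item(0.6, 0.10)
    smoker = probit_item(0.3, 0.507)

    def cont_item(mean, sd, loading):
        return mean + sd * (loading * VR + np.sqrt(1 - loading**2) * rng.normal(0, 1, n))

    hba1c = cont_item(39.0, 6.4, 0.45)
    cholesterol = cont_item(5.2, 1.1, 0.15)
    sbp = cont_item(146.5, 18.0, 0.50)
    dbp = cont_item(79.7, 9.8, 0.45)

    mht = np.clip(np.round(MHT_MEAN + MHT_SD * MHTz), 0, 76)
    edu = np.round(EDU_MEAN + EDU_SD * (EDU_MHT_CORR * MHTz
                   + np.sqrt(1 - EDU_MHT_CORR**2) * rng.normal(0, 1, n)), 1)

    # --- growth factors
    predictor = wmh_liab if truth.wmh_as_predictor else F
    preds = np.column_stack([predictor, VR, MHTz, sex_z])
    R4 = _predictor_corr_matrix(truth)
    if truth.wmh_as_predictor:
        # wmh liability correlates with vascular/mht through F, scaled by its loading
        R4[0, 1] = R4[1, 0] = lw * R4[0, 1]
        R4[0, 2] = R4[2, 0] = lw * R4[0, 2]
    GI, GS = _structural_draw(truth, preds, R4, rng)

    dI, dS = {}, {}
    rho_d = truth.domain_is_corr
    for d in DOMAINS:
        zi = rng.normal(0, 1, n)
        zs = rho_d * zi + np.sqrt(max(1.0 - rho_d**2, 0.0)) * rng.normal(0, 1, n)
        dI[d] = truth.domain_intercept_sds[d] * zi
        dS[d] = truth.domain_slope_sds[d] * zs

    # --- observed test scores
    cols: dict[str, np.ndarray] = {"subject_id": np.arange(1, n + 1)}
    for w, wave in enumerate(WAVES):
        cols[f"age_w{wave}"] = np.round(ages[:, w], 2)
    mean_age_w = ages.mean(axis=0)
    for dom, tests in DOMAINS.items():
        for t in tests:
            tt: TestTruth = truth.tests[t]
            I_t = tt.lam_i_g * GI + tt.lam_i_d * dI[dom] + tt.u_sd * rng.normal(0, 1, n)
            # the domain's mean-decline offset rides the domain-specific channel
            # when one exists (so the bifactor mean structure stays exact) and
            # the common channel otherwise (hierarchical scenarios)
            if truth.domain_slope_sds[dom] > 0:
                S_t = tt.lam_s_g * GS \
                    + tt.lam_s_d * (dS[dom] + truth.domain_slope_offsets[dom]) \
                    + tt.v_sd * rng.normal(0, 1, n)
            else:
                S_t = tt.lam_s_g * (GS + truth.domain_slope_offsets[dom]) \
                    + tt.lam_s_d * dS[dom] + tt.v_sd * rng.normal(0, 1, n)
            mean_t, scale_t = TEST_SCALES[t]
            resid_sd = truth.resolved_resid_sd(t)
            for w, wave in enumerate(WAVES):
                z = I_t + truth.time_loadings[w] * S_t \
                    + truth.age_direct * (ages[:, w] - mean_age_w[w]) \
                    + resid_sd * rng.normal(0, 1, n)
                raw = mean_t - scale_t * z if t in NEGATED_TESTS else mean_t + scale_t * z
                cols[f"{t}_w{wave}"] = np.round(raw, 3)

    cols.update(
        wmh_ratio=np.round(wmh_ratio, 6), pvs_count=pvs_count,
        lacunes=markers["lacunes"], microbleeds=markers["microbleeds"],
        hypertension=hypertension, diabetes=diabetes, smoker=smoker,
        hba1c=np.round(hba1c, 1), cholesterol=np.round(cholesterol, 2),
        sbp=np.round(sbp, 1), dbp=np.round(dbp, 1),
        sex=sex, mht_age11=mht, education_years=edu,
    )
    return pd.DataFrame(cols)


def _calibrated_intercept(target: float, sd: float) -> float:
    """Intercept c with E[expit(c + sd*Z)] = target, Z standard normal."""
    if target <= 0.0:
        return -np.inf
    t, w = np.polynomial.hermite.hermgauss(41)
    w = w / np.sqrt(np.pi)

    def mean_prob(c):
        return float(w @ expit(c + sd * np.sqrt(2.0) * t)) - target

    return brentq(mean_prob, -20.0, 20.0)


def apply_attrition(cohort: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Monotone wave-on-wave dropout, selective on WMH burden and education.

    Dropout at each follow-up wave is Bernoulli with logistic probability in
    the standardized log WMH ratio (positive) and education (negative); once
    a subject drops out all later cognitive scores and ages are missing.
    Baseline (wave 2) is never removed.  Deterministic given ``truth.seed``.
    """
    att = truth.attrition
    test_cols_by_wave = {
        wave: [f"{t}_w{wave}" for t in ALL_TESTS] for wave in WAVES[1:]
    }
    for wave in WAVES[1:]:
        present = [c for c in test_cols_by_wave[wave] if c not in cohort.columns]
        if present:
            raise KeyError(f"cohort lacks expected columns {present}")
    if cohort[[c for w in WAVES[1:] for c in test_cols_by_wave[w]]].isna().any().any():
        raise ValueError("cohort already contains attrition (missing follow-up scores)")
    out = cohort.copy()
    n = len(out)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 31415]))
    lw = np.log(out["wmh_ratio"].to_numpy(dtype=float))
    z_wmh = (lw - lw.mean()) / lw.std()
    edu = out["education_years"].to_numpy(dtype=float)
    z_edu = (edu - edu.mean()) / edu.std()
    lin = att.b_wmh * z_wmh + att.b_education * z_edu
    sd_lin = float(np.sqrt(att.b_wmh**2 + att.b_education**2))
    active = np.ones(n, dtype=bool)
    for w_idx, wave in enumerate(WAVES[1:]):
        base = att.base_rates[w_idx]
        if base <= 0.0:
            continue
        c = _calibrated_intercept(base, sd_lin)
        p_drop = expit(c + lin)
        dropped_now = active & (rng.random(n) < p_drop)
        active &= ~dropped_now
        gone = ~active
        out.loc[gone, test_cols_by_wave[wave]] = np.nan
        out.loc[gone, f"age_w{wave}"] = np.nan
    return out


def write_cohort(cohort: pd.DataFrame, path, truth: SimTruth | None = None) -> None:
    cohort.to_csv(path, index=False, na_rep="")
    if truth is not None:
        sidecar = str(path).rsplit(".", 1)[0] + "_truth.json"
        with open(sidecar, "w") as fh:
            fh.write(truth.to_json())
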