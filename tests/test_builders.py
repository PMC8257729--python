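import numpy as np
import pandas as pd
import pytest

from svdgrowth.builders import (COVARIATE_STEPS, DOMAIN_MAP, GrowthStructure,
                                bifactor_spec, domain_tests, foc_spec,
                                prepare_analysis_frame, svd_cfa_spec,
                                vascular_cfa_spec, vascular_factor_scores)
from svdgrowth.fitting import fit, standardized_solution
from svdgrowth.likelihood import binary_marginal_prevalence
from svdgrowth.simulate import (DOMAINS, WAVES, default_truth, simulate_cohort)


def test_growth_structure_defaults_and_validation():
    g = GrowthStructure()
    assert g.wave_times == (0.0, 3.78, 6.83, 9.55)
    with pytest.raises(ValueError):
        GrowthStructure((1.0, 3.78, 6.83, 9.55))
    with pytest.raises(ValueError):
        GrowthStructure((0.0, 6.83, 3.78, 9.55))


def test_domain_map_membership():
    assert domain_tests("speed") == ["digit_symbol", "symbol_search",
                                     "inspection_time", "choice_rt"]
    assert len(domain_tests("general")) == 10
    assert set(domain_tests("general")) == set().union(*DOMAIN_MAP.values())
    with pytest.raises(ValueError):
        domain_tests("gardening")


def test_prepare_orients_and_standardizes(small_cohort):
    prep = prepare_analysis_frame(small_cohort)
    # baseline z-scores: mean 0, SD 1
    assert prep["z_digit_symbol_w2"].mean() == pytest.approx(0.0, abs=1e-10)
    assert prep["z_digit_symbol_w2"].std() == pytest.approx(1.0, abs=1e-10)
    # reaction time negated: higher raw RT must map to lower z
    rt = small_cohort["choice_rt_w2"]
    z = prep["z_choice_rt_w2"]
    assert np.corrcoef(rt, z)[0, 1] < -0.99
    # age columns centred per wave on observed ages
    assert prep["cage_w3"].mean() == pytest.approx(0.0, abs=1e-10)


def test_svd_cfa_structure_and_recovery():
    spec = svd_cfa_spec()
    assert len(spec.observed) == 4
    assert spec.latents == ["svd"]
    assert spec.binary_vars == ["lacunes", "microbleeds"]
    spec.validate()
    truth = default_truth("paper_foC", n_subjects=2000, seed=41)
    prep = prepare_analysis_frame(simulate_cohort(truth))
    res = fit(spec, prep, n_starts=2, compute_se=False)
    assert res.converged
    ss = standardized_solution(res.model, res.theta_t)
    for key in ("z_wmh=~svd", "z_pvs=~svd", "lacunes=~svd", "microbleeds=~svd"):
        assert ss[key] > 0.1, key
    prev = binary_marginal_prevalence(res.model, res.theta_t)
    assert prev["lacunes"] == pytest.approx(0.051, abs=0.015)
    assert prev["microbleeds"] == pytest.approx(0.120, abs=0.022)


def test_vascular_scores_determinism_and_recovery():
    truth = default_truth("paper_foC", n_subjects=2000, seed=42)
    coh = simulate_cohort(truth)
    prep = prepare_analysis_frame(coh)
    s1, fit1 = vascular_factor_scores(prep)
    s2, _ = vascular_factor_scores(prep)
    pd.testing.assert_series_equal(s1, s2)
    assert s1.mean() == pytest.approx(0.0, abs=1e-9)
    assert fit1.converged
    # identical indicator rows get identical scores
    cols = ["hypertension", "diabetes", "smoker", "z_hba1c", "z_chol", "z_sbp", "z_dbp"]
    dup = prep[cols].round(6).duplicated(keep=False)
    if dup.any():
        grp = prep[dup].groupby(prep[cols].round(6).apply(tuple, axis=1)).groups
        for _, idx in list(grp.items())[:3]:
            assert s1.loc[idx].std() == pytest.approx(0.0, abs=1e-9)
    # scores track the generating vascular liability: reconstruct via z_mht-free
    # proxy: correlation with the liability-driven indicators' sum
    proxy = prep[["z_hba1c", "z_sbp", "z_dbp"]].mean(axis=1)
    assert np.corrcoef(s1, proxy)[0, 1] > 0.7


@pytest.mark.parametrize("domain,n_tests", [("general", 10), ("speed", 4),
                                            ("memory", 3), ("visuospatial", 3)])
def test_foc_spec_structure(domain, n_tests):
    spec = foc_spec(domain, step="none", predictor="svd_latent")
    cog = [v for v in spec.observed if v.startswith("z_") and "_w" in v
           and v not in ("z_wmh", "z_pvs")]
    assert len(cog) == n_tests * 4
    # first-order latents: one intercept and one slope per test, plus the
    # second-order pair and the SVD factor
    assert sum(l.startswith("i_") for l in spec.latents) == n_tests
    assert sum(l.startswith("s_") for l in spec.latents) == n_tests
    assert {"G_i", "G_s", "svd"} <= set(spec.latents)
    spec.validate()
    # slope loadings fixed at span-scaled wave times
    unit = 9.55
    for w_idx, w in enumerate(WAVES):
        e = spec.lambda_[(cog[w_idx], f"s_{cog[0][2:-3]}")]
        assert not e.free


@pytest.mark.parametrize("step", COVARIATE_STEPS)
def test_foc_covariate_steps_nest(step):
    spec = foc_spec("speed", step=step, predictor="svd_latent")
    spec.validate()
    rank = COVARIATE_STEPS.index(step)
    assert ("sex" in spec.observed) == (rank >= 1)
    assert ("vascular_score" in spec.observed) == (rank >= 2)
    assert ("z_mht" in spec.observed) == (rank >= 3)
    # age wiring appears from step 1 on and never changes the cognitive block
    assert (len(spec.exog) > 0) == (rank >= 1)
    cog = [v for v in spec.observed if v.startswith("z_") and v.endswith(
        tuple(f"_w{w}" for w in WAVES)) and v not in ("z_wmh", "z_pvs")]
    assert len(cog) == 16


def test_foc_wmh_predictor_variant_all_continuous():
    spec = foc_spec("general", step="childhood", predictor="wmh_ratio")
    spec.validate()
    assert spec.binary_vars == []
    assert "wmhp" in spec.latents
    assert "z_pvs" not in spec.observed


def test_bifactor_structure_and_orthogonality():
    spec = bifactor_spec(step="none", predictor="svd_latent")
    spec.validate()
    second = [f"{f}_{io}" for f in ("g", "speed", "memory", "visuospatial")
              for io in ("i", "s")]
    assert set(second) <= set(spec.latents)
    # cross-factor covariances are fixed at zero (absent from Psi),
    # within-factor intercept-slope covariances free
    for f1 in ("g", "speed"):
        for f2 in ("memory", "visuospatial"):
            assert (f"{f1}_i", f"{f2}_i") not in spec.psi
    for f_ in ("g", "speed", "memory", "visuospatial"):
        assert spec.psi[(f"{f_}_i", f"{f_}_s")].free
        assert not spec.psi[(f"{f_}_i", f"{f_}_i")].free  # unit residual variance
    # every test loads on g and exactly one domain; svd predicts all eight
    svd_paths = [k for k, e in spec.beta.items() if k[1] == "svd" and e.free]
    assert len(svd_paths) == 8


def test_bifactor_degenerate_truth_matches_hierarchical_fit():
    """With zero domain-specific variance in truth, the bifactor's fitted
    domain slope loadings collapse toward zero and its SVD->general-slope
    path agrees with the hierarchical general-model fit within sampling
    error."""
    from svdgrowth.builders import canonicalize_bifactor_signs
    from svdgrowth.simulate import apply_attrition

    zero = dict.fromkeys(["speed", "memory", "visuospatial"], 0.0)
    truth = default_truth("paper_bifactor", seed=21, n_subjects=2000,
                          domain_intercept_sds=zero, domain_slope_sds=zero,
                          domain_slope_offsets=zero)
    prep = prepare_analysis_frame(apply_attrition(simulate_cohort(truth), truth))
    foc = fit(foc_spec("general", step="none", predictor="svd_latent", data=prep),
              prep, n_starts=1, compute_se=False)
    bif = fit(bifactor_spec(step="none", predictor="svd_latent", data=prep),
              prep, n_starts=1, compute_se=False)
    assert foc.converged and bif.converged
    canonicalize_bifactor_signs(bif)
    g_foc = standardized_solution(foc.model, foc.theta_t)["G_s~svd"]
    g_bif = standardized_solution(bif.model, bif.theta_t)["g_s~svd"]
    assert abs(g_foc - g_bif) < 0.08
    dom_sq = sum(v**2 for k, v in bif.estimates.items() if k.startswith("bd_s_"))
    assert dom_sq < 0.02  # implied domain slope contributions near zero


def test_every_builder_spec_passes_identification_validator():
    specs = [svd_cfa_spec(), vascular_cfa_spec()]
    for step in COVARIATE_STEPS:
        specs.append(foc_spec("memory", step=step, predictor="svd_latent"))
        specs.append(foc_spec("general", step=step, predictor="wmh_ratio"))
        specs.append(bifactor_spec(step=step))
    specs.append(foc_spec("visuospatial", step="none", predictor=None))
    for spec in specs:
        spec.validate()
        model = spec.compile()
        assert model.n_free > 0
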