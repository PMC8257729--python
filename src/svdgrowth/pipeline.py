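"""Config-driven orchestration: cohort I/O, measurement models, association grid.

The pipeline reproduces the study's full analysis plan on a cohort table:
covariate-free factor-of-curves measurement models per cognitive domain
(trajectory summaries), then the association grid of SVD-burden and
WMH-predictor factor-of-curves models and bifactor models across nested
covariate steps, with grouped FDR correction and (optionally) likelihood-ratio
comparisons against less-restrictive neighbour models.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import builders
from .builders import (COVARIATE_STEPS, DOMAIN_MAP, GrowthStructure, STEP_LABELS,
                       bifactor_spec, canonicalize_bifactor_signs, foc_spec,
                       prepare_analysis_frame, vascular_factor_scores)
from .fitting import FitResult, fit, standardized_solution
from .model import ModelSpec, free
from .simulate import (ALL_TESTS, TIME_LOADINGS, WAVES, apply_attrition,
                       default_truth, simulate_cohort, write_cohort)
from .stats import (LRTestResult, ResultRow, attach_fdr, lr_test, result_table,
                    slope_r2)

log = logging.getLogger("svdgrowth")

REQUIRED_COLUMNS = (
    [f"{t}_w{w}" for t in ALL_TESTS for w in WAVES]
    + [f"age_w{w}" for w in WAVES]
    + ["wmh_ratio", "pvs_count", "lacunes", "microbleeds",
       "hypertension", "diabetes", "smoker", "hba1c", "cholesterol", "sbp", "dbp",
       "sex", "mht_age11"]
)
OPTIONAL_COLUMNS = ("subject_id", "education_years")
BINARY_COLUMNS = ("lacunes", "microbleeds", "hypertension", "diabetes", "smoker", "sex")


@dataclass
class AnalysisConfig:
    """Validated configuration for one pipeline run."""

    cohort_csv: str | None = None
    scenario: str | None = "paper_foC"
    n_subjects: int = 540
    seed: int = 1
    wave_times: tuple[float, ...] = TIME_LOADINGS
    domains: tuple[str, ...] = ("general", "speed", "memory", "visuospatial")
    steps: tuple[str, ...] = COVARIATE_STEPS
    predictors: tuple[str, ...] = ("svd_latent", "wmh_ratio")
    wmh_transform: str = "log"
    with_bifactor: bool = True
    with_lr: bool = False
    n_starts: int = 1
    n_nodes: int = 21
    compute_se: bool = True
    output_dir: str = "results"

    def __post_init__(self):
        if self.cohort_csv is None and self.scenario is None:
            raise ValueError("config needs either cohort_csv or a simulation scenario")
        for s in self.steps:
            if s not in COVARIATE_STEPS:
                raise ValueError(f"unknown covariate step {s!r}")
        for p in self.predictors:
            if p not in builders.PREDICTORS:
                raise ValueError(f"unknown predictor {p!r}")
        GrowthStructure(tuple(self.wave_times))

    @staticmethod
    def from_yaml(path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("wave_times", "domains", "steps", "predictors"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return AnalysisConfig(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_cohort(path) -> pd.DataFrame:
    """Read and validate a wide cohort CSV (empty cell or 'NA' = missing)."""
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing[:8]}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + list(OPTIONAL_COLUMNS)]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
    for c in BINARY_COLUMNS:
        vals = df[c].dropna().unique()
        if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            raise ValueError(f"binary column {c!r} contains values outside 0/1")
    ages = df[[f"age_w{w}" for w in WAVES]].to_numpy(dtype=float)
    for i in range(ages.shape[0]):
        a = ages[i][~np.isnan(ages[i])]
        if np.any(np.diff(a) <= 0):
            raise ValueError(f"ages not strictly increasing for row {i}")
    for t in ALL_TESTS:
        cols = [f"{t}_w{w}" for w in WAVES]
        if df[cols].isna().all().all():
            raise ValueError(f"test {t!r} has no observed scores at any wave")
    return df


def get_cohort(config: AnalysisConfig) -> pd.DataFrame:
    if config.cohort_csv:
        return load_cohort(config.cohort_csv)
    truth = default_truth(config.scenario, seed=config.seed,
                          n_subjects=config.n_subjects)
    return apply_attrition(simulate_cohort(truth), truth)


def prepare(config: AnalysisConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Analysis frame incl. the vascular-risk factor score when any step needs it."""
    prep = prepare_analysis_frame(cohort, wmh_transform=config.wmh_transform)
    if any(builders._step_rank(s) >= 2 for s in config.steps):
        scores, _ = vascular_factor_scores(prep, n_nodes=config.n_nodes)
        prep["vascular_score"] = scores / scores.std()
    return prep


# ---------------------------------------------------------------------------

def run_measurement_models(config: AnalysisConfig, cohort: pd.DataFrame | None = None,
                           prepared: pd.DataFrame | None = None) -> dict:
    """Covariate-free FoC per domain: trajectory summaries in baseline-SD units."""
    if prepared is None:
        prepared = prepare(config, cohort if cohort is not None else get_cohort(config))
    growth = GrowthStructure(tuple(config.wave_times))
    unit = growth.wave_times[-1]
    out = {}
    for domain in config.domains:
        spec = foc_spec(domain, growth=growth, step="none", predictor=None, data=prepared)
        res = fit(spec, prepared, n_starts=config.n_starts, n_nodes=config.n_nodes,
                  compute_se=config.compute_se)
        if not res.converged:
            log.warning("measurement model for %s did not converge", domain)
            out[domain] = {"converged": False}
            continue
        est = res.estimates
        entry = {
            "converged": True,
            "decline_per_year": est["alpha_slope"] / unit,
            "slope_sd_per_year": float(np.sqrt(est["psi_Gs"])) / unit,
            "intercept_sd": float(np.sqrt(est["psi_Gi"])),
            "loglik": res.loglik,
            "n_used": res.n_used,
        }
        if res.se.get("alpha_slope") is not None:
            entry["decline_per_year_se"] = res.se["alpha_slope"] / unit
        out[domain] = entry
    return out


def _foc_rows(config, prepared, predictor, domain, step, growth) -> tuple[list[ResultRow], FitResult | None]:
    family = "foc_svd" if predictor == "svd_latent" else "foc_wmh"
    pred_name = "svd" if predictor == "svd_latent" else "wmh"
    lat = "svd" if predictor == "svd_latent" else "wmhp"
    spec = foc_spec(domain, growth=growth, step=step, predictor=predictor, data=prepared)
    res = fit(spec, prepared, n_starts=config.n_starts, n_nodes=config.n_nodes,
              compute_se=config.compute_se)
    rows = []
    if not res.converged:
        log.warning("FoC %s/%s/%s did not converge", predictor, domain, step)
        for oc in ("intercept", "slope"):
            rows.append(ResultRow(family=family, model=domain, step=step,
                                  outcome=f"{oc}({domain})", predictor=pred_name,
                                  beta_std=np.nan, se=None, ci_lo=np.nan, ci_hi=np.nan,
                                  p=np.nan, converged=False))
        return rows, None
    for oc, fac in (("intercept", "G_i"), ("slope", "G_s")):
        key = f"{fac}~{lat}"
        std = res.standardized.get(key)
        if std is None:
            ss = standardized_solution(res.model, res.theta_t)
            from .fitting import StdEstimate
            std = StdEstimate(ss[key], None)
        lo, hi = std.ci
        rows.append(ResultRow(
            family=family, model=domain, step=step, outcome=f"{oc}({domain})",
            predictor=pred_name, beta_std=std.est, se=std.se, ci_lo=lo, ci_hi=hi,
            p=std.p, r2_slope=slope_r2(res, "G_s", lat) if oc == "slope" else None,
            loglik=res.loglik,
        ))
    return rows, res


def _bifactor_rows(config, prepared, step, growth) -> tuple[list[ResultRow], FitResult | None]:
    spec = bifactor_spec(growth=growth, step=step, predictor="svd_latent", data=prepared)
    res = fit(spec, prepared, n_starts=config.n_starts, n_nodes=config.n_nodes,
              compute_se=config.compute_se)
    names = {"g": "general", "speed": "speed", "memory": "memory",
             "visuospatial": "visuospatial"}
    rows = []
    if not res.converged:
        log.warning("bifactor model at step %s did not converge", step)
        for f_, nm in names.items():
            for oc in ("intercept", "slope"):
                rows.append(ResultRow(family="bifactor", model="bifactor", step=step,
                                      outcome=f"{oc}({nm})", predictor="svd",
                                      beta_std=np.nan, se=None, ci_lo=np.nan,
                                      ci_hi=np.nan, p=np.nan, converged=False))
        return rows, None
    canonicalize_bifactor_signs(res)
    if config.compute_se:
        from .fitting import add_standard_errors
        from .likelihood import ModelData
        add_standard_errors(res, ModelData(res.model, prepared))
    for f_, nm in names.items():
        for oc, io in (("intercept", "i"), ("slope", "s")):
            key = f"{f_}_{io}~svd"
            std = res.standardized.get(key)
            if std is None:
                continue
            lo, hi = std.ci
            rows.append(ResultRow(
                family="bifactor", model="bifactor", step=step,
                outcome=f"{oc}({nm})", predictor="svd", beta_std=std.est, se=std.se,
                ci_lo=lo, ci_hi=hi, p=std.p,
                r2_slope=slope_r2(res, f"{f_}_s", "svd") if oc == "slope" else None,
                loglik=res.loglik,
            ))
    return rows, res


def correlational_neighbour(spec: ModelSpec, predictor_latent: str) -> ModelSpec:
    """Less-restrictive neighbour: the predictor additionally covaries freely
    with every first-order intercept/slope disturbance, relaxing the
    constraint that its association with the tests flows only through the
    second-order factors.  Nests the original model (labels are a superset)."""
    nb = ModelSpec.from_json(spec.to_json())
    nb.meta = dict(spec.meta)
    for lat in nb.latents:
        if lat.startswith(("i_", "s_")):
            nb.set_psi(lat, predictor_latent, free(f"covnb_{lat}_pred", 0.0))
    return nb


def run_association_grid(config: AnalysisConfig, cohort: pd.DataFrame | None = None,
                         prepared: pd.DataFrame | None = None) -> dict:
    """The full association grid; returns rows, per-model metadata, and tables."""
    if prepared is None:
        prepared = prepare(config, cohort if cohort is not None else get_cohort(config))
    growth = GrowthStructure(tuple(config.wave_times))
    rows: list[ResultRow] = []
    meta: dict[str, dict] = {}
    for predictor in config.predictors:
        for domain in config.domains:
            for step in config.steps:
                key = f"{predictor}:{domain}:{step}"
                r, res = _foc_rows(config, prepared, predictor, domain, step, growth)
                rows.extend(r)
                meta[key] = {"converged": res is not None,
                             "loglik": res.loglik if res else None,
                             "n_params": res.n_params if res else None}
                if res is not None and predictor == "wmh_ratio" and step == "none":
                    # absolute fit indices are available for the all-continuous
                    # WMH-predictor models (no exogenous regressors at this step)
                    try:
                        from .fitting import fit_baseline, fit_saturated
                        from .stats import fit_indices
                        cols = res.model.cont_vars
                        sat = fit_saturated(prepared, columns=cols)
                        base = fit_baseline(prepared, columns=cols)
                        fi = fit_indices(res, sat, base, n=res.n_used)
                        meta[key]["fit_indices"] = {
                            "rmsea": fi.rmsea, "cfi": fi.cfi,
                            "tli": fi.tli, "srmr": fi.srmr}
                    except Exception as exc:
                        log.warning("fit indices for %s failed: %s", key, exc)
                if (res is not None and config.with_lr and step == "none"
                        and predictor == "svd_latent"):
                    try:
                        nb_spec = correlational_neighbour(res.spec, "svd")
                        nb = fit(nb_spec, prepared, n_starts=config.n_starts,
                                 n_nodes=config.n_nodes, compute_se=False)
                        lr = lr_test(res, nb)
                        meta[key]["lr"] = {"stat": lr.lr_stat, "df": lr.df, "p": lr.p}
                    except Exception as exc:  # LR failure must not kill the grid
                        log.warning("LR for %s failed: %s", key, exc)
                        meta[key]["lr"] = {"error": str(exc)}
    if config.with_bifactor and "svd_latent" in config.predictors:
        for step in config.steps:
            r, res = _bifactor_rows(config, prepared, step, growth)
            rows.extend(r)
            meta[f"bifactor:{step}"] = {"converged": res is not None,
                                        "loglik": res.loglik if res else None,
                                        "n_params": res.n_params if res else None}
    attach_fdr(rows)
    return {"rows": rows, "meta": meta, "table": result_table(rows)}


# ---------------------------------------------------------------------------
# reporting

def write_report(grid: dict, out_dir, config: AnalysisConfig | None = None,
                 measurement: dict | None = None) -> None:
    """TSV + JSON result tables and a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table: pd.DataFrame = grid["table"]
    table.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.6g")
    doc = {
        "config": config.to_dict() if config else None,
        "measurement": measurement,
        "associations": table.to_dict(orient="records"),
        "models": grid["meta"],
    }
    with open(out / "results.json", "w") as fh:
        json.dump(doc, fh, indent=1, default=_json_default)
    lines = ["Association models", "=" * 60]
    if measurement:
        lines = ["Trajectory summaries (baseline-SD units per year)", "-" * 60] + [
            f"  {d}: decline/yr = {m.get('decline_per_year', float('nan')):+.3f}"
            + ("" if m.get("converged") else "  [NOT CONVERGED]")
            for d, m in measurement.items()
        ] + ["", *lines]
    for r in grid["rows"]:
        if not r.converged:
            lines.append(f"{r.family:9s} {r.model:12s} {STEP_LABELS.get(r.step, r.step):55s}"
                         f" {r.outcome:24s} NOT CONVERGED")
            continue
        se = f"({r.se:.2f})" if r.se is not None else "(--)"
        pfdr = f"{r.p_fdr:.3f}" if r.p_fdr is not None else "--"
        lines.append(
            f"{r.family:9s} {r.model:12s} {STEP_LABELS.get(r.step, r.step):55s} "
            f"{r.outcome:24s} beta={r.beta_std:+.3f} {se} "
            f"CI[{r.ci_lo:+.3f},{r.ci_hi:+.3f}] p={r.p:.3f} pFDR={pfdr}"
        )
    for key, m in grid["meta"].items():
        if "lr" in m and "stat" in m["lr"]:
            lines.append(f"LR {key}: stat={m['lr']['stat']:.2f} df={m['lr']['df']}"
                         f" p={m['lr']['p']:.3f}")
        if "fit_indices" in m:
            fi = m["fit_indices"]
            lines.append(f"Fit {key}: RMSEA={fi['rmsea']:.3f} CFI={fi['cfi']:.3f} "
                         f"TLI={fi['tli']:.3f} SRMR={fi['srmr']:.3f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def simulate_to_csv(scenario: str, n: int, seed: int, out_path) -> pd.DataFrame:
    truth = default_truth(scenario, seed=seed, n_subjects=n)
    cohort = apply_attrition(simulate_cohort(truth), truth)
    write_cohort(cohort, out_path, truth)
    return cohort
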