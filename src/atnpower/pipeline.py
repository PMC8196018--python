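"""Configuration-driven orchestration of the full analysis battery.

``run_full_analysis`` executes, on one synthetic cohort: baseline
descriptives with CN-vs-SCD group comparisons, the longitudinal
mixed-model battery (basic / A / T / N / ATN), the Cox conversion battery,
and the trial-enrichment battery over all screening schemes and both
endpoints.  All randomness flows from one global seed through a
counter-based child-seed scheme, so module-level reruns reproduce the
pipeline's numbers.  ``emit_report`` writes the bundle as CSV tables plus
a JSON manifest (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from . import __version__ as _version
from .cohort import Cohort, generate_cohort
from .config import GeneratorConfig, TrialDesign, paper_calibrated
from .enrichment import (
    EnrichmentScheme,
    bootstrap_ssdelta,
    fit_multivariable_scheme,
    subject_summary,
    threshold_sweep,
)
from .longitudinal import (
    LmmSpec,
    build_model_frame,
    compare_aic_lrt,
    fit_lmm,
    marginal_r2,
    model_r2_bootstrap,
)
from .preprocessing import compute_pacc, rate_matched_cutoff, transform_and_standardize
from .survival import CoxSpec, build_survival_frame, conversion_auc_bootstrap, fit_cox

__all__ = ["RunConfig", "run_full_analysis", "emit_report", "analysis_frame",
           "descriptives_table", "POSITIVITY_RATES"]

#: published plasma positivity rates used for the rate-matched cutoffs
POSITIVITY_RATES = {"plasma_ab42_40_z": 0.462, "plasma_ptau217_z": 0.372,
                    "plasma_nfl_z": 0.379}

_BIOMARKER_LABELS = {"plasma_ab42_40_z": "A", "plasma_ptau217_z": "T", "plasma_nfl_z": "N"}


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    preset: str = "paper_calibrated"
    generator: GeneratorConfig | None = None
    outcome: Literal["pacc", "mmse"] = "pacc"
    event: Literal["ad_dementia", "any_dementia"] = "ad_dementia"
    covariates: Literal["basic", "basic+apoe", "basic+scd"] = "basic"
    biomarker_source: Literal["plasma", "csf"] = "plasma"
    bootstrap_B: int = Field(default=200, ge=10)
    include_fraction: float = Field(default=0.30, gt=0, lt=1)
    run_r2_bootstrap: bool = False
    run_auc_bootstrap: bool = True
    run_sweep: bool = False
    seed: int = 0

    def generator_config(self) -> GeneratorConfig:
        if self.generator is not None:
            return self.generator
        if self.preset != "paper_calibrated":
            raise ValueError(f"unknown preset {self.preset!r}")
        return paper_calibrated(seed=child_seed(self.seed, 0))


def child_seed(global_seed: int, index: int) -> int:
    """Deterministic counter-based child seeds (documented scheme)."""
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % (2**31))


def analysis_frame(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    """Preprocess a cohort into the long modeling table (plus scalers).

    Transforms/standardizes biomarkers, builds the PACC, and merges subject
    covariates and event columns onto the visit rows.
    """
    std = transform_and_standardize(cohort.subjects)
    visits = compute_pacc(cohort.visits)
    frame = build_model_frame(cohort.subjects, visits, std.zscores)
    frame = frame.merge(cohort.events, on="subject_id")
    return frame, std.scalers


@dataclass
class ResultBundle:
    run_config: RunConfig
    generator_config: GeneratorConfig
    table1: pd.DataFrame | None = None
    table2_lmm: pd.DataFrame | None = None
    table3_cox: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    sweep: pd.DataFrame | None = None
    log: list = field(default_factory=list)
    completed: list = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "package_version": _version,
            "seed": self.run_config.seed,
            "config_hash": self.generator_config.config_hash(),
            "run_config": json.loads(self.run_config.model_dump_json(exclude={"generator"})),
            "completed_stages": self.completed,
            "log": self.log,
        }


#: CSF amyloid positivity rate used for the Youden reference contrast
CSF_ABETA_POSITIVITY = 1.0 - 350.0 / 435.0


def derive_youden_cutoffs(frame: pd.DataFrame) -> dict:
    """Youden-index plasma cutoffs from the cohort's conversion contrast.

    Cases are CU converters to AD dementia; controls are CSF-Abeta-negative
    CU nonconverters (CSF positivity rate-matched).  Returns analysis-scale
    cutoffs with provenance labels.  These document the cutoff operation;
    the screening analyses use the published positivity rates instead.
    """
    from .preprocessing import binarize, derive_youden_cutoff

    base = frame.drop_duplicates("subject_id").reset_index(drop=True)
    csf_cut = rate_matched_cutoff(base["csf_ab42_40_z"].dropna().to_numpy(),
                                  CSF_ABETA_POSITIVITY, "high", "csf_ab42_40_z")
    csf_neg = binarize(base["csf_ab42_40_z"].to_numpy(), csf_cut) == 0.0
    cases = base["ad_dementia"] == 1
    keep = cases | (csf_neg & ~cases)
    out = {}
    for colz in POSITIVITY_RATES:
        sub = base.loc[keep].dropna(subset=[colz])
        cut, j = derive_youden_cutoff(sub[colz].to_numpy(), sub["ad_dementia"].to_numpy(),
                                      direction="high")
        out[colz] = {"threshold_z": cut.threshold, "youden_j": j,
                     "provenance": "youden:cu_converters_vs_csf_abeta_negative"}
    return out


def _mean_sd(x: np.ndarray) -> str:
    x = x[np.isfinite(x)]
    return f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})"


def descriptives_table(cohort: Cohort, frame: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by diagnosis with CN-vs-SCD comparisons.

    Continuous rows use Welch t-tests, categorical rows chi-square tests;
    two-sided, no multiplicity adjustment (matching the convention of the
    source tables).
    """
    subj = cohort.subjects.merge(cohort.events, on="subject_id")
    base = frame[frame["time"] == 0].drop_duplicates("subject_id")
    subj = subj.merge(base[["subject_id", "pacc", "mmse"]], on="subject_id", how="left")
    cn = subj[subj["diagnosis"] == "CN"]
    scd = subj[subj["diagnosis"] == "SCD"]

    rows = []

    def cont(label, col):
        a, b = cn[col].to_numpy(float), scd[col].to_numpy(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        rows.append({"variable": label, "overall": _mean_sd(subj[col].to_numpy(float)),
                     "cn": _mean_sd(a), "scd": _mean_sd(b), "p_value": float(p),
                     "test": "welch_t"})

    def cat(label, indicator):
        tab = pd.crosstab(subj["diagnosis"], indicator)
        p = stats.chi2_contingency(tab).pvalue if tab.shape == (2, 2) else np.nan
        def fmt(d):
            k = int(indicator[d.index].sum())
            return f"{k} ({100 * k / len(d):.1f})"
        rows.append({"variable": label, "overall": fmt(subj), "cn": fmt(cn), "scd": fmt(scd),
                     "p_value": float(p), "test": "chi2"})

    rows.append({"variable": "n", "overall": str(len(subj)), "cn": str(len(cn)),
                 "scd": str(len(scd)), "p_value": np.nan, "test": ""})
    cont("Age, years", "age")
    cont("Education, years", "education")
    cat("Sex = male (%)", (subj["sex"] == "male"))
    cat("APOE e4 carrier (%)", subj["apoe4"].astype(bool))
    cont("MMSE, baseline", "mmse")
    cont("PACC, baseline", "pacc")
    cont("Follow-up time, years", "followup_years")
    cat("Converted to AD dementia (%)", subj["ad_dementia"].astype(bool))
    cat("Converted to any dementia (%)", subj["any_dementia"].astype(bool))
    for col, label in (("plasma_ab42_40", "Plasma Ab42/40"), ("plasma_ptau217", "Plasma P-tau217"),
                       ("plasma_nfl", "Plasma NfL"), ("csf_ab42_40", "CSF Ab42/40"),
                       ("csf_ptau181", "CSF P-tau181"), ("csf_nfl", "CSF NfL")):
        # analysis scale (log where applicable), as in the reference table
        from .cohort import RAW_SCALES

        if RAW_SCALES[col]["log"]:
            subj[f"_{col}"] = np.log(subj[col].to_numpy(float))
        else:
            subj[f"_{col}"] = subj[col]
        cn_, scd_ = subj[subj.diagnosis == "CN"], subj[subj.diagnosis == "SCD"]
        p = stats.ttest_ind(cn_[f"_{col}"], scd_[f"_{col}"], equal_var=False).pvalue
        rows.append({"variable": f"{label}, baseline", "overall": _mean_sd(subj[f"_{col}"].to_numpy()),
                     "cn": _mean_sd(cn_[f"_{col}"].to_numpy()), "scd": _mean_sd(scd_[f"_{col}"].to_numpy()),
                     "p_value": float(p), "test": "welch_t"})
    return pd.DataFrame(rows)


def _lmm_battery(frame: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    from .longitudinal import BIOMARKER_SETS

    source = "CSF" if cfg.biomarker_source == "csf" else ""
    models = ["none"] + [f"{source}{'-' if source else ''}{m}" if source else m
                          for m in ("A", "T", "N")]
    models.append("CSF" if source else "ATN")
    # common complete-case sample so AIC/LRT comparisons are valid
    frame = frame.dropna(subset=BIOMARKER_SETS[models[-1]])
    basic = fit_lmm(frame, LmmSpec(outcome=cfg.outcome, biomarkers="none",
                                   covariates=cfg.covariates))
    rows = []
    for i, model in enumerate(models):
        spec = LmmSpec(outcome=cfg.outcome, biomarkers=model, covariates=cfg.covariates)
        fit = basic if model == "none" else fit_lmm(frame, spec)
        cmp = compare_aic_lrt(basic, fit) if model != "none" else {
            "aic_delta": 0.0, "p_value": np.nan, "better_fit": False}
        r2m, r2c = marginal_r2(fit)
        row = {"model": "basic" if model == "none" else model,
               "aic": fit.aic, "aic_delta": cmp["aic_delta"],
               "anova_p": cmp["p_value"], "anova_method": "LRT(chi2)",
               "r2_marginal": r2m, "r2_conditional": r2c,
               "n_subjects": fit.n_subjects, "n_obs": fit.n_obs,
               "converged": fit.converged, "singular": fit.singular,
               "resid_normality_p": fit.normality_p}
        if cfg.run_r2_bootstrap:
            bs = model_r2_bootstrap(frame, spec, B=cfg.bootstrap_B,
                                    seed=child_seed(cfg.seed, 30 + i))
            row["r2_ci_lo"], row["r2_ci_hi"] = bs.ci
            row["r2_method"] = "bootstrap-percentile"
        from .longitudinal import BIOMARKER_SETS

        for colz in BIOMARKER_SETS[model if model != "none" else "none"]:
            beta, ci, p = fit.biomarker_time_effect(colz)
            lab = _BIOMARKER_LABELS.get(colz, colz)
            row[f"beta_{lab}"] = beta
            row[f"beta_{lab}_ci_lo"], row[f"beta_{lab}_ci_hi"] = ci
            row[f"beta_{lab}_p"] = p
            row[f"beta_{lab}_method"] = "Wald"
        rows.append(row)
    return pd.DataFrame(rows)


def _cox_battery(frame: pd.DataFrame, cfg: RunConfig, seed: int) -> pd.DataFrame:
    from .longitudinal import BIOMARKER_SETS

    models = ["none", "A", "T", "N", "ATN"]
    sframe = (frame.drop_duplicates("subject_id").reset_index(drop=True)
              .dropna(subset=BIOMARKER_SETS["ATN"]))
    basic = fit_cox(sframe, CoxSpec(event=cfg.event, biomarkers="none",
                                    covariates=cfg.covariates))
    rows = []
    for i, model in enumerate(models):
        spec = CoxSpec(event=cfg.event, biomarkers=model, covariates=cfg.covariates)
        fit = basic if model == "none" else fit_cox(sframe, spec)
        cmp = compare_aic_lrt(basic, fit) if model != "none" else {
            "aic_delta": 0.0, "p_value": np.nan}
        row = {"model": "basic" if model == "none" else model,
               "aic": fit.aic, "aic_delta": cmp["aic_delta"],
               "anova_p": cmp["p_value"], "anova_method": "LRT(chi2)",
               "n_events": fit.n_events, "n_subjects": fit.n_subjects}
        from .longitudinal import BIOMARKER_SETS

        for colz in BIOMARKER_SETS[model if model != "none" else "none"]:
            lab = _BIOMARKER_LABELS.get(colz, colz)
            row[f"hr_{lab}"] = float(fit.hazard_ratios[colz])
            row[f"hr_{lab}_ci_lo"] = float(fit.conf_int.loc[colz, 0])
            row[f"hr_{lab}_ci_hi"] = float(fit.conf_int.loc[colz, 1])
            row[f"hr_{lab}_p"] = float(fit.pvalues[colz])
            row[f"hr_{lab}_method"] = "Wald"
        if cfg.run_auc_bootstrap:
            auc = conversion_auc_bootstrap(sframe, spec, horizon_years=4.0,
                                           B=cfg.bootstrap_B, seed=child_seed(seed, 40 + i))
            row["auc"] = auc.point
            row["auc_ci_lo"], row["auc_ci_hi"] = auc.ci
            row["auc_method"] = "bootstrap-percentile"
        rows.append(row)
    return pd.DataFrame(rows)


def _enrichment_battery(frame: pd.DataFrame, scalers: dict, cfg: RunConfig,
                        seed: int) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    summary = subject_summary(frame)
    cuts = {
        colz: rate_matched_cutoff(summary[colz].dropna().to_numpy(), rate, "high", colz)
        for colz, rate in POSITIVITY_RATES.items()
    }
    rows, sweep_rows = [], []
    for j, endpoint in enumerate(("pacc_slope", "ad_conversion")):
        design = TrialDesign(endpoint=endpoint)
        schemes = [EnrichmentScheme(kind="none", label="none")]
        schemes += [
            EnrichmentScheme(kind="univariate", label=_BIOMARKER_LABELS[colz], cutoff=cut)
            for colz, cut in cuts.items()
        ]
        schemes.append(fit_multivariable_scheme(frame, endpoint,
                                                include_fraction=cfg.include_fraction))
        schemes.append(EnrichmentScheme(kind="scd_status", label="SCD"))
        for k, scheme in enumerate(schemes):
            res = bootstrap_ssdelta(summary, scheme, design, B=cfg.bootstrap_B,
                                    seed=child_seed(seed, 100 + 10 * j + k),
                                    event_col=cfg.event)
            rows.append({
                "endpoint": endpoint, "scheme": res.scheme,
                "n_unenriched": res.n_unenriched, "n_enriched": res.n_enriched,
                "ss_delta_pct": res.ss_delta, "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                "p_value": res.p_value, "p_label": res.p_label,
                "ci_method": "bootstrap-percentile",
                "screen_pass_fraction": res.screen_pass_fraction,
                "number_needed_to_screen": res.number_needed_to_screen,
                "B": res.B,
            })
        if cfg.run_sweep:
            for colz, cut in cuts.items():
                scheme = EnrichmentScheme(kind="univariate",
                                          label=_BIOMARKER_LABELS[colz], cutoff=cut)
                sw = threshold_sweep(summary, scheme, design, scalers,
                                     B=max(cfg.bootstrap_B // 2, 50),
                                     seed=child_seed(seed, 200 + 10 * j))
                part = sw.rows.copy()
                part.insert(0, "endpoint", endpoint)
                part.insert(1, "biomarker", _BIOMARKER_LABELS[colz])
                sweep_rows.append(part)
    sweep = pd.concat(sweep_rows, ignore_index=True) if sweep_rows else None
    return pd.DataFrame(rows), sweep


def run_full_analysis(cfg: RunConfig) -> ResultBundle:
    """Generate, preprocess and analyze one cohort end to end.

    Stages run in order (descriptives, mixed models, Cox models,
    enrichment); a failure aborts the stage but the bundle is still
    returned with a manifest of completed stages.
    """
    gen = cfg.generator_config()
    bundle = ResultBundle(run_config=cfg, generator_config=gen)
    cohort = generate_cohort(gen)
    frame, scalers = analysis_frame(cohort)
    bundle.completed.append("generate")
    stages = [
        ("table1", lambda: descriptives_table(cohort, frame)),
        ("table2_lmm", lambda: _lmm_battery(frame, cfg)),
        ("table3_cox", lambda: _cox_battery(frame, cfg, cfg.seed)),
        ("enrichment", lambda: _enrichment_battery(frame, scalers, cfg, cfg.seed)),
    ]
    for name, fn in stages:
        try:
            out = fn()
            if name == "enrichment":
                bundle.enrichment, bundle.sweep = out
            else:
                setattr(bundle, name, out)
            bundle.completed.append(name)
            bundle.log.append({"stage": name, "status": "ok"})
        except Exception as err:  # partial bundles are a documented outcome
            bundle.log.append({"stage": name, "status": "error", "error": str(err)})
            break
    return bundle


def emit_report(bundle: ResultBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as CSV tables plus a JSON manifest; idempotent."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise RuntimeError(f"output directory not writable: {outdir}") from err

    written = []
    for name in ("table1", "table2_lmm", "table3_cox", "enrichment", "sweep"):
        table = getattr(bundle, name)
        if table is None:
            continue
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    manifest = bundle.manifest()
    payload = json.dumps(manifest, indent=2, sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(path)
    return written
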