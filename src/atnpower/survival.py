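"""Cox proportional-hazards models of conversion to dementia.

Cause-specific Cox regression (Efron tie handling, via lifelines) with the
same covariate batteries as the longitudinal models; hazard ratios are per
SD of abnormality-oriented biomarker.  Discrimination is summarized as the
AUC for conversion within a fixed horizon (default 4 years), scoring
subjects by the fitted linear predictor and excluding non-events censored
before the horizon from the label set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.metrics import roc_auc_score

from .longitudinal import BIOMARKER_SETS, BootstrapSummary, ModelError

__all__ = ["CoxSpec", "CoxFit", "build_survival_frame", "fit_cox",
           "conversion_auc_bootstrap"]

_COVARIATE_SETS = {
    "basic": ["age_z", "male", "edu_z"],
    "basic+apoe": ["age_z", "male", "edu_z", "apoe4"],
    "basic+scd": ["age_z", "male", "edu_z", "scd"],
}


@dataclass(frozen=True)
class CoxSpec:
    event: str = "ad_dementia"  # or "any_dementia"
    biomarkers: str = "none"
    covariates: str = "basic"

    def predictors(self) -> list[str]:
        return _COVARIATE_SETS[self.covariates] + BIOMARKER_SETS[self.biomarkers]


@dataclass
class CoxFit:
    spec: CoxSpec
    hazard_ratios: pd.Series
    conf_int: pd.DataFrame  # HR scale
    pvalues: pd.Series
    coefs: pd.Series
    llf: float  # partial log-likelihood
    aic: float
    k_params: int
    n_events: int
    n_subjects: int
    n_obs: int
    ph_test_p: dict = field(default_factory=dict)
    fe_names: list[str] = field(default_factory=list)
    _fitter: CoxPHFitter | None = None

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.fe_names].to_numpy(dtype=float)
        return x @ self.coefs.reindex(self.fe_names).to_numpy()


def build_survival_frame(
    subjects: pd.DataFrame, events: pd.DataFrame, zscores: pd.DataFrame
) -> pd.DataFrame:
    """One row per subject: covariates, duration and event indicators."""
    subj = subjects.merge(zscores, on="subject_id").merge(events, on="subject_id")
    subj["age_z"] = (subj["age"] - subj["age"].mean()) / subj["age"].std(ddof=1)
    subj["edu_z"] = (subj["education"] - subj["education"].mean()) / subj["education"].std(ddof=1)
    subj["male"] = (subj["sex"] == "male").astype(float)
    subj["scd"] = (subj["diagnosis"] == "SCD").astype(float)
    return subj


def fit_cox(frame: pd.DataFrame, spec: CoxSpec) -> CoxFit:
    """Cox partial-likelihood fit with right censoring and Efron ties.

    Requires at least five events.  Complete separation surfaces as a
    lifelines convergence failure and is re-raised naming the covariate
    with the most extreme coefficient.
    """
    cols = spec.predictors()
    data = frame.dropna(subset=cols).copy()
    n_events = int(data[spec.event].sum())
    if n_events == 0:
        raise ModelError("no events observed")
    if n_events < 5:
        raise ModelError(f"too few events for a Cox fit ({n_events} < 5)")

    model = CoxPHFitter()
    sub = data[cols + ["time_to_event_years", spec.event]]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(sub, duration_col="time_to_event_years", event_col=spec.event)
    except ConvergenceError as err:
        raise ModelError(f"Cox fit failed to converge (possible separation): {err}") from err
    coefs = model.params_
    if np.any(np.abs(coefs) > 15):
        worst = coefs.abs().idxmax()
        raise ModelError(f"complete separation suspected for covariate '{worst}'")

    ph_p = {}
    try:
        from lifelines.statistics import proportional_hazard_test

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(model, sub, time_transform="rank")
        ph_p = {str(k): float(v) for k, v in ph.summary["p"].items()}
    except Exception:  # diagnostic only; never fail the fit
        pass

    ci = np.exp(model.confidence_intervals_)
    ci.columns = [0, 1]
    return CoxFit(
        spec=spec,
        hazard_ratios=np.exp(coefs),
        conf_int=ci,
        pvalues=model.summary["p"].copy(),
        coefs=coefs.copy(),
        llf=float(model.log_likelihood_),
        aic=float(model.AIC_partial_),
        k_params=len(cols),
        n_events=n_events,
        n_subjects=int(len(data)),
        n_obs=int(len(data)),
        ph_test_p=ph_p,
        fe_names=cols,
        _fitter=model,
    )


def horizon_labels(frame: pd.DataFrame, event: str, horizon: float) -> pd.Series:
    """Binary conversion-within-horizon labels.

    Events at or before the horizon are positive; subjects censored before
    the horizon without an event carry no label (NaN) and are excluded from
    AUC computation -- the documented fixed-horizon convention.
    """
    t = frame["time_to_event_years"].to_numpy(dtype=float)
    e = frame[event].to_numpy(dtype=float)
    label = np.where(
        (e == 1) & (t <= horizon), 1.0,
        np.where(t >= horizon, 0.0, np.nan),
    )
    return pd.Series(label, index=frame.index, name="label")


def conversion_auc_bootstrap(
    frame: pd.DataFrame,
    spec: CoxSpec,
    horizon_years: float = 4.0,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """AUC of the Cox linear predictor for conversion within the horizon.

    The point estimate scores the full cohort with the full-cohort fit; each
    bootstrap resample of subjects refits the model and scores itself
    (apparent AUC), giving a percentile CI.
    """
    full = fit_cox(frame, spec)
    labels = horizon_labels(frame, spec.event, horizon_years)
    mask = labels.notna()
    if labels[mask].sum() < 5:
        raise ModelError("fewer than 5 events within the horizon")
    point = float(roc_auc_score(labels[mask], full.linear_predictor(frame[mask])))

    rng = np.random.default_rng(seed)
    n = len(frame)
    vals, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = frame.iloc[idx].reset_index(drop=True)
        blab = horizon_labels(boot, spec.event, horizon_years)
        bmask = blab.notna()
        try:
            bfit = fit_cox(boot, spec)
            if blab[bmask].nunique() < 2:
                raise ModelError("single-class resample")
            vals.append(float(roc_auc_score(blab[bmask], bfit.linear_predictor(boot[bmask]))))
        except (ModelError, ValueError):
            failures += 1
    if failures > 0.10 * B:
        raise ModelError(f"bootstrap failures: {failures}/{B}")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapSummary("auc", point, (float(lo), float(hi)), B, seed,
                            n_failures=failures, samples=np.asarray(vals))
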