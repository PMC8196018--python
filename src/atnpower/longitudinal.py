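"""Linear mixed-effects models of longitudinal cognition.

Models follow the analysis battery of the cohort study: outcome (PACC or
MMSE) against time with random intercepts and slopes (unstructured 2x2
covariance), a basic covariate set (age, sex, education, each with a main
effect and a time interaction), and biomarkers added singly or together.
All fits use maximum likelihood (not REML) so AIC differences and
likelihood-ratio comparisons across nested fixed-effect sets are coherent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LmmSpec",
    "LmmFit",
    "BootstrapSummary",
    "build_model_frame",
    "fit_lmm",
    "model_r2_bootstrap",
    "compare_aic_lrt",
    "ModelError",
    "BIOMARKER_SETS",
]


class ModelError(RuntimeError):
    pass


#: biomarker set label -> list of z-score columns entering the model
BIOMARKER_SETS = {
    "none": [],
    "A": ["plasma_ab42_40_z"],
    "T": ["plasma_ptau217_z"],
    "N": ["plasma_nfl_z"],
    "ATN": ["plasma_ab42_40_z", "plasma_ptau217_z", "plasma_nfl_z"],
    "CSF": ["csf_ab42_40_z", "csf_ptau181_z", "csf_nfl_z"],
    "CSF-A": ["csf_ab42_40_z"],
    "CSF-T": ["csf_ptau181_z"],
    "CSF-N": ["csf_nfl_z"],
}

_COVARIATE_SETS = {
    "basic": ["age_z", "male", "edu_z"],
    "basic+apoe": ["age_z", "male", "edu_z", "apoe4"],
    "basic+scd": ["age_z", "male", "edu_z", "scd"],
}


@dataclass(frozen=True)
class LmmSpec:
    """Specification of one mixed-model fit."""

    outcome: str = "pacc"  # "pacc" or "mmse"
    biomarkers: str = "none"  # key of BIOMARKER_SETS
    covariates: str = "basic"  # key of _COVARIATE_SETS
    interact_covariates_with_time: bool = True

    def predictors(self) -> list[str]:
        return _COVARIATE_SETS[self.covariates] + BIOMARKER_SETS[self.biomarkers]


@dataclass
class LmmFit:
    """Fixed effects, variance components and fit statistics of one LME."""

    spec: LmmSpec
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    cov_re: np.ndarray  # 2x2 random intercept/slope covariance
    sigma2: float  # residual variance
    llf: float
    aic: float
    k_params: int
    n_subjects: int
    n_obs: int
    converged: bool
    singular: bool
    normality_p: float
    fe_names: list[str] = field(default_factory=list)
    _design: tuple | None = None  # (exog, endog, groups, times) kept for R2

    def biomarker_time_effect(self, column: str) -> tuple[float, tuple[float, float], float]:
        """(beta, 95% CI, P) of a biomarker-by-time interaction, points/yr/SD."""
        name = f"{column}:time"
        return (
            float(self.params[name]),
            (float(self.conf_int.loc[name, 0]), float(self.conf_int.loc[name, 1])),
            float(self.pvalues[name]),
        )

    @property
    def random_intercept_sd(self) -> float:
        return float(np.sqrt(self.cov_re[0, 0]))

    @property
    def random_slope_sd(self) -> float:
        return float(np.sqrt(self.cov_re[1, 1]))

    @property
    def intercept_slope_corr(self) -> float:
        denom = np.sqrt(self.cov_re[0, 0] * self.cov_re[1, 1])
        return float(self.cov_re[0, 1] / denom) if denom > 0 else 0.0


def build_model_frame(
    subjects: pd.DataFrame, visits: pd.DataFrame, zscores: pd.DataFrame
) -> pd.DataFrame:
    """Long-format modeling table: one row per visit with subject covariates.

    Demographics are standardized against the cohort; ``male``/``apoe4``/
    ``scd`` are 0/1 indicators; biomarker columns are the abnormality-
    oriented z-scores.
    """
    subj = subjects.merge(zscores, on="subject_id")
    subj["age_z"] = (subj["age"] - subj["age"].mean()) / subj["age"].std(ddof=1)
    subj["edu_z"] = (subj["education"] - subj["education"].mean()) / subj["education"].std(ddof=1)
    subj["male"] = (subj["sex"] == "male").astype(float)
    subj["scd"] = (subj["diagnosis"] == "SCD").astype(float)
    keep = ["subject_id", "age_z", "male", "edu_z", "apoe4", "scd"] + [
        c for c in subj.columns if c.endswith("_z") and c not in ("age_z", "edu_z")
    ]
    frame = visits.merge(subj[keep], on="subject_id")
    return frame.rename(columns={"time_years": "time"})


def _design_matrix(frame: pd.DataFrame, spec: LmmSpec) -> tuple[np.ndarray, list[str]]:
    cols = {"Intercept": np.ones(len(frame)), "time": frame["time"].to_numpy()}
    for pred in spec.predictors():
        cols[pred] = frame[pred].to_numpy(dtype=float)
    for pred in spec.predictors():
        if spec.interact_covariates_with_time or pred in BIOMARKER_SETS[spec.biomarkers]:
            cols[f"{pred}:time"] = cols[pred] * cols["time"]
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def fit_lmm(frame: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """Fit one mixed model by ML with random intercepts and slopes.

    A singular unstructured random-effects covariance triggers a refit with
    the intercept-slope correlation pinned to zero (diagonal covariance),
    with the fallback recorded on the returned fit.  Residual normality is
    summarized with a D'Agostino-Pearson test (diagnostic only).
    """
    data = frame.dropna(subset=[spec.outcome, "time"] + spec.predictors()).copy()
    counts = data.groupby("subject_id")["time"].count()
    if (counts >= 2).sum() == 0:
        raise ModelError("no subject has two or more visits")

    exog, names = _design_matrix(data, spec)
    endog = data[spec.outcome].to_numpy(dtype=float)
    groups = data["subject_id"].to_numpy()
    exog_re = np.column_stack([np.ones(len(data)), data["time"].to_numpy()])

    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    fit, singular = _robust_fit(model)

    cov_re = np.asarray(fit.cov_re, dtype=float)
    k = len(names) + (3 if not singular else 2) + 1  # FE + RE cov + residual
    resid = np.asarray(fit.resid, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm_p = float(stats.normaltest(resid).pvalue) if resid.size >= 20 else float("nan")

    params = pd.Series(np.asarray(fit.fe_params, dtype=float), index=names)
    ci = pd.DataFrame(
        np.asarray(fit.conf_int())[: len(names)], index=names, columns=[0, 1]
    )
    pvals = pd.Series(np.asarray(fit.pvalues)[: len(names)], index=names)

    return LmmFit(
        spec=spec,
        params=params,
        conf_int=ci,
        pvalues=pvals,
        cov_re=cov_re,
        sigma2=float(fit.scale),
        llf=float(fit.llf),
        aic=2.0 * k - 2.0 * float(fit.llf),
        k_params=k,
        n_subjects=int(data["subject_id"].nunique()),
        n_obs=int(len(data)),
        converged=bool(fit.converged),
        singular=singular,
        normality_p=norm_p,
        fe_names=names,
        _design=(exog, endog, groups, data["time"].to_numpy()),
    )


def _robust_fit(model):
    """ML fit with optimizer fallbacks; diagonal RE covariance as last resort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            cov = np.asarray(fit.cov_re)
            if fit.converged and np.all(np.isfinite(cov)) and np.linalg.det(cov) > 1e-10:
                return fit, False
        # diagonal covariance: free pattern with zero intercept-slope covariance
        free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
            fe_params=np.ones(model.exog.shape[1]), cov_re=np.eye(2)
        )
        fit = model.fit(reml=False, free=free, maxiter=500)
        if not np.all(np.isfinite(np.asarray(fit.fe_params))):
            raise ModelError("mixed model failed to converge")
        return fit, True


def marginal_r2(fit: LmmFit) -> tuple[float, float]:
    """(marginal, conditional) R2 by fixed/random variance partitioning.

    Marginal R2 is the share of outcome variance carried by the fixed
    effects; conditional R2 adds the random-effect variance evaluated at
    the observed visit times.
    """
    exog, endog, groups, times = fit._design
    var_f = float(np.var(exog @ fit.params.to_numpy(), ddof=0))
    c = fit.cov_re
    var_re = float(
        c[0, 0] + 2.0 * c[0, 1] * np.mean(times) + c[1, 1] * np.mean(times**2)
    )
    total = var_f + var_re + fit.sigma2
    return var_f / total, (var_f + var_re) / total


@dataclass
class BootstrapSummary:
    statistic: str
    point: float
    ci: tuple[float, float]
    B: int
    seed: int
    n_failures: int = 0
    samples: np.ndarray | None = None


def model_r2_bootstrap(
    frame: pd.DataFrame, spec: LmmSpec, B: int = 1000, seed: int = 0
) -> BootstrapSummary:
    """Marginal R2 with a percentile CI from resampling subjects.

    Subjects (not observations) are drawn with replacement; each resample is
    refit and its marginal R2 recorded.  More than 5% failed refits aborts.
    """
    full = fit_lmm(frame, spec)
    point, _ = marginal_r2(full)
    if full.sigma2 < 1e-12 and full.cov_re.max() < 1e-12:
        return BootstrapSummary("r2", point, (point, point), B, seed)

    rng = np.random.default_rng(seed)
    ids = frame["subject_id"].unique()
    grouped = dict(tuple(frame.groupby("subject_id")))
    vals, failures = [], 0
    for _ in range(B):
        draw = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for j, sid in enumerate(draw):
            part = grouped[sid].copy()
            part["subject_id"] = f"B{j}"
            parts.append(part)
        boot = pd.concat(parts, ignore_index=True)
        try:
            bfit = fit_lmm(boot, spec)
            vals.append(marginal_r2(bfit)[0])
        except (ModelError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.05 * B:
        raise ModelError(f"bootstrap refit failures: {failures}/{B}")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapSummary("r2", point, (float(lo), float(hi)), B, seed,
                            n_failures=failures, samples=np.asarray(vals))


def compare_aic_lrt(fit_basic, fit_extended) -> dict:
    """AIC difference and likelihood-ratio comparison of nested ML fits.

    Returns AIC_delta = AIC(extended) - AIC(basic), the LRT statistic
    2*(llf_ext - llf_basic) with a chi-square P on the parameter-count
    difference, and better_fit = (AIC_delta <= -2), the conventional
    meaningful-improvement threshold.
    """
    names_a, names_b = set(fit_basic.fe_names), set(fit_extended.fe_names)
    if not names_a <= names_b:
        raise ModelError("models are not nested (fixed effects are not a superset)")
    if fit_basic.n_obs != fit_extended.n_obs:
        raise ModelError("models were fit on different data")
    lrt = 2.0 * (fit_extended.llf - fit_basic.llf)
    df = fit_extended.k_params - fit_basic.k_params
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(max(lrt, 0.0), df))
    aic_delta = fit_extended.aic - fit_basic.aic
    return {
        "aic_delta": float(aic_delta),
        "lrt": float(lrt),
        "df": int(df),
        "p_value": p,
        "better_fit": bool(aic_delta <= -2.0),
    }
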