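"""Synthetic cognitively-unimpaired cohort generator.

Produces three relational tables (subjects, visits, events) with the
statistical structure the downstream analyses assume:

* three correlated plasma biomarkers plus correlated CSF analogues, drawn
  from a joint latent Gaussian on the abnormality scale and decorated onto
  raw assay scales;
* linear latent PACC trajectories with bivariate-normal random effects and
  biomarker/demographic fixed effects, observed through four cognitive
  component scores (MMSE, ADAS delayed recall, animal fluency, TMT-B);
* proportional-hazards conversion to AD dementia with a competing non-AD
  dementia process, right-censored at the end of follow-up.

Everything is driven by a single :class:`~atnpower.config.GeneratorConfig`
and a seed; identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BIOMARKERS, ConfigError, GeneratorConfig

__all__ = [
    "generate_cohort",
    "simulate_visits",
    "simulate_conversion",
    "Cohort",
    "RAW_SCALES",
    "PACC_WEIGHTS",
]

#: PACC component weights (delayed recall double-weighted)
PACC_WEIGHTS = {"mmse": 1.0, "adas_delayed_recall": 2.0, "animal_fluency": 1.0, "tmt_b": 1.0}

#: raw-scale decoration of the latent abnormality scores.  ``loc``/``scale``
#: are on the analysis scale (natural-log for every marker except plasma
#: Abeta42/40), matching the published baseline descriptives; ``sign`` is -1
#: where the raw scale runs opposite to abnormality (amyloid ratios).
RAW_SCALES = {
    "plasma_ab42_40": {"log": False, "loc": 66.08, "scale": 7.28, "sign": -1},
    "plasma_ptau217": {"log": True, "loc": 4.97, "scale": 0.81, "sign": +1},
    "plasma_nfl": {"log": True, "loc": 7.59, "scale": 0.46, "sign": +1},
    "csf_ab42_40": {"log": True, "loc": 7.13, "scale": 0.50, "sign": -1},
    "csf_ptau181": {"log": True, "loc": 2.96, "scale": 0.40, "sign": +1},
    "csf_nfl": {"log": True, "loc": 6.79, "scale": 0.45, "sign": +1},
}

_COMPONENT_MAPS = {
    # component -> (mean, sd, flip, lo, hi, decimals)  on the raw test scale
    "mmse": (28.80, 1.21, +1, 0.0, 30.0, 0),
    "adas_delayed_recall": (3.00, 1.50, -1, 0.0, 12.0, 1),
    "animal_fluency": (21.0, 5.5, +1, 0.0, None, 0),
    "tmt_b": (90.0, 35.0, -1, 10.0, None, 0),
}


@dataclass
class Cohort:
    """Bundle of the three relational tables plus the generating config."""

    subjects: pd.DataFrame
    visits: pd.DataFrame
    events: pd.DataFrame
    config: GeneratorConfig


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _generate_subjects(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    n_scd = int(round(n * config.prop_scd))
    diagnosis = np.array(["CN"] * (n - n_scd) + ["SCD"] * n_scd)
    rng.shuffle(diagnosis)
    is_scd = diagnosis == "SCD"

    age = rng.normal(config.age_mean, config.age_sd, n) + config.age_scd_shift * is_scd
    age = np.clip(age, 55.0, 100.0)
    education = np.clip(rng.normal(config.education_mean, config.education_sd, n), 5.0, 25.0)
    male = rng.random(n) < config.prop_male

    # joint plasma/CSF abnormality latents
    cov = config.latent_cov()
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(6))
    z6 = rng.standard_normal((n, 6)) @ chol.T
    z6[:, :3] += np.asarray(config.scd_biomarker_shift) * is_scd[:, None]
    z6[:, 3:] += np.asarray(config.scd_biomarker_shift) * is_scd[:, None] * np.sqrt(
        np.asarray(config.csf_plasma_corr)
    )
    z_plasma, z_csf = z6[:, :3], z6[:, 3:]

    # APOE e4 assigned from a logistic model in amyloid/tau abnormality so
    # carriers are enriched for pathology; intercepts hit the group rates.
    wa, wt = config.apoe4_biomarker_weights
    lin = wa * z_plasma[:, 0] + wt * z_plasma[:, 1]
    apoe = np.zeros(n, dtype=bool)
    for group, target in ((~is_scd, config.prop_apoe4_cn), (is_scd, config.prop_apoe4_scd)):
        if group.sum() == 0:
            continue
        b0 = _logit_intercept(lin[group], target)
        p = 1.0 / (1.0 + np.exp(-(b0 + lin[group])))
        apoe[group] = rng.random(group.sum()) < p

    followup = rng.normal(config.followup_mean, config.followup_sd, n)
    followup = followup + config.followup_scd_shift * is_scd
    if config.dropout_rate > 0:
        followup = np.minimum(followup, rng.exponential(1.0 / config.dropout_rate, n))
    followup = np.clip(followup, config.followup_min, config.followup_max)

    # latent trajectory: analysis-scale parameters scaled to the latent scale
    s = config.latent_scale()
    gamma = config.direct_slope_effects()
    beta0 = config.direct_baseline_effects()
    d_sl = np.asarray(config.demog_slope_effects)
    d_b0 = np.asarray(config.demog_baseline_effects)
    age_z = (age - config.age_mean) / config.age_sd
    edu_z = (education - config.education_mean) / config.education_sd

    re_cov = np.array(
        [
            [config.random_intercept_sd**2,
             config.intercept_slope_corr * config.random_intercept_sd * config.random_slope_sd],
            [config.intercept_slope_corr * config.random_intercept_sd * config.random_slope_sd,
             config.random_slope_sd**2],
        ]
    )
    u = rng.multivariate_normal([0.0, 0.0], re_cov, size=n, method="cholesky")

    slope = (
        config.mean_slope
        + z_plasma @ gamma
        + d_sl[0] * age_z + d_sl[1] * male + d_sl[2] * edu_z
        + config.scd_slope_offset * is_scd
        + u[:, 1]
    ) * s * config.slope_calibration
    intercept = (
        z_plasma @ beta0
        + d_b0[0] * age_z + d_b0[1] * male + d_b0[2] * edu_z
        + config.scd_baseline_offset * is_scd
        + u[:, 0]
    ) * s

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": np.round(age, 2),
            "sex": np.where(male, "male", "female"),
            "education": np.round(education, 2),
            "apoe4": apoe.astype(int),
            "diagnosis": diagnosis,
            "followup_years": np.round(followup, 3),
            # analysis-scale latent slope (the trajectory the observed
            # composite tracks, net of the decoration calibration)
            "true_slope": slope / (s * config.slope_calibration),
        }
    )
    for j, name in enumerate(BIOMARKERS):
        df[f"plasma_{name}"] = _decorate(f"plasma_{name}", z_plasma[:, j])
        df[f"csf_{name if name != 'ptau217' else 'ptau181'}"] = _decorate(
            f"csf_{name if name != 'ptau217' else 'ptau181'}", z_csf[:, j]
        )
    df.attrs["latent_intercept"] = intercept
    df.attrs["latent_slope"] = slope
    return df


def _logit_intercept(lin: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(b0 + lin)) = target by bisection."""
    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + lin)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _decorate(column: str, z: np.ndarray) -> np.ndarray:
    spec = RAW_SCALES[column]
    analysis = spec["loc"] + spec["scale"] * spec["sign"] * z
    raw = np.exp(analysis) if spec["log"] else analysis
    return np.round(np.maximum(raw, 1e-6), 6)


def simulate_visits(
    subjects: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Longitudinal cognitive component scores on the scheduled visit grid.

    Each subject's latent PACC is linear in time; the four component scores
    share the latent visit-level value plus component noise constructed
    orthogonal to the PACC weighting, so the reconstructed composite tracks
    the latent trajectory without extra attenuation.
    """
    times = np.asarray(config.visit_times, dtype=float)
    if times.size == 0:
        raise ConfigError("visit_times is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])

    if "latent_intercept" not in subjects.attrs:
        raise ConfigError("subjects table was not produced by this generator/config")
    intercept = np.asarray(subjects.attrs["latent_intercept"], dtype=float)
    slope = np.asarray(subjects.attrs["latent_slope"], dtype=float)
    followup = subjects["followup_years"].to_numpy()

    keep = times[None, :] <= followup[:, None] + 1e-9
    keep[:, 0] = True  # baseline visit always exists
    subj_idx, visit_idx = np.nonzero(keep)
    t = times[visit_idx]
    n_rows = t.size

    latent = intercept[subj_idx] + slope[subj_idx] * t
    latent = latent + rng.normal(0.0, config.residual_sd * config.latent_scale(), n_rows)

    w = np.asarray(list(PACC_WEIGHTS.values()))
    e = rng.normal(0.0, config.component_noise_sd, (n_rows, 4))
    d = e - np.outer(e @ w / float(w @ w), w)  # weighted component noise sums to zero

    out = {"subject_id": subjects["subject_id"].to_numpy()[subj_idx], "time_years": t}
    for k, comp in enumerate(PACC_WEIGHTS):
        mean, sd, flip, lo, hi, dec = _COMPONENT_MAPS[comp]
        raw = mean + sd * flip * (latent + d[:, k])
        raw = np.clip(raw, lo, hi if hi is not None else np.inf)
        out[comp] = np.round(raw, dec) if dec else np.round(raw).astype(float)
    out["pacc"] = np.full(n_rows, np.nan)
    return pd.DataFrame(out)


def simulate_conversion(
    subjects: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Time-to-dementia events under proportional hazards with censoring.

    AD dementia follows a constant-baseline-hazard model whose linear
    predictor is the direct per-SD log-hazard vector plus an SCD offset; a
    competing NfL-weighted process generates non-AD dementia.  The first
    event within follow-up wins; everyone else is censored at last
    follow-up.
    """
    if config.baseline_hazard < 0 or config.allcause_extra_hazard < 0:
        raise ConfigError("hazards must be non-negative")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    z = _analysis_z(subjects)
    is_scd = (subjects["diagnosis"] == "SCD").to_numpy()
    eta = config.direct_log_hr()
    rate_ad = config.baseline_hazard * np.exp(z @ eta + config.scd_log_hazard * is_scd)
    rate_na = config.allcause_extra_hazard * np.exp(
        config.allcause_nfl_loghr * z[:, 2] + config.allcause_scd_log_hazard * is_scd
    )

    t_ad = _exp_times(rate_ad, rng)
    t_na = _exp_times(rate_na, rng)
    followup = subjects["followup_years"].to_numpy()

    first = np.minimum(t_ad, t_na)
    observed = first <= followup
    time = np.where(observed, first, followup)
    ad = observed & (t_ad <= t_na)
    anyd = observed

    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "time_to_event_years": np.round(time, 4),
            "ad_dementia": ad.astype(int),
            "any_dementia": anyd.astype(int),
        }
    )


def _exp_times(rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exponential event times; zero rate means the event never occurs."""
    u = rng.random(rate.shape)
    with np.errstate(divide="ignore"):
        return np.where(rate > 0, -np.log1p(-u) / np.where(rate > 0, rate, 1.0), np.inf)


def _analysis_z(subjects: pd.DataFrame) -> np.ndarray:
    """Recover abnormality-oriented z-scores from the raw plasma columns."""
    cols = []
    for name in BIOMARKERS:
        spec = RAW_SCALES[f"plasma_{name}"]
        raw = subjects[f"plasma_{name}"].to_numpy()
        analysis = np.log(raw) if spec["log"] else raw
        cols.append(spec["sign"] * (analysis - spec["loc"]) / spec["scale"])
    return np.column_stack(cols)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort (subjects, visits, events).

    Deterministic for a fixed config+seed.  Visits falling after a subject's
    dementia conversion are removed (cognitive follow-up stops at clinical
    conversion), mirroring how the real cohort is censored.
    """
    rng_subjects = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    subjects = _generate_subjects(config, rng_subjects)
    events = simulate_conversion(subjects, config)
    visits = simulate_visits(subjects, config)

    converted = events.set_index("subject_id")
    ev_time = converted.loc[visits["subject_id"], "time_to_event_years"].to_numpy()
    ev_flag = converted.loc[visits["subject_id"], "any_dementia"].to_numpy()
    drop = (ev_flag == 1) & (visits["time_years"].to_numpy() > ev_time + 1e-9)
    drop &= visits["time_years"].to_numpy() > 0  # baseline always kept
    visits = visits.loc[~drop].reset_index(drop=True)

    return Cohort(subjects=subjects, visits=visits, events=events, config=config)
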