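"""Required-sample-size computation for biomarker-screened prevention trials.

A two-arm 1:1 trial aims to slow PACC decline, or to reduce the hazard of
conversion to AD dementia, by a fraction ``effect`` over ``duration`` years
at a target power.  Screening schemes (none / univariate biomarker cutoff /
multivariable risk score / SCD status) restrict the randomized population;
the enrichment yield is SS_delta = 1 - N_enriched / N_unenriched, with a
subject-level bootstrap for confidence intervals and a tail-probability P.

Sample-size machinery:

* cognitive-slope endpoint -- mixed-model slope-difference formula::

      n/arm = 2 (z_{1-a/2} + z_pow)^2 sigma_eff^2 / (effect * |mean slope|)^2
      sigma_eff^2 = Var(subject slopes) + sigma_resid^2 / S_xx(design visits)

* conversion endpoint -- Schoenfeld event count with expected event
  probabilities from the screened population's Kaplan-Meier curve::

      d = 4 (z_{1-a/2} + z_pow)^2 / ln(1 - effect)^2
      N  = 2 * ceil(d / (p_control + p_treated))

Endpoint parameters are estimated with a deliberately lightweight two-stage
estimator (per-subject OLS slopes with a method-of-moments variance
partition; KM for event probabilities) so that the B=1000 bootstrap stays
cheap; both formulas are validated against Monte-Carlo power simulations in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .config import ConfigError, TrialDesign
from .preprocessing import CutoffSet

__all__ = [
    "EnrichmentScheme",
    "EnrichmentResult",
    "ThresholdSweepResult",
    "SlopeParams",
    "estimate_slope_params",
    "slope_trial_n",
    "event_trial_n",
    "km_event_prob",
    "fit_multivariable_scheme",
    "apply_scheme",
    "enrich_and_reduce",
    "bootstrap_ssdelta",
    "threshold_sweep",
    "EnrichmentError",
]

MIN_SCREENED = 20


class EnrichmentError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# endpoint parameter estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlopeParams:
    """Trajectory parameters of a (sub)population for trial design."""

    mean_slope: float
    slope_var: float
    resid_var: float
    n_subjects: int


def _subject_slopes(times: np.ndarray, values: np.ndarray, starts: np.ndarray) -> tuple:
    """Vectorized per-subject OLS slopes over a ragged visit layout.

    ``starts`` delimits subjects in the flat arrays.  Returns (slopes, sxx,
    rss, dof) with NaN slopes for subjects with fewer than two usable
    visits.
    """
    n = len(starts) - 1
    slopes = np.full(n, np.nan)
    sxx = np.full(n, np.nan)
    rss = np.zeros(n)
    dof = np.zeros(n, dtype=int)
    for i in range(n):
        t = times[starts[i]:starts[i + 1]]
        y = values[starts[i]:starts[i + 1]]
        ok = np.isfinite(y)
        t, y = t[ok], y[ok]
        if t.size < 2 or np.ptp(t) == 0:
            continue
        tc = t - t.mean()
        s = float(tc @ tc)
        b = float(tc @ y) / s
        a = float(y.mean())
        slopes[i], sxx[i] = b, s
        if t.size > 2:
            r = y - a - b * tc
            rss[i] = float(r @ r)
            dof[i] = t.size - 2
    return slopes, sxx, rss, dof


def estimate_slope_params(visits: pd.DataFrame, outcome: str = "pacc") -> SlopeParams:
    """Two-stage estimate of (mean slope, slope variance, residual variance).

    Stage 1 fits per-subject OLS slopes; stage 2 averages them and removes
    the average estimation variance (residual variance over S_xx) from their
    spread, the standard method-of-moments partition.  Residual variance is
    pooled over subjects with three or more visits.
    """
    v = visits.sort_values(["subject_id", "time_years"], kind="mergesort")
    codes, _ = pd.factorize(v["subject_id"], sort=False)
    starts = np.searchsorted(codes, np.arange(codes.max() + 2))
    slopes, sxx, rss, dof = _subject_slopes(
        v["time_years"].to_numpy(float), v[outcome].to_numpy(float), starts
    )
    ok = np.isfinite(slopes)
    if ok.sum() < 3:
        raise EnrichmentError("too few subjects with >=2 visits to estimate slopes")
    if dof.sum() == 0:
        raise EnrichmentError("no subject has >=3 visits; residual variance inestimable")
    resid_var = float(rss.sum() / dof.sum())
    mean_slope = float(np.mean(slopes[ok]))
    raw_var = float(np.var(slopes[ok], ddof=1))
    slope_var = max(raw_var - resid_var * float(np.mean(1.0 / sxx[ok])), 0.0)
    return SlopeParams(mean_slope, slope_var, resid_var, int(ok.sum()))


def km_event_prob(events: pd.DataFrame, horizon: float, event_col: str = "ad_dementia") -> float:
    """Kaplan-Meier probability of conversion by ``horizon`` years."""
    if events[event_col].sum() == 0:
        raise EnrichmentError("event rate inestimable: zero events in subpopulation")
    km = KaplanMeierFitter()
    km.fit(events["time_to_event_years"], events[event_col])
    return float(1.0 - km.predict(horizon))


# ---------------------------------------------------------------------------
# sample-size formulas
# ---------------------------------------------------------------------------


def slope_trial_n(params: SlopeParams, design: TrialDesign) -> int:
    """Total randomized N for the cognitive-slope endpoint (both arms)."""
    if params.mean_slope >= 0:
        raise EnrichmentError("non-declining population: cognitive endpoint undefined")
    if params.resid_var <= 0 and params.slope_var <= 0:
        raise EnrichmentError("nonpositive variance estimates")
    delta = design.effect * abs(params.mean_slope)
    sigma_eff2 = params.slope_var + params.resid_var / design.sxx()
    n_arm = 2.0 * (design.z_alpha() + design.z_power()) ** 2 * sigma_eff2 / delta**2
    return 2 * math.ceil(n_arm)


def event_trial_n(p_control: float, design: TrialDesign) -> int:
    """Total randomized N for the conversion endpoint (Schoenfeld events)."""
    if not 0 < p_control <= 1:
        raise EnrichmentError("control-arm event probability must be in (0, 1]")
    d = 4.0 * (design.z_alpha() + design.z_power()) ** 2 / math.log(1.0 - design.effect) ** 2
    p_treat = 1.0 - (1.0 - p_control) ** (1.0 - design.effect)
    p_bar = 0.5 * (p_control + p_treat)
    return 2 * math.ceil(d / (2.0 * p_bar))


# ---------------------------------------------------------------------------
# screening schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentScheme:
    """A screening rule mapping a subject table to an inclusion mask.

    ``univariate`` thresholds one abnormality z-score; ``multivariable``
    thresholds a fixed linear risk score (coefficients fitted once on the
    screening sample); ``scd_status`` includes the SCD group; ``none``
    includes everyone.
    """

    kind: str  # none | univariate | multivariable | scd_status | random
    label: str = ""
    cutoff: CutoffSet | None = None  # univariate (z-scale, direction "high")
    score_columns: tuple[str, ...] = ()
    score_coefs: tuple[float, ...] = ()
    score_threshold: float = float("nan")
    include_fraction: float = float("nan")
    random_fraction: float = 0.5  # only for the null "random" scheme
    random_seed: int = 0

    def __post_init__(self):
        if self.kind == "univariate" and self.cutoff is None:
            raise ConfigError("univariate scheme requires exactly one biomarker cutoff")


def fit_multivariable_scheme(
    frame: pd.DataFrame,
    endpoint: str,
    include_fraction: float = 0.30,
    covariates: tuple[str, ...] = ("age_z", "male", "edu_z"),
    biomarkers: tuple[str, ...] = ("plasma_ab42_40_z", "plasma_ptau217_z", "plasma_nfl_z"),
) -> EnrichmentScheme:
    """Fit the combined screening model and freeze it as a scheme.

    For the cognitive endpoint the score is the predicted decline rate from
    regressing per-subject OLS slopes on demographics + biomarkers; for the
    conversion endpoint it is the Cox linear predictor of the basic+ATN
    model.  The threshold admits the ``include_fraction`` highest-risk
    subjects of the screening sample and is then fixed.
    """
    cols = list(covariates) + list(biomarkers)
    if endpoint == "pacc_slope":
        per = _per_subject_slope_table(frame)
        data = per.dropna(subset=["slope"] + cols)
        x = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in cols])
        coef, *_ = np.linalg.lstsq(x, data["slope"].to_numpy(float), rcond=None)
        score_coefs = -coef[1:]  # higher score = faster predicted decline
    elif endpoint == "ad_conversion":
        from .survival import CoxSpec, fit_cox

        spec = CoxSpec(event="ad_dementia", biomarkers="ATN", covariates="basic")
        fit = fit_cox(frame.drop_duplicates("subject_id"), spec)
        score_coefs = fit.coefs.reindex(cols).to_numpy()
    else:
        raise ConfigError(f"unknown endpoint {endpoint!r}")

    base = frame.drop_duplicates("subject_id").dropna(subset=cols)
    scores = base[cols].to_numpy(float) @ np.asarray(score_coefs, float)
    thr = float(np.quantile(scores, 1.0 - include_fraction))
    return EnrichmentScheme(
        kind="multivariable",
        label=f"combined:{endpoint}",
        score_columns=tuple(cols),
        score_coefs=tuple(float(c) for c in score_coefs),
        score_threshold=thr,
        include_fraction=include_fraction,
    )


def _per_subject_slope_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Subject-level table with OLS PACC slopes plus baseline covariates."""
    return _as_summary(frame)


def apply_scheme(subjects: pd.DataFrame, scheme: EnrichmentScheme) -> np.ndarray:
    """Boolean inclusion mask over a subject-level table."""
    if scheme.kind == "none":
        return np.ones(len(subjects), dtype=bool)
    if scheme.kind == "scd_status":
        return (subjects["scd"] == 1).to_numpy()
    if scheme.kind == "random":
        rng = np.random.default_rng(scheme.random_seed)
        return rng.random(len(subjects)) < scheme.random_fraction
    if scheme.kind == "univariate":
        vals = subjects[scheme.cutoff.biomarker].to_numpy(float)
        if scheme.cutoff.direction == "high":
            return np.nan_to_num(vals, nan=-np.inf) > scheme.cutoff.threshold
        return np.nan_to_num(vals, nan=np.inf) < scheme.cutoff.threshold
    if scheme.kind == "multivariable":
        x = subjects[list(scheme.score_columns)].to_numpy(float)
        scores = x @ np.asarray(scheme.score_coefs, float)
        return np.nan_to_num(scores, nan=-np.inf) > scheme.score_threshold
    raise ConfigError(f"unknown scheme kind {scheme.kind!r}")


# ---------------------------------------------------------------------------
# enrichment computation
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    scheme: str
    endpoint: str
    n_unenriched: int
    n_enriched: int
    ss_delta: float  # percent
    screen_pass_fraction: float
    number_needed_to_screen: float
    ci: tuple[float, float] | None = None
    p_value: float | None = None
    p_label: str = ""
    B: int = 0
    seed: int = 0
    samples: np.ndarray | None = None


def subject_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Subject-level summary sufficient for every enrichment computation.

    One row per subject carrying baseline covariates/scores/events plus the
    per-subject OLS slope statistics (slope, S_xx, residual sum of squares
    and degrees of freedom).  These statistics are invariant under subject
    resampling, which makes the bootstrap a cheap indexing exercise.
    """
    v = frame.sort_values(["subject_id", "time"], kind="mergesort")
    codes, ids = pd.factorize(v["subject_id"], sort=False)
    starts = np.searchsorted(codes, np.arange(codes.max() + 2))
    slopes, sxx, rss, dof = _subject_slopes(
        v["time"].to_numpy(float), v["pacc"].to_numpy(float), starts
    )
    per = v.drop_duplicates("subject_id").set_index("subject_id").loc[ids].reset_index()
    per["slope"] = slopes
    per["slope_sxx"] = sxx
    per["slope_rss"] = rss
    per["slope_dof"] = dof
    return per


def _slope_params_from_summary(summary: pd.DataFrame) -> SlopeParams:
    ok = np.isfinite(summary["slope"].to_numpy(float))
    if ok.sum() < 3:
        raise EnrichmentError("too few subjects with >=2 visits to estimate slopes")
    dof = summary["slope_dof"].to_numpy(float)
    if dof.sum() == 0:
        raise EnrichmentError("no subject has >=3 visits; residual variance inestimable")
    resid_var = float(summary["slope_rss"].sum() / dof.sum())
    slopes = summary.loc[ok, "slope"].to_numpy(float)
    raw_var = float(np.var(slopes, ddof=1))
    mean_inv_sxx = float(np.mean(1.0 / summary.loc[ok, "slope_sxx"].to_numpy(float)))
    slope_var = max(raw_var - resid_var * mean_inv_sxx, 0.0)
    return SlopeParams(float(np.mean(slopes)), slope_var, resid_var, int(ok.sum()))


def _required_n(summary: pd.DataFrame, design: TrialDesign,
                event_col: str = "ad_dementia") -> int:
    if design.endpoint == "pacc_slope":
        return slope_trial_n(_slope_params_from_summary(summary), design)
    p = km_event_prob(summary, design.duration, event_col)
    return event_trial_n(p, design)


def _as_summary(frame: pd.DataFrame) -> pd.DataFrame:
    if "slope" in frame.columns and "slope_sxx" in frame.columns:
        return frame
    return subject_summary(frame)


def enrich_and_reduce(
    frame: pd.DataFrame, scheme: EnrichmentScheme, design: TrialDesign,
    event_col: str = "ad_dementia",
) -> EnrichmentResult:
    """Point estimate of the screening-induced sample-size reduction.

    ``frame`` is either the long modeling table (one row per visit, subject
    covariates and event columns merged in) or a precomputed
    :func:`subject_summary`.  Endpoint parameters are re-estimated on the
    screened subpopulation; N counts randomized subjects only
    (screen-failures are reported through ``number_needed_to_screen``).
    """
    summary = _as_summary(frame)
    mask = apply_scheme(summary, scheme)
    if scheme.kind != "none" and mask.sum() < MIN_SCREENED:
        raise EnrichmentError(f"screen too strict: {int(mask.sum())} subjects pass")

    n_full = _required_n(summary, design, event_col)
    n_enr = n_full if scheme.kind == "none" else _required_n(summary[mask], design, event_col)
    frac = float(mask.mean())
    return EnrichmentResult(
        scheme=scheme.label or scheme.kind,
        endpoint=design.endpoint,
        n_unenriched=n_full,
        n_enriched=n_enr,
        ss_delta=100.0 * (1.0 - n_enr / n_full),
        screen_pass_fraction=frac,
        number_needed_to_screen=(n_enr / frac if frac > 0 else float("inf")),
    )


def bootstrap_ssdelta(
    frame: pd.DataFrame,
    scheme: EnrichmentScheme,
    design: TrialDesign,
    B: int = 1000,
    seed: int = 0,
    event_col: str = "ad_dementia",
) -> EnrichmentResult:
    """SS_delta with percentile CI and bootstrap P over subject resamples.

    Subjects are resampled with replacement; the (fixed) scheme is
    re-applied and the endpoint parameters re-estimated per resample.  The
    P-value is the two-sided tail probability of SS_delta <= 0, floored at
    1/B (reported as "< 1/B" via ``p_label``).
    """
    summary = _as_summary(frame)
    point = enrich_and_reduce(summary, scheme, design, event_col)
    rng = np.random.default_rng(seed)
    n = len(summary)

    vals, failures = [], 0
    for _ in range(B):
        boot = summary.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        try:
            mask = apply_scheme(boot, scheme)
            if scheme.kind != "none" and mask.sum() < MIN_SCREENED:
                raise EnrichmentError("screen too strict in resample")
            nf = _required_n(boot, design, event_col)
            ne = nf if scheme.kind == "none" else _required_n(boot[mask], design, event_col)
            vals.append(100.0 * (1.0 - ne / nf))
        except EnrichmentError:
            failures += 1
    if failures > 0.10 * B:
        raise EnrichmentError(f"bootstrap resample failures: {failures}/{B}")

    vals_arr = np.asarray(vals)
    lo, hi = np.percentile(vals_arr, [2.5, 97.5])
    tail = float(np.mean(vals_arr <= 0.0))
    p = max(min(2.0 * tail, 1.0), 1.0 / B)
    point.ci = (float(lo), float(hi))
    point.p_value = p
    point.p_label = f"< {1.0 / B:g}" if tail == 0.0 else f"{p:.4g}"
    point.B = B
    point.seed = seed
    point.samples = vals_arr
    return point


@dataclass
class ThresholdSweepResult:
    biomarker: str
    endpoint: str
    rows: pd.DataFrame  # pct_shift, threshold, ss_delta, ci_lo, ci_hi, significant


def threshold_sweep(
    frame: pd.DataFrame,
    scheme: EnrichmentScheme,
    design: TrialDesign,
    scalers: dict,
    grid_pct: tuple[float, ...] = (-20, -15, -10, -5, 0, 5, 10, 15, 20),
    B: int = 200,
    seed: int = 0,
) -> ThresholdSweepResult:
    """Univariate-threshold sensitivity sweep (+-20% of the reference cutoff).

    The shift is applied on the raw assay scale (multiplying the raw cutoff
    by 1 + pct/100) and mapped back to the analysis z-scale through the
    stored standardization, matching how an assay-level cutoff drift would
    propagate.  Points whose screen passes fewer than 20 subjects are
    recorded as missing rather than fatal.
    """
    if scheme.kind != "univariate":
        raise ConfigError("threshold sweep applies to univariate schemes")
    summary = _as_summary(frame)
    cut = scheme.cutoff
    name = cut.biomarker.removesuffix("_z")
    sc = scalers[name]
    sign = -1.0 if sc["direction"] == "low" else 1.0
    analysis_cut = sc["mean"] + sc["sd"] * sign * cut.threshold  # invert orientation
    raw_cut = math.exp(analysis_cut) if sc["log"] else analysis_cut

    rows = []
    for k, pct in enumerate(grid_pct):
        raw = raw_cut * (1.0 + pct / 100.0)
        analysis = math.log(raw) if sc["log"] else raw
        z = sign * (analysis - sc["mean"]) / sc["sd"]
        shifted = replace(scheme, cutoff=CutoffSet(
            biomarker=cut.biomarker, threshold=float(z), direction=cut.direction,
            provenance=f"{cut.provenance}|shift:{pct:+g}%"),
            label=f"{scheme.label}@{pct:+g}%")
        try:
            res = bootstrap_ssdelta(summary, shifted, design, B=B, seed=seed + k)
            rows.append({"pct_shift": pct, "threshold_z": float(z),
                         "ss_delta": res.ss_delta, "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                         "significant": bool(res.ci[0] > 0.0),
                         "screen_pass_fraction": res.screen_pass_fraction})
        except EnrichmentError:
            rows.append({"pct_shift": pct, "threshold_z": float(z), "ss_delta": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "significant": False,
                         "screen_pass_fraction": np.nan})
    return ThresholdSweepResult(cut.biomarker, design.endpoint, pd.DataFrame(rows))
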