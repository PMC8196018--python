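"""Sample-size formulas, screening schemes and bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest

from atnpower.config import TrialDesign
from atnpower.enrichment import (
    EnrichmentError,
    EnrichmentScheme,
    SlopeParams,
    bootstrap_ssdelta,
    enrich_and_reduce,
    event_trial_n,
    fit_multivariable_scheme,
    km_event_prob,
    slope_trial_n,
    subject_summary,
    threshold_sweep,
)
from atnpower.preprocessing import CutoffSet

# ---------------------------------------------------------------------------
# Monte-Carlo power oracles
# ---------------------------------------------------------------------------


def simulate_slope_trial_power(n_total, params, design, n_sims=1500, seed=0):
    """Fraction of simulated trials rejecting H0 at the computed N.

    Each trial randomizes n_total/2 per arm, draws subject slopes (treated
    slopes slowed by the design effect), observes noisy visits on the design
    schedule, and compares per-subject OLS slopes between arms with a
    two-sample t-test.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    t = np.asarray(design.visit_times)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    n_arm = n_total // 2
    rejections = 0
    for _ in range(n_sims):
        mu_c = params.mean_slope
        mu_t = params.mean_slope * (1 - design.effect)
        slopes_c = rng.normal(mu_c, np.sqrt(params.slope_var), n_arm)
        slopes_t = rng.normal(mu_t, np.sqrt(params.slope_var), n_arm)
        # per-subject OLS slope = true slope + residual-driven noise
        noise_sd = np.sqrt(params.resid_var / sxx)
        est_c = slopes_c + rng.normal(0, noise_sd, n_arm)
        est_t = slopes_t + rng.normal(0, noise_sd, n_arm)
        p = stats.ttest_ind(est_c, est_t).pvalue
        rejections += p < design.alpha
    return rejections / n_sims


def simulate_event_trial_power(n_total, p_control, design, n_sims=800, seed=0):
    """Log-rank rejection rate at the computed N under proportional hazards."""
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(seed)
    lam_c = -np.log(1 - p_control) / design.duration
    lam_t = lam_c * (1 - design.effect)
    n_arm = n_total // 2
    rejections = 0
    for _ in range(n_sims):
        tc = rng.exponential(1 / lam_c, n_arm)
        tt = rng.exponential(1 / lam_t, n_arm)
        ec, et = tc <= design.duration, tt <= design.duration
        res = logrank_test(np.minimum(tc, design.duration), np.minimum(tt, design.duration),
                           ec, et)
        rejections += res.p_value < design.alpha
    return rejections / n_sims


# ---------------------------------------------------------------------------
# formula behavior
# ---------------------------------------------------------------------------


def test_doubling_delta_quarters_the_per_arm_n():
    design = TrialDesign()
    p1 = SlopeParams(-0.2, 0.09, 0.16, 400)
    p2 = SlopeParams(-0.4, 0.09, 0.16, 400)
    n1, n2 = slope_trial_n(p1, design), slope_trial_n(p2, design)
    assert n1 / 4 - 2 <= n2 <= n1 / 4 + 2  # exact up to per-arm ceiling


def test_slope_formula_matches_power_simulation():
    """Rejection rate at the computed N is within 3 points of the target."""
    design = TrialDesign(effect=0.3, power=0.8)
    for params, seed in [
        (SlopeParams(-0.4, 1.0 - 0.16 / 8, 0.16, 400), 1),  # sigma_eff ~ 1
        (SlopeParams(-0.5, 0.20, 0.25, 400), 2),
        (SlopeParams(-0.3, 0.10, 0.36, 400), 3),
    ]:
        n = slope_trial_n(params, design)
        power = simulate_slope_trial_power(n, params, design, seed=seed)
        assert power == pytest.approx(design.power, abs=0.03)


def test_event_formula_matches_power_simulation():
    """Schoenfeld N achieves the target log-rank power, within 3 points."""
    design = TrialDesign(endpoint="ad_conversion")
    for p_control, seed in [(1.0, 1), (0.5, 2), (0.25, 3)]:
        n = event_trial_n(min(p_control, 0.999999), design)
        power = simulate_event_trial_power(n, min(p_control, 0.999999), design,
                                           seed=seed)
        assert power == pytest.approx(design.power, abs=0.03)


def test_everyone_converts_reduces_to_schoenfeld_event_count():
    import math

    design = TrialDesign(endpoint="ad_conversion")
    d = 4 * (design.z_alpha() + design.z_power()) ** 2 / math.log(0.7) ** 2
    n = event_trial_n(1.0, design)
    # p_treat < 1, so N slightly exceeds the bare event count d
    assert d <= n <= 1.1 * d + 4


def test_required_n_diverges_as_effect_vanishes():
    params = SlopeParams(-0.3, 0.1, 0.2, 400)
    sizes = [slope_trial_n(params, TrialDesign(effect=e)) for e in (0.5, 0.3, 0.2, 0.1, 0.05)]
    assert all(a < b for a, b in zip(sizes, sizes[1:]))
    ev = [event_trial_n(0.3, TrialDesign(endpoint="ad_conversion", effect=e))
          for e in (0.5, 0.3, 0.2, 0.1, 0.05)]
    assert all(a < b for a, b in zip(ev, ev[1:]))


def test_non_declining_population_is_refused():
    with pytest.raises(EnrichmentError, match="non-declining"):
        slope_trial_n(SlopeParams(0.05, 0.1, 0.2, 100), TrialDesign())


# ---------------------------------------------------------------------------
# schemes and SS_delta
# ---------------------------------------------------------------------------


def test_identity_scheme_gives_zero_reduction(preset_analysis):
    _, _, summary = preset_analysis
    for endpoint in ("pacc_slope", "ad_conversion"):
        res = enrich_and_reduce(summary, EnrichmentScheme(kind="none"),
                                TrialDesign(endpoint=endpoint))
        assert res.ss_delta == 0.0
        assert res.n_enriched == res.n_unenriched


def test_ssdelta_invariant_to_row_order(preset_analysis):
    frame, _, summary = preset_analysis
    design = TrialDesign()
    scheme = fit_multivariable_scheme(frame, "pacc_slope", include_fraction=0.25)
    a = enrich_and_reduce(summary, scheme, design).ss_delta
    shuffled = summary.sample(frac=1.0, random_state=5).reset_index(drop=True)
    b = enrich_and_reduce(shuffled, scheme, design).ss_delta
    assert a == pytest.approx(b, abs=1e-9)


def test_random_screen_has_null_mean_reduction(preset_analysis):
    """Uninformative screens yield SS_delta scattered around zero."""
    _, _, summary = preset_analysis
    design = TrialDesign()
    vals = [
        enrich_and_reduce(
            summary,
            EnrichmentScheme(kind="random", label="null", random_fraction=0.4,
                             random_seed=s),
            design,
        ).ss_delta
        for s in range(60)
    ]
    assert abs(np.mean(vals)) < 6.0  # Monte-Carlo noise around 0


def test_null_screen_false_significance_rate(preset_analysis):
    """CI-excludes-zero happens at roughly the nominal 5% under the null."""
    _, _, summary = preset_analysis
    design = TrialDesign()
    sig = 0
    reps = 40
    for s in range(reps):
        scheme = EnrichmentScheme(kind="random", label="null", random_fraction=0.4,
                                  random_seed=1000 + s)
        res = bootstrap_ssdelta(summary, scheme, design, B=150, seed=s)
        sig += res.ci[0] > 0.0 or res.ci[1] < 0.0
    assert sig / reps <= 0.18  # ~5% nominal with generous MC slack


def test_strict_screen_is_refused(preset_analysis):
    _, _, summary = preset_analysis
    cut = CutoffSet(biomarker="plasma_ptau217_z", threshold=50.0, direction="high")
    scheme = EnrichmentScheme(kind="univariate", label="T", cutoff=cut)
    with pytest.raises(EnrichmentError, match="too strict"):
        enrich_and_reduce(summary, scheme, TrialDesign())


def test_bootstrap_brackets_point_and_orders_ci(preset_analysis):
    frame, _, summary = preset_analysis
    scheme = fit_multivariable_scheme(frame, "pacc_slope", include_fraction=0.25)
    res = bootstrap_ssdelta(summary, scheme, TrialDesign(), B=200, seed=9)
    assert res.ci[0] <= res.ss_delta <= res.ci[1]
    assert res.p_value <= 0.05
    assert res.B == 200


def test_degenerate_screen_selecting_everyone(preset_analysis):
    """A screen passing every subject has an exactly degenerate bootstrap."""
    _, _, summary = preset_analysis
    cut = CutoffSet(biomarker="plasma_ptau217_z", threshold=-50.0, direction="high")
    scheme = EnrichmentScheme(kind="univariate", label="all", cutoff=cut)
    res = bootstrap_ssdelta(summary, scheme, TrialDesign(), B=50, seed=1)
    assert res.ss_delta == 0.0
    assert res.ci == (0.0, 0.0)


def test_sweep_single_point_reproduces_bootstrap(preset_analysis):
    frame, scalers, summary = preset_analysis
    vals = summary["plasma_ptau217_z"].dropna().to_numpy()
    thr = float(np.quantile(vals, 1 - 0.372))
    cut = CutoffSet(biomarker="plasma_ptau217_z", threshold=thr, direction="high")
    scheme = EnrichmentScheme(kind="univariate", label="T", cutoff=cut)
    sw = threshold_sweep(summary, scheme, TrialDesign(), scalers, grid_pct=(0,),
                         B=100, seed=3)
    direct = bootstrap_ssdelta(summary, scheme, TrialDesign(), B=100, seed=3)
    row = sw.rows.iloc[0]
    assert row["pct_shift"] == 0
    assert row["ss_delta"] == pytest.approx(direct.ss_delta, abs=1e-9)
    assert (row["ci_lo"], row["ci_hi"]) == pytest.approx(direct.ci, abs=1e-9)


def test_sweep_stricter_thresholds_do_not_weaken_enrichment(preset_analysis):
    """Across the +-20% grid, stricter inclusion tends to larger SS_delta."""
    frame, scalers, summary = preset_analysis
    vals = summary["plasma_ptau217_z"].dropna().to_numpy()
    thr = float(np.quantile(vals, 1 - 0.372))
    cut = CutoffSet(biomarker="plasma_ptau217_z", threshold=thr, direction="high")
    scheme = EnrichmentScheme(kind="univariate", label="T", cutoff=cut)
    sw = threshold_sweep(summary, scheme, TrialDesign(), scalers,
                         grid_pct=(-20, -10, 0, 10, 20), B=80, seed=2)
    rows = sw.rows.dropna(subset=["ss_delta"])
    # P-tau217 is log-scaled, so +pct raw shifts = stricter cutoffs
    corr = np.corrcoef(rows["pct_shift"], rows["ss_delta"])[0, 1]
    assert corr > 0.0
    assert rows["significant"].any()


def test_km_event_prob_agrees_with_direct_count():
    """No censoring before the horizon: KM equals the empirical fraction."""
    n = 400
    rng = np.random.default_rng(12)
    t = rng.exponential(5.0, n)
    ev = pd.DataFrame({
        "subject_id": np.arange(n).astype(str),
        "time_to_event_years": np.minimum(t, 10.0),
        "ad_dementia": (t <= 10.0).astype(int),
    })
    p = km_event_prob(ev, 4.0)
    assert p == pytest.approx(np.mean(t <= 4.0), abs=1e-9)
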