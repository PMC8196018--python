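"""Biomarker standardization, PACC construction and cutoff derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from atnpower.preprocessing import (
    BiomarkerColumnSpec,
    CutoffSet,
    PaccWeights,
    PreprocessingError,
    binarize,
    compute_pacc,
    derive_youden_cutoff,
    rate_matched_cutoff,
    transform_and_standardize,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_youden(values, labels, direction="high"):
    """Exhaustive scan over all midpoint thresholds, maximizing J.

    Ties broken toward higher specificity, mirroring the documented rule.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(values)
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = [uniq[0] - span] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])] + [uniq[-1] + span]
    best = None
    for thr in cands:
        pos = values > thr if direction == "high" else values < thr
        sens = (pos & labels).sum() / labels.sum()
        spec = (~pos & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, thr, j)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# transform / standardize
# ---------------------------------------------------------------------------


def _table(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], **cols})


def test_four_sd_outlier_is_excluded_by_direct_arithmetic():
    """{0 x 1000, 5}: the 5 sits beyond 4 SD of the full column and goes."""
    vals = np.array([0.0] * 1000 + [5.0])
    mean, sd = vals.mean(), vals.std(ddof=1)
    assert abs(5.0 - mean) > 4 * sd  # the premise, by direct computation
    res = transform_and_standardize(
        _table(x=vals), registry=(BiomarkerColumnSpec("x", False, "high"),)
    )
    assert res.excluded == [("S1000", "x")]
    assert np.isnan(res.zscores["x_z"].iloc[-1])


def test_constant_column_reports_zero_variance():
    res = transform_and_standardize(
        _table(x=np.ones(50)), registry=(BiomarkerColumnSpec("x", False, "high"),)
    )
    assert res.excluded == []
    assert any("zero variance" in e["error"] for e in res.errors)
    assert res.zscores["x_z"].isna().all()


def test_log_registry_matches_default_convention(preset_cohort):
    """Plasma amyloid ratio untransformed; P-tau217 and NfL logged."""
    res = transform_and_standardize(preset_cohort.subjects)
    assert res.scalers["plasma_ab42_40"]["log"] is False
    assert res.scalers["plasma_ptau217"]["log"] is True
    assert res.scalers["plasma_nfl"]["log"] is True
    # z-scores standardized and abnormality-oriented: raw amyloid correlates
    # negatively with its own z-score
    j = preset_cohort.subjects.merge(res.zscores, on="subject_id")
    assert np.corrcoef(j["plasma_ab42_40"], j["plasma_ab42_40_z"])[0, 1] < -0.99
    assert np.corrcoef(np.log(j["plasma_ptau217"]), j["plasma_ptau217_z"])[0, 1] > 0.99


def test_nonpositive_values_under_log_become_row_errors():
    vals = np.array([1.0, 2.0, 0.0, 3.0, -1.0, 2.5])
    res = transform_and_standardize(
        _table(x=vals), registry=(BiomarkerColumnSpec("x", True, "high"),)
    )
    assert len(res.errors) == 2
    assert res.zscores["x_z"].isna().sum() == 2


def test_standardization_is_affine_invariant():
    """Rescaling raw inputs leaves the z-scores unchanged (no-log column)."""
    rng = np.random.default_rng(4)
    vals = rng.normal(50, 5, 300)
    reg = (BiomarkerColumnSpec("x", False, "high"),)
    z1 = transform_and_standardize(_table(x=vals), reg).zscores["x_z"]
    z2 = transform_and_standardize(_table(x=3.0 * vals + 10), reg).zscores["x_z"]
    np.testing.assert_allclose(z1, z2, atol=1e-10)


# ---------------------------------------------------------------------------
# PACC
# ---------------------------------------------------------------------------


def _visits(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "time_years": 0.0,
        "mmse": rng.normal(28, 1.2, n),
        "adas_delayed_recall": rng.normal(3, 1.5, n),
        "animal_fluency": rng.normal(21, 5, n),
        "tmt_b": rng.normal(90, 30, n),
        "pacc": np.nan,
    })


def test_pacc_zero_at_reference_means():
    v = _visits()
    out = compute_pacc(v)
    ref = out.attrs["pacc_reference"]
    probe = v.iloc[[0]].copy()
    for comp, (m, _) in ref.items():
        probe[comp] = m
    w = PaccWeights(reference=ref)
    assert compute_pacc(probe, w)["pacc"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_pacc_weighted_mean_hand_example():
    """z = (+1, -1 pre-flip, +1, -1 pre-flip) gives (1+2+1+1)/5 = 1."""
    ref = {"mmse": (28.0, 1.0), "adas_delayed_recall": (3.0, 1.0),
           "animal_fluency": (21.0, 5.0), "tmt_b": (90.0, 30.0)}
    v = pd.DataFrame({
        "subject_id": ["A"], "time_years": [0.0],
        "mmse": [29.0],                # z = +1
        "adas_delayed_recall": [2.0],  # z = -1, flipped -> +1, weight 2
        "animal_fluency": [26.0],      # z = +1
        "tmt_b": [60.0],               # z = -1, flipped -> +1
        "pacc": [np.nan],
    })
    out = compute_pacc(v, PaccWeights(reference=ref))
    assert out["pacc"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_pacc_missing_component_rule():
    ref = {"mmse": (28.0, 1.0), "adas_delayed_recall": (3.0, 1.0),
           "animal_fluency": (21.0, 5.0), "tmt_b": (90.0, 30.0)}
    v = _visits(n=3)
    # subject 0: recall+tmt missing = 3/5 of the weight -> missing PACC
    v.loc[0, ["adas_delayed_recall", "tmt_b"]] = np.nan
    # subject 1: only fluency missing = 1/5 of the weight -> PACC kept
    v.loc[1, "animal_fluency"] = np.nan
    # subject 2: everything missing
    v.loc[2, ["mmse", "adas_delayed_recall", "animal_fluency", "tmt_b"]] = np.nan
    out = compute_pacc(v, PaccWeights(reference=ref))
    assert np.isnan(out["pacc"].iloc[0])
    assert np.isfinite(out["pacc"].iloc[1])
    assert np.isnan(out["pacc"].iloc[2])


def test_pacc_invariant_to_component_rescaling():
    """Affine rescaling of any raw component is absorbed by the z-reference."""
    v = _visits(n=60, seed=2)
    out1 = compute_pacc(v)["pacc"]
    v2 = v.copy()
    v2["tmt_b"] = 2.5 * v2["tmt_b"] + 7.0
    out2 = compute_pacc(v2)["pacc"]
    np.testing.assert_allclose(out1, out2, atol=1e-10)


def test_preset_baseline_pacc_distribution(preset_analysis):
    """Baseline PACC centered at 0 with SD close to the calibrated 0.74."""
    frame, _, _ = preset_analysis
    base = frame[frame["time"] == 0]["pacc"]
    assert base.mean() == pytest.approx(0.0, abs=0.05)
    assert base.std() == pytest.approx(0.74, abs=0.08)


# ---------------------------------------------------------------------------
# Youden cutoff / binarize
# ---------------------------------------------------------------------------


def test_youden_perfect_separation():
    vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    cut, j = derive_youden_cutoff(vals, labels, "high")
    assert j == pytest.approx(1.0)
    assert 3.0 < cut.threshold < 10.0


def test_youden_four_point_example():
    cut, j = derive_youden_cutoff(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]), "high")
    assert j == pytest.approx(1.0)
    assert 2.0 < cut.threshold < 3.0


def test_youden_overlapping_toy_set_matches_bruteforce():
    vals = np.array([1.0, 2, 2, 3, 2, 3, 4, 5])
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    cut, j = derive_youden_cutoff(vals, labels, "high")
    thr_o, j_o = brute_force_youden(vals, labels, "high")
    assert j == pytest.approx(j_o)
    assert cut.threshold == pytest.approx(thr_o)


def test_youden_degenerate_labels_error():
    with pytest.raises(PreprocessingError, match="degenerate"):
        derive_youden_cutoff(np.arange(5.0), np.ones(5), "high")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n=hst.integers(8, 50),
    seed=hst.integers(0, 10_000),
    direction=hst.sampled_from(["high", "low"]),
)
def test_youden_equals_exhaustive_oracle_on_random_instances(n, seed, direction):
    """The implementation ties out with the exhaustive scan on every draw."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, bool)
    labels[: n // 2] = True
    shift = 1.0 if direction == "high" else -1.0
    vals = np.round(rng.normal(0, 1, n) + shift * labels, 1)  # ties likely
    cut, j = derive_youden_cutoff(vals, labels, direction)
    thr_o, j_o = brute_force_youden(vals, labels, direction)
    assert j == pytest.approx(j_o, abs=1e-12)
    assert cut.threshold == pytest.approx(thr_o, abs=1e-9)


def test_binarize_boundary_and_direction():
    cut = CutoffSet(biomarker="x", threshold=0.066, direction="low")
    out = binarize(np.array([0.05, 0.07, 0.066, np.nan]), cut)
    assert out[0] == 1.0 and out[1] == 0.0
    assert out[2] == 0.0  # exactly at threshold -> negative
    assert np.isnan(out[3])
    high = CutoffSet(biomarker="x", threshold=1.0, direction="high")
    assert binarize(np.array([1.0, 1.0]), high).sum() == 0.0


def test_binarize_is_idempotent_through_rate_matching(preset_analysis):
    """Rate-matched cutoffs reproduce the requested positivity rates."""
    _, _, summary = preset_analysis
    for colz, rate in (("plasma_ab42_40_z", 0.462), ("plasma_ptau217_z", 0.372),
                       ("plasma_nfl_z", 0.379)):
        vals = summary[colz].dropna().to_numpy()
        cut = rate_matched_cutoff(vals, rate, "high", colz)
        got = np.nanmean(binarize(vals, cut))
        assert got == pytest.approx(rate, abs=0.01)
        # binarizing the binarized statuses against 0.5 changes nothing
        status = binarize(vals, cut)
        again = binarize(status, CutoffSet(colz, 0.5, "high"))
        np.testing.assert_array_equal(status, again)
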