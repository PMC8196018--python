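"""Biomarker transformation, outlier screening, cutoffs and the PACC composite.

The analysis scale of a biomarker is its natural log except for the plasma
Abeta42/40 ratio, which is analyzed untransformed; values more than four
standard deviations from the column mean (computed once, before exclusion)
are dropped.  Standardized scores are oriented so that higher always means
more abnormal, which fixes the sign convention of every downstream effect
size ("per SD increase toward pathology").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerColumnSpec",
    "DEFAULT_REGISTRY",
    "CutoffSet",
    "PaccWeights",
    "transform_and_standardize",
    "compute_pacc",
    "derive_youden_cutoff",
    "binarize",
    "rate_matched_cutoff",
    "PreprocessingError",
]


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class BiomarkerColumnSpec:
    name: str
    log_transform: bool
    abnormal_direction: str  # "high" or "low" on the analysis scale

    def __post_init__(self):
        if self.abnormal_direction not in ("high", "low"):
            raise PreprocessingError("abnormal_direction must be 'high' or 'low'")


#: default biomarker registry: everything log-transformed except the plasma
#: amyloid ratio; amyloid ratios are abnormal when low.
DEFAULT_REGISTRY = (
    BiomarkerColumnSpec("plasma_ab42_40", log_transform=False, abnormal_direction="low"),
    BiomarkerColumnSpec("plasma_ptau217", log_transform=True, abnormal_direction="high"),
    BiomarkerColumnSpec("plasma_nfl", log_transform=True, abnormal_direction="high"),
    BiomarkerColumnSpec("csf_ab42_40", log_transform=True, abnormal_direction="low"),
    BiomarkerColumnSpec("csf_ptau181", log_transform=True, abnormal_direction="high"),
    BiomarkerColumnSpec("csf_nfl", log_transform=True, abnormal_direction="high"),
)


@dataclass
class StandardizationResult:
    """Analysis-scale biomarker table plus the exclusion/error report.

    ``zscores`` columns are abnormality-oriented; ``scalers`` records, per
    biomarker, the transform and the mean/SD used, which is what maps a raw
    cutoff onto the analysis z-scale (and back) elsewhere in the pipeline.
    """

    zscores: pd.DataFrame
    scalers: dict[str, dict]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (subject_id, biomarker)
    errors: list[dict] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "n_excluded": len(self.excluded),
            "excluded": [{"subject_id": s, "biomarker": b} for s, b in self.excluded],
            "errors": self.errors,
        }


def transform_and_standardize(
    subjects: pd.DataFrame,
    registry: tuple[BiomarkerColumnSpec, ...] = DEFAULT_REGISTRY,
    sd_limit: float = 4.0,
) -> StandardizationResult:
    """Log-transform, 4-SD screen and z-score the biomarker columns.

    The mean/SD used for the outlier rule are computed on the transformed
    column in a single pass (no re-computation after exclusion); z-scoring
    then uses the mean/SD of the surviving values.  Nonpositive values under
    a log transform are recorded as row-level errors and excluded without
    aborting the run.
    """
    ids = subjects["subject_id"].astype(str)
    out = pd.DataFrame({"subject_id": ids})
    result = StandardizationResult(zscores=out, scalers={})

    for spec in registry:
        if spec.name not in subjects.columns:
            continue
        raw = subjects[spec.name].to_numpy(dtype=float)
        vals = raw.copy()
        if spec.log_transform:
            bad = ~(vals > 0)
            for i in np.nonzero(bad & np.isfinite(vals))[0]:
                result.errors.append(
                    {"subject_id": ids.iloc[i], "biomarker": spec.name,
                     "error": "nonpositive value under log transform"}
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(bad, np.nan, np.log(np.where(bad, np.nan, vals)))

        finite = np.isfinite(vals)
        mean = np.nanmean(vals[finite]) if finite.any() else np.nan
        sd = np.nanstd(vals[finite], ddof=1) if finite.sum() > 1 else np.nan
        if not np.isfinite(sd) or sd == 0:
            result.errors.append({"biomarker": spec.name, "error": "zero variance"})
            out[f"{spec.name}_z"] = np.nan
            result.scalers[spec.name] = {
                "log": spec.log_transform, "mean": float(mean), "sd": float("nan"),
                "direction": spec.abnormal_direction,
            }
            continue

        outlier = finite & (np.abs(vals - mean) > sd_limit * sd)
        for i in np.nonzero(outlier)[0]:
            result.excluded.append((ids.iloc[i], spec.name))
        vals = np.where(outlier, np.nan, vals)

        kept = np.isfinite(vals)
        mu, s = float(np.nanmean(vals[kept])), float(np.nanstd(vals[kept], ddof=1))
        if not np.isfinite(s) or s == 0:
            result.errors.append({"biomarker": spec.name, "error": "zero variance"})
            out[f"{spec.name}_z"] = np.nan
            result.scalers[spec.name] = {
                "log": spec.log_transform, "mean": mu, "sd": float("nan"),
                "direction": spec.abnormal_direction,
            }
            continue
        z = (vals - mu) / s
        if spec.abnormal_direction == "low":
            z = -z
        out[f"{spec.name}_z"] = z
        result.scalers[spec.name] = {
            "log": spec.log_transform, "mean": mu, "sd": s,
            "direction": spec.abnormal_direction,
        }
    return result


# ---------------------------------------------------------------------------
# PACC composite
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaccWeights:
    """Component weights and (optional) pre-computed baseline z-references."""

    weights: dict = field(
        default_factory=lambda: {"mmse": 1.0, "adas_delayed_recall": 2.0,
                                 "animal_fluency": 1.0, "tmt_b": 1.0}
    )
    # components whose raw scale runs opposite to cognition (worse = higher)
    flipped: tuple[str, ...] = ("adas_delayed_recall", "tmt_b")
    reference: dict | None = None  # component -> (mean, sd) at baseline


def compute_pacc(visits: pd.DataFrame, weights: PaccWeights | None = None) -> pd.DataFrame:
    """Fill the ``pacc`` column: weighted mean of baseline-referenced z-scores.

    The z-reference is the baseline (time 0) distribution of the full cohort
    unless explicit references are supplied.  Delayed recall is weighted
    double; recall and TMT-B are sign-flipped so higher PACC is better.
    Visits missing more than half of the total component weight get a
    missing PACC.
    """
    weights = weights or PaccWeights()
    visits = visits.copy()
    ref = weights.reference
    if ref is None:
        base = visits.loc[visits["time_years"] == 0.0]
        if base.empty:
            raise PreprocessingError("no baseline visits to build the PACC z-reference")
        ref = {}
        for comp in weights.weights:
            vals = base[comp].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2 or np.std(vals, ddof=1) == 0:
                raise PreprocessingError(f"degenerate baseline reference for {comp}")
            ref[comp] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))

    w = np.array([weights.weights[c] for c in weights.weights])
    zmat = np.column_stack(
        [
            (visits[c].to_numpy(dtype=float) - ref[c][0]) / ref[c][1]
            * (-1.0 if c in weights.flipped else 1.0)
            for c in weights.weights
        ]
    )
    present = np.isfinite(zmat)
    wsum = present @ w
    half = 0.5 * w.sum()
    num = np.nansum(zmat * w, axis=1, where=present)
    with np.errstate(invalid="ignore"):
        pacc = np.where(wsum > half, num / wsum, np.nan)
    visits["pacc"] = pacc
    visits.attrs["pacc_reference"] = ref
    return visits


# ---------------------------------------------------------------------------
# Cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutoffSet:
    """A per-biomarker decision threshold on the analysis scale."""

    biomarker: str
    threshold: float
    direction: str  # "high": positive above threshold; "low": positive below
    provenance: str = ""

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise PreprocessingError("cutoff threshold must be finite")
        if self.direction not in ("high", "low"):
            raise PreprocessingError("cutoff direction must be 'high' or 'low'")


def derive_youden_cutoff(
    values: np.ndarray, labels: np.ndarray, direction: str = "high"
) -> tuple[CutoffSet, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent sorted unique values (plus
    open-ended sentinels); ties in J are broken toward the candidate with
    higher specificity.  ``labels`` is boolean-like with True = case
    (converter).  Returns the cutoff and the achieved J.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    if labels.all() or (~labels).all():
        raise PreprocessingError("degenerate labels: both classes must be nonempty")

    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate([[uniq[0] - span], mids, [uniq[-1] + span]])

    pos = values > candidates[:, None] if direction == "high" else values < candidates[:, None]
    sens = (pos & labels).sum(axis=1) / labels.sum()
    spec = (~pos & ~labels).sum(axis=1) / (~labels).sum()
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.nonzero(j >= best_j - 1e-12)[0]
    best = tied[np.argmax(spec[tied])]
    cut = CutoffSet(
        biomarker="", threshold=float(candidates[best]), direction=direction,
        provenance="youden",
    )
    return cut, float(best_j)


def rate_matched_cutoff(
    values: np.ndarray, rate: float, direction: str = "high", biomarker: str = ""
) -> CutoffSet:
    """Threshold such that a fraction ``rate`` of values is called positive.

    Used for the published positivity rates when raw-scale cutoffs are not
    transferable to synthetic data.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if not 0 < rate < 1:
        raise PreprocessingError("rate must be in (0, 1)")
    q = 1.0 - rate if direction == "high" else rate
    thr = float(np.quantile(values, q))
    return CutoffSet(biomarker=biomarker, threshold=thr, direction=direction,
                     provenance=f"rate_matched:{rate:g}")


def binarize(values: np.ndarray, cutoff: CutoffSet) -> np.ndarray:
    """Positive iff strictly beyond the threshold in the abnormal direction.

    Values exactly at the threshold are negative (documented convention);
    missing values propagate as NaN.
    """
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        pos = values > cutoff.threshold if cutoff.direction == "high" else values < cutoff.threshold
    out = pos.astype(float)
    out[~np.isfinite(values)] = np.nan
    return out
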