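"""Early transmurality prediction from unipolar LF recovery dynamics.

After pulsed field ablation the current-of-injury recovers faster for
nontransmural lesions, so the normalized unipolar low-frequency value
shortly after ablation separates the two outcomes: a lesion whose score
falls below a threshold is called nontransmural.  The default score is
the normalized LF value at 60 s (the earliest time at which the group
difference becomes significant); a recovery-slope score is available as
an option.  The underlying group-level evidence does not include a
per-lesion decision rule, so any threshold used here is calibrated on
synthetic cohorts and carries no clinical validity.

The rule is only defined for PFA: radiofrequency ablation shows no
unipolar LF discrimination between transmural and nontransmural
lesions, and sham placements have no ablation event at all; both are
refused.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSeries
from .stats import recovery_slope

__all__ = ["TransmuralityCall", "score_series", "predict_transmurality", "calibrate_threshold"]

#: A valid timepoint must exist within this distance of the decision time.
DECISION_TIME_TOLERANCE_S = 10.0


@dataclass
class TransmuralityCall:
    """Per-lesion transmurality decision."""

    lesion_id: str
    score: float
    decision_time_s: float
    threshold: float
    label: str  # "transmural" | "nontransmural"
    mode: str = "value"
    note: str = ""


def score_series(
    series: FeatureSeries,
    decision_time_s: float = 60.0,
    mode: str = "value",
    slope_from_s: float = 30.0,
) -> float:
    """Score one post30s-normalized unipolar LF series.

    ``mode="value"``: normalized value at the valid timepoint nearest to
    ``decision_time_s`` (within +-10 s; equidistant timepoints resolve to
    the earlier one).  ``mode="slope"``: OLS recovery slope over
    [slope_from_s, decision_time_s].
    """
    if series.normalized is None or series.normalization_mode != "post30s":
        raise ValueError("series must be normalized to the first valid post-ablation value")
    if decision_time_s < 30.0:
        raise ValueError("decision time must be >= 30 s (unipolar validity)")
    if mode == "slope":
        return recovery_slope(series, slope_from_s, decision_time_s)
    if mode != "value":
        raise ValueError(f"unknown scoring mode {mode!r}")
    t = series.times_rel_s
    ok = series.valid_mask & np.isfinite(series.normalized) & (t > 0)
    if not ok.any():
        raise ValueError(f"{series.lesion_id}: no valid post-ablation points")
    dist = np.abs(t[ok] - decision_time_s)
    if dist.min() > DECISION_TIME_TOLERANCE_S:
        raise ValueError(
            f"{series.lesion_id}: no valid timepoint within "
            f"{DECISION_TIME_TOLERANCE_S} s of t={decision_time_s} s"
        )
    return float(series.normalized[ok][np.argmin(dist)])


def predict_transmurality(
    series: FeatureSeries,
    threshold: float,
    decision_time_s: float = 60.0,
    mode: str = "value",
    modality: str | None = None,
) -> TransmuralityCall:
    """Deterministic per-lesion call: nontransmural when the score is
    strictly below ``threshold`` (faster COI recovery), transmural
    otherwise -- a score exactly at the threshold keeps the
    lesion-retaining "transmural" call."""
    modality = modality if modality is not None else series.meta.get("modality")
    if modality != "PFA":
        raise ValueError(
            f"transmurality prediction is defined for PFA only, got {modality!r} "
            "(RFA shows no unipolar LF discrimination; SHAM has no ablation event)"
        )
    score = score_series(series, decision_time_s=decision_time_s, mode=mode)
    label = "nontransmural" if score < threshold else "transmural"
    return TransmuralityCall(
        lesion_id=series.lesion_id,
        score=score,
        decision_time_s=decision_time_s,
        threshold=threshold,
        label=label,
        mode=mode,
    )


def calibrate_threshold(scores, transmural_labels) -> float:
    """Threshold maximizing Youden's J for the rule
    "transmural iff score >= threshold".

    Candidate thresholds are the midpoints between consecutive distinct
    scores; ties in J resolve to the midpoint of the tied candidates.
    When no candidate beats J = 0 (indistinguishable score
    distributions) the pooled median is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(
        [bool(l) if isinstance(l, (bool, np.bool_)) else l == "transmural" for l in transmural_labels]
    )
    if len(s) != len(y) or len(s) == 0:
        raise ValueError("scores and labels must be non-empty and aligned")
    if y.all() or (~y).all():
        raise ValueError("need both transmural and nontransmural training lesions")
    uniq = np.unique(s)
    if uniq.size < 2:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = y.sum()
    n_neg = (~y).sum()
    js = np.array(
        [((s >= c) & y).sum() / n_pos + ((s < c) & ~y).sum() / n_neg - 1.0 for c in candidates]
    )
    best = js.max()
    if best <= 1e-12:
        return float(np.median(s))
    tied = candidates[js >= best - 1e-12]
    return float((tied.min() + tied.max()) / 2.0)
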