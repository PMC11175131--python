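"""Per-cycle stability scoring and hazard-zone aggregation.

Each detected gait cycle of a trial is scored by its DTW cost against the
participant's reference gait (higher cost = larger deviation from the
unfatigued, unobstructed gait = lower body stability).  The trial-level
statistic is the mean score over the cycles that overlap the hazard zone;
these hazard-zone means are then aggregated into an environment x fatigue
level condition table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocessing as prep
from .dtw import dtw_distance
from .errors import (
    DataError,
    EmptyHazardError,
    InvalidParameterError,
    ZeroVarianceError,
)
from .preprocessing import AccelTrace, GaitCycleSegment

__all__ = [
    "StabilityRecord",
    "score_cycles",
    "hazard_zone_mean",
    "hazard_zone_peaks",
    "score_trial",
    "aggregate_condition_table",
    "pearson_r",
    "consecutive_hazard_increase",
]


@dataclass
class StabilityRecord:
    """Per-cycle DTW series for one trial plus its hazard-zone summary."""

    participant_id: str
    environment: str
    fatigue_level: int
    per_cycle_dtw: np.ndarray
    segments: list[GaitCycleSegment]
    hazard_windows: list[tuple[int, int]]
    hazard_mean: float

    def hazard_cycle_indices(self) -> list[int]:
        return _overlapping_indices(self.segments, self.hazard_windows)


def score_cycles(cycles: list[np.ndarray], reference: np.ndarray) -> np.ndarray:
    """DTW cost of each cycle against the reference gait, in cycle order."""
    ref = np.asarray(reference, dtype=np.float64)
    if ref.size == 0:
        raise DataError("empty reference gait")
    if not cycles:
        raise DataError("no cycles to score")
    out = np.empty(len(cycles))
    for k, cyc in enumerate(cycles):
        arr = np.asarray(cyc, dtype=np.float64)
        if arr.size == 0:
            raise DataError(f"cycle {k} is empty")
        out[k] = dtw_distance(ref, arr)
    return out


def _overlapping_indices(
    segments: list[GaitCycleSegment], hazard_windows: list[tuple[int, int]]
) -> list[int]:
    return [
        k
        for k, seg in enumerate(segments)
        if any(seg.overlaps(lo, hi) for lo, hi in hazard_windows)
    ]


def hazard_zone_mean(
    per_cycle_dtw: np.ndarray,
    segments: list[GaitCycleSegment],
    hazard_windows: list[tuple[int, int]],
) -> float:
    """Mean per-cycle DTW over cycles overlapping any hazard window.

    Overlap is a non-empty intersection of half-open intervals: a window that
    only touches a cycle at its boundary does not include it.
    """
    idx = _overlapping_indices(segments, hazard_windows)
    if not idx:
        raise EmptyHazardError("no gait cycle overlaps a hazard window")
    return float(np.mean(np.asarray(per_cycle_dtw)[idx]))


def hazard_zone_peaks(
    per_cycle_dtw: np.ndarray,
    segments: list[GaitCycleSegment],
    hazard_windows: list[tuple[int, int]],
) -> list[float]:
    """Peak (maximum) per-cycle DTW for each hazard window separately.

    Used for consecutive-hazard case studies: element k is the highest cycle
    score among cycles overlapping window k.
    """
    dtw = np.asarray(per_cycle_dtw)
    peaks = []
    for lo, hi in hazard_windows:
        idx = _overlapping_indices(segments, [(lo, hi)])
        if not idx:
            raise EmptyHazardError(f"no cycle overlaps hazard window [{lo}, {hi})")
        peaks.append(float(dtw[idx].max()))
    return peaks


def score_trial(
    trace: AccelTrace,
    reference: np.ndarray,
    *,
    hampel_window: int = prep.DEFAULT_HAMPEL_WINDOW,
    hampel_threshold: float = prep.DEFAULT_HAMPEL_THRESHOLD,
    min_period: float = prep.DEFAULT_MIN_PERIOD_SECONDS,
    prominence: float = prep.DEFAULT_PROMINENCE_FRACTION,
) -> StabilityRecord:
    """Full scoring path for one trial: SVM -> Hampel -> segmentation -> DTW.

    Convenience wrapper used by the pipeline, the calibration pilots and the
    acceptance checks, so all of them score trials identically.
    """
    svm = prep.compute_svm(trace)
    filtered = prep.filter_outliers(svm, hampel_window, hampel_threshold)
    segments = prep.detect_gait_cycles(filtered, min_period, prominence)
    cycles = prep.cycle_subseries(filtered, segments)
    scores = score_cycles(cycles, reference)
    hz_mean = hazard_zone_mean(scores, segments, trace.hazard_windows)
    return StabilityRecord(
        participant_id=trace.participant_id,
        environment=trace.environment,
        fatigue_level=trace.fatigue_level,
        per_cycle_dtw=scores,
        segments=segments,
        hazard_windows=list(trace.hazard_windows),
        hazard_mean=hz_mean,
    )


def aggregate_condition_table(records: list[StabilityRecord]) -> pd.DataFrame:
    """Mean hazard-zone DTW per (environment, fatigue level) cell.

    Trials are weighted equally.  Returns a DataFrame with columns
    ``environment, level, mean_dtw, n`` sorted by environment then level.
    """
    if not records:
        raise DataError("no records to aggregate")
    df = pd.DataFrame(
        {
            "environment": [r.environment for r in records],
            "level": [r.fatigue_level for r in records],
            "hazard_mean": [r.hazard_mean for r in records],
        }
    )
    out = (
        df.groupby(["environment", "level"], as_index=False)
        .agg(mean_dtw=("hazard_mean", "mean"), n=("hazard_mean", "size"))
        .sort_values(["environment", "level"], ignore_index=True)
    )
    return out


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation between two vectors."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 3:
        raise InvalidParameterError("need equal-length 1-d vectors of length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ZeroVarianceError("correlation undefined for constant input")
    return float(stats.pearsonr(xa, ya).statistic)


def consecutive_hazard_increase(first_peak_dtw: float, second_peak_dtw: float) -> float:
    """Percent change in peak DTW from the first to the second hazard."""
    if first_peak_dtw <= 0:
        raise InvalidParameterError("first peak DTW must be positive")
    return 100.0 * (second_peak_dtw - first_peak_dtw) / first_peak_dtw
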