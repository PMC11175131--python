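"""Recovery-time estimation from per-cycle stability scores.

After a hazard perturbs the gait, per-cycle DTW spikes to a *peak point* (the
hazard-zone cycle of lowest stability) and then relaxes back toward the
pre-hazard level.  The relaxation is modelled as a logarithmic trendline

    y = -a ln(x) + b,    x = 1, 2, ... cycles after the peak,

fitted by least squares (linear regression of y on ln x).  The *meeting
point* is the analytic intersection of the trendline with the pre-hazard
baseline y0 (the mean per-cycle DTW before the hazard):

    recovery_time = exp((b - y0) / a)   [cycles after the peak],

i.e. the first x at which the fitted trend is back at or below baseline.  A
fit with a <= 0 (non-decreasing trend) carries no recovery time and is
flagged unconverged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyHazardError,
    InsufficientDataError,
    NoRecoveryError,
)
from .stability import StabilityRecord

__all__ = [
    "RecoveryFit",
    "before_hazard_baseline",
    "find_peak_point",
    "fit_log_recovery",
    "recovery_time",
    "analyze_recovery",
    "recovery_summary_by_level",
]

MIN_PRE_HAZARD_CYCLES = 3
MIN_POST_PEAK_CYCLES = 4

#: a fitted trend flatter than this never plausibly returns to baseline
#: within a walking bout; such fits are flagged unconverged (about 90
#: minutes of continuous walking at a typical step period)
MAX_RECOVERY_CYCLES = 10_000.0


@dataclass
class RecoveryFit:
    """Baseline, peak point, log-trendline and derived recovery time for one trial."""

    participant_id: str
    environment: str
    fatigue_level: int
    baseline: float
    peak_index: int
    peak_value: float
    a: float
    b: float
    recovery_time_cycles: float
    converged: bool


def before_hazard_baseline(per_cycle_dtw, hazard_start_cycle: int) -> float:
    """Mean per-cycle DTW strictly before the first hazard cycle
    (the "before-hazard average line")."""
    y = np.asarray(per_cycle_dtw, dtype=np.float64)
    if hazard_start_cycle < MIN_PRE_HAZARD_CYCLES:
        raise InsufficientDataError(
            f"need >= {MIN_PRE_HAZARD_CYCLES} pre-hazard cycles, "
            f"got {hazard_start_cycle}"
        )
    return float(np.mean(y[:hazard_start_cycle]))


def find_peak_point(per_cycle_dtw, hazard_window_cycles: tuple[int, int]) -> tuple[int, float]:
    """Cycle of maximal DTW (lowest stability) within the half-open hazard
    cycle window; ties break to the earliest cycle."""
    lo, hi = hazard_window_cycles
    y = np.asarray(per_cycle_dtw, dtype=np.float64)
    lo = max(lo, 0)
    hi = min(hi, y.size)
    if hi <= lo:
        raise EmptyHazardError("empty hazard cycle window")
    k = int(lo + np.argmax(y[lo:hi]))
    return k, float(y[k])


def fit_log_recovery(post_peak_dtw) -> tuple[float, float]:
    """Least-squares fit of y = -a ln(x) + b to the post-peak scores.

    x runs 1, 2, ... over the cycles after the peak.  Returns ``(a, b)``;
    positive ``a`` means the trend decreases (recovery is under way).
    """
    y = np.asarray(post_peak_dtw, dtype=np.float64)
    if y.size < MIN_POST_PEAK_CYCLES:
        raise InsufficientDataError(
            f"need >= {MIN_POST_PEAK_CYCLES} post-peak cycles, got {y.size}"
        )
    x = np.log(np.arange(1, y.size + 1, dtype=np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    return float(-slope), float(intercept)


def recovery_time(fit: tuple[float, float], baseline: float) -> float:
    """Smallest x with -a ln(x) + b <= baseline: x* = exp((b - baseline) / a).

    Expressed in cycles after the peak; multiply by the mean cycle duration
    to convert to seconds.
    """
    a, b = fit
    if a <= 0:
        raise NoRecoveryError(f"trend not decreasing (a = {a:.4g})")
    return float(np.exp((b - baseline) / a))


def analyze_recovery(
    record: StabilityRecord,
    *,
    max_fit_cycles: int | None = None,
    max_recovery_cycles: float = MAX_RECOVERY_CYCLES,
) -> RecoveryFit:
    """Full recovery analysis of one scored trial.

    Uses the first hazard window: baseline from the cycles before it, peak
    within it, log fit over up to ``max_fit_cycles`` cycles after the peak.
    Fits that do not decrease (a <= 0) or whose extrapolated meeting point
    exceeds ``max_recovery_cycles`` are flagged unconverged.
    """
    hazard_idx = record.hazard_cycle_indices()
    if not hazard_idx:
        raise EmptyHazardError("trial has no hazard-overlapping cycles")
    first = [
        k
        for k in hazard_idx
        if record.segments[k].overlaps(*record.hazard_windows[0])
    ]
    y = record.per_cycle_dtw
    baseline = before_hazard_baseline(y, first[0])
    peak_index, peak_value = find_peak_point(y, (first[0], first[-1] + 1))
    post = y[peak_index + 1 :]
    if max_fit_cycles is not None:
        post = post[:max_fit_cycles]
    a, b = fit_log_recovery(post)
    try:
        rt = recovery_time((a, b), baseline)
        converged = rt <= max_recovery_cycles
    except NoRecoveryError:
        rt, converged = np.nan, False
    return RecoveryFit(
        participant_id=record.participant_id,
        environment=record.environment,
        fatigue_level=record.fatigue_level,
        baseline=baseline,
        peak_index=peak_index,
        peak_value=peak_value,
        a=a,
        b=b,
        recovery_time_cycles=rt,
        converged=converged,
    )


def recovery_summary_by_level(fits: list[RecoveryFit]) -> pd.DataFrame:
    """Mean recovery time per (environment, fatigue level).

    Unconverged fits are excluded from the mean but counted in ``n_excluded``.
    """
    df = pd.DataFrame(
        {
            "environment": [f.environment for f in fits],
            "level": [f.fatigue_level for f in fits],
            "recovery_time_cycles": [f.recovery_time_cycles for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    out = (
        df.groupby(["environment", "level"], as_index=False)
        .agg(
            mean_recovery_time=(
                "recovery_time_cycles",
                lambda s: s[df.loc[s.index, "converged"]].mean(),
            ),
            n=("converged", "size"),
            n_excluded=("converged", lambda s: int((~s).sum())),
        )
        .sort_values(["environment", "level"], ignore_index=True)
    )
    return out
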