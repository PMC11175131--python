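"""Raw-trace preprocessing: SVM, outlier filtering, gait segmentation, reference gait.

A trial arrives as a tri-axial acceleration recording from a waist-worn IMU.
The pipeline reduces it to the scalar signal vector magnitude (SVM, the
per-sample Euclidean norm of the three axes), removes spikes with a Hampel
filter, delimits gait cycles peak-to-peak on a smoothed copy of the SVM, and —
for the non-fatigued, non-obstacle trial of each participant — extracts the
medoid cycle as that participant's reference gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .dtw import dtw_distance
from .errors import (
    DataError,
    InsufficientDataError,
    InvalidParameterError,
    NoGaitError,
)

__all__ = [
    "AccelTrace",
    "SvmSeries",
    "GaitCycleSegment",
    "compute_svm",
    "filter_outliers",
    "detect_gait_cycles",
    "extract_reference_gait",
    "cycle_subseries",
]

#: defaults shared by the pipeline and the calibration pilots
DEFAULT_SMOOTH_SECONDS = 0.25
DEFAULT_MIN_PERIOD_SECONDS = 0.3
DEFAULT_PROMINENCE_FRACTION = 0.5
DEFAULT_HAMPEL_WINDOW = 11
DEFAULT_HAMPEL_THRESHOLD = 3.0

_MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for Gaussian noise


@dataclass
class AccelTrace:
    """Tri-axial acceleration recording (m/s^2, gravity-inclusive).

    ``samples`` has shape (n, 3) with columns (ax, ay, az); ``hazard_windows``
    are half-open sample-index intervals marking the hazard zone(s) on the
    walkway.
    """

    samples: np.ndarray
    sampling_rate: float
    participant_id: str = ""
    environment: str = ""
    fatigue_level: int = 0
    hazard_windows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError("samples must have shape (n, 3)")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        n = self.samples.shape[0]
        for lo, hi in self.hazard_windows:
            if not (0 <= lo < hi <= n):
                raise DataError(f"hazard window [{lo}, {hi}) outside [0, {n})")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class SvmSeries:
    """Scalar SVM series aligned sample-for-sample with its source trace."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True, order=True)
class GaitCycleSegment:
    """Half-open sample-index interval [start, end) delimiting one gait cycle."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"degenerate segment [{self.start}, {self.end})")

    def overlaps(self, lo: int, hi: int) -> bool:
        """Non-empty intersection with the half-open interval [lo, hi)."""
        return self.start < hi and lo < self.end


def compute_svm(trace: AccelTrace) -> SvmSeries:
    """Per-sample signal vector magnitude sqrt(ax^2 + ay^2 + az^2)."""
    if len(trace) == 0:
        raise DataError("empty trace")
    bad = ~np.all(np.isfinite(trace.samples), axis=1)
    if bad.any():
        raise DataError(f"non-finite sample at index {int(np.flatnonzero(bad)[0])}")
    return SvmSeries(np.linalg.norm(trace.samples, axis=1), trace.sampling_rate)


def filter_outliers(
    series: SvmSeries,
    window: int = DEFAULT_HAMPEL_WINDOW,
    threshold: float = DEFAULT_HAMPEL_THRESHOLD,
) -> SvmSeries:
    """Hampel filter: replace points further than ``threshold`` scaled MADs
    from their centred-window median by that median.

    Windows are truncated at the series boundaries; length is preserved.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 3")
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    x = series.values
    n = x.shape[0]
    if window > n:
        raise InvalidParameterError(f"window {window} exceeds series length {n}")
    half = window // 2
    out = x.copy()
    # interior: full centred windows, vectorised
    if n >= window:
        win = np.lib.stride_tricks.sliding_window_view(x, window)
        med = np.median(win, axis=1)
        mad = np.median(np.abs(win - med[:, None]), axis=1)
        centre = x[half : n - half]
        replace = np.abs(centre - med) > threshold * _MAD_SCALE * mad
        out[half : n - half] = np.where(replace, med, centre)
    # edges: truncated windows
    for i in list(range(half)) + list(range(n - half, n)):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = x[lo:hi]
        med_i = np.median(w)
        mad_i = np.median(np.abs(w - med_i))
        if np.abs(x[i] - med_i) > threshold * _MAD_SCALE * mad_i:
            out[i] = med_i
    return SvmSeries(out, series.sampling_rate)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with edge truncation (same length as input)."""
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_gait_cycles(
    series: SvmSeries,
    min_period: float = DEFAULT_MIN_PERIOD_SECONDS,
    prominence: float = DEFAULT_PROMINENCE_FRACTION,
    smooth_seconds: float = DEFAULT_SMOOTH_SECONDS,
) -> list[GaitCycleSegment]:
    """Delimit gait cycles peak-to-peak on the smoothed SVM series.

    Peaks must be at least ``min_period`` seconds apart and have prominence of
    at least ``prominence`` times the inter-quartile range of the smoothed
    series (so segmentation is invariant to amplitude scaling).  Each pair of
    consecutive peaks bounds one cycle.
    """
    fs = series.sampling_rate
    x = series.values
    if x.shape[0] <= 2 * min_period * fs:
        raise NoGaitError("series shorter than two minimum gait periods")
    width = max(1, int(round(smooth_seconds * fs)))
    smoothed = _moving_average(x, width)
    q75, q25 = np.percentile(smoothed, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise NoGaitError("flat series: no gait peaks")
    peaks, _ = find_peaks(
        smoothed,
        distance=max(1, int(round(min_period * fs))),
        prominence=prominence * iqr,
    )
    if peaks.size < 2:
        raise NoGaitError(f"found {peaks.size} gait peak(s); need >= 2")
    return [
        GaitCycleSegment(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])
    ]


def cycle_subseries(
    series: SvmSeries, segments: list[GaitCycleSegment]
) -> list[np.ndarray]:
    """Slice the SVM values for each cycle segment."""
    return [series.values[s.start : s.end] for s in segments]


def reference_from_trace(
    trace: AccelTrace,
    window: int = DEFAULT_HAMPEL_WINDOW,
    threshold: float = DEFAULT_HAMPEL_THRESHOLD,
    min_period: float = DEFAULT_MIN_PERIOD_SECONDS,
    prominence: float = DEFAULT_PROMINENCE_FRACTION,
) -> np.ndarray:
    """Reference gait straight from a raw level-0 non-obstacle trial.

    Chains SVM computation, Hampel filtering, cycle detection and medoid
    extraction with the pipeline defaults.
    """
    svm = compute_svm(trace)
    filtered = filter_outliers(svm, window, threshold)
    segments = detect_gait_cycles(filtered, min_period, prominence)
    return extract_reference_gait(cycle_subseries(filtered, segments))


def extract_reference_gait(cycles: list[np.ndarray]) -> np.ndarray:
    """Medoid gait cycle: the cycle minimising total DTW distance to all others.

    The medoid (rather than a pointwise mean) keeps the reference in DTW's own
    metric and sidesteps averaging cycles of unequal length.  Ties break to the
    earliest cycle.  Intended for the level-0, non-obstacle trial of one
    participant.
    """
    if len(cycles) < 3:
        raise InsufficientDataError(
            f"need >= 3 cycles to extract a reference gait, got {len(cycles)}"
        )
    n = len(cycles)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(cycles[i], cycles[j])
            total[i] += d
            total[j] += d
    return np.asarray(cycles[int(np.argmin(total))], dtype=np.float64).copy()
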