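"""Seeded synthetic walking-trial generator with known ground truth.

No raw accelerometry is deposited with the study this pipeline re-implements,
so cohorts are simulated.  Each participant walks a ~15 m course at their own
step frequency; a trial is a quasi-periodic tri-axial acceleration trace
(gravity-inclusive, m/s^2) built cycle by cycle:

* the per-step waveform is a fixed low-order harmonic template of the step
  frequency (3 harmonics on the vertical axis, 2 anterio-posterior, 1
  medio-lateral), scaled by the participant's base amplitude;
* fatigue level k (0..5) multiplies cycle-timing jitter, cycle-amplitude
  variability and sensor noise linearly, from 1x at level 0 to 3x at level 5;
* inside the hazard window a constant vertical offset of calibrated magnitude
  is added (an integer number of cycles); after the window the offset decays
  along the preset's logarithmic profile r(k) = max(0, b - a ln k);
* consecutive hazards accumulate: a second hazard met before the first has
  decayed rides on the residual offset, so it perturbs the gait harder.

Every trial returns its ground truth (cycle boundaries, hazard windows,
injected magnitude, decay coefficients) so tests can verify segmentation and
scoring against construction.  All randomness flows from numpy SeedSequences:
a fixed cohort seed reproduces the cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidSpecError
from .preprocessing import AccelTrace, reference_from_trace
from .presets import EnvironmentPreset, default_presets
from .stability import score_trial

__all__ = [
    "CohortSpec",
    "ParticipantProfile",
    "TrialGroundTruth",
    "Trial",
    "Cohort",
    "fatigue_multiplier",
    "sample_failure_counts",
    "steps_for_level",
    "synth_trial",
    "generate_cohort",
    "make_pilots",
    "calibrate_hazard_magnitude",
]

GRAVITY = 9.81

# harmonic templates (phase 0 = the SVM peak that opens each cycle)
_VERT = ((1.0, 1), (0.30, 2), (0.10, 3))  # cosine series, symmetric peak at 0
_AP = ((0.45, 1), (0.12, 2))  # sine series, zero at the peak
_ML_AMP, _ML_PHASE = 0.25, -1.2

# study-condition defaults: per-cycle timing jitter sd (fraction of the cycle
# period), cycle-amplitude variability sd (fraction of base amplitude), and
# the fatigue multiplier reached at level 5.
TIMING_JITTER_SD = 0.03
AMPLITUDE_JITTER_SD = 0.04
FATIGUE_MAX_MULTIPLIER = 3.0
DEFAULT_NOISE_SCALE = 0.08  # m/s^2 white noise per axis at level 0

DEFAULT_SAMPLING_RATE = 128.0
DEFAULT_CYCLES_PER_TRIAL = 20
DEFAULT_HAZARD_START_FRACTION = 0.4
DEFAULT_HAZARD_CYCLES = 2

_STEP_FREQ_RANGE = (1.7, 2.1)  # Hz
_BASE_AMPLITUDE_MEAN, _BASE_AMPLITUDE_SD = 3.0, 0.3  # m/s^2


@dataclass
class ParticipantProfile:
    """Per-participant walking characteristics and step-test endurance."""

    participant_id: str
    failure_count: int
    step_frequency: float
    base_amplitude: float
    noise_scale: float = DEFAULT_NOISE_SCALE

    def __post_init__(self) -> None:
        if self.failure_count < 1:
            raise InvalidSpecError("failure_count must be >= 1")
        if not (0.5 < self.step_frequency < 3.0):
            raise InvalidSpecError("step_frequency must lie in (0.5, 3.0) Hz")
        if self.noise_scale < 0:
            raise InvalidSpecError("noise_scale must be non-negative")


@dataclass
class CohortSpec:
    """Design of a synthetic cohort (defaults reproduce the full study design:
    72 participants x 6 fatigue levels x 4 environments at 128 Hz)."""

    n_participants: int = 72
    fatigue_levels: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    environments: tuple[str, ...] = ("A", "B", "C", "D")
    cycles_per_trial: int = DEFAULT_CYCLES_PER_TRIAL
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0
    failure_count_distribution: tuple[float, float, float] = (120.0, 30.0, 40.0)
    environment_presets: dict[str, EnvironmentPreset] = field(
        default_factory=default_presets
    )

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidSpecError("n_participants must be >= 1")
        if self.cycles_per_trial < 5:
            raise InvalidSpecError("cycles_per_trial must be >= 5")
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")
        if any(lv not in range(6) for lv in self.fatigue_levels):
            raise InvalidSpecError("fatigue levels must be in 0..5")
        unknown = set(self.environments) - set(self.environment_presets)
        if unknown:
            raise InvalidSpecError(f"no preset for environment(s) {sorted(unknown)}")


@dataclass
class TrialGroundTruth:
    """Construction-time truth for one trial (for tests, not for scoring)."""

    cycle_boundaries: list[tuple[int, int]]
    hazard_windows: list[tuple[int, int]]
    injected_magnitude: float
    decay_coefficients: tuple[float, float]

    def __post_init__(self) -> None:
        bounds = self.cycle_boundaries
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            if not (a0 < a1 <= b0 < b1):
                raise InvalidSpecError("cycle boundaries must be ordered, disjoint")


@dataclass
class Trial:
    trace: AccelTrace
    ground_truth: TrialGroundTruth


@dataclass
class Cohort:
    spec: CohortSpec
    profiles: list[ParticipantProfile]
    trials: dict[tuple[str, str, int], Trial]  # (participant, environment, level)
    manifest: pd.DataFrame


def fatigue_multiplier(level: int) -> float:
    """Linear variability multiplier: 1.0 at level 0, 3.0 at level 5."""
    if level not in range(6):
        raise InvalidSpecError(f"fatigue level {level} outside 0..5")
    return 1.0 + (FATIGUE_MAX_MULTIPLIER - 1.0) * level / 5.0


def steps_for_level(failure_count: int, level: int) -> int:
    """Steps performed before a trial at the given fatigue level.

    Level k corresponds to k x 10% of the participant's failure count,
    rounded to the nearest integer with ties rounding up.
    """
    if failure_count < 1:
        raise InvalidSpecError("failure_count must be >= 1")
    if level not in range(6):
        raise InvalidSpecError(f"fatigue level {level} outside 0..5")
    return int(math.floor(0.10 * level * failure_count + 0.5))


def sample_failure_counts(
    spec: CohortSpec, rng: np.random.Generator
) -> list[ParticipantProfile]:
    """Draw one participant profile per cohort member.

    Failure counts follow a truncated normal (resampled below the minimum);
    step frequency is uniform on (1.7, 2.1) Hz and base amplitude normal
    around 3 m/s^2, mimicking ordinary adult walking.
    """
    mean, sd, minimum = spec.failure_count_distribution
    profiles = []
    for p in range(spec.n_participants):
        count = rng.normal(mean, sd)
        while count < minimum:
            count = rng.normal(mean, sd)
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{p:03d}",
                failure_count=int(round(count)),
                step_frequency=float(rng.uniform(*_STEP_FREQ_RANGE)),
                base_amplitude=float(
                    max(1.5, rng.normal(_BASE_AMPLITUDE_MEAN, _BASE_AMPLITUDE_SD))
                ),
            )
        )
    return profiles


def _default_hazard(cycles: int) -> list[tuple[int, int]]:
    return [(int(round(DEFAULT_HAZARD_START_FRACTION * cycles)), DEFAULT_HAZARD_CYCLES)]


def _template(phase: np.ndarray, amplitude: float) -> np.ndarray:
    """(n, 3) acceleration template at the given phases (rad)."""
    vert = sum(a * np.cos(k * phase) for a, k in _VERT)
    ap = sum(a * np.sin(k * phase) for a, k in _AP)
    ml = _ML_AMP * np.sin(phase + _ML_PHASE)
    out = np.empty((phase.size, 3))
    out[:, 0] = amplitude * ap
    out[:, 1] = amplitude * ml
    out[:, 2] = GRAVITY + amplitude * vert
    return out


def synth_trial(
    profile: ParticipantProfile,
    preset: EnvironmentPreset,
    level: int,
    cycles: int = DEFAULT_CYCLES_PER_TRIAL,
    rng: np.random.Generator | None = None,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    hazard_cycles: list[tuple[int, int]] | None = None,
    injected_magnitude: float | None = None,
) -> Trial:
    """Simulate one walking trial.

    ``hazard_cycles`` is a list of ``(start_cycle, n_cycles)`` hazard
    placements (default: one two-cycle hazard 40% of the way along the
    course).  ``injected_magnitude`` overrides the preset's calibrated
    magnitude for this level.
    """
    if rng is None:
        rng = np.random.default_rng()
    if cycles < 5:
        raise InvalidSpecError("cycles must be >= 5")
    mult = fatigue_multiplier(level)
    hz = hazard_cycles if hazard_cycles is not None else _default_hazard(cycles)
    for start, length in hz:
        if length < 1 or start < 1 or start + length > cycles - 1:
            raise InvalidSpecError(
                f"hazard cycles [{start}, {start + length}) must lie strictly "
                f"inside cycles 1..{cycles - 1}"
            )
    s = (
        injected_magnitude
        if injected_magnitude is not None
        else preset.hazard_magnitude_by_level[level]
    )
    a_dec, b_dec = preset.recovery_decay_by_level[level]

    # per-cycle perturbation offsets: in-window magnitude plus the log-decayed
    # residual of every earlier window (consecutive hazards stack)
    offset = np.zeros(cycles)
    for start, length in hz:
        offset[start : start + length] += s
        for k in range(start + length, cycles):
            lag = k - (start + length) + 1
            offset[k] += s * max(0.0, b_dec - a_dec * math.log(lag))

    period = 1.0 / profile.step_frequency
    n_cycle = np.maximum(
        8,
        np.round(
            period
            * (1.0 + TIMING_JITTER_SD * mult * rng.standard_normal(cycles))
            * sampling_rate
        ).astype(int),
    )
    amps = profile.base_amplitude * (
        1.0 + AMPLITUDE_JITTER_SD * mult * rng.standard_normal(cycles)
    )
    amps = np.maximum(amps, 0.2 * profile.base_amplitude)

    n_half = max(4, int(round(0.5 * period * sampling_rate)))
    chunks = [_template(np.linspace(-np.pi, 0.0, n_half, endpoint=False), amps[0])]
    boundaries: list[tuple[int, int]] = []
    pos = n_half
    for k in range(cycles):
        phase = 2.0 * np.pi * np.arange(n_cycle[k]) / n_cycle[k]
        chunk = _template(phase, amps[k])
        chunk[:, 2] += offset[k]
        chunks.append(chunk)
        boundaries.append((pos, pos + int(n_cycle[k])))
        pos += int(n_cycle[k])
    chunks.append(_template(np.linspace(0.0, np.pi, n_half), amps[-1]))

    samples = np.concatenate(chunks, axis=0)
    if profile.noise_scale > 0:
        samples = samples + rng.normal(
            0.0, profile.noise_scale * mult, size=samples.shape
        )

    hazard_windows = [
        (boundaries[start][0], boundaries[start + length - 1][1])
        for start, length in hz
    ]
    truth = TrialGroundTruth(
        cycle_boundaries=boundaries,
        hazard_windows=hazard_windows,
        injected_magnitude=float(s),
        decay_coefficients=(a_dec, b_dec),
    )
    trace = AccelTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        participant_id=profile.participant_id,
        environment=preset.name,
        fatigue_level=level,
        hazard_windows=hazard_windows,
    )
    return Trial(trace=trace, ground_truth=truth)


def _trial_rng(seed: int, participant_index: int, env: str, level: int):
    return np.random.default_rng(
        np.random.SeedSequence([seed, participant_index, ord(env), level])
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate one trial per participant x fatigue level x environment.

    The manifest lists every trial with its metadata and hazard windows; the
    whole cohort is a pure function of the spec (including its seed).
    """
    profile_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    profiles = sample_failure_counts(spec, profile_rng)
    trials: dict[tuple[str, str, int], Trial] = {}
    rows = []
    for p, prof in enumerate(profiles):
        for env in spec.environments:
            preset = spec.environment_presets[env]
            for level in spec.fatigue_levels:
                trial = synth_trial(
                    prof,
                    preset,
                    level,
                    spec.cycles_per_trial,
                    _trial_rng(spec.seed, p, env, level),
                    sampling_rate=spec.sampling_rate,
                )
                trials[(prof.participant_id, env, level)] = trial
                rows.append(
                    {
                        "participant_id": prof.participant_id,
                        "environment": env,
                        "fatigue_level": level,
                        "n_samples": len(trial.trace),
                        "hazard_windows": ";".join(
                            f"{a}-{b}" for a, b in trial.trace.hazard_windows
                        ),
                        "steps_performed": steps_for_level(prof.failure_count, level),
                    }
                )
    manifest = pd.DataFrame(rows)
    return Cohort(spec=spec, profiles=profiles, trials=trials, manifest=manifest)


# ---------------------------------------------------------------------------
# hazard-magnitude calibration
# ---------------------------------------------------------------------------


@dataclass
class Pilot:
    """One calibration replicate: a profile, its reference gait (or None for
    self-reference) and the seed of its trial stream."""

    profile: ParticipantProfile
    reference: np.ndarray | None
    trial_seed: int


def make_pilots(
    n: int,
    seed: int,
    presets: dict[str, EnvironmentPreset] | None = None,
    *,
    self_reference: bool = False,
    cycles: int = DEFAULT_CYCLES_PER_TRIAL,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[Pilot]:
    """Build calibration pilots: fresh participants with reference gaits.

    Unless ``self_reference`` is set, each pilot's reference gait is the
    medoid cycle of a level-0 non-obstacle trial generated with preset A's
    calibrated magnitude, exactly as the pipeline extracts it.
    """
    presets = presets if presets is not None else default_presets()
    spec = CohortSpec(n_participants=n, seed=seed, environment_presets=presets)
    profile_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    profiles = sample_failure_counts(spec, profile_rng)
    pilots = []
    for i, prof in enumerate(profiles):
        reference = None
        if not self_reference:
            ref_trial = synth_trial(
                prof,
                presets["A"],
                0,
                cycles,
                np.random.default_rng(np.random.SeedSequence([seed, i, 0xEF])),
                sampling_rate=sampling_rate,
            )
            reference = reference_from_trace(ref_trial.trace)
        pilots.append(Pilot(profile=prof, reference=reference, trial_seed=seed * 100003 + i))
    return pilots


def _pilot_hazard_mean(
    preset: EnvironmentPreset,
    level: int,
    scale: float,
    pilots: list[Pilot],
    *,
    cycles: int = DEFAULT_CYCLES_PER_TRIAL,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> float:
    """Mean hazard-zone DTW over the pilots at a given injected magnitude.

    Each pilot reuses the same trial seed at every magnitude (common random
    numbers), so the mean is a smooth, monotone function of the magnitude and
    bisection is well behaved.
    """
    vals = []
    for pilot in pilots:
        rng = np.random.default_rng(
            np.random.SeedSequence([pilot.trial_seed, ord(preset.name), level])
        )
        trial = synth_trial(
            pilot.profile,
            preset,
            level,
            cycles,
            rng,
            sampling_rate=sampling_rate,
            injected_magnitude=scale,
        )
        reference = pilot.reference
        if reference is None:
            reference = reference_from_trace(trial.trace)
        record = score_trial(trial.trace, reference)
        vals.append(record.hazard_mean)
    return float(np.mean(vals))


def calibrate_hazard_magnitude(
    preset: EnvironmentPreset,
    level: int,
    pilots: list[Pilot],
    *,
    target: float | None = None,
    tol: float = 0.01,
    max_scale: float = 40.0,
    max_iter: int = 60,
    cycles: int = DEFAULT_CYCLES_PER_TRIAL,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> float:
    """Bisect the injected hazard magnitude so the pilot mean hazard-zone DTW
    matches the preset's target for this level (within ``tol``, relative).

    Requires the unperturbed floor (magnitude 0) to sit below the target;
    raises :class:`CalibrationError` otherwise, or if no magnitude up to
    ``max_scale`` reaches the target.
    """
    if target is None:
        target = preset.target_hazard_dtw_by_level[level]
    if target == 0:
        return 0.0

    def mean_at(s: float) -> float:
        return _pilot_hazard_mean(
            preset, level, s, pilots, cycles=cycles, sampling_rate=sampling_rate
        )

    lo, f_lo = 0.0, mean_at(0.0)
    if f_lo >= target:
        raise CalibrationError(
            f"{preset.name} level {level}: unperturbed floor {f_lo:.2f} already "
            f"at or above target {target:.2f}"
        )
    hi = 0.25
    f_hi = mean_at(hi)
    while f_hi < target:
        hi *= 2.0
        if hi > max_scale:
            raise CalibrationError(
                f"{preset.name} level {level}: target {target:.2f} not reachable "
                f"below magnitude {max_scale}"
            )
        f_hi = mean_at(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = mean_at(mid)
        if abs(f_mid - target) <= tol * target:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
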