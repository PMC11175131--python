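"""Walking-environment presets.

The study design crosses six fatigue levels (0-5, each level k meaning the
participant performed k x 10% of their individual step-test failure count
before walking) with four walkway environments:

    A - non-obstacle, B - obstacle, C - water-slick surface, D - oil-slick surface.

Each preset carries, per fatigue level:

* ``target_hazard_dtw_by_level`` - the expected hazard-zone DTW the synthetic
  generator is calibrated to reproduce.  These are the published condition
  means for each environment.  The level-4 value for environment A is not
  published; it is filled by geometric interpolation between the level-3 and
  level-5 values and is configurable.
* ``hazard_magnitude_by_level`` - the additive vertical-acceleration offset
  (m/s^2) injected in the hazard zone.  These are *calibrated*, not
  hand-tuned: ``analysis/02_calibrate_presets.py`` bisects each magnitude so
  the simulated cohort mean hazard-zone DTW matches the target under the
  default generator settings, and the resulting values are frozen here.
* ``recovery_decay_by_level`` - dimensionless coefficients (a, b) of the
  post-hazard perturbation decay r(k) = max(0, b - a ln k), k = 1, 2, ... in
  cycles after the hazard.  b is the fraction of the hazard magnitude that
  persists one cycle after the hazard; the profile reaches zero at the
  recovery horizon K = exp(b / a), which grows with fatigue level and with
  environment severity (slippery surfaces recover slowest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidSpecError

__all__ = ["EnvironmentPreset", "default_presets", "ENVIRONMENT_LABELS"]

ENVIRONMENT_LABELS = {
    "A": "non-obstacle",
    "B": "obstacle",
    "C": "water",
    "D": "oil",
}

#: published condition means (hazard-zone DTW) per environment and level.
#: A's level-4 entry is interpolated (geometric mean of levels 3 and 5).
_TARGETS: dict[str, tuple[float, ...]] = {
    "A": (8.0, 9.4, 9.7, 10.7, round(math.sqrt(10.7 * 23.1), 1), 23.1),
    "B": (9.5, 11.2, 12.0, 15.3, 18.9, 24.8),
    "C": (9.7, 10.3, 13.0, 15.9, 18.9, 26.7),
    "D": (10.5, 15.5, 16.3, 19.1, 20.1, 34.5),
}

#: recovery horizon K (cycles until the injected perturbation has fully
#: decayed), per environment at level 0; levels scale it by (1 + 0.4 * level).
_RECOVERY_HORIZON_L0 = {"A": 6.0, "B": 8.0, "C": 9.0, "D": 11.0}
_RECOVERY_HORIZON_LEVEL_GAIN = 0.4
_RECOVERY_B = 0.9

#: calibrated hazard magnitudes (m/s^2), written by
#: analysis/02_calibrate_presets.py under the default generator settings.
_CALIBRATED_MAGNITUDE: dict[str, tuple[float, ...]] = {
    "A": (1.1328, 1.1875, 1.1953, 1.2188, 1.3750, 1.5938),
    "B": (1.1953, 1.2656, 1.2891, 1.3984, 1.4922, 1.6328),
    "C": (1.2031, 1.2266, 1.3281, 1.4141, 1.4922, 1.6719),
    "D": (1.2344, 1.4062, 1.4297, 1.5000, 1.5156, 1.8438),
}


@dataclass
class EnvironmentPreset:
    """Per-environment generator settings (see module docstring)."""

    name: str
    label: str
    target_hazard_dtw_by_level: dict[int, float]
    hazard_magnitude_by_level: dict[int, float]
    recovery_decay_by_level: dict[int, tuple[float, float]]
    perturbation_shape: str = "vertical-offset"

    def __post_init__(self) -> None:
        targets = self.target_hazard_dtw_by_level
        if any(v <= 0 for v in targets.values()):
            raise InvalidSpecError(f"preset {self.name}: targets must be positive")
        levels = sorted(targets)
        vals = [targets[lv] for lv in levels]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise InvalidSpecError(
                f"preset {self.name}: targets must be non-decreasing in level"
            )


def _decay_coefficients(env: str, level: int) -> tuple[float, float]:
    horizon = _RECOVERY_HORIZON_L0[env] * (1 + _RECOVERY_HORIZON_LEVEL_GAIN * level)
    b = _RECOVERY_B
    a = b / math.log(horizon)
    return (a, b)


def default_presets() -> dict[str, EnvironmentPreset]:
    """The four packaged environment presets, keyed by environment code."""
    presets = {}
    for env, label in ENVIRONMENT_LABELS.items():
        presets[env] = EnvironmentPreset(
            name=env,
            label=label,
            target_hazard_dtw_by_level={
                lv: t for lv, t in enumerate(_TARGETS[env])
            },
            hazard_magnitude_by_level={
                lv: m for lv, m in enumerate(_CALIBRATED_MAGNITUDE[env])
            },
            recovery_decay_by_level={
                lv: _decay_coefficients(env, lv) for lv in range(6)
            },
        )
    return presets
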