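"""Cohort-level replication experiments on calibrated synthetic cohorts.

These helpers run the full pipeline path (simulate -> SVM -> Hampel ->
segmentation -> DTW vs the participant's own reference gait -> hazard-zone
aggregation) for selected study conditions across replicate cohorts, without
materialising trials that the requested conditions do not need.  Trial random
streams are identical to :func:`gaitstab.synthetic.generate_cohort`'s, so a
condition mean computed here equals the corresponding cell of a full cohort
run with the same seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocessing import reference_from_trace
from .presets import EnvironmentPreset, default_presets
from .recovery import analyze_recovery, recovery_summary_by_level
from .stability import aggregate_condition_table, score_trial
from .synthetic import (
    CohortSpec,
    _trial_rng,
    sample_failure_counts,
    synth_trial,
)

__all__ = ["replicate_condition_means", "replicate_recovery_summary"]

REFERENCE_ENV, REFERENCE_LEVEL = "A", 0


def _cohort_profiles(n_participants: int, seed: int, presets) -> list:
    spec = CohortSpec(
        n_participants=n_participants, seed=seed, environment_presets=presets
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    return sample_failure_counts(spec, rng)


def _run_conditions(
    conditions: list[tuple[str, int]],
    seeds: list[int],
    n_participants: int,
    presets: dict[str, EnvironmentPreset] | None,
    cycles_per_trial: int,
):
    """Score the requested (environment, level) conditions; yield records."""
    presets = presets if presets is not None else default_presets()
    want = list(dict.fromkeys(conditions))
    records = []
    for seed in seeds:
        profiles = _cohort_profiles(n_participants, seed, presets)
        for p, prof in enumerate(profiles):
            ref_trial = synth_trial(
                prof,
                presets[REFERENCE_ENV],
                REFERENCE_LEVEL,
                cycles_per_trial,
                _trial_rng(seed, p, REFERENCE_ENV, REFERENCE_LEVEL),
            )
            reference = reference_from_trace(ref_trial.trace)
            for env, level in want:
                if (env, level) == (REFERENCE_ENV, REFERENCE_LEVEL):
                    trial = ref_trial
                else:
                    trial = synth_trial(
                        prof,
                        presets[env],
                        level,
                        cycles_per_trial,
                        _trial_rng(seed, p, env, level),
                    )
                records.append((seed, score_trial(trial.trace, reference)))
    return records


def replicate_condition_means(
    conditions: list[tuple[str, int]],
    seeds: list[int],
    *,
    n_participants: int = 72,
    presets: dict[str, EnvironmentPreset] | None = None,
    cycles_per_trial: int = 20,
) -> pd.DataFrame:
    """Mean hazard-zone DTW per requested condition, pooled over replicate
    cohorts (one cohort of ``n_participants`` per seed).

    Returns a DataFrame with columns ``environment, level, mean_dtw, n``.
    """
    records = _run_conditions(
        conditions, seeds, n_participants, presets, cycles_per_trial
    )
    return aggregate_condition_table([r for _, r in records])


def replicate_recovery_summary(
    conditions: list[tuple[str, int]],
    seeds: list[int],
    *,
    n_participants: int = 72,
    presets: dict[str, EnvironmentPreset] | None = None,
    cycles_per_trial: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition means and mean recovery times for the requested conditions.

    Returns ``(condition_table, recovery_summary)`` pooled over seeds.
    """
    records = _run_conditions(
        conditions, seeds, n_participants, presets, cycles_per_trial
    )
    fits = [analyze_recovery(r) for _, r in records]
    return (
        aggregate_condition_table([r for _, r in records]),
        recovery_summary_by_level(fits),
    )
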