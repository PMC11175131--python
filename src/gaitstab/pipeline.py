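"""End-to-end orchestration: simulate/load -> preprocess -> score -> aggregate -> recover.

The pipeline consumes either a trial manifest on disk or a simulation spec,
scores every trial against its participant's reference gait (the medoid cycle
of their level-0 non-obstacle trial), and writes four artefacts to the output
directory:

* ``condition_table.csv``  - mean hazard-zone DTW per environment x level,
* ``records.csv``          - per-cycle DTW for every scored trial,
* ``recovery.csv``         - per-trial recovery fits and recovery times,
* ``run_summary.json``     - counts, seed, versions, per-stage timings,
  and every excluded trial with its reason.

Outputs are a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (
    GaitStabError,
    InvalidParameterError,
    InvalidSpecError,
)
from .preprocessing import AccelTrace, reference_from_trace
from .recovery import RecoveryFit, analyze_recovery, recovery_summary_by_level
from .stability import StabilityRecord, aggregate_condition_table, score_trial
from .synthetic import CohortSpec, generate_cohort
from . import io as gio

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "analyze_traces",
    "proportion_reporting_fatigue",
]

logger = logging.getLogger("gaitstab")

REFERENCE_CONDITION = ("A", 0)  # non-obstacle walking without fatigue


@dataclass
class PipelineConfig:
    """Pipeline run configuration (YAML-mappable).

    Exactly one of ``manifest`` / ``simulation`` must be set; ``simulation``
    holds CohortSpec keyword arguments.
    """

    out_dir: Path
    manifest: Path | None = None
    simulation: dict | None = None
    seed: int = 0
    hampel_window: int = 11
    hampel_threshold: float = 3.0
    min_period: float = 0.3
    prominence: float = 0.5
    max_fit_cycles: int | None = None
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.simulation is None):
            raise InvalidSpecError(
                "exactly one of manifest / simulation must be provided"
            )
        self.out_dir = Path(self.out_dir)
        if self.manifest is not None:
            self.manifest = Path(self.manifest)
            if not self.manifest.exists():
                raise InvalidSpecError(f"manifest not found: {self.manifest}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def proportion_reporting_fatigue(count: int, total: int) -> float:
    """Percentage of participants reporting significant fatigue, rounded
    half-up to two decimals."""
    if total < 1:
        raise InvalidParameterError("total must be >= 1")
    if not (0 <= count <= total):
        raise InvalidParameterError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def analyze_traces(
    traces: list[AccelTrace],
    *,
    hampel_window: int = 11,
    hampel_threshold: float = 3.0,
    min_period: float = 0.3,
    prominence: float = 0.5,
    max_fit_cycles: int | None = None,
) -> tuple[list[StabilityRecord], list[RecoveryFit], list[dict]]:
    """Score every trial and fit recovery curves, excluding (not aborting on)
    trials that fail with a package error; exclusions carry a reason."""
    records: list[StabilityRecord] = []
    fits: list[RecoveryFit] = []
    exclusions: list[dict] = []
    by_participant: dict[str, list[AccelTrace]] = {}
    for tr in traces:
        by_participant.setdefault(tr.participant_id, []).append(tr)

    kw = dict(
        hampel_window=hampel_window,
        hampel_threshold=hampel_threshold,
        min_period=min_period,
        prominence=prominence,
    )
    for pid, group in by_participant.items():
        ref_trace = next(
            (
                t
                for t in group
                if (t.environment, t.fatigue_level) == REFERENCE_CONDITION
            ),
            None,
        )
        if ref_trace is None:
            for t in group:
                exclusions.append(
                    _exclusion(t, "no level-0 non-obstacle reference trial")
                )
            continue
        try:
            reference = reference_from_trace(
                ref_trace, hampel_window, hampel_threshold, min_period, prominence
            )
        except GaitStabError as err:
            for t in group:
                exclusions.append(_exclusion(t, f"reference extraction: {err}"))
            continue
        for t in group:
            try:
                rec = score_trial(t, reference, **kw)
            except GaitStabError as err:
                exclusions.append(_exclusion(t, f"scoring: {err}"))
                logger.warning("excluded %s: %s", _trial_id(t), err)
                continue
            records.append(rec)
            try:
                fits.append(analyze_recovery(rec, max_fit_cycles=max_fit_cycles))
            except GaitStabError as err:
                exclusions.append(_exclusion(t, f"recovery: {err}"))
                logger.warning("no recovery fit for %s: %s", _trial_id(t), err)
    return records, fits, exclusions


def _trial_id(t: AccelTrace) -> str:
    return f"{t.participant_id}/{t.environment}/L{t.fatigue_level}"


def _exclusion(t: AccelTrace, reason: str) -> dict:
    return {
        "participant_id": t.participant_id,
        "environment": t.environment,
        "fatigue_level": t.fatigue_level,
        "reason": reason,
    }


def _records_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        hz = set(r.hazard_cycle_indices())
        for k, val in enumerate(r.per_cycle_dtw):
            rows.append(
                {
                    "participant": r.participant_id,
                    "environment": r.environment,
                    "level": r.fatigue_level,
                    "cycle_index": k,
                    "dtw": val,
                    "in_hazard": k in hz,
                }
            )
    return pd.DataFrame(rows)


def _recovery_frame(fits: list[RecoveryFit], cycle_seconds: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [f.participant_id for f in fits],
            "environment": [f.environment for f in fits],
            "level": [f.fatigue_level for f in fits],
            "baseline": [f.baseline for f in fits],
            "peak_index": [f.peak_index for f in fits],
            "peak_value": [f.peak_value for f in fits],
            "a": [f.a for f in fits],
            "b": [f.b for f in fits],
            "recovery_time_cycles": [f.recovery_time_cycles for f in fits],
            "recovery_time_seconds": [
                f.recovery_time_cycles * cycle_seconds for f in fits
            ],
            "converged": [f.converged for f in fits],
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the four output artefacts.

    Returns the run summary (also written as JSON)."""
    logging.basicConfig(level=config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        spec = CohortSpec(**sim_kwargs)
        cohort = generate_cohort(spec)
        traces = [trial.trace for trial in cohort.trials.values()]
        mean_cycle_seconds = float(
            np.mean([1.0 / p.step_frequency for p in cohort.profiles])
        )
        seed = spec.seed
        logger.info("stage simulate: %d trials", len(traces))
    else:
        traces = gio.read_manifest(config.manifest)
        mean_cycle_seconds = float("nan")  # estimated below from detected cycles
        seed = config.seed
        logger.info("stage load: %d trials from %s", len(traces), config.manifest)
    timings["simulate_or_load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records, fits, exclusions = analyze_traces(
        traces,
        hampel_window=config.hampel_window,
        hampel_threshold=config.hampel_threshold,
        min_period=config.min_period,
        prominence=config.prominence,
        max_fit_cycles=config.max_fit_cycles,
    )
    timings["score_and_recover"] = time.perf_counter() - t0
    logger.info(
        "stage score: %d records, %d recovery fits, %d exclusions",
        len(records),
        len(fits),
        len(exclusions),
    )

    t0 = time.perf_counter()
    condition = aggregate_condition_table(records)
    condition.to_csv(out / "condition_table.csv", index=False)
    _records_frame(records).to_csv(out / "records.csv", index=False)
    if np.isnan(mean_cycle_seconds) and records:
        fs = traces[0].sampling_rate
        durs = [(s.end - s.start) / fs for r in records for s in r.segments]
        mean_cycle_seconds = float(np.mean(durs))
    _recovery_frame(fits, mean_cycle_seconds).to_csv(out / "recovery.csv", index=False)
    recovery_summary_by_level(fits).to_csv(out / "recovery_summary.csv", index=False)
    timings["aggregate_and_write"] = time.perf_counter() - t0

    summary = {
        "version": __version__,
        "seed": seed,
        "n_trials": len(traces),
        "n_records": len(records),
        "n_recovery_fits": len(fits),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "outputs": [
            "condition_table.csv",
            "records.csv",
            "recovery.csv",
            "recovery_summary.csv",
        ],
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
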