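"""On-disk formats: trace CSV, trial manifest JSON, ground-truth JSON.

A trace CSV has the header ``t,ax,ay,az`` with ``t`` in seconds on a regular
1/fs grid; a manifest is a JSON array of trial entries pointing at trace and
ground-truth files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocessing import AccelTrace
from .synthetic import Cohort

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_cohort",
    "read_manifest",
]


def write_trace_csv(trace: AccelTrace, path: Path | str) -> None:
    n = len(trace)
    t = np.arange(n) / trace.sampling_rate
    df = pd.DataFrame(
        {
            "t": t,
            "ax": trace.samples[:, 0],
            "ay": trace.samples[:, 1],
            "az": trace.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(
    path: Path | str,
    *,
    participant_id: str = "",
    environment: str = "",
    fatigue_level: int = 0,
    hazard_windows: list[tuple[int, int]] | None = None,
) -> AccelTrace:
    df = pd.read_csv(path)
    missing = {"t", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    dt = np.diff(df["t"].to_numpy())
    # tolerate per-sample timestamp rounding from text serialisation
    if dt.size == 0 or not np.allclose(dt, dt.mean(), atol=5e-6):
        raise DataError(f"{path}: time column is not a regular grid")
    return AccelTrace(
        samples=df[["ax", "ay", "az"]].to_numpy(),
        sampling_rate=1.0 / float(dt.mean()),
        participant_id=participant_id,
        environment=environment,
        fatigue_level=fatigue_level,
        hazard_windows=hazard_windows or [],
    )


def write_cohort(cohort: Cohort, out_dir: Path | str) -> Path:
    """Write every trial's trace/ground truth and the manifest JSON.

    Returns the manifest path.  Layout: ``traces/<pid>_<env>_L<level>.csv``
    and ``truth/...json`` under ``out_dir``.
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    entries = []
    for (pid, env, level), trial in cohort.trials.items():
        stem = f"{pid}_{env}_L{level}"
        trace_path = out / "traces" / f"{stem}.csv"
        truth_path = out / "truth" / f"{stem}.json"
        write_trace_csv(trial.trace, trace_path)
        gt = trial.ground_truth
        truth_path.write_text(
            json.dumps(
                {
                    "cycle_boundaries": gt.cycle_boundaries,
                    "hazard_windows": gt.hazard_windows,
                    "injected_magnitude": gt.injected_magnitude,
                    "decay_coefficients": gt.decay_coefficients,
                },
                indent=1,
            )
        )
        entries.append(
            {
                "trace_path": str(trace_path.relative_to(out)),
                "participant_id": pid,
                "environment": env,
                "fatigue_level": level,
                "hazard_windows": [list(w) for w in trial.trace.hazard_windows],
                "ground_truth_path": str(truth_path.relative_to(out)),
            }
        )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return manifest_path


def read_manifest(manifest_path: Path | str) -> list[AccelTrace]:
    """Load every trial trace listed in a manifest JSON."""
    mpath = Path(manifest_path)
    root = mpath.parent
    entries = json.loads(mpath.read_text())
    traces = []
    for e in entries:
        trace_file = root / e["trace_path"]
        if not trace_file.exists():
            raise DataError(f"manifest references missing trace: {trace_file}")
        traces.append(
            read_trace_csv(
                trace_file,
                participant_id=e["participant_id"],
                environment=e["environment"],
                fatigue_level=int(e["fatigue_level"]),
                hazard_windows=[tuple(w) for w in e["hazard_windows"]],
            )
        )
    return traces
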