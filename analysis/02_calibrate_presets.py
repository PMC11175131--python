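"""Calibrate the hazard-injection magnitude of every environment x level cell.

For each of the 24 study conditions this bisects the additive vertical
acceleration offset until the mean hazard-zone DTW over a pilot cohort
matches the published condition mean (within 1%).  The level-0 non-obstacle
cell is calibrated first with self-referenced pilots (in the pipeline that
trial doubles as the reference-gait source), and its magnitude then feeds the
reference trials of all other cells.

Writes ``results/calibration.csv``; the frozen values in
``gaitstab.presets`` were produced by this script (pilot size 120, seed
20259).  Rerun after changing any generator default.
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from gaitstab.presets import default_presets
from gaitstab.synthetic import (
    calibrate_hazard_magnitude,
    make_pilots,
    _pilot_hazard_mean,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pilots", type=int, default=120)
    ap.add_argument("--seed", type=int, default=20259)
    ap.add_argument("--out", type=Path, default=Path("results/calibration.csv"))
    args = ap.parse_args()

    presets = default_presets()
    rows = []

    print("calibrating A level 0 (self-referenced pilots) ...")
    pilots_self = make_pilots(args.pilots, args.seed, presets, self_reference=True)
    s_a0 = calibrate_hazard_magnitude(presets["A"], 0, pilots_self)
    presets["A"].hazard_magnitude_by_level[0] = s_a0
    check = _pilot_hazard_mean(presets["A"], 0, s_a0, pilots_self)
    rows.append(("A", 0, presets["A"].target_hazard_dtw_by_level[0], s_a0, check))
    print(f"  A L0: magnitude {s_a0:.4f}, pilot mean {check:.2f}")

    pilots = make_pilots(args.pilots, args.seed, presets)
    for env in "ABCD":
        preset = presets[env]
        for level in range(6):
            if env == "A" and level == 0:
                continue
            t0 = time.time()
            s = calibrate_hazard_magnitude(preset, level, pilots)
            preset.hazard_magnitude_by_level[level] = s
            check = _pilot_hazard_mean(preset, level, s, pilots)
            target = preset.target_hazard_dtw_by_level[level]
            rows.append((env, level, target, s, check))
            print(
                f"  {env} L{level}: target {target:5.1f}  magnitude {s:.4f}  "
                f"pilot mean {check:5.2f}  ({time.time() - t0:.1f}s)"
            )

    df = pd.DataFrame(
        rows, columns=["environment", "level", "target_dtw", "magnitude", "pilot_mean"]
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.4f")
    print(f"wrote {args.out}")
    for env in "ABCD":
        mags = df[df.environment == env].sort_values("level")["magnitude"]
        print(f'    "{env}": (' + ", ".join(f"{m:.4f}" for m in mags) + "),")


if __name__ == "__main__":
    main()
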