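# Methods

## Problem and model

`gaitstab` quantifies walking (body) stability from a single waist-worn
tri-axial accelerometer and asks two questions: how does stability degrade
with physical fatigue and walkway hazards, and how quickly does it recover
after a hazard is met.

Stability is scored per gait cycle by dynamic time warping (DTW).  For a
reference cycle C (length I) and a test cycle T (length J), both scalar SVM
series,

    DTW(C, T) = min_W sum_q (C[i_q] - T[j_q])^2,

minimised over warp paths W that start at (1,1), end at (I,J), move by unit
steps in i and/or j, and therefore satisfy max(I,J) <= Q <= I+J-1.  The cost
uses the squared Euclidean local distance, no warping window, and no
path-length normalisation; raw costs are compared across trials.  The
reference C is the participant's own gait from non-fatigued (level-0),
non-obstacle walking, so the score reads as "deviation from this person's
natural gait": higher DTW = lower stability.

Fatigue is staged per participant as k x 10% (k = 0..5) of their individual
step-test failure count, and trials cross the 6 levels with 4 walkway
environments: A non-obstacle, B obstacle, C water-slick, D oil-slick.  The
trial-level statistic is the mean per-cycle DTW over the cycles overlapping
the hazard zone, aggregated into an environment x level condition table.

Recovery per trial: the pre-hazard baseline y0 is the mean per-cycle DTW
before the hazard; the peak point is the hazard-zone cycle with maximal DTW;
the post-peak series is fitted by least squares to y = -a ln(x) + b with
x = 1, 2, ... cycles after the peak, and the recovery time is the analytic
meeting point x* = exp((b - y0)/a) — the first x at which the fitted trend
returns to baseline.  Fits with a <= 0 carry no recovery time and are
excluded (and counted) in summaries.

## Processing chain

1. SVM: per-sample Euclidean norm of (ax, ay, az); orientation-free and
   gravity-inclusive.
2. Outlier removal: Hampel filter on the SVM series (window 11 samples,
   threshold 3 scaled MADs, edge windows truncated).  The filter order
   (after SVM, before segmentation) is a package choice.
3. Gait segmentation: peaks of a 0.25 s moving-average-smoothed SVM with
   minimum spacing 0.3 s and prominence >= 0.5 x the smoothed series' IQR
   (scale-free); consecutive peaks bound one cycle, so a cycle here is one
   step period.  All intervals are 0-based and half-open.  The 0.3 s spacing
   floor leaves headroom for fast walkers under high fatigue: at 2.1 Hz with
   tripled timing jitter a 0.4 s floor merges ~4% of level-5 trials' step
   pairs into double-length cycles, which double those trials' hazard-zone
   scores; at 0.3 s no merges occur across the generator's operating range.
4. Reference gait: the medoid cycle (minimal total DTW distance to all other
   cycles, ties to the earliest) of the participant's level-0 non-obstacle
   trial.  A medoid rather than a pointwise mean keeps the reference inside
   DTW's own metric and avoids averaging unequal-length cycles.
5. Scoring and aggregation as above.  A cycle belongs to the hazard zone if
   its interval overlaps a hazard window at all (non-empty intersection of
   half-open intervals); condition cells average trials with equal weight.

DTW details: the dynamic program g(i,j) = d(i,j) + min(g(i-1,j), g(i,j-1),
g(i-1,j-1)) is numba-compiled; backtracking prefers diagonal, then vertical,
then horizontal predecessors, making paths deterministic.  An exhaustive
path-enumeration oracle (lengths <= 8) provides the independent check in the
test suite.

## Synthetic cohorts

No recordings are deposited with the study, so cohorts are simulated with
known ground truth.  Defaults reproduce the study design: 72 participants x
6 levels x 4 environments at 128 Hz, 20 cycles per trial (~10.5 s of walking
at a typical step period, matching a 15 m course).

Per participant: step frequency ~ U(1.7, 2.1) Hz, base acceleration
amplitude ~ N(3.0, 0.3) m/s^2, sensor noise sd 0.08 m/s^2 per axis, and a
step-test failure count ~ N(120, 30) truncated at 40 steps (the published
distribution is shown only graphically; these moments are package defaults,
configurable in `CohortSpec`).

Per trial, cycle by cycle: a fixed low-order harmonic template (3 vertical
harmonics with symmetric peak, 2 anterio-posterior, 1 medio-lateral) of the
step frequency, with per-cycle timing jitter (sd 3% of the period) and
amplitude jitter (sd 4%), both multiplied by the fatigue factor
1 + 2k/5 (1x at level 0, 3x at level 5); the same factor scales sensor
noise.  Fatigue is thus modelled purely as increased gait variability — the
published work states outcomes, not a mechanism, so this is the package's
modelling choice.

Hazard injection: a constant vertical offset of magnitude s over an integer
number of cycles (default 2 cycles starting 40% into the trial).  After the
hazard the offset decays as s * max(0, b - a ln k) in cycle index k, with
(a, b) per environment and level chosen so that b = 0.9 and the decay
reaches zero at a horizon K = K0(env) * (1 + 0.4 * level) cycles
(K0 = 6/8/9/11 for A/B/C/D).  Overlapping decays stack, so a second hazard
met before recovery perturbs the gait harder — the mechanism behind the
consecutive-hazard case study.

Calibration: for each of the 24 conditions, s is found by bisection so that
the mean hazard-zone DTW over a pilot cohort (400 pilots, common random
numbers across magnitudes) matches the published condition mean within 1%.
The packaged magnitudes in `gaitstab.presets` were produced by
`analysis/02_calibrate_presets.py`; the level-0 non-obstacle cell is
calibrated first with self-referenced pilots because in the pipeline that
trial also supplies the reference gait.  The published level-4 mean for
environment A is not printed and is filled by geometric interpolation
between levels 3 and 5.

What the generator does *not* emulate: real foot-strike waveform asymmetries
and inter-stride correlation structure, surface-specific gait adaptations
(it encodes environment severity only through the calibrated perturbation
and decay horizon), drift or orientation change of the sensor, and any
physiological fatigue dynamics.  Passing cohort-level checks therefore shows
that the pipeline recovers the statistics the generator was calibrated to
encode — a parameter-recovery result, not evidence about new human data.

## Numerical choices and degenerate inputs

- DTW ties in backtracking: diagonal > vertical > horizontal; medoid ties:
  earliest cycle; peak-point ties: earliest cycle.
- The log fit needs >= 4 post-peak cycles and the baseline >= 3 pre-hazard
  cycles; trials failing either are excluded with a reason, not aborted on.
- `recovery_time` requires a > 0; flat or rising trends are reported as
  unconverged.  A converged trial additionally needs its extrapolated
  meeting point within 10^4 cycles (~90 min of walking): a near-flat but
  formally decreasing fit otherwise extrapolates to astronomical recovery
  times that would dominate any cell mean.
- Hampel with a zero-MAD window replaces nothing unless the point differs
  from the median (threshold * 0 rule), so constant series pass unchanged.
- Segmentation requires >= 2 peaks and a positive IQR; constant series raise
  a no-gait error.
- Bisection for calibration requires the unperturbed floor to sit below the
  target (it does, by a factor >= 2, at every level) and a bracket below
  magnitude 40 m/s^2.

## Problem sizes

Cohort-scale checks run 72 participants x 10 replicate cohorts for the five
headline conditions (3 600 scored trials) and 24 participants x 10 cohorts
for the full 24-condition grid; these sizes give cell-mean standard errors
well under the tolerances tested while keeping a full run in minutes on one
CPU.

## Known limitations

- The generator's post-hazard DTW decays as the square of a log-linear
  amplitude profile, so fitted (a, b) are not the injected (a, b); only the
  recovery-time *ordering* across levels and environments is asserted.
- Published per-environment Pearson correlations and the printed
  recovery-intersection x-values are internally inconsistent with the
  published condition means and trendlines they accompany; the package
  recomputes both quantities correctly from its own outputs and does not
  target the printed values (see `analysis/03`, `analysis/04`).
- Consecutive hazards stack additively in acceleration amplitude; since DTW
  is quadratic in amplitude, the second-hazard peak grows relatively faster
  in the simulator than in human cohorts, so the consecutive-hazard case
  study is read for its ordering (dense > sparse, level 5 > level 3), not
  its percentages.
- Hazard-zone membership by any overlap slightly widens the zone at its
  boundaries relative to a containment rule; calibration absorbs the
  difference.
- Because the level-0 non-obstacle trial both carries a (small) calibrated
  hazard and supplies the reference gait, its medoid can sit marginally above
  a pristine cycle; the whole pipeline — calibration included — shares this
  reference, so condition means are unaffected, but the expected hazard-zone
  DTW is strictly increasing in injected magnitude only relative to an
  uncontaminated reference.
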