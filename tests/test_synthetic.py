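"""Synthetic-cohort generator: determinism, ground truth, fatigue staging and
hazard-magnitude calibration."""

import numpy as np
import pytest
from scipy import stats

from gaitstab.dtw import dtw_align
from gaitstab.errors import CalibrationError, InvalidSpecError
from gaitstab.preprocessing import reference_from_trace
from gaitstab.stability import score_trial
from gaitstab.synthetic import (
    CohortSpec,
    ParticipantProfile,
    calibrate_hazard_magnitude,
    generate_cohort,
    make_pilots,
    sample_failure_counts,
    steps_for_level,
    synth_trial,
)


class TestStepsForLevel:
    @pytest.mark.parametrize(
        "failure_count,level,expected",
        [(200, 5, 100), (200, 0, 0), (183, 5, 92), (100, 1, 10), (125, 3, 38)],
    )
    def test_ten_percent_increments_round_half_up(self, failure_count, level, expected):
        assert steps_for_level(failure_count, level) == expected

    def test_level_out_of_range(self):
        with pytest.raises(InvalidSpecError):
            steps_for_level(100, 6)


class TestFailureCounts:
    def test_seed_determinism(self):
        spec = CohortSpec(n_participants=10, seed=3)
        a = sample_failure_counts(spec, np.random.default_rng(11))
        b = sample_failure_counts(spec, np.random.default_rng(11))
        assert a == b

    def test_truncation_at_minimum(self):
        spec = CohortSpec(
            n_participants=200, seed=0, failure_count_distribution=(45.0, 30.0, 40.0)
        )
        profiles = sample_failure_counts(spec, np.random.default_rng(1))
        assert min(p.failure_count for p in profiles) >= 40

    def test_large_sample_mean(self):
        spec = CohortSpec(n_participants=10_000, seed=0)
        profiles = sample_failure_counts(spec, np.random.default_rng(2))
        mean = np.mean([p.failure_count for p in profiles])
        # truncation at 40 barely shifts a N(120, 30) mean
        assert abs(mean - 120.0) < 1.0

    def test_invalid_cohort_size(self):
        with pytest.raises(InvalidSpecError):
            CohortSpec(n_participants=0)


class TestSynthTrial:
    def test_seed_determinism(self, profile, presets):
        t1 = synth_trial(profile, presets["B"], 2, 12, np.random.default_rng(9))
        t2 = synth_trial(profile, presets["B"], 2, 12, np.random.default_rng(9))
        assert np.array_equal(t1.trace.samples, t2.trace.samples)
        assert t1.ground_truth.cycle_boundaries == t2.ground_truth.cycle_boundaries

    def test_ground_truth_has_requested_cycles(self, profile, presets):
        trial = synth_trial(profile, presets["A"], 0, 20, np.random.default_rng(0))
        assert len(trial.ground_truth.cycle_boundaries) == 20
        bounds = trial.ground_truth.cycle_boundaries
        assert all(a1 == b0 for (_, a1), (b0, _) in zip(bounds, bounds[1:]))

    def test_hazard_must_fit_inside_trial(self, profile, presets):
        with pytest.raises(InvalidSpecError):
            synth_trial(
                profile, presets["A"], 0, 8, np.random.default_rng(0),
                hazard_cycles=[(2, 10)],
            )

    def test_unperturbed_floor_below_level0_target(self, profile, presets):
        """Without injection, hazard-zone DTW sits well under the calibrated
        level-0 condition mean (pilot over 20 seeds)."""
        vals = []
        for seed in range(20):
            trial = synth_trial(
                profile, presets["A"], 0, 20, np.random.default_rng(seed),
                injected_magnitude=0.0,
            )
            ref = reference_from_trace(trial.trace)
            vals.append(score_trial(trial.trace, ref).hazard_mean)
        assert np.mean(vals) < presets["A"].target_hazard_dtw_by_level[0]


class TestConsecutiveHazards:
    def test_second_dense_hazard_peaks_higher(self, profile, presets):
        """A hazard met before the first one has decayed rides on its
        residual perturbation, so its peak DTW is higher on average."""
        from gaitstab.stability import hazard_zone_peaks

        firsts, seconds = [], []
        for seed in range(8):
            ref = reference_from_trace(
                synth_trial(
                    profile, presets["A"], 0, 24, np.random.default_rng(500 + seed)
                ).trace
            )
            trial = synth_trial(
                profile, presets["D"], 5, 24, np.random.default_rng(seed),
                hazard_cycles=[(5, 2), (9, 2)],
            )
            rec = score_trial(trial.trace, ref)
            p1, p2 = hazard_zone_peaks(
                rec.per_cycle_dtw, rec.segments, rec.hazard_windows
            )
            firsts.append(p1)
            seconds.append(p2)
        assert np.mean(seconds) > np.mean(firsts)


class TestGenerateCohort:
    def test_product_count_small(self, presets):
        spec = CohortSpec(
            n_participants=2,
            fatigue_levels=(0, 5),
            environments=("A", "D"),
            seed=1,
            environment_presets=presets,
        )
        cohort = generate_cohort(spec)
        assert len(cohort.trials) == 8
        assert len(cohort.manifest) == 8

    def test_full_design_trial_count(self, presets):
        spec = CohortSpec(n_participants=72, seed=1, environment_presets=presets)
        assert len(generate_cohort(spec).manifest) == 72 * 6 * 4

    def test_manifest_digest_determinism(self, presets):
        spec = CohortSpec(
            n_participants=2, fatigue_levels=(0,), environments=("A",), seed=7,
            environment_presets=presets,
        )
        m1 = generate_cohort(spec).manifest.to_csv(index=False)
        m2 = generate_cohort(spec).manifest.to_csv(index=False)
        assert m1 == m2


class TestCalibration:
    def test_zero_target_needs_no_injection(self, presets):
        assert (
            calibrate_hazard_magnitude(presets["A"], 0, pilots=[], target=0.0) == 0.0
        )

    def test_constant_offset_dtw_is_length_times_delta_squared(self):
        # on a constant reference every warp path has cost Q * delta^2 and the
        # shortest path has Q = L, so DTW = L * delta^2 exactly
        L, delta = 40, 0.7
        ref = np.full(L, 9.81)
        res = dtw_align(ref, ref + delta)
        assert res.distance == pytest.approx(L * delta**2, rel=1e-12)

    def test_unreachable_target_raises(self, presets):
        pilots = make_pilots(3, 99, presets)
        with pytest.raises(CalibrationError):
            # floor is ~1 DTW; a target far below it cannot be bracketed
            calibrate_hazard_magnitude(presets["A"], 0, pilots, target=0.01)

    def test_bisection_hits_pilot_target_within_tolerance(self, presets):
        from gaitstab.synthetic import _pilot_hazard_mean

        pilots = make_pilots(25, 17, presets)
        target = 14.0
        s = calibrate_hazard_magnitude(presets["C"], 2, pilots, target=target)
        achieved = _pilot_hazard_mean(presets["C"], 2, s, pilots)
        assert achieved == pytest.approx(target, rel=0.01)

    def test_mean_dtw_monotone_in_injected_magnitude(self, presets):
        """Spearman correlation of 1 between magnitude and mean hazard DTW
        (5 magnitudes x 50 seeds)."""
        magnitudes = [0.0, 0.5, 1.0, 1.5, 2.0]
        prof = ParticipantProfile("P0", 120, 1.9, 3.0)
        # unperturbed reference trials isolate the injection mechanism from
        # the (small) hazard carried by a calibrated reference trial
        refs = []
        for seed in range(50):
            ref_trial = synth_trial(
                prof, presets["A"], 0, 20, np.random.default_rng(10_000 + seed),
                injected_magnitude=0.0,
            )
            refs.append(reference_from_trace(ref_trial.trace))
        means = []
        for s in magnitudes:
            vals = [
                score_trial(
                    synth_trial(
                        prof, presets["D"], 3, 20, np.random.default_rng(seed),
                        injected_magnitude=s,
                    ).trace,
                    refs[seed],
                ).hazard_mean
                for seed in range(50)
            ]
            means.append(np.mean(vals))
        rho = stats.spearmanr(magnitudes, means).statistic
        assert rho == pytest.approx(1.0)
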