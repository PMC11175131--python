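"""SVM computation, Hampel filtering, gait segmentation and reference-gait
extraction."""

import numpy as np
import pytest

from gaitstab.dtw import dtw_distance
from gaitstab.errors import (
    DataError,
    InsufficientDataError,
    InvalidParameterError,
    NoGaitError,
)
from gaitstab.preprocessing import (
    AccelTrace,
    SvmSeries,
    compute_svm,
    cycle_subseries,
    detect_gait_cycles,
    extract_reference_gait,
    filter_outliers,
)
from gaitstab.synthetic import ParticipantProfile, synth_trial


def make_trace(samples):
    return AccelTrace(samples=np.asarray(samples, float), sampling_rate=128.0)


class TestSvm:
    def test_zero_and_pythagorean_triples(self):
        svm = compute_svm(make_trace([[0, 0, 0], [3, 4, 0]]))
        assert svm.values.tolist() == [0.0, 5.0]

    def test_matches_euclidean_norm_oracle(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(200, 3))
        svm = compute_svm(make_trace(xyz))
        oracle = np.sqrt(np.sum(xyz**2, axis=1))
        assert np.allclose(svm.values, oracle, atol=1e-12)

    def test_rotation_invariance(self):
        """The norm ignores sensor orientation: any axis rotation leaves it put."""
        rng = np.random.default_rng(4)
        xyz = rng.normal(size=(100, 3))
        base = compute_svm(make_trace(xyz)).values
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            rotated = compute_svm(make_trace(xyz @ q)).values
            assert np.allclose(rotated, base, atol=1e-9)

    def test_non_finite_sample_named(self):
        xyz = np.ones((10, 3))
        xyz[7, 1] = np.nan
        with pytest.raises(DataError, match="7"):
            compute_svm(make_trace(xyz))


class TestHampel:
    def test_constant_series_unchanged(self):
        s = SvmSeries(np.full(50, 9.81), 128.0)
        assert np.array_equal(filter_outliers(s).values, s.values)

    def test_single_spike_replaced_by_local_median(self):
        # hand evaluation, 7-point window: window around the spike is
        # [1.0 1.1 0.9 100 1.0 0.9 1.1] -> median 1.0, MAD 0.1; the spike is
        # far beyond 3 * 1.4826 * 0.1 and is replaced by 1.0
        vals = np.array([1.0, 1.1, 0.9, 1.0, 1.1, 0.9, 100.0, 1.0, 0.9, 1.1, 1.0, 0.9, 1.1])
        out = filter_outliers(SvmSeries(vals, 128.0), window=7, threshold=3.0)
        assert out.values[6] == pytest.approx(1.0)
        untouched = np.delete(np.arange(vals.size), 6)
        assert np.array_equal(out.values[untouched], vals[untouched])

    def test_huge_threshold_is_identity(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 1, size=100)
        out = filter_outliers(SvmSeries(vals, 128.0), threshold=1e12)
        assert np.array_equal(out.values, vals)

    @pytest.mark.parametrize("window", [2, 1, 201])
    def test_bad_window_rejected(self, window):
        s = SvmSeries(np.ones(100), 128.0)
        with pytest.raises(InvalidParameterError):
            filter_outliers(s, window=window)


class TestSegmentation:
    def test_recovers_ground_truth_cycles(self, clean_trial):
        segs = detect_gait_cycles(compute_svm(clean_trial.trace))
        truth = clean_trial.ground_truth.cycle_boundaries
        assert len(segs) == len(truth) == 10
        for seg, (lo, hi) in zip(segs, truth):
            assert abs(seg.start - lo) <= 2
            assert abs(seg.end - hi) <= 2

    def test_constant_series_has_no_gait(self):
        with pytest.raises(NoGaitError):
            detect_gait_cycles(SvmSeries(np.full(1000, 9.81), 128.0))

    def test_amplitude_scaling_invariance(self, clean_trial):
        svm = compute_svm(clean_trial.trace)
        doubled = SvmSeries(2.0 * svm.values, svm.sampling_rate)
        assert detect_gait_cycles(svm) == detect_gait_cycles(doubled)

    def test_idempotent_after_filtering(self, clean_trial):
        filtered = filter_outliers(compute_svm(clean_trial.trace))
        first = detect_gait_cycles(filtered)
        again = detect_gait_cycles(filter_outliers(filtered))
        assert first == again

    def test_cycle_count_robust_to_default_noise(self, presets):
        """Across seeds, the detected count matches construction at the
        default sensor-noise level."""
        prof = ParticipantProfile("P0", 120, 1.9, 3.0)
        for seed in range(20):
            trial = synth_trial(
                prof, presets["A"], 0, 12, np.random.default_rng(seed),
                injected_magnitude=0.0,
            )
            filtered = filter_outliers(compute_svm(trial.trace))
            assert len(detect_gait_cycles(filtered)) == 12


class TestReferenceGait:
    def test_all_identical_cycles_pick_first(self):
        cyc = np.sin(np.linspace(0, 2 * np.pi, 60))
        ref = extract_reference_gait([cyc.copy() for _ in range(5)])
        assert np.array_equal(ref, cyc)

    def test_medoid_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        cycles = [rng.normal(size=rng.integers(50, 70)) for _ in range(5)]
        totals = [
            sum(dtw_distance(cycles[i], cycles[j]) for j in range(5) if j != i)
            for i in range(5)
        ]
        ref = extract_reference_gait(cycles)
        assert np.array_equal(ref, cycles[int(np.argmin(totals))])

    def test_corrupted_cycle_not_chosen(self, clean_trial):
        svm = compute_svm(clean_trial.trace)
        segs = detect_gait_cycles(svm)
        cycles = cycle_subseries(svm, segs)[:5]
        cycles[2] = cycles[2] + 50.0  # gross corruption inflates its distances
        ref = extract_reference_gait(cycles)
        assert not np.array_equal(ref, cycles[2])

    def test_too_few_cycles_rejected(self):
        with pytest.raises(InsufficientDataError):
            extract_reference_gait([np.ones(10), np.ones(10)])
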