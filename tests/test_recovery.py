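"""Baseline, peak point, logarithmic trendline fitting and recovery time."""

import numpy as np
import pytest

from gaitstab.errors import (
    EmptyHazardError,
    InsufficientDataError,
    NoRecoveryError,
)
from gaitstab.recovery import (
    RecoveryFit,
    analyze_recovery,
    before_hazard_baseline,
    find_peak_point,
    fit_log_recovery,
    recovery_summary_by_level,
    recovery_time,
)
from gaitstab.stability import score_trial
from gaitstab.preprocessing import reference_from_trace
from gaitstab.synthetic import synth_trial


def log_series(a, b, n):
    k = np.arange(1, n + 1)
    return -a * np.log(k) + b


class TestBaseline:
    def test_mean_of_constant(self):
        assert before_hazard_baseline(np.full(8, 3.3), 5) == pytest.approx(3.3)

    def test_simple_mean(self):
        assert before_hazard_baseline([8.0, 10.0, 12.0, 99.0], 3) == 10.0

    def test_post_hazard_values_ignored(self):
        y = np.array([1.0, 2.0, 3.0, 50.0, 60.0])
        z = np.array([1.0, 2.0, 3.0, -50.0, 0.0])
        assert before_hazard_baseline(y, 3) == before_hazard_baseline(z, 3)

    def test_too_few_pre_hazard_cycles(self):
        with pytest.raises(InsufficientDataError):
            before_hazard_baseline([1.0, 2.0, 3.0], 2)


class TestPeakPoint:
    def test_argmax_in_window(self):
        assert find_peak_point([5.0, 9.0, 7.0], (0, 3)) == (1, 9.0)

    def test_tie_takes_earliest(self):
        assert find_peak_point([1.0, 9.0, 9.0, 2.0], (1, 3)) == (1, 9.0)

    def test_global_max_outside_window_ignored(self):
        assert find_peak_point([100.0, 3.0, 4.0], (1, 3)) == (2, 4.0)

    def test_empty_window(self):
        with pytest.raises(EmptyHazardError):
            find_peak_point([1.0, 2.0], (1, 1))


class TestLogFit:
    def test_exact_recovery_of_published_trendline(self):
        """A noise-free y = -1.497 ln x + 18.202 series is recovered to 1e-9."""
        a, b = fit_log_recovery(log_series(1.497, 18.202, 50))
        assert a == pytest.approx(1.497, abs=1e-9)
        assert b == pytest.approx(18.202, abs=1e-9)

    def test_constant_series_gives_flat_fit(self):
        a, b = fit_log_recovery(np.full(10, 4.5))
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(4.5)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(10)
        estimates = [
            fit_log_recovery(log_series(1.5, 18.0, 30) + rng.normal(0, 0.1, 30))[0]
            for _ in range(20)
        ]
        assert abs(np.mean(estimates) - 1.5) < 0.05

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_log_recovery([3.0, 2.0, 1.0])


class TestRecoveryTime:
    def test_intercept_at_baseline_gives_one(self):
        assert recovery_time((2.0, 10.0), 10.0) == pytest.approx(1.0)

    def test_closed_form(self):
        assert recovery_time((2.0, 20.0), 10.0) == pytest.approx(np.exp(5.0))

    def test_published_level0_example(self):
        # the level-0 trendline meets its 10.82 baseline at x ~ 138.5
        assert recovery_time((1.497, 18.202), 10.82) == pytest.approx(138.545, abs=0.01)

    def test_non_decreasing_trend_rejected(self):
        with pytest.raises(NoRecoveryError):
            recovery_time((0.0, 5.0), 1.0)

    def test_monotone_in_b_and_baseline(self):
        a = 1.5
        times_b = [recovery_time((a, b), 5.0) for b in np.linspace(6, 20, 10)]
        assert np.all(np.diff(times_b) > 0)
        times_y0 = [recovery_time((a, 12.0), y0) for y0 in np.linspace(2, 10, 10)]
        assert np.all(np.diff(times_y0) < 0)

    def test_closed_form_consistency_on_noise_free_decay(self):
        """Fit + intersection on exact log decay reproduces exp((b-y0)/a)."""
        a_true, b_true, y0 = 2.2, 25.0, 11.0
        a, b = fit_log_recovery(log_series(a_true, b_true, 40))
        rt = recovery_time((a, b), y0)
        assert rt == pytest.approx(np.exp((b_true - y0) / a_true), rel=1e-9)


class TestTrialAnalysis:
    def test_full_trial_recovery_fit(self, profile, presets):
        trial = synth_trial(
            profile, presets["D"], 5, 24, np.random.default_rng(21)
        )
        ref = reference_from_trace(
            synth_trial(profile, presets["A"], 0, 24, np.random.default_rng(22)).trace
        )
        record = score_trial(trial.trace, ref)
        fit = analyze_recovery(record)
        assert fit.peak_value >= fit.baseline
        assert fit.peak_index in record.hazard_cycle_indices()
        if fit.converged:
            assert fit.recovery_time_cycles > 0


class TestSummary:
    @staticmethod
    def fit(env, level, rt, converged=True):
        return RecoveryFit(
            participant_id="P0",
            environment=env,
            fatigue_level=level,
            baseline=10.0,
            peak_index=8,
            peak_value=30.0,
            a=1.5,
            b=20.0,
            recovery_time_cycles=rt,
            converged=converged,
        )

    def test_single_fit_identity(self):
        table = recovery_summary_by_level([self.fit("A", 0, 12.0)])
        assert table.iloc[0]["mean_recovery_time"] == 12.0

    def test_mean_and_exclusions(self):
        table = recovery_summary_by_level(
            [
                self.fit("A", 0, 100.0),
                self.fit("A", 0, 200.0),
                self.fit("A", 0, np.nan, converged=False),
            ]
        )
        row = table.iloc[0]
        assert row["mean_recovery_time"] == 150.0
        assert row["n"] == 3 and row["n_excluded"] == 1
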