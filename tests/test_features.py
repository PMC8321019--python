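import numpy as np
import pytest

from articuvel.audio import SpeechMarks
from articuvel.core import VelocityCurve
from articuvel.features import (StopPoints, aggregate_peaks, peak_velocities,
                                phase_means, timing_stats, zero_crossings)
from articuvel.pc_velocity import roi_velocity
from articuvel.synthetic import default_roi, render_pc_series


def _curve(times, values):
    return VelocityCurve(np.asarray(times, float), np.asarray(values, float))


class TestZeroCrossings:
    def test_linear_interpolation_between_samples(self):
        curve = _curve([0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4],
                       [0, 2, -2, 2, -2, 2, -2])
        stops = zero_crossings(curve, [(0.75, 1.45)], noise_floor=0.0)
        assert not stops.flagged[0]
        # crossing between (0.9 s, +2) and (1.0 s, -2) is at 0.95 s
        assert stops.t[0, 1] == pytest.approx(0.95)
        np.testing.assert_allclose(stops.t[0, 1:],
                                   [0.95, 1.05, 1.15, 1.25, 1.35])

    def test_sine_roots_recovered(self):
        # [DERIVED] sin(2 pi t) sampled at 100 Hz has roots at 0, 0.5, 1,...
        t = np.arange(0, 3.0, 0.01)
        curve = _curve(t, np.sin(2 * np.pi * t))
        stops = zero_crossings(curve, [(-0.05, 2.95)], noise_floor=0.0)
        assert not stops.flagged[0]
        np.testing.assert_allclose(stops.t[0], [0.0, 0.5, 1.0, 1.5, 2.0, 2.5],
                                   atol=1e-3)

    def test_exact_zero_sample_is_the_crossing(self):
        curve = _curve([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
                       [-1, 0, 1, -1, 1, -1, 1, -1])
        stops = zero_crossings(curve, [(-0.5, 7.5)], noise_floor=0.0)
        assert stops.t[0, 0] == pytest.approx(1.0)

    def test_plateau_collapsed_to_midpoint(self):
        t = np.arange(0, 2.0, 0.1)
        v = np.where(t < 0.5, 2.0, np.where(t < 1.0, 0.1, -2.0))
        curve = _curve(t, v)
        stops_events = zero_crossings(curve, [(0, 2.0)], noise_floor=0.5)
        # one crossing expected (not six) -> flagged, but the event sits
        # at the plateau midpoint; check via the internal helper
        from articuvel.features import _crossings_in_window
        ev = _crossings_in_window(t, v, 0.5)
        assert len(ev) == 1
        assert ev[0] == pytest.approx(0.5 * (0.5 + 0.9), abs=0.05)
        assert stops_events.flagged[0]

    def test_wrong_crossing_count_flagged(self):
        t = np.arange(0, 1.0, 0.01)
        curve = _curve(t, np.ones(t.size))
        stops = zero_crossings(curve, [(0, 1.0)])
        assert stops.flagged[0]
        assert np.isnan(stops.t[0]).all()

    def test_stop_points_bracketed_by_samples(self, default_spec, default_truth):
        pc = render_pc_series(default_truth, default_spec)
        curve = roi_velocity(pc, default_roi(default_truth, default_spec))
        wins = [(k * 2.0, (k + 1) * 2.0) for k in range(default_spec.n_cycles)]
        stops = zero_crossings(curve, wins)
        assert not stops.flagged.any()
        for row, (w0, w1) in zip(stops.t, wins):
            assert np.all(row >= w0) and np.all(row <= w1)
            assert np.all(np.diff(row) > 0)

    def test_stops_match_trajectory_extrema(self, default_spec, default_truth):
        # zero-velocity points sit at extreme points of the trajectory
        pc = render_pc_series(default_truth, default_spec)
        curve = roi_velocity(pc, default_roi(default_truth, default_spec))
        wins = [(k * 2.0, (k + 1) * 2.0) for k in range(default_spec.n_cycles)]
        stops = zero_crossings(curve, wins)
        t_dense = np.arange(0.0, default_spec.duration, 1e-3)
        s = default_truth.s_mm(t_dense)
        for t1, t3 in stops.t[:, (1, 3)]:      # top points: s maximal
            for tt in (t1, t3):
                i = np.argmin(np.abs(t_dense - tt))
                assert s[i] > s.max() - 0.5
        for t2, t4 in stops.t[:, (2, 4)]:      # low points: s minimal
            for tt in (t2, t4):
                i = np.argmin(np.abs(t_dense - tt))
                assert s[i] < s.min() + 0.5


class TestPeakVelocities:
    def test_phantom_peaks_recovered(self, default_spec, default_truth):
        # [DERIVED] analytic extrema are +-peak_speed on the main strokes
        pc = render_pc_series(default_truth, default_spec)
        curve = roi_velocity(pc, default_roi(default_truth, default_spec))
        wins = [(k * 2.0, (k + 1) * 2.0) for k in range(default_spec.n_cycles)]
        peaks = peak_velocities(curve, zero_crossings(curve, wins))
        v = default_spec.peak_speed
        np.testing.assert_allclose(peaks, [[-v, v, -v]] * len(wins), rtol=0.05)

    def test_zero_curve_zero_extrema(self):
        t = np.arange(0, 2.0, 0.01)
        curve = _curve(t, np.zeros(t.size))
        stops = StopPoints(np.array([[0.1, 0.3, 0.7, 1.2, 1.7, 1.9]]),
                           np.array([False]))
        np.testing.assert_array_equal(peak_velocities(curve, stops),
                                      [[0.0, 0.0, 0.0]])

    def test_sign_pattern_minus_plus_minus(self, default_spec, default_truth):
        pc = render_pc_series(default_truth, default_spec)
        curve = roi_velocity(pc, default_roi(default_truth, default_spec))
        wins = [(k * 2.0, (k + 1) * 2.0) for k in range(default_spec.n_cycles)]
        peaks = peak_velocities(curve, zero_crossings(curve, wins))
        assert np.all(peaks[:, 0] < 0)
        assert np.all(peaks[:, 1] > 0)
        assert np.all(peaks[:, 2] < 0)

    def test_flagged_rep_gives_nan(self):
        t = np.arange(0, 2.0, 0.01)
        curve = _curve(t, np.zeros(t.size))
        stops = StopPoints(np.full((1, 6), np.nan), np.array([True]))
        assert np.isnan(peak_velocities(curve, stops)).all()


class TestPhaseMeans:
    def test_constant_absolute_velocity(self):
        t = np.arange(0, 2.0, 0.01)
        curve = _curve(t, np.full(t.size, -3.0))
        stops = StopPoints(np.array([[0.1, 0.3, 0.7, 1.2, 1.7, 1.9]]),
                           np.array([False]))
        np.testing.assert_allclose(phase_means(curve, stops), 3.0)

    def test_half_zero_half_ten(self):
        t = np.arange(0.0, 1.0, 0.001)
        v = np.where(t < 0.5, 0.0, 10.0)
        curve = _curve(t, v)
        stops = StopPoints(np.array([[-.2, 0.0, 1.0, 1.5, 2.0, 2.5]]),
                           np.array([False]))
        means = phase_means(curve, stops)
        assert means[0, 0] == pytest.approx(5.0, abs=0.05)

    def test_phantom_matches_quadrature(self, default_spec, default_truth):
        # [DERIVED] quadrature oracle on the closed-form velocity curve
        t = np.arange(0.0, default_spec.duration, 1e-3)
        curve = _curve(t, default_truth.velocity_normal_cm_s(t))
        wins = [(k * 2.0, (k + 1) * 2.0) for k in range(default_spec.n_cycles)]
        stops = zero_crossings(curve, wins, noise_floor=1e-9)
        assert not stops.flagged.any()
        means = phase_means(curve, stops)
        for k in range(stops.n_reps):
            _, t1, t2, t3, t4, _ = stops.t[k]
            for j, (a, b) in enumerate(((t1, t2), (t2, t3), (t3, t4))):
                tt = np.linspace(a, b, 20001)
                expected = np.trapezoid(np.abs(
                    default_truth.velocity_normal_cm_s(tt)), tt) / (b - a)
                assert means[k, j] == pytest.approx(expected, rel=0.02)

    def test_pc_sampled_means_close_to_quadrature(self, default_spec,
                                                  default_truth):
        # at the cine frame rate the sample mean drifts from the true
        # time average only by discretization, ~10%
        pc = render_pc_series(default_truth, default_spec)
        curve = roi_velocity(pc, default_roi(default_truth, default_spec))
        wins = [(k * 2.0, (k + 1) * 2.0) for k in range(default_spec.n_cycles)]
        stops = zero_crossings(curve, wins)
        means = phase_means(curve, stops)
        for k in range(stops.n_reps):
            _, t1, t2, t3, t4, _ = stops.t[k]
            for j, (a, b) in enumerate(((t1, t2), (t2, t3), (t3, t4))):
                tt = np.linspace(a, b, 2000)
                expected = np.mean(np.abs(
                    default_truth.velocity_normal_cm_s(tt)))
                assert means[k, j] == pytest.approx(expected, rel=0.10)


class TestTimingStats:
    def _stops(self, rows):
        rows = np.asarray(rows, dtype=float)
        return StopPoints(rows, np.zeros(len(rows), dtype=bool))

    def _marks(self, rows):
        rows = np.asarray(rows, dtype=float)
        return SpeechMarks(rows, np.zeros(len(rows), dtype=bool))

    def test_identical_marks_zero_stats(self):
        stops = self._stops([[0.0, 0.2, 0.7, 1.2, 1.7, 1.9]] * 2)
        marks = self._marks([[0.2, 0.7, 1.2, 1.7]] * 2)
        ts = timing_stats(stops, marks)
        np.testing.assert_allclose(ts.mean_ms, 0.0)
        np.testing.assert_allclose(ts.std_ms, 0.0)

    def test_hand_arithmetic(self):
        # differences {60, 70} ms -> mean 65, sample std ~7.07
        stops = self._stops([[0.0, 0.2, 0.7, 1.2, 1.7, 1.9],
                             [2.0, 2.2, 2.7, 3.2, 3.7, 3.9]])
        q = np.array([[0.26, 0.76, 1.26, 1.76],
                      [2.27, 2.77, 3.27, 3.77]])
        ts = timing_stats(stops, self._marks(q))
        np.testing.assert_allclose(ts.mean_ms, 65.0)
        np.testing.assert_allclose(ts.std_ms, 10.0 / np.sqrt(2), rtol=1e-9)

    def test_flagged_reps_excluded(self):
        stops = StopPoints(np.array([[0.0, 0.2, 0.7, 1.2, 1.7, 1.9],
                                     [np.nan] * 6]),
                           np.array([False, True]))
        marks = self._marks([[0.25, 0.75, 1.25, 1.75], [9, 10, 11, 12]])
        ts = timing_stats(stops, marks)
        assert ts.n == 1
        np.testing.assert_allclose(ts.mean_ms, 50.0)
        assert np.isnan(ts.std_ms).all()

    def test_no_matched_reps_raises(self):
        stops = StopPoints(np.full((1, 6), np.nan), np.array([True]))
        marks = self._marks([[0.2, 0.7, 1.2, 1.7]])
        with pytest.raises(ValueError):
            timing_stats(stops, marks)


class TestAggregatePeaks:
    def test_single_repetition_no_std(self):
        out = aggregate_peaks(np.array([[-7.38, 19.74, -8.43]]))
        np.testing.assert_allclose(out["mean"], [-7.38, 19.74, -8.43])
        assert out["std"] is None

    def test_two_values(self):
        out = aggregate_peaks(np.array([[-15.0], [-17.0]]))
        assert out["mean"][0] == pytest.approx(-16.0)
        assert out["std"][0] == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_nan_rows_dropped(self):
        out = aggregate_peaks(np.array([[1.0, 2.0], [np.nan, 3.0]]))
        assert out["n"] == 1
        np.testing.assert_allclose(out["mean"], [1.0, 2.0])
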