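"""Drift statistics: lengths, angles, tuning, Rayleigh, ISOA, gains."""

import numpy as np
import pytest

from foveolar import (
    GazeTrace,
    angle_to_landmark,
    convergence_ratio,
    detect_microsaccades,
    drift_direction,
    drift_length,
    drift_velocity,
    isoa,
    rayleigh_test,
    sampling_gain,
    potential_sampling_gain,
    tuning_ratio,
    trial_drift_metrics,
    aggregate_directionality,
)
from foveolar.drift import trial_exclusion
from foveolar.synthetic import DriftParams, generate_drift_trace

from conftest import straight_trace


class TestGazeTrace:
    def test_non_monotonic_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GazeTrace(times_ms=np.array([0.0, 10.0, 10.0]),
                      xy=np.zeros((3, 2)))

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError, match="window"):
            GazeTrace(times_ms=np.arange(5) * 33.3, xy=np.zeros((5, 2)) + 1,
                      window_ms=(0.0, 500.0))

    def test_strip_level_trace_decimated_to_frame_level(self):
        t = np.arange(0, 1000, 1000.0 / 960.0)
        xy = np.column_stack([np.linspace(0, 1, len(t)), np.zeros(len(t))]) + 5
        trace = GazeTrace(times_ms=t, xy=xy, frame_rate_hz=960.0,
                          window_ms=(100.0, 600.0))
        tw, _ = trace.window_samples()
        assert np.all(np.diff(tw) >= 30.0)  # ~33 ms frame steps


class TestDriftLength:
    def test_straight_line_arithmetic(self):
        trace = straight_trace(n_frames=15, step=(0.5, 0.0))
        assert drift_length(trace) == pytest.approx(7.0)
        assert drift_velocity(trace) == pytest.approx(
            7.0 / trace.window_duration_s)

    def test_closed_loop_counts_full_path(self):
        theta = np.linspace(0, 2 * np.pi, 17)
        xy = np.column_stack([np.cos(theta), np.sin(theta)]) * 3 + 10
        trace = GazeTrace(times_ms=np.arange(17) * 33.3, xy=xy)
        assert drift_length(trace) > 17.0
        assert np.allclose(xy[0], xy[-1])

    def test_length_bounds_net_displacement(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            xy = np.cumsum(rng.normal(0, 0.4, (16, 2)), axis=0) + 20
            trace = GazeTrace(times_ms=np.arange(16) * 33.3, xy=xy)
            net = np.linalg.norm(xy[-1] - xy[0])
            assert drift_length(trace) >= net - 1e-12

    def test_brownian_expectation(self):
        """Path length of a Brownian walk: E[L] = n * sigma * sqrt(pi/2)."""
        rng = np.random.default_rng(1)
        sigma, n = 0.4, 15
        lengths = []
        for _ in range(1000):
            xy = np.vstack([[0, 0],
                            np.cumsum(rng.normal(0, sigma, (n, 2)), 0)]) + 25
            lengths.append(drift_length(
                GazeTrace(times_ms=np.arange(n + 1) * 100 / 3, xy=xy)))
        expected = n * sigma * np.sqrt(np.pi / 2.0)
        assert np.mean(lengths) == pytest.approx(expected, rel=0.05)

    def test_single_frame_window_rejected(self):
        trace = GazeTrace(times_ms=np.array([0.0, 33.0, 66.0]),
                          xy=np.zeros((3, 2)) + 5, window_ms=(30.0, 40.0))
        with pytest.raises(ValueError, match="2 frames"):
            drift_length(trace)


class TestAngles:
    def test_axis_conventions(self):
        right = straight_trace(step=(0.1, 0.0))
        up = straight_trace(step=(0.0, -0.1))  # image y is downward
        assert drift_direction(right) == pytest.approx(0.0)
        assert drift_direction(up) == pytest.approx(90.0)

    def test_zero_net_displacement_is_undefined(self):
        xy = np.array([[5.0, 5.0], [6.0, 5.0], [5.0, 5.0]])
        trace = GazeTrace(times_ms=np.arange(3) * 33.3, xy=xy)
        assert np.isnan(drift_direction(trace))

    def test_angle_to_landmark_sign_convention(self):
        toward = straight_trace(step=(0.1, 0.0), start=(10.0, 10.0))
        assert angle_to_landmark(toward, (20.0, 10.0)) == pytest.approx(0.0)
        assert abs(angle_to_landmark(toward, (0.0, 10.0))) \
            == pytest.approx(180.0)
        up = straight_trace(step=(0.0, -0.1), start=(10.0, 10.0))
        assert angle_to_landmark(up, (20.0, 10.0)) == pytest.approx(90.0)

    def test_onset_at_landmark_undefined(self):
        trace = straight_trace(step=(0.1, 0.0), start=(10.0, 10.0))
        assert np.isnan(angle_to_landmark(trace, (10.0, 10.0)))

    def test_rotation_invariance_of_landmark_angle(self):
        rng = np.random.default_rng(2)
        xy = np.cumsum(rng.normal(0, 0.4, (16, 2)), axis=0) + 20
        landmark = np.array([25.0, 18.0])
        trace = GazeTrace(times_ms=np.arange(16) * 33.3, xy=xy)
        base = angle_to_landmark(trace, tuple(landmark))
        phi = np.deg2rad(73.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        trace_r = GazeTrace(times_ms=np.arange(16) * 33.3, xy=xy @ rot.T)
        assert angle_to_landmark(trace_r, tuple(rot @ landmark)) \
            == pytest.approx(base, abs=1e-9)

    def test_von_mises_bias_recovered_in_theta_retina(self):
        angles = []
        for s in range(500):
            trace, _ = generate_drift_trace(DriftParams(kappa=4.0),
                                            (25.0, 25.0),
                                            target=(35.0, 25.0), seed=s)
            angles.append(drift_direction(trace))
        mean = np.degrees(np.angle(np.exp(1j * np.deg2rad(angles)).mean()))
        assert abs(mean) < 5.0


class TestTuningRatio:
    def test_frequency_arithmetic(self):
        angles = ([0.0] * 49 + [90.0] * 17 + [180.0] * 17 + [-90.0] * 17)
        assert tuning_ratio(angles) == pytest.approx(0.49 / (0.17), rel=1e-9)

    def test_uniform_angles_give_unity(self):
        rng = np.random.default_rng(0)
        ratio = tuning_ratio(rng.uniform(-180, 180, 10000))
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_degenerate_all_toward_is_infinite(self):
        with pytest.warns(RuntimeWarning):
            assert np.isinf(tuning_ratio([0.0, 10.0, -30.0]))

    def test_no_defined_angles_rejected(self):
        with pytest.raises(ValueError):
            tuning_ratio([np.nan, np.nan])


class TestRayleigh:
    def test_identical_angles_maximally_significant(self):
        r, p = rayleigh_test([37.0] * 50)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(11)
        rej = sum(rayleigh_test(rng.uniform(-180, 180, 100))[1] < 0.05
                  for _ in range(2000))
        assert rej / 2000 == pytest.approx(0.05, abs=0.01)

    def test_power_against_von_mises(self):
        rng = np.random.default_rng(12)
        rej = sum(rayleigh_test(np.degrees(rng.vonmises(0, 1.0, 100)))[1]
                  < 0.05 for _ in range(100))
        assert rej / 100 > 0.99

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 10.0, 20.0, 30.0])


class TestISOA:
    def test_isotropic_gaussian_closed_form(self):
        """Area enclosing 68.27% of an isotropic Gaussian:
        2 pi sigma^2 ln(1/0.3173) ~ 28.9 arcmin^2 for sigma = 2."""
        rng = np.random.default_rng(123)
        pts = rng.normal(0.0, 2.0, (2000, 2))
        result = isoa(pts)
        expected = 2 * np.pi * 4.0 * np.log(1 / 0.3173)
        assert result.area == pytest.approx(expected, rel=0.10)
        assert result.contours  # at least one enclosing polygon

    def test_scaling_points_scales_area_quadratically(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0.0, 1.5, (500, 2))
        a1 = isoa(pts).area
        a2 = isoa(pts * 2.0).area
        assert a2 / a1 == pytest.approx(4.0, rel=0.05)

    def test_biased_drift_shrinks_offset_isoa(self):
        """Target-directed drift concentrates offsets: offset ISOA < onset
        ISOA, qualitatively mirroring convergence onto the CDC."""
        rng = np.random.default_rng(9)
        onsets, offsets = [], []
        for s in range(150):
            start = tuple(rng.normal(0, 3.0, 2) + 25.0)
            trace, _ = generate_drift_trace(DriftParams(kappa=2.0), start,
                                            target=(25.0, 25.0), seed=s)
            _, xy = trace.window_samples()
            onsets.append(xy[0])
            offsets.append(xy[-1])
        assert isoa(np.asarray(offsets)).area < isoa(np.asarray(onsets)).area

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            isoa(np.full((20, 2), 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            isoa(np.random.default_rng(0).normal(size=(5, 2)))


class TestMicrosaccades:
    def test_slow_drift_produces_no_events(self):
        # pure Brownian drift sampled at strip rate: no ballistic excursions,
        # so no above-threshold run survives the minimum-duration criterion
        rng = np.random.default_rng(3)
        n = 961
        step = 0.3 / np.sqrt(32.0)  # same diffusion as 0.3/frame at 30 Hz
        xy = np.vstack([[0, 0],
                        np.cumsum(rng.normal(0, step, (n - 1, 2)), 0)]) + 25
        trace = GazeTrace(times_ms=np.arange(n) * 1000.0 / 960.0, xy=xy,
                          frame_rate_hz=960.0)
        assert detect_microsaccades(trace) == []

    def test_injected_excursions_recovered(self):
        params = DriftParams(frame_rate_hz=960.0, microsaccade_rate=1.0)
        total = hits = 0
        for s in range(50):
            trace, labels = generate_drift_trace(params, (25.0, 25.0),
                                                 seed=100 + s)
            events = detect_microsaccades(trace)
            total += len(labels)
            for a, b in labels:
                hits += any(e.start_ms < b and e.end_ms > a for e in events)
        assert total == 50
        assert hits == total  # recall 1.0

    def test_event_in_window_flags_exclusion(self):
        params = DriftParams(frame_rate_hz=960.0, microsaccade_rate=1.0)
        flagged = 0
        checked = 0
        for s in range(20):
            trace, labels = generate_drift_trace(params, (25.0, 25.0),
                                                 seed=200 + s)
            a, b = labels[0]
            in_window = a < trace.window_ms[1] and b > trace.window_ms[0]
            excluded, reason = trial_exclusion(trace)
            if in_window:
                checked += 1
                flagged += excluded and reason == "microsaccade"
        assert checked > 0 and flagged == checked

    def test_blink_gap_flags_exclusion(self):
        t = np.concatenate([np.arange(0, 400, 100 / 3),
                            np.arange(500, 1000, 100 / 3)])
        xy = np.full((len(t), 2), 10.0) + np.random.default_rng(0).normal(
            0, 0.05, (len(t), 2))
        trace = GazeTrace(times_ms=t, xy=xy, window_ms=(300.0, 800.0))
        excluded, reason = trial_exclusion(trace)
        assert excluded and reason == "blink"

    def test_too_short_trace_rejected(self):
        trace = GazeTrace(times_ms=np.arange(3) * 33.0, xy=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="100 ms"):
            detect_microsaccades(trace)


class TestConvergenceAndGain:
    @pytest.mark.parametrize("start,end,expected", [
        ((0.0, 10.0), (5.0, 10.0), 0.5),    # onset 10, offset 5
        ((0.0, 10.0), (0.0, 10.0), 0.0),    # no net motion
        ((0.0, 10.0), (-2.0, 10.0), -0.2),  # drifts away
    ])
    def test_convergence_arithmetic(self, start, end, expected):
        xy = np.linspace(start, end, 16) + 20.0
        trace = GazeTrace(times_ms=np.arange(16) * 33.3, xy=xy)
        assert convergence_ratio(trace, (30.0, 30.0)) \
            == pytest.approx(expected, abs=1e-9)

    def test_onset_at_landmark_rejected(self):
        trace = straight_trace(start=(10.0, 10.0), step=(0.1, 0.0))
        with pytest.raises(ValueError):
            convergence_ratio(trace, (10.0, 10.0))

    def test_sampling_gain_arithmetic(self):
        from foveolar.activation import SamplingDensitySeries
        d = np.linspace(10000.0, 11000.0, 15)
        d = np.concatenate([d, d[::-1][1:]])
        series = SamplingDensitySeries(
            times_ms=np.arange(len(d)) * 33.3, densities=d,
            counts=np.full(len(d), 100), positions=np.zeros((len(d), 2)),
            defined=np.ones(len(d), dtype=bool))
        assert sampling_gain(series) == pytest.approx(1.10)

    def test_potential_gain_uses_cdc_density(self):
        from foveolar.activation import SamplingDensitySeries

        class LM:
            cdc_density = 13000.0

        series = SamplingDensitySeries(
            times_ms=np.arange(3) * 33.3,
            densities=np.array([10000.0, 10500.0, 10200.0]),
            counts=np.array([50, 50, 50]), positions=np.zeros((3, 2)),
            defined=np.ones(3, dtype=bool))
        assert potential_sampling_gain(LM(), series) == pytest.approx(1.3)
        assert sampling_gain(series) == pytest.approx(1.05)


@pytest.fixture(scope="module")
def landmarks():
    from foveolar.mosaic import FoveolarLandmarks
    return FoveolarLandmarks(
        pcd_location=(26.0, 24.0), pcd_value=14000.0,
        cdc_location=(25.0, 25.0), cdc_density=13600.0,
        icd_arcmin=0.54, nyquist_arcmin=0.468,
        prl_location=(20.0, 25.0))


class TestAggregation:
    def test_biased_trials_rank_cdc_above_displaced_prl(self, landmarks):
        metrics = []
        for s in range(200):
            start = tuple(np.random.default_rng(1000 + s).normal(0, 3.0, 2)
                          + 25.0)
            trace, _ = generate_drift_trace(DriftParams(kappa=2.0), start,
                                            target=(25.0, 25.0),
                                            trial_id=s, seed=s)
            metrics.append(trial_drift_metrics(trace, landmarks))
        stats = aggregate_directionality(metrics, landmarks)
        assert stats["cdc"].tuning_ratio > stats["prl"].tuning_ratio
        assert stats["cdc"].rayleigh_p < 0.001
        assert stats["cdc"].quadrant_frequencies.sum() == pytest.approx(1.0)

    def test_uniform_drift_gives_unit_ratios_everywhere(self, landmarks):
        metrics = []
        for s in range(400):
            start = tuple(np.random.default_rng(5000 + s).normal(0, 4.0, 2)
                          + 25.0)
            trace, _ = generate_drift_trace(DriftParams(kappa=0.0), start,
                                            trial_id=s, seed=s)
            metrics.append(trial_drift_metrics(trace, landmarks))
        stats = aggregate_directionality(metrics, landmarks)
        for name in ("cdc", "prl", "pcd"):
            assert stats[name].tuning_ratio == pytest.approx(1.0, abs=0.35)

    def test_kappa_monotonically_drives_tuning(self, landmarks):
        """Stronger open-loop bias concentrates drift directions on the
        landmark quadrant (window at trial onset, before any convergence)."""
        freqs = []
        params = dict(duration_ms=500.0, window_ms=(0.0, 500.0),
                      closed_loop=False)
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            metrics = []
            for s in range(300):
                rng = np.random.default_rng(7000 + s)
                start = tuple(rng.normal(0, 4.0, 2) + 25.0)
                trace, _ = generate_drift_trace(
                    DriftParams(kappa=kappa, **params), start,
                    target=(25.0, 25.0), trial_id=s, seed=s)
                metrics.append(trial_drift_metrics(trace, landmarks))
            stats = aggregate_directionality(metrics, landmarks)["cdc"]
            freqs.append(stats.quadrant_frequencies[0])
        assert all(np.diff(freqs) > 0)
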