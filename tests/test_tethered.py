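"""Tethered-cell rotation analysis: orientation, rates, bias, steps,
revolution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motorlab import synthetic_data as syn
from motorlab import tethered_analysis as teth
from motorlab.tethered_analysis import (
    AngleSeries,
    EndpointTrack,
    InsufficientDataError,
    UndefinedStatisticError,
    compute_bias,
    compute_orientation,
    compute_rotation_rate,
    detect_steps,
    mean_ccw_speed,
    revolution_variance,
)


def _track_from_angles(theta, fps=60.0, half=1.0):
    u = np.column_stack((np.cos(theta), np.sin(theta)))
    t = np.arange(len(theta)) / fps
    return EndpointTrack(t=t, end1=-half * u, end2=half * u, fps=fps)


def _series_from_rates(rates, fps=60.0):
    """Angle series whose frame-to-frame rates are exactly ``rates``."""
    dtheta = np.asarray(rates) * 2 * np.pi / fps
    theta = np.concatenate(([0.0], np.cumsum(dtheta)))
    return compute_rotation_rate(
        AngleSeries(t=np.arange(len(theta)) / fps, theta=theta), fps
    )


class TestOrientation:
    @pytest.mark.parametrize(
        "end2,expected",
        [((2.0, 0.0), 0.0), ((0.0, 2.0), np.pi / 2), ((-1.0, 0.0), np.pi)],
    )
    def test_planar_angle_of_axis(self, end2, expected):
        tr = EndpointTrack(
            t=[0.0, 1.0],
            end1=[[0.0, 0.0], [0.0, 0.0]],
            end2=[list(end2)] * 2,
            fps=1.0,
        )
        assert compute_orientation(tr).theta[0] == pytest.approx(expected)

    def test_coincident_ends_error_names_frame(self):
        tr = EndpointTrack(
            t=[0.0, 1.0, 2.0],
            end1=[[0, 0], [1, 1], [0, 0]],
            end2=[[2, 0], [1, 1], [0, 2]],
            fps=1.0,
        )
        with pytest.raises(ValueError, match="frame 1"):
            compute_orientation(tr)

    def test_recovers_simulated_angle_in_noiseless_limit(self):
        params = syn.MotorSimParams(
            duration=20, angle_noise_sd=0.0, steps_per_rev_per_unit=200_000, seed=4
        )
        track, truth = syn.simulate_tethered(params, syn.mb_protocol())
        angles = compute_orientation(track)
        assert np.allclose(angles.theta, truth.true_angle, atol=1e-9)
        assert angles.adequately_sampled

    def test_unwrapping_accumulates_full_revolutions(self):
        theta_true = np.linspace(0, 6 * np.pi, 400)  # 3 revolutions
        angles = compute_orientation(_track_from_angles(theta_true))
        assert np.allclose(angles.theta - angles.theta[0], theta_true)

    def test_undersampled_rotation_flagged(self):
        # ~0.49 rev/frame: frame-to-frame change close to pi
        theta_true = np.arange(40) * (0.49 * 2 * np.pi)
        angles = compute_orientation(_track_from_angles(theta_true))
        assert not angles.adequately_sampled


class TestRotationRate:
    def test_one_rev_per_second_is_one_hz(self):
        theta = np.arange(120) * (2 * np.pi / 60.0)
        series = compute_rotation_rate(
            AngleSeries(t=np.arange(120) / 60.0, theta=theta), 60.0
        )
        assert np.allclose(series.rate, 1.0)
        assert not series.pause_mask.any()

    def test_constant_angle_all_paused(self):
        series = compute_rotation_rate(
            AngleSeries(t=np.arange(30) / 60.0, theta=np.zeros(30)), 60.0
        )
        assert np.allclose(series.rate, 0.0)
        assert series.pause_mask.all()

    @pytest.mark.parametrize("boundary_rate", [0.05, -0.05])
    def test_pause_band_is_closed(self, boundary_rate):
        theta = np.array([0.0, boundary_rate * 2 * np.pi])
        series = compute_rotation_rate(AngleSeries(t=[0.0, 1.0], theta=theta), 1.0)
        assert abs(series.rate[0]) == pytest.approx(0.05)
        assert series.pause_mask[0]

    def test_just_outside_band_is_not_pause(self):
        series = _series_from_rates([0.06, -0.06], fps=1.0)
        assert not series.pause_mask.any()

    def test_invalid_fps_rejected(self):
        angles = AngleSeries(t=[0.0, 1.0], theta=[0.0, 1.0])
        with pytest.raises(ValueError):
            compute_rotation_rate(angles, 0.0)

    def test_smoothing_window_trailing(self):
        series = _series_from_rates(np.arange(20, dtype=float) * 0.1 + 1.0)
        assert np.isnan(series.smoothed[:9]).all()
        assert np.isfinite(series.smoothed[9:]).all()
        # trailing average of sample i covers samples i-9..i
        expected = np.mean(series.rate[0:10])
        assert series.smoothed[9] == pytest.approx(expected)

    def test_moving_average_preserves_stationary_mean(self):
        rng = np.random.default_rng(0)
        rates = 5.0 + rng.normal(0, 0.3, 5000)
        series = _series_from_rates(rates)
        valid = np.isfinite(series.smoothed)
        assert np.mean(series.smoothed[valid]) == pytest.approx(
            np.mean(series.rate[9:]), abs=1e-3
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(offset=st.floats(-np.pi, np.pi, allow_nan=False))
    def test_rate_invariant_under_planar_rotation(self, offset):
        theta = np.cumsum(np.full(50, 0.3))
        base = compute_rotation_rate(AngleSeries(t=np.arange(50.0), theta=theta), 1.0)
        rot = compute_orientation(_track_from_angles(theta + offset, fps=1.0))
        rotated = compute_rotation_rate(rot, 1.0)
        assert np.allclose(rotated.rate, base.rate, atol=1e-9)

    def test_mirror_reflection_flips_sign(self):
        theta = np.cumsum(np.full(50, 0.3))
        tr = _track_from_angles(theta, fps=1.0)
        mirrored = EndpointTrack(
            t=tr.t, end1=tr.end1 * [1, -1], end2=tr.end2 * [1, -1], fps=1.0
        )
        r0 = compute_rotation_rate(compute_orientation(tr), 1.0).rate
        r1 = compute_rotation_rate(compute_orientation(mirrored), 1.0).rate
        assert np.allclose(r1, -r0, atol=1e-9)


class TestBiasAndSpeed:
    def test_all_ccw_bias_one(self):
        assert compute_bias(_series_from_rates(np.full(40, 3.0))) == 1.0

    def test_alternating_bias_half(self):
        rates = np.tile([4.0, -4.0], 20)
        assert compute_bias(_series_from_rates(rates)) == 0.5

    def test_all_paused_bias_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compute_bias(_series_from_rates(np.zeros(20)))

    def test_switching_disabled_simulation_runs_only(self):
        # CheY-null-like motor: no CW intervals, bias locked at 1
        params = syn.MotorSimParams(duration=30, seed=9)
        track, _ = syn.simulate_tethered(params, syn.mb_protocol())
        series = compute_rotation_rate(compute_orientation(track), params.fps)
        assert compute_bias(series) == 1.0

    def test_switching_enabled_bias_below_one(self):
        params = syn.MotorSimParams(
            duration=120, ccw_to_cw_rate=0.5, cw_to_ccw_rate=1.0, seed=9
        )
        track, truth = syn.simulate_tethered(params, syn.mb_protocol())
        series = compute_rotation_rate(compute_orientation(track), params.fps)
        b = compute_bias(series)
        assert 0.0 < b < 1.0
        assert b == pytest.approx(np.mean(truth.ccw), abs=0.05)

    def test_mean_ccw_speed_excludes_cw(self):
        rates = np.tile([4.0, -4.0], 20)
        assert mean_ccw_speed(_series_from_rates(rates)) == pytest.approx(4.0)

    def test_mean_ccw_speed_constant(self):
        assert mean_ccw_speed(_series_from_rates(np.full(30, 6.0))) == pytest.approx(6.0)

    def test_no_ccw_samples_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mean_ccw_speed(_series_from_rates(np.full(20, -3.0)))

    def test_noisy_simulation_recovers_true_speed(self):
        # 3.8 units x 1.5 Hz would not be integer; use 4 units at 1.425 Hz
        params = syn.MotorSimParams(
            duration=120, unit_increment=1.425, seed=21
        )  # true speed 5.7 Hz
        track, _ = syn.simulate_tethered(params, syn.mb_protocol())
        series = compute_rotation_rate(compute_orientation(track), params.fps)
        active = ~series.pause_mask & (series.rate > 0)
        sem = np.std(series.rate[active], ddof=1) / np.sqrt(active.sum())
        assert abs(mean_ccw_speed(series) - 5.7) < 3 * sem


class TestStepDetection:
    def test_constant_series_no_events(self):
        series = _series_from_rates(np.full(3000, 6.0))
        assert detect_steps(series, min_step=0.5, min_segment=10.0) == []

    def test_short_series_no_detection(self):
        series = _series_from_rates(np.full(100, 6.0))
        assert detect_steps(series, min_step=0.5, min_segment=10.0) == []

    def test_noiseless_single_step_exact(self):
        # 6 Hz -> 7.5 Hz at t = 100 s, from a noiseless simulated motor
        proto = syn.LigandProtocol(label="glucose", onset_delay=100.0, recruited_units=1)
        params = syn.MotorSimParams(
            duration=200, angle_noise_sd=0.0, steps_per_rev_per_unit=1_000_000, seed=3
        )
        track, _ = syn.simulate_tethered(params, proto)
        series = compute_rotation_rate(compute_orientation(track), params.fps)
        events = detect_steps(series, min_step=0.5, min_segment=10.0)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.t - 100.0) <= 1.0 / params.fps
        assert ev.delta == pytest.approx(1.5, abs=0.01)
        assert ev.pre_level == pytest.approx(6.0, abs=0.01)
        assert ev.post_level == pytest.approx(7.5, abs=0.01)

    def test_downward_step_detected(self):
        rates = np.concatenate([np.full(3000, 7.5), np.full(3000, 6.0)])
        events = detect_steps(_series_from_rates(rates), min_step=0.5, min_segment=10.0)
        assert len(events) == 1
        assert events[0].delta == pytest.approx(-1.5, abs=1e-6)

    def test_small_fluctuation_below_min_step_suppressed(self):
        rates = np.concatenate([np.full(3000, 6.0), np.full(3000, 6.3)])
        assert detect_steps(_series_from_rates(rates), min_step=0.5) == []

    def test_two_steps_under_noise(self):
        proto = syn.LigandProtocol(
            label="glucose", onset_delay=100.0, recruited_units=2, recruit_stagger=550.0
        )
        params = syn.MotorSimParams(duration=900, angle_noise_sd=0.05, seed=42)
        track, _ = syn.simulate_tethered(params, proto)
        series = compute_rotation_rate(compute_orientation(track), params.fps)
        events = detect_steps(series, min_step=0.5, min_segment=60.0)
        assert len(events) == 2
        assert abs(events[0].t - 100.0) <= 5.0
        assert abs(events[1].t - 650.0) <= 5.0
        assert events[0].delta == pytest.approx(1.5, abs=0.2)
        assert events[1].delta == pytest.approx(1.5, abs=0.2)


class TestRevolutionVariance:
    def _angles(self, params, protocol=None, seed=None):
        if seed is not None:
            params = syn.MotorSimParams(**{**params.__dict__, "seed": seed})
        track, _ = syn.simulate_tethered(params, protocol or syn.mb_protocol())
        return compute_orientation(track)

    def test_deterministic_rotation_zero_variance(self):
        theta = np.arange(0, 40 * np.pi, 0.1)
        stats = revolution_variance(AngleSeries(t=np.arange(len(theta)) * 0.01, theta=theta))
        assert stats.var_time == pytest.approx(0.0, abs=1e-20)
        assert np.isinf(stats.est_steps_per_rev)

    def test_insufficient_revolutions(self):
        theta = np.linspace(0, 2 * np.pi, 100)  # one revolution only
        with pytest.raises(InsufficientDataError):
            revolution_variance(AngleSeries(t=np.linspace(0, 1, 100), theta=theta))

    def test_estimates_steps_per_rev(self):
        params = syn.MotorSimParams(
            duration=200, fps=60, baseline_units=1, unit_increment=1.0,
            steps_per_rev_per_unit=50, angle_noise_sd=0.0, seed=11,
        )
        stats = revolution_variance(self._angles(params), k=1)
        assert stats.est_steps_per_rev == pytest.approx(50, rel=0.35)

    def test_more_units_smaller_variance(self):
        # doubling bound units doubles steps/rev at fixed speed -> smoother
        common = dict(duration=120, fps=60, angle_noise_sd=0.0, seed=13)
        few = syn.MotorSimParams(baseline_units=2, unit_increment=2.5, **common)
        many = syn.MotorSimParams(baseline_units=4, unit_increment=1.25, **common)
        v_few = revolution_variance(self._angles(few)).var_time
        v_many = revolution_variance(self._angles(many)).var_time
        assert v_many < v_few

    def test_time_rescaling_invariance(self):
        params = syn.MotorSimParams(
            duration=100, baseline_units=1, unit_increment=2.0,
            steps_per_rev_per_unit=30, angle_noise_sd=0.0, seed=5,
        )
        angles = self._angles(params)
        scaled = AngleSeries(t=angles.t * 3.0, theta=angles.theta)
        a = revolution_variance(angles).est_steps_per_rev
        b = revolution_variance(scaled).est_steps_per_rev
        assert a == pytest.approx(b, rel=1e-9)


class TestEndpointTrackValidation:
    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            EndpointTrack(t=[0.0], end1=[[0, 0]], end2=[[1, 0]], fps=60.0)

    def test_rejects_non_monotonic_time(self):
        with pytest.raises(ValueError):
            EndpointTrack(
                t=[0.0, 0.0], end1=[[0, 0]] * 2, end2=[[1, 0]] * 2, fps=60.0
            )

    def test_rejects_nonfinite_coordinates(self):
        with pytest.raises(ValueError):
            EndpointTrack(
                t=[0.0, 1.0], end1=[[0, 0], [np.nan, 0]], end2=[[1, 0]] * 2, fps=60.0
            )
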