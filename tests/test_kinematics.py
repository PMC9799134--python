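"""Kinematic summaries: movement offset rule, mean speed, endpoint metrics,
path curvature and Savitzky-Golay peak-velocity direction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachprime.agent import Trajectory, minimum_jerk_trajectory
from reachprime.kinematics import (
    SAVGOL_WINDOW,
    detect_movement_offset,
    direction_at_peak_velocity,
    endpoint_metrics,
    kinematics_table,
    max_path_deviation,
    mean_speed,
    savgol_speed,
    summarize_trial,
    wrap_angle_deg,
)
from reachprime.schedule import TargetShape, TargetSpec

DT = 5.0  # ms


def make_traj(points, freeze_tail=0):
    """Trajectory from a list of (x, y) at 5 ms spacing, with an optional
    frozen tail repeating the last point."""
    pts = list(points) + [points[-1]] * freeze_tail
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    return Trajectory(t_ms=np.arange(len(pts)) * DT, x_cm=x, y_cm=y)


def linear_reach(dist_cm, duration_ms, tail_samples=20):
    n = int(duration_ms / DT)
    ys = np.linspace(0.0, dist_cm, n + 1)
    return make_traj([(0.0, y) for y in ys], freeze_tail=tail_samples)


class TestMovementOffset:
    def test_motion_then_frozen(self):
        traj = linear_reach(15.0, 500.0, tail_samples=20)
        onset, offset, flag = detect_movement_offset(traj)
        assert offset == 500.0
        assert not flag
        assert onset < offset

    def test_short_freeze_is_not_offset(self):
        """A 30 ms stationary episode (< 33.3 ms) does not end the
        movement; the later 600 ms freeze does."""
        ys = list(np.linspace(0.0, 7.0, 61))       # move until 300 ms
        ys += [7.0] * 6                            # frozen 30 ms (6 steps)
        ys += list(np.linspace(7.0, 15.0, 55))[1:]  # move again until 600 ms
        traj = make_traj([(0.0, y) for y in ys], freeze_tail=20)
        onset, offset, flag = detect_movement_offset(traj)
        assert offset == 600.0
        assert not flag

    def test_exact_33ms_freeze_ends_movement(self):
        """7 stationary inter-sample intervals (35 ms >= 33.3 ms) at 450 ms
        terminate the movement there."""
        ys = list(np.linspace(0.0, 10.0, 91))      # move until 450 ms
        ys += [10.0] * 7                           # frozen 35 ms
        ys += list(np.linspace(10.0, 15.0, 30))[1:]
        traj = make_traj([(0.0, y) for y in ys])
        _, offset, _ = detect_movement_offset(traj)
        assert offset == 450.0

    def test_all_stationary_after_leaving_home(self):
        pts = [(0.0, 0.0)] + [(0.0, 1.0)] * 12
        traj = make_traj(pts)
        onset, offset, flag = detect_movement_offset(traj)
        assert onset == 5.0
        assert offset == 10.0  # first post-onset sample
        assert not flag

    def test_never_stationary_flags_no_offset(self):
        ys = np.linspace(0.0, 15.0, 100)
        traj = make_traj([(0.0, y) for y in ys])
        _, offset, flag = detect_movement_offset(traj)
        assert flag
        assert offset == traj.t_ms[-1]

    def test_never_leaves_home_raises(self):
        traj = make_traj([(0.0, 0.01 * i) for i in range(20)])
        with pytest.raises(ValueError):
            detect_movement_offset(traj)


class TestMeanSpeed:
    @pytest.mark.parametrize("dist,dur,expected,slow", [
        (15.0, 500.0, 30.0, False),
        (15.0, 1000.0, 15.0, True),
    ])
    def test_arithmetic(self, dist, dur, expected, slow):
        traj = linear_reach(dist, dur)
        onset, offset, _ = detect_movement_offset(traj)
        speed, flag = mean_speed(traj, onset, offset)
        assert speed == pytest.approx(expected, rel=1e-9)
        assert flag is slow

    def test_boundary_is_strict_less_than(self):
        """Exactly 20 cm/s does not trip the slow flag."""
        import pandas as pd
        df = pd.DataFrame(dict(
            trial_uid=["a", "b"], target_loc_deg=[0.0, 0.0],
            endpoint_x_cm=[0.0, 0.0], endpoint_y_cm=[15.0, 15.0],
            mean_speed_cm_s=[20.0, 19.999999], max_path_deviation_cm=0.0))
        out = kinematics_table(df, None)
        assert out.slow_flag.tolist() == [False, True]

    def test_zero_duration_rejected(self):
        traj = linear_reach(15.0, 500.0)
        with pytest.raises(ValueError):
            mean_speed(traj, 100.0, 100.0)


class TestEndpointMetrics:
    def test_on_target(self):
        for loc in (-30.0, 0.0, 30.0):
            t = TargetSpec(TargetShape.DOT, loc)
            d, e = endpoint_metrics(t.center_xy, t)
            assert d == pytest.approx(0.0, abs=1e-12)
            assert e == pytest.approx(15.0)

    def test_pure_extent_displacement(self):
        t = TargetSpec(TargetShape.DOT, 0.0)
        d, e = endpoint_metrics((0.0, 17.25), t)
        assert d == 0.0
        assert e == pytest.approx(17.25)

    def test_angular_convention_clockwise_positive(self):
        t = TargetSpec(TargetShape.DOT, 0.0)
        a = math.radians(8.53)
        d, e = endpoint_metrics((15 * math.sin(a), 15 * math.cos(a)), t)
        assert d == pytest.approx(8.53, abs=1e-9)
        assert e == pytest.approx(15.0)

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            endpoint_metrics((0.0, 0.0), TargetSpec(TargetShape.DOT, 0.0))

    def test_wrap(self):
        assert wrap_angle_deg(190.0) == pytest.approx(-170.0)
        assert wrap_angle_deg(-190.0) == pytest.approx(170.0)
        assert wrap_angle_deg(180.0) == pytest.approx(180.0)


class TestMaxPathDeviation:
    def test_straight_path_zero(self):
        traj = linear_reach(15.0, 500.0)
        onset, offset, _ = detect_movement_offset(traj)
        assert max_path_deviation(traj, onset, offset) == pytest.approx(
            0.0, abs=1e-12)

    def test_semicircular_detour(self):
        """Semicircle of radius 2 bulging off a straight 15 cm reach."""
        pts = [(0.0, y) for y in np.linspace(0, 5.5, 40)]
        theta = np.linspace(0, np.pi, 41)  # includes pi/2 exactly
        pts += [(2 * np.sin(th), 7.5 - 2 * np.cos(th))
                for th in theta]  # semicircle centred at (0, 7.5), radius 2
        pts += [(0.0, y) for y in np.linspace(9.5, 15.0, 40)]
        traj = make_traj(pts, freeze_tail=10)
        dev = max_path_deviation(traj, 0.0, traj.t_ms[-1])
        assert dev == pytest.approx(2.0, abs=1e-9)

    def test_single_displaced_sample(self):
        pts = [(0.0, y) for y in np.linspace(0, 15, 100)]
        pts[50] = (3.0, pts[50][1])
        traj = make_traj(pts, freeze_tail=10)
        dev = max_path_deviation(traj, 0.0, traj.t_ms[-1])
        assert dev == pytest.approx(3.0, abs=1e-12)


class TestSavitzkyGolay:
    def test_window_is_155_ms(self):
        assert SAVGOL_WINDOW * DT == 155.0

    def test_exact_on_quadratic(self):
        """Order-2 filter differentiates a quadratic position signal
        exactly on interior samples."""
        t = np.arange(200) * DT / 1000.0
        x = 3.0 * t**2 + 2.0 * t
        y = -1.5 * t**2 + 4.0 * t
        traj = Trajectory(t_ms=np.arange(200) * DT, x_cm=x * 0, y_cm=y)
        traj2 = Trajectory(t_ms=np.arange(200) * DT, x_cm=x, y_cm=y * 0)
        for tr, deriv in ((traj, -3.0 * t + 4.0), (traj2, 6.0 * t + 2.0)):
            idx, speed = savgol_speed(tr)
            assert np.abs(speed - np.abs(deriv[idx])).max() < 1e-9

    def test_too_short_trajectory_flagged(self):
        traj = make_traj([(0.0, y) for y in np.linspace(0, 15, 20)])
        d, v, missing = direction_at_peak_velocity(
            traj, TargetSpec(TargetShape.DOT, 0.0), 0.0, traj.t_ms[-1])
        assert missing and math.isnan(d)

    def test_straight_min_jerk_reach_peak_direction(self, rng):
        """Noise-free straight reach: peak-velocity direction equals the
        target direction to machine precision."""
        target = TargetSpec(TargetShape.DOT, 30.0)
        traj = minimum_jerk_trajectory(target.center_xy, 0.5, rng,
                                       jitter_sd_cm=0.0)
        onset, offset, _ = detect_movement_offset(traj)
        d, v, missing = direction_at_peak_velocity(traj, target, onset,
                                                   offset)
        assert not missing
        assert d == pytest.approx(0.0, abs=1e-6)
        assert v > 0

    def test_initially_deviated_path(self):
        """A reach that starts 5 deg clockwise and curves back onto the
        target has a larger (more clockwise) direction at peak velocity
        than at the endpoint."""
        n = 120
        tau = np.linspace(0, 1, n)
        s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        bearing = np.radians(5.0 * (1 - s))  # 5 deg early, 0 at end
        r = 15.0 * s
        pts = list(zip(r * np.sin(bearing), r * np.cos(bearing)))
        traj = make_traj(pts, freeze_tail=10)
        target = TargetSpec(TargetShape.DOT, 0.0)
        onset, offset, _ = detect_movement_offset(traj)
        summ = summarize_trial(traj, target)
        assert summ.peakvel_direction_deg > summ.endpoint_direction_deg
        assert summ.peakvel_direction_deg > 0.5


@settings(max_examples=25, deadline=None)
@given(loc=st.sampled_from([-30.0, 0.0, 30.0]),
       dir_off=st.floats(-10, 10), ext_off=st.floats(-3, 3),
       dur=st.floats(0.42, 0.7))
def test_straight_reach_invariants(loc, dir_off, ext_off, dur):
    """For straight noise-free reaches: endpoint direction equals
    peak-velocity direction, deviation is ~0, and endpoint metrics recover
    the generating offsets."""
    rng = np.random.default_rng(0)
    ang = math.radians(loc + dir_off)
    r = 15.0 + ext_off
    traj = minimum_jerk_trajectory((r * math.sin(ang), r * math.cos(ang)),
                                   dur, rng, jitter_sd_cm=0.0)
    target = TargetSpec(TargetShape.DOT, loc)
    summ = summarize_trial(traj, target)
    assert summ.endpoint_direction_deg == pytest.approx(dir_off, abs=1e-6)
    # the tolerance-based offset rule stops just before the nominal end,
    # where the minimum-jerk tail creeps below the detectability threshold
    assert summ.endpoint_extent_cm == pytest.approx(r, abs=0.05)
    assert summ.max_path_deviation_cm < 1e-6
    assert summ.peakvel_direction_deg == pytest.approx(
        summ.endpoint_direction_deg, abs=1e-6)
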