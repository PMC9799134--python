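"""Per-trial kinematic summaries from 200-Hz stylus trajectories.

Movement onset is the first sample beyond the home region; movement offset
is the first sample after onset that is followed by at least 33.3 ms with
no detectable change in stylus coordinates.  Direction is the bearing of a
position about the home position (degrees, clockwise positive), expressed
relative to the target bearing; extent is the Euclidean distance from home.
Peak-velocity direction uses a second-order Savitzky-Golay derivative with
a 31-sample (155 ms) window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

from .agent import SAMPLE_INTERVAL_MS, SLOW_SPEED_THRESHOLD, Trajectory
from .schedule import TargetSpec

HOME_RADIUS_CM = 0.5
STATIONARY_MS = 100.0 / 3.0           # two 60-Hz monitor refreshes
STATIONARY_TOL_CM = 0.01              # "no detectable change" tolerance
# 33.3 ms at 200 Hz spans 6.67 inter-sample intervals; the first duration
# meeting "at least 33.3 ms" is 7 consecutive stationary intervals
STATIONARY_RUN = math.ceil(STATIONARY_MS / SAMPLE_INTERVAL_MS)
SAVGOL_WINDOW = 31
SAVGOL_ORDER = 2
CURVED_THRESHOLD_CM = 2.0


@dataclass(frozen=True)
class KinematicSummary:
    onset_ms: float
    offset_ms: float
    mean_speed_cm_s: float
    slow_flag: bool
    endpoint_direction_deg: float
    endpoint_extent_cm: float
    max_path_deviation_cm: float
    peakvel_direction_deg: float
    peak_speed_cm_s: float
    no_offset_flag: bool
    peakvel_missing: bool


def wrap_angle_deg(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angular difference to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def bearing_deg(x: float | np.ndarray, y: float | np.ndarray):
    """Bearing about home: degrees from +y, clockwise positive."""
    return np.degrees(np.arctan2(x, y))


def detect_movement_offset(traj: Trajectory,
                           home_radius_cm: float = HOME_RADIUS_CM
                           ) -> tuple[float, float, bool]:
    """Return ``(onset_ms, offset_ms, no_offset_flag)``.

    Onset: first sample farther than ``home_radius_cm`` from the origin.
    Offset: first sample after onset followed by >= 7 consecutive
    inter-sample displacements below tolerance (>= 33.3 ms stationary).
    If no such run exists, the last sample is returned flagged.
    """
    x, y, t = traj.x_cm, traj.y_cm, traj.t_ms
    dist_home = np.hypot(x, y)
    outside = np.flatnonzero(dist_home > home_radius_cm)
    if outside.size < 2:
        raise ValueError("trajectory never leaves the home region")
    onset_i = int(outside[0])

    step = np.hypot(np.diff(x), np.diff(y))
    stationary = step < STATIONARY_TOL_CM
    # ahead[i] = number of consecutive stationary intervals starting at i
    ahead = np.zeros(len(stationary) + 1, dtype=int)
    for i in range(len(stationary) - 1, -1, -1):
        ahead[i] = ahead[i + 1] + 1 if stationary[i] else 0
    # offset strictly follows onset: search from the first post-onset sample
    start = onset_i + 1
    candidates = np.flatnonzero(ahead[start:] >= STATIONARY_RUN)
    if candidates.size:
        offset_i = start + int(candidates[0])
        return float(t[onset_i]), float(t[offset_i]), False
    return float(t[onset_i]), float(t[-1]), True


def mean_speed(traj: Trajectory, onset_ms: float,
               offset_ms: float) -> tuple[float, bool]:
    """Path length between onset and offset divided by duration (cm/s),
    with the slow flag (< 20 cm/s, strict)."""
    if offset_ms <= onset_ms:
        raise ValueError("offset must follow onset")
    sel = (traj.t_ms >= onset_ms) & (traj.t_ms <= offset_ms)
    x, y = traj.x_cm[sel], traj.y_cm[sel]
    path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    speed = path / ((offset_ms - onset_ms) / 1000.0)
    return speed, speed < SLOW_SPEED_THRESHOLD


def endpoint_metrics(endpoint: tuple[float, float],
                     target: TargetSpec) -> tuple[float, float]:
    """Direction relative to the target bearing (deg, clockwise positive)
    and extent (cm) of an endpoint."""
    x, y = endpoint
    extent = math.hypot(x, y)
    if extent == 0.0:
        raise ValueError("endpoint at home position has undefined direction")
    direction = wrap_angle_deg(bearing_deg(x, y) - target.location_deg)
    return float(direction), extent


def max_path_deviation(traj: Trajectory, onset_ms: float,
                       offset_ms: float) -> float:
    """Maximum normal distance of any sample between onset and offset from
    the straight segment connecting home to the movement endpoint."""
    sel = (traj.t_ms >= onset_ms) & (traj.t_ms <= offset_ms)
    x, y = traj.x_cm[sel], traj.y_cm[sel]
    ex, ey = x[-1], y[-1]
    d = math.hypot(ex, ey)
    if d == 0.0:
        raise ValueError("endpoint coincides with home")
    ux, uy = ex / d, ey / d
    proj = np.clip(x * ux + y * uy, 0.0, d)
    return float(np.max(np.hypot(x - proj * ux, y - proj * uy)))


def savgol_speed(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay (order 2, 31-sample window) first-derivative speed.

    Evaluated only where the full window fits; returns ``(indices, speed)``
    where ``indices`` are sample indices into the trajectory (interior
    samples) and ``speed`` is in cm/s.
    """
    n = len(traj)
    if n < SAVGOL_WINDOW:
        return np.array([], dtype=int), np.array([])
    dt = SAMPLE_INTERVAL_MS / 1000.0
    # convolution kernel for the smoothed first derivative
    c = savgol_coeffs(SAVGOL_WINDOW, SAVGOL_ORDER, deriv=1, delta=dt,
                      use="conv")
    vx = np.convolve(traj.x_cm, c, mode="valid")
    vy = np.convolve(traj.y_cm, c, mode="valid")
    half = SAVGOL_WINDOW // 2
    idx = np.arange(half, n - half)
    return idx, np.hypot(vx, vy)


def direction_at_peak_velocity(traj: Trajectory, target: TargetSpec,
                               onset_ms: float, offset_ms: float,
                               use_velocity_bearing: bool = False,
                               ) -> tuple[float, float, bool]:
    """Movement direction at the time of peak speed, relative to the target.

    Speed is the Savitzky-Golay derivative magnitude; the peak is searched
    between onset and offset (within interior samples where the full window
    fits).  By default the direction is the bearing of the stylus *position*
    at peak time, consistent with the endpoint definition; optionally the
    bearing of the velocity vector itself.

    Returns ``(direction_deg, peak_speed, missing_flag)``; on too-short
    trajectories the direction is NaN and the flag set.
    """
    idx, speed = savgol_speed(traj)
    if idx.size == 0:
        return float("nan"), float("nan"), True
    t = traj.t_ms[idx]
    in_move = (t >= onset_ms) & (t <= offset_ms)
    if not np.any(in_move):
        return float("nan"), float("nan"), True
    k = int(np.flatnonzero(in_move)[np.argmax(speed[in_move])])
    peak_speed = float(speed[k])
    i = int(idx[k])
    if use_velocity_bearing:
        dt = SAMPLE_INTERVAL_MS / 1000.0
        c = savgol_coeffs(SAVGOL_WINDOW, SAVGOL_ORDER, deriv=1, delta=dt,
                          use="conv")
        vx = float(np.convolve(traj.x_cm, c, mode="valid")[k])
        vy = float(np.convolve(traj.y_cm, c, mode="valid")[k])
        direction = wrap_angle_deg(bearing_deg(vx, vy) - target.location_deg)
    else:
        direction = wrap_angle_deg(
            bearing_deg(traj.x_cm[i], traj.y_cm[i]) - target.location_deg)
    return float(direction), peak_speed, False


def summarize_trial(traj: Trajectory, target: TargetSpec,
                    use_velocity_bearing: bool = False) -> KinematicSummary:
    """Full kinematic summary of one reach."""
    onset, offset, no_off = detect_movement_offset(traj)
    speed, slow = mean_speed(traj, onset, offset)
    sel = (traj.t_ms >= onset) & (traj.t_ms <= offset)
    ex = float(traj.x_cm[sel][-1])
    ey = float(traj.y_cm[sel][-1])
    direction, extent = endpoint_metrics((ex, ey), target)
    deviation = max_path_deviation(traj, onset, offset)
    pv_dir, pv_speed, pv_missing = direction_at_peak_velocity(
        traj, target, onset, offset, use_velocity_bearing)
    return KinematicSummary(
        onset_ms=onset, offset_ms=offset, mean_speed_cm_s=speed,
        slow_flag=slow, endpoint_direction_deg=direction,
        endpoint_extent_cm=extent, max_path_deviation_cm=deviation,
        peakvel_direction_deg=pv_dir, peak_speed_cm_s=pv_speed,
        no_offset_flag=no_off, peakvel_missing=pv_missing)


def _target_of(row: pd.Series) -> TargetSpec:
    from .schedule import TargetShape
    return TargetSpec(TargetShape(row["target_shape"]),
                      row["target_loc_deg"])


def kinematics_table(trials: pd.DataFrame,
                     trajectories: dict[str, Trajectory] | None,
                     use_velocity_bearing: bool = False) -> pd.DataFrame:
    """Attach kinematic summary columns to a trial table.

    With trajectories, every summary is computed from the samples; the
    measured movement offset replaces the recorded endpoint.  Without
    trajectories, endpoint direction/extent are computed from the recorded
    endpoint and the simulator's nominal speed/deviation columns are kept
    (peak-velocity direction then equals endpoint direction, as the
    generator produces straight paths).
    """
    df = trials.copy()
    tloc = df["target_loc_deg"].to_numpy(float)
    if trajectories is not None:
        summaries = []
        for _, row in df.iterrows():
            s = summarize_trial(trajectories[row["trial_uid"]],
                                _target_of(row), use_velocity_bearing)
            summaries.append(s)
        for name in KinematicSummary.__dataclass_fields__:
            df[name] = [getattr(s, name) for s in summaries]
    else:
        x = df["endpoint_x_cm"].to_numpy(float)
        y = df["endpoint_y_cm"].to_numpy(float)
        df["endpoint_direction_deg"] = wrap_angle_deg(bearing_deg(x, y) - tloc)
        df["endpoint_extent_cm"] = np.hypot(x, y)
        df["slow_flag"] = df["mean_speed_cm_s"] < SLOW_SPEED_THRESHOLD
        df["peakvel_direction_deg"] = df["endpoint_direction_deg"]
        df["no_offset_flag"] = False
        df["peakvel_missing"] = False
    return df
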