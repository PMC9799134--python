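"""Generative agent for the reach-priming paradigm.

The agent reaches to targets with separable planning and execution noise in
two target-centred dimensions: movement direction (degrees about the home
position, clockwise positive) and movement extent (cm of radial distance).
Each trial the planned aim point absorbs that trial's planning draw and is
then pulled back toward the target centre by a per-dimension gain
``lambda``.  With ``lambda = 0`` the aim performs a random walk driven by
planning noise (the planned-aim-point-correction account of endpoint drift
along redundant target dimensions); with ``lambda = 1`` aim corrections are
complete and endpoints are serially independent.

During priming, the gain is low along the redundant dimension of the target
(direction for arcs, extent for radial lines) and high along the constrained
dimension, producing a lag-1-autocorrelated walk along the redundant
dimension only.  On perturbed test-phase trials the aim additionally shifts
against the feedback error by a single-trial learning rate
``B_d = b0_d + kappa * [d was redundant during this session's priming]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .schedule import (
    TARGET_LOCATIONS_DEG,
    TARGET_RADIUS_CM,
    Perturbation,
    PerturbationKind,
    SessionSchedule,
)

SAMPLE_INTERVAL_MS = 5.0  # 200 Hz tablet sampling
SLOW_SPEED_THRESHOLD = 20.0  # cm/s; error sound below this


@dataclass(frozen=True)
class Trajectory:
    """200-Hz stylus samples for one reach, cm relative to home."""

    t_ms: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("sample times must be strictly increasing")
        if math.hypot(self.x_cm[0], self.y_cm[0]) > 0.5:
            raise ValueError("trajectory must start within 0.5 cm of home")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class AgentParams:
    """Generative-model parameters.

    Noise SDs are per dimension (direction in degrees, extent in cm).
    ``lambda_redundant``/``lambda_constrained`` are the aim-correction gains
    used during priming for the redundant/constrained target dimension;
    ``lambda_dir``/``lambda_ext`` are the baseline test-phase gains, of which
    a fraction ``carryover`` is relaxed toward ``lambda_redundant`` in the
    previously redundant dimension (priming after-effect on variability).
    ``b0_dir``/``b0_ext`` are baseline single-trial learning rates and
    ``kappa`` the priming-dependent increment.  ``location_scale_plan_*``
    multiply planning-noise SD per target location (-30, 0, +30 deg),
    emulating workspace anisotropy of planning noise.
    """

    sigma_plan_dir: float = 1.6
    sigma_plan_ext: float = 0.7
    sigma_exec_dir: float = 1.6
    sigma_exec_ext: float = 0.62
    lambda_dir: float = 0.8
    lambda_ext: float = 0.8
    lambda_redundant: float = 0.15
    lambda_constrained: float = 0.8
    carryover: float = 0.65
    b0_dir: float = 0.2
    b0_ext: float = 0.2
    kappa: float = 0.15
    p_slow: float = 0.0
    p_curved: float = 0.0
    p_outlier: float = 0.0
    location_scale_plan_dir: tuple[float, float, float] = (1.25, 0.92, 0.92)
    location_scale_plan_ext: tuple[float, float, float] = (0.85, 1.06, 1.06)
    rt_mean_ms: float = 483.8
    rt_test_drop_ms: float = 23.0
    rt_sd_ms: float = 40.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_plan_dir", "sigma_plan_ext",
                     "sigma_exec_dir", "sigma_exec_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("lambda_dir", "lambda_ext", "lambda_redundant",
                     "lambda_constrained", "carryover", "b0_dir", "b0_ext",
                     "p_slow", "p_curved", "p_outlier"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def noise_free(cls, **overrides) -> "AgentParams":
        """All noise, learning and artifact parameters zeroed."""
        base = dict(
            sigma_plan_dir=0.0, sigma_plan_ext=0.0,
            sigma_exec_dir=0.0, sigma_exec_ext=0.0,
            b0_dir=0.0, b0_ext=0.0, kappa=0.0,
            p_slow=0.0, p_curved=0.0, p_outlier=0.0,
            rt_sd_ms=0.0,
            location_scale_plan_dir=(1.0, 1.0, 1.0),
            location_scale_plan_ext=(1.0, 1.0, 1.0),
        )
        base.update(overrides)
        return cls(**base)


def apply_perturbation(endpoint: tuple[float, float],
                       pert: Perturbation) -> tuple[float, float]:
    """Perturb the endpoint-cursor position.

    Rotations add the signed magnitude (degrees, clockwise positive) to the
    endpoint's bearing about home while keeping radial distance veridical;
    gain changes scale the radial distance by ``1 + delta`` while keeping
    the bearing veridical.
    """
    x, y = endpoint
    r = math.hypot(x, y)
    if r == 0.0:
        raise ValueError("endpoint at home position has undefined bearing")
    if pert.kind is PerturbationKind.NONE:
        return (x, y)
    ang = math.atan2(x, y)  # clockwise-positive bearing from +y
    if pert.kind is PerturbationKind.ROTATION:
        ang += math.radians(pert.magnitude)
    else:
        r *= 1.0 + pert.magnitude
    return (r * math.sin(ang), r * math.cos(ang))


def signed_perturbation_cm(pert: Perturbation) -> float:
    """Signed perturbation size on the common cm scale at the 15 cm target
    radius: ``15*tan(theta)`` for rotations (clockwise positive),
    ``15*delta`` for gains (overshoot positive)."""
    if pert.kind is PerturbationKind.ROTATION:
        return TARGET_RADIUS_CM * math.tan(math.radians(pert.magnitude))
    if pert.kind is PerturbationKind.GAIN:
        return TARGET_RADIUS_CM * pert.magnitude
    raise ValueError("veridical feedback has no signed perturbation size")


def minimum_jerk_trajectory(endpoint: tuple[float, float], duration_s: float,
                            rng: np.random.Generator,
                            curved_amp_cm: float = 0.0,
                            jitter_sd_cm: float = 0.002,
                            tail_ms: float = 60.0) -> Trajectory:
    """Minimum-jerk path from home to ``endpoint`` sampled at 200 Hz, with
    optional lateral detour (zero at both ends), small positional jitter on
    moving samples, and a stationary tail at the endpoint."""
    dt = SAMPLE_INTERVAL_MS / 1000.0
    n_move = max(int(round(duration_s / dt)), 4)
    tau = np.arange(n_move + 1) / n_move
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ex, ey = endpoint
    x = ex * s
    y = ey * s
    if curved_amp_cm != 0.0:
        d = math.hypot(ex, ey)
        px, py = ey / d, -ex / d  # unit normal to the straight path
        bump = curved_amp_cm * np.sin(np.pi * s)
        x = x + px * bump
        y = y + py * bump
    if jitter_sd_cm > 0:
        x[1:-1] += rng.normal(0.0, jitter_sd_cm, n_move - 1)
        y[1:-1] += rng.normal(0.0, jitter_sd_cm, n_move - 1)
    n_tail = int(round(tail_ms / SAMPLE_INTERVAL_MS))
    x = np.concatenate([x, np.full(n_tail, ex)])
    y = np.concatenate([y, np.full(n_tail, ey)])
    t = np.arange(len(x)) * SAMPLE_INTERVAL_MS
    return Trajectory(t_ms=t, x_cm=x, y_cm=y)


def _flatten_schedule(schedule: SessionSchedule) -> list[dict]:
    rows: list[dict] = []
    for pt in schedule.priming_trials:
        rows.append(dict(phase="priming", block=pt.block, miniblock=0,
                         trial_in_unit=pt.trial, role="plain",
                         target_loc_deg=pt.target.location_deg,
                         target_shape=pt.target.shape.value,
                         pert=None, feedback=pt.feedback))
    for mb in schedule.test_miniblocks:
        for t in range(mb.n_trials):
            if t == mb.n_trials - 2:
                role, pert, fb = "perturbed", mb.perturbation, True
            elif t == mb.n_trials - 1:
                role, pert, fb = "test", None, False
            else:
                role, pert, fb = "plain", None, False
            rows.append(dict(phase="test", block=0, miniblock=mb.index,
                             trial_in_unit=t, role=role,
                             target_loc_deg=mb.target.location_deg,
                             target_shape=mb.target.shape.value,
                             pert=pert, feedback=fb))
    return rows


def _phase_lambdas(params: AgentParams, condition: str,
                   phase: str) -> tuple[float, float]:
    if phase == "priming":
        if condition == "arc":       # direction redundant
            return params.lambda_redundant, params.lambda_constrained
        return params.lambda_constrained, params.lambda_redundant
    lam_dir, lam_ext = params.lambda_dir, params.lambda_ext
    if condition == "arc":
        lam_dir -= params.carryover * (lam_dir - params.lambda_redundant)
    else:
        lam_ext -= params.carryover * (lam_ext - params.lambda_redundant)
    return lam_dir, lam_ext


def simulate_session(schedule: SessionSchedule, params: AgentParams,
                     subject_id: str = "s01", session: int = 1,
                     rng: np.random.Generator | int | None = None,
                     trajectories: bool = True,
                     ) -> tuple[pd.DataFrame, dict[str, Trajectory] | None]:
    """Simulate every reach of one session.

    Returns a trial table (one row per reach) and, when ``trajectories`` is
    true, a dict mapping trial uid to its :class:`Trajectory`.  With
    ``trajectories=False`` the table still carries self-consistent
    ``mean_speed_cm_s`` / ``max_path_deviation_cm`` columns derived from the
    generative draws, so exclusion rules remain exercisable.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    condition = schedule.priming_condition
    spec_rows = _flatten_schedule(schedule)
    n = len(spec_rows)

    b_dir = params.b0_dir + (params.kappa if condition == "arc" else 0.0)
    b_ext = params.b0_ext + (params.kappa if condition == "line" else 0.0)

    loc_index = {loc: i for i, loc in enumerate(TARGET_LOCATIONS_DEG)}
    # per-location planned aim offsets: [direction deg, extent cm]
    aim = [[0.0, 0.0] for _ in TARGET_LOCATIONS_DEG]

    plan_dir = rng.normal(0.0, 1.0, n)
    plan_ext = rng.normal(0.0, 1.0, n)
    exec_dir = rng.normal(0.0, params.sigma_exec_dir, n)
    exec_ext = rng.normal(0.0, params.sigma_exec_ext, n)
    u_artifact = rng.random((n, 3))
    rt_ms = params.rt_mean_ms + rng.normal(0.0, params.rt_sd_ms, n)
    slow_inj = u_artifact[:, 0] < params.p_slow
    curved_inj = u_artifact[:, 1] < params.p_curved
    outlier_inj = u_artifact[:, 2] < params.p_outlier
    speed_nominal = np.where(slow_inj, rng.uniform(10.0, 15.0, n),
                             rng.uniform(22.0, 36.0, n))
    curved_amp = np.where(curved_inj, 2.5 + rng.uniform(0.0, 1.0, n), 0.0)

    endpoint_x = np.empty(n)
    endpoint_y = np.empty(n)
    cursor_x = np.full(n, np.nan)
    cursor_y = np.full(n, np.nan)
    trajs: dict[str, Trajectory] | None = {} if trajectories else None
    uid_prefix = f"{subject_id}_s{session}_"
    uids = [f"{uid_prefix}{row['phase']}_{i:04d}"
            for i, row in enumerate(spec_rows)]

    lam_by_phase = {ph: _phase_lambdas(params, condition, ph)
                    for ph in ("priming", "test")}
    s_plan_dir = [params.sigma_plan_dir * s
                  for s in params.location_scale_plan_dir]
    s_plan_ext = [params.sigma_plan_ext * s
                  for s in params.location_scale_plan_ext]

    plan_dir_l = plan_dir.tolist()
    plan_ext_l = plan_ext.tolist()
    exec_dir_l = exec_dir.tolist()
    exec_ext_l = exec_ext.tolist()

    for i, row in enumerate(spec_rows):
        li = loc_index[row["target_loc_deg"]]
        lam_dir, lam_ext = lam_by_phase[row["phase"]]

        pd_draw = plan_dir_l[i] * s_plan_dir[li]
        pe_draw = plan_ext_l[i] * s_plan_ext[li]

        dir_off = aim[li][0] + pd_draw + exec_dir_l[i]
        ext_off = aim[li][1] + pe_draw + exec_ext_l[i]
        aim[li][0] = (aim[li][0] + pd_draw) * (1.0 - lam_dir)
        aim[li][1] = (aim[li][1] + pe_draw) * (1.0 - lam_ext)

        r = TARGET_RADIUS_CM + ext_off
        ang = math.radians(row["target_loc_deg"] + dir_off)
        ex, ey = r * math.sin(ang), r * math.cos(ang)

        if outlier_inj[i]:
            ta = math.radians(row["target_loc_deg"])
            tx, ty = (TARGET_RADIUS_CM * math.sin(ta),
                      TARGET_RADIUS_CM * math.cos(ta))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            dist = rng.uniform(10.5, 14.0)
            ex, ey = tx + dist * math.cos(phi), ty + dist * math.sin(phi)

        pert: Perturbation | None = row["pert"]
        if row["role"] == "perturbed":
            if pert is not None and pert.kind is not PerturbationKind.NONE:
                cursor_x[i], cursor_y[i] = apply_perturbation((ex, ey), pert)
                if pert.kind is PerturbationKind.ROTATION:
                    u = math.tan(math.radians(aim[li][0])) - \
                        b_dir * math.tan(math.radians(pert.magnitude))
                    aim[li][0] = math.degrees(math.atan(u))
                else:
                    aim[li][1] -= b_ext * TARGET_RADIUS_CM * pert.magnitude
            else:
                cursor_x[i], cursor_y[i] = ex, ey
        elif row["role"] == "test":
            rt_ms[i] -= params.rt_test_drop_ms

        endpoint_x[i] = ex
        endpoint_y[i] = ey

        if trajectories:
            dist = math.hypot(ex, ey)
            duration = min(max(dist / speed_nominal[i], 0.25), 1.5)
            trajs[uids[i]] = minimum_jerk_trajectory(  # type: ignore[index]
                (ex, ey), duration, rng, curved_amp_cm=curved_amp[i])

    perts = [row["pert"] for row in spec_rows]
    df = pd.DataFrame({
        "trial_uid": uids,
        "subject": subject_id, "session": session, "priming": condition,
        "phase": [r["phase"] for r in spec_rows],
        "block": [r["block"] for r in spec_rows],
        "miniblock": [r["miniblock"] for r in spec_rows],
        "trial_in_unit": [r["trial_in_unit"] for r in spec_rows],
        "trial_index": np.arange(n),
        "role": [r["role"] for r in spec_rows],
        "target_loc_deg": [r["target_loc_deg"] for r in spec_rows],
        "target_shape": [r["target_shape"] for r in spec_rows],
        "pert_kind": [p.kind.value if p is not None else "none"
                      for p in perts],
        "pert_magnitude": [p.magnitude if p is not None else 0.0
                           for p in perts],
        "endpoint_x_cm": endpoint_x, "endpoint_y_cm": endpoint_y,
        "cursor_x_cm": cursor_x, "cursor_y_cm": cursor_y,
        "feedback": [bool(r["feedback"]) for r in spec_rows],
        "rt_ms": rt_ms,
        "slow_injected": slow_inj, "curved_injected": curved_inj,
        "outlier_injected": outlier_inj,
    })
    if not trajectories:
        # endpoint-only stand-ins for the kinematic summary
        df["mean_speed_cm_s"] = speed_nominal
        df["max_path_deviation_cm"] = curved_amp
    return df, trajs
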