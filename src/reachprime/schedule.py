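"""Trial schedules for the two-session reach-priming paradigm.

Each session comprises a priming phase (7 blocks x 60 reaches to arc- or
radial-line-shaped targets) followed by a test phase (90 mini-blocks of 3-5
reaches to dot targets, with a rotation or gain perturbation of the endpoint
cursor on the penultimate trial of most mini-blocks).

Coordinate frame: home position at the origin, straight ahead along +y,
angles in degrees measured from +y with clockwise positive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

TARGET_RADIUS_CM = 15.0
TARGET_EXTENT_CM = 8.0
DOT_DIAMETER_CM = 0.8
TARGET_LOCATIONS_DEG = (-30.0, 0.0, 30.0)

ROTATION_MAGNITUDES_DEG = (8.53, 5.71)
GAIN_DELTAS = (0.15, 0.10)

N_MINIBLOCKS = 90
N_CYCLES = 9
MINIBLOCK_LENGTHS = (3, 4, 5)
N_PRIMING_BLOCKS = 7
TRIALS_PER_PRIMING_BLOCK = 60
PRIMING_FEEDBACK_FRACTION = 0.25
BREAKS_AFTER = (30, 60)


class TargetShape(str, enum.Enum):
    ARC = "arc"
    RADIAL_LINE = "radial_line"
    DOT = "dot"


class PerturbationKind(str, enum.Enum):
    NONE = "none"
    ROTATION = "rotation"
    GAIN = "gain"


class ScheduleError(RuntimeError):
    """Raised when schedule constraints cannot be satisfied."""


@dataclass(frozen=True)
class TargetSpec:
    """A reach target: shape, angular location and spatial extent.

    Arc targets are centred on the home position (direction redundant);
    radial lines point away from home (extent redundant); dots constrain
    both dimensions.
    """

    shape: TargetShape
    location_deg: float
    radius_cm: float = TARGET_RADIUS_CM
    extent_cm: float = TARGET_EXTENT_CM

    def __post_init__(self) -> None:
        if self.location_deg not in TARGET_LOCATIONS_DEG:
            raise ValueError(f"target location {self.location_deg} not in "
                             f"{TARGET_LOCATIONS_DEG}")
        if self.radius_cm <= 0:
            raise ValueError("target radius must be positive")

    @property
    def arc_central_angle_deg(self) -> float:
        """Central angle subtended by an arc of this extent (degrees)."""
        return math.degrees(self.extent_cm / self.radius_cm)

    @property
    def center_xy(self) -> tuple[float, float]:
        a = math.radians(self.location_deg)
        return (self.radius_cm * math.sin(a), self.radius_cm * math.cos(a))


def dot_target(location_deg: float) -> TargetSpec:
    return TargetSpec(TargetShape.DOT, location_deg, extent_cm=DOT_DIAMETER_CM)


@dataclass(frozen=True)
class Perturbation:
    """Endpoint-cursor perturbation: rotation (deg, clockwise positive) or
    radial gain change (signed gain delta, overshoot positive)."""

    kind: PerturbationKind
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind is PerturbationKind.NONE:
            if self.magnitude != 0.0:
                raise ValueError("veridical feedback has zero magnitude")
        elif self.kind is PerturbationKind.ROTATION:
            if abs(self.magnitude) not in ROTATION_MAGNITUDES_DEG:
                raise ValueError(f"disallowed rotation {self.magnitude}")
        elif self.kind is PerturbationKind.GAIN:
            # 0 is the degenerate identity gain (gain factor 1.0)
            if self.magnitude != 0.0 and not any(
                    math.isclose(abs(self.magnitude), g)
                    for g in GAIN_DELTAS):
                raise ValueError(f"disallowed gain delta {self.magnitude}")

    @property
    def label(self) -> str:
        if self.kind is PerturbationKind.NONE:
            return "none"
        return f"{self.kind.value}{self.magnitude:+g}"


VERIDICAL = Perturbation(PerturbationKind.NONE)


def all_perturbations() -> list[Perturbation]:
    """The eight perturbations used in the test phase."""
    perts = []
    for m in ROTATION_MAGNITUDES_DEG:
        perts += [Perturbation(PerturbationKind.ROTATION, s * m)
                  for s in (+1, -1)]
    for g in GAIN_DELTAS:
        perts += [Perturbation(PerturbationKind.GAIN, s * g)
                  for s in (+1, -1)]
    return perts


@dataclass(frozen=True)
class MiniBlock:
    """3-5 consecutive reaches to one dot target; the perturbation applies
    on the penultimate trial, adaptation is read out on the last."""

    index: int
    n_trials: int
    target: TargetSpec
    perturbation: Perturbation

    def __post_init__(self) -> None:
        if self.n_trials not in MINIBLOCK_LENGTHS:
            raise ValueError("mini-block length must be 3, 4 or 5")

    @property
    def perturbed_trial_index(self) -> int:
        return self.n_trials - 2  # zero-based penultimate


@dataclass(frozen=True)
class PrimingTrial:
    block: int          # 1..7
    trial: int          # zero-based within block
    target: TargetSpec
    feedback: bool      # one-dimensional endpoint feedback shown


@dataclass
class SessionSchedule:
    """Full schedule of one session. The test part is built once per subject
    and reused in both sessions; the priming part differs by target shape."""

    priming_condition: str                      # "arc" or "line"
    priming_trials: list[PrimingTrial] = field(default_factory=list)
    test_miniblocks: list[MiniBlock] = field(default_factory=list)
    breaks_after: tuple[int, ...] = BREAKS_AFTER

    @property
    def n_test_trials(self) -> int:
        return sum(mb.n_trials for mb in self.test_miniblocks)


def _condition_shape(condition: str) -> TargetShape:
    if condition == "arc":
        return TargetShape.ARC
    if condition == "line":
        return TargetShape.RADIAL_LINE
    raise ValueError(f"unknown priming condition {condition!r}")


def build_test_schedule(rng_seed: int | np.random.Generator) -> list[MiniBlock]:
    """Pseudorandomize the 90 test mini-blocks.

    The sequence is 9 cycles of 10 mini-blocks; each cycle contains each of
    the 8 perturbations exactly once plus 2 veridical mini-blocks, in
    shuffled order, so a perturbation never repeats within a cycle.
    Mini-block lengths (3/4/5) are balanced against perturbation (3 each per
    perturbation, 6 each veridical) and, independently, target locations are
    balanced against length (10 per location per length, 30 per location
    overall).
    """
    rng = np.random.default_rng(rng_seed)
    perts = all_perturbations()

    # perturbation order: shuffled cycles of (8 perturbations + 2 veridical)
    order: list[Perturbation] = []
    for _ in range(N_CYCLES):
        cycle = perts + [VERIDICAL, VERIDICAL]
        rng.shuffle(cycle)
        order.extend(cycle)

    # lengths: each perturbation gets 3/4/5 three times across its 9 slots;
    # veridical gets each length six times across its 18 slots
    length_pool: dict[str, list[int]] = {}
    for p in perts:
        pool = [n for n in MINIBLOCK_LENGTHS for _ in range(3)]
        rng.shuffle(pool)
        length_pool[p.label] = pool
    vpool = [n for n in MINIBLOCK_LENGTHS for _ in range(6)]
    rng.shuffle(vpool)
    length_pool[VERIDICAL.label] = vpool
    lengths = [length_pool[p.label].pop() for p in order]

    # locations: within each length group (30 mini-blocks) assign each
    # location 10 times, shuffled -> location x length exactly balanced
    locations = np.empty(N_MINIBLOCKS)
    for n in MINIBLOCK_LENGTHS:
        idx = [i for i, ln in enumerate(lengths) if ln == n]
        locs = [loc for loc in TARGET_LOCATIONS_DEG for _ in range(10)]
        rng.shuffle(locs)
        if len(idx) != len(locs):
            raise ScheduleError("length marginal infeasible")
        locations[idx] = locs

    miniblocks = [
        MiniBlock(index=i + 1, n_trials=lengths[i],
                  target=dot_target(locations[i]), perturbation=order[i])
        for i in range(N_MINIBLOCKS)
    ]
    _validate_test_schedule(miniblocks)
    return miniblocks


def _validate_test_schedule(mbs: list[MiniBlock]) -> None:
    if len(mbs) != N_MINIBLOCKS:
        raise ScheduleError("expected 90 mini-blocks")
    for c in range(N_CYCLES):
        cycle = mbs[10 * c:10 * (c + 1)]
        labels = [m.perturbation.label for m in cycle
                  if m.perturbation.kind is not PerturbationKind.NONE]
        if len(labels) != 8 or len(set(labels)) != 8:
            raise ScheduleError(f"cycle {c} does not contain each "
                                "perturbation exactly once")
    for p in all_perturbations():
        sel = [m for m in mbs if m.perturbation.label == p.label]
        if len(sel) != 9:
            raise ScheduleError(f"{p.label} not in 9 mini-blocks")
        for n in MINIBLOCK_LENGTHS:
            if sum(m.n_trials == n for m in sel) != 3:
                raise ScheduleError("perturbation x length imbalance")
    for n in MINIBLOCK_LENGTHS:
        sel = [m for m in mbs if m.n_trials == n]
        if len(sel) != 30:
            raise ScheduleError("length marginal violated")
        for loc in TARGET_LOCATIONS_DEG:
            if sum(m.target.location_deg == loc for m in sel) != 10:
                raise ScheduleError("location x length imbalance")


def build_priming_schedule(condition: str,
                           rng_seed: int | np.random.Generator
                           ) -> list[PrimingTrial]:
    """Pseudorandomize the 420 priming trials (7 blocks x 60).

    Each block presents each target location 20 times in shuffled order and
    contains exactly 15 feedback trials (25% per block, hence 25% overall).
    """
    rng = np.random.default_rng(rng_seed)
    shape = _condition_shape(condition)
    n_fb = int(TRIALS_PER_PRIMING_BLOCK * PRIMING_FEEDBACK_FRACTION)
    trials: list[PrimingTrial] = []
    for block in range(1, N_PRIMING_BLOCKS + 1):
        locs = [loc for loc in TARGET_LOCATIONS_DEG
                for _ in range(TRIALS_PER_PRIMING_BLOCK // 3)]
        rng.shuffle(locs)
        fb = np.zeros(TRIALS_PER_PRIMING_BLOCK, dtype=bool)
        fb[rng.choice(TRIALS_PER_PRIMING_BLOCK, size=n_fb, replace=False)] = True
        for t, loc in enumerate(locs):
            trials.append(PrimingTrial(
                block=block, trial=t,
                target=TargetSpec(shape, loc), feedback=bool(fb[t])))
    return trials


def build_session_schedule(condition: str, priming_seed: int,
                           test_seed: int) -> SessionSchedule:
    """Assemble a full session schedule from separate seeds, so the test
    part can be held constant across a subject's two sessions."""
    return SessionSchedule(
        priming_condition=condition,
        priming_trials=build_priming_schedule(condition, priming_seed),
        test_miniblocks=build_test_schedule(test_seed),
    )
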