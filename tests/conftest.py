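import numpy as np
import pytest

from reachprime.agent import AgentParams, simulate_session
from reachprime.kinematics import kinematics_table
from reachprime.schedule import (
    PrimingTrial,
    SessionSchedule,
    TargetShape,
    TargetSpec,
    build_test_schedule,
)


@pytest.fixture(scope="session")
def test_only_schedule():
    """A session schedule with only the test phase (seed 5)."""
    def make(condition="arc", seed=5):
        return SessionSchedule(priming_condition=condition,
                               priming_trials=[],
                               test_miniblocks=build_test_schedule(seed))
    return make


@pytest.fixture(scope="session")
def long_single_target_schedule():
    """Arc-priming schedule with many reaches to a single target, for
    random-walk statistics."""
    def make(n_trials, location=0.0, condition="arc"):
        trials = [PrimingTrial(block=1 + i // 60, trial=i % 60,
                               target=TargetSpec(TargetShape.ARC, location),
                               feedback=False)
                  for i in range(n_trials)]
        return SessionSchedule(priming_condition=condition,
                               priming_trials=trials, test_miniblocks=[])
    return make


@pytest.fixture(scope="session")
def noiseless_learning_pairs(test_only_schedule):
    """Noise-free sessions with full aim correction (lambda = 1), so every
    perturbed->test response change equals -B * perturbation exactly."""
    from reachprime.adaptation import build_pair_table

    def make(condition, **params):
        base = dict(lambda_dir=1.0, lambda_ext=1.0, carryover=0.0)
        base.update(params)
        p = AgentParams.noise_free(**base)
        df, _ = simulate_session(test_only_schedule(condition), p, rng=0,
                                 trajectories=False)
        return build_pair_table(kinematics_table(df, None))
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
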