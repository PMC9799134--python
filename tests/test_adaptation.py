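"""Pair table construction, per-subject OLS models and fit-quality gates."""

import math

import numpy as np
import pandas as pd
import pytest

from reachprime.adaptation import (
    COMBINED_TERMS,
    SingleTrialAdaptation,
    build_pair_table,
    fit_subject_models,
    ols_fit,
    r2_gate,
    signed_perturbation_cm,
)
from reachprime.agent import AgentParams, simulate_session
from reachprime.kinematics import kinematics_table
from reachprime.schedule import Perturbation, PerturbationKind

ROT = PerturbationKind.ROTATION
GAIN = PerturbationKind.GAIN


class TestSignedPerturbation:
    @pytest.mark.parametrize("kind,mag,cm", [
        (ROT, 8.53, 2.25), (ROT, -8.53, -2.25),
        (ROT, 5.71, 1.50), (ROT, -5.71, -1.50),
        (GAIN, 0.15, 2.25), (GAIN, -0.15, -2.25),
        (GAIN, 0.10, 1.50), (GAIN, -0.10, -1.50),
    ])
    def test_printed_equivalences(self, kind, mag, cm):
        assert signed_perturbation_cm(
            Perturbation(kind, mag)) == pytest.approx(cm, abs=0.005)

    def test_identity_gain_is_zero(self):
        assert signed_perturbation_cm(Perturbation(GAIN, 0.0)) == 0.0

    def test_veridical_rejected(self):
        with pytest.raises(ValueError):
            signed_perturbation_cm(Perturbation(PerturbationKind.NONE))


@pytest.fixture(scope="module")
def trials(test_only_schedule):
    df, _ = simulate_session(test_only_schedule("arc"), AgentParams(),
                             rng=0, trajectories=False)
    return kinematics_table(df, None)


class TestPairTable:
    def test_one_observation_per_perturbed_miniblock(self, trials):
        pairs = build_pair_table(trials)
        assert len(pairs) == 72  # 36 rotation + 36 gain mini-blocks
        assert (pairs[pairs.pert_kind == "rotation"].dimension
                == "direction").all()
        assert (pairs[pairs.pert_kind == "gain"].dimension == "extent").all()

    def test_veridical_policy(self, trials):
        default = build_pair_table(trials)
        assert not (default.pert_kind == "none").any()
        with_v = build_pair_table(trials, include_veridical=True)
        verid = with_v[with_v.pert_kind == "none"]
        assert len(verid) == 36  # 18 mini-blocks x 2 dimensions
        assert (verid.signed_perturbation_cm == 0).all()

    def test_excluded_pair_dropped(self, trials):
        full = build_pair_table(trials)
        # drop one test trial -> its mini-block cannot form a pair
        victim = trials[(trials.role == "test")
                        & (trials.miniblock == full.miniblock.iloc[0])]
        reduced = build_pair_table(trials.drop(victim.index))
        assert len(reduced) < len(full)

    def test_z_scores_are_per_subject_per_dimension(self, trials):
        pairs = build_pair_table(trials)
        for _, g in pairs.groupby(["subject", "dimension"]):
            assert g.delta_z.mean() == pytest.approx(0.0, abs=1e-12)
            assert g.delta_z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestOLS:
    def test_matches_statsmodels(self, rng):
        """Coefficients, R^2, AIC and BIC agree with statsmodels OLS."""
        import statsmodels.api as sm

        X = np.column_stack([np.ones(40), rng.normal(0, 1, (40, 3))])
        y = rng.normal(0, 1, 40)
        mine = ols_fit(X, y, ("c", "x1", "x2", "x3"))
        ref = sm.OLS(y, X).fit()
        assert mine.params == pytest.approx(ref.params, abs=1e-10)
        assert mine.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
        assert mine.aic == pytest.approx(ref.aic, abs=1e-8)
        assert mine.bic == pytest.approx(ref.bic, abs=1e-8)

    def test_exact_fit_noiseless_linear_fixture(self, rng):
        """Deltas constructed as an exact linear function of the
        predictors give R^2 = 1 and coefficients to 1e-9."""
        p = rng.choice([-2.25, -1.5, 1.5, 2.25], 48)
        g = np.tile([0.0, 1.0], 24)
        d = np.repeat([0.0, 1.0], 24)
        beta = np.array([0.3, -0.25, 0.1, -0.05, 0.07, -0.12, 0.02, -0.2])
        X = np.column_stack([np.ones(48), p, g, d, p * g, p * d, g * d,
                             p * g * d])
        y = X @ beta
        fit = ols_fit(X, y, COMBINED_TERMS)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.params == pytest.approx(beta, abs=1e-9)

    def test_rank_deficiency_detected(self):
        X = np.column_stack([np.ones(20), np.zeros(20)])
        with pytest.raises(ValueError, match="rank-deficient"):
            ols_fit(X, np.arange(20.0), ("c", "z"))

    def test_too_few_observations(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="at least"):
            ols_fit(X, np.arange(3.0), ("a", "b"))


class TestSlopeRecovery:
    def test_noiseless_slopes_equal_minus_b(self, noiseless_learning_pairs):
        """Dimension-wise perturbation coefficient equals -B_d exactly on
        noiseless pairs (cm scale)."""
        frames = []
        for session, cond in ((1, "arc"), (2, "line")):
            pairs = noiseless_learning_pairs(cond, b0_dir=0.3, b0_ext=0.2,
                                             kappa=0.1)
            pairs["session"] = session
            frames.append(pairs)
        pairs = pd.concat(frames, ignore_index=True)
        pairs["delta_native"] = np.where(pairs.dimension == "direction",
                                         pairs.delta_cm, pairs.delta_native)
        z = pairs.groupby(["subject", "dimension"])["delta_native"] \
            .transform(lambda v: (v - v.mean()) / v.std(ddof=1))
        pairs["delta_z"] = z
        fits = fit_subject_models(pairs)
        c_dir = fits["dimwise_direction"].coef
        c_ext = fits["dimwise_extent"].coef
        # arc dummy = 1: pert coefficient is the line-priming slope, the
        # interaction adds the arc-vs-line difference
        assert c_dir["pert"] == pytest.approx(-0.3, abs=1e-9)
        assert c_dir["pert_x_priming"] == pytest.approx(-0.1, abs=1e-9)
        assert c_ext["pert"] == pytest.approx(-0.2 - 0.1, abs=1e-9)
        assert c_ext["pert_x_priming"] == pytest.approx(+0.1, abs=1e-9)

    def test_dummy_swap_flips_interactions_only(self, test_only_schedule):
        df1, _ = simulate_session(test_only_schedule("arc"), AgentParams(),
                                  subject_id="s01", session=1, rng=1,
                                  trajectories=False)
        df2, _ = simulate_session(test_only_schedule("line"), AgentParams(),
                                  subject_id="s01", session=2, rng=2,
                                  trajectories=False)
        trials = kinematics_table(pd.concat([df1, df2], ignore_index=True),
                                  None)
        pairs = build_pair_table(trials)
        fits = fit_subject_models(pairs)
        swapped = pairs.copy()
        swapped["priming_dummy"] = 1.0 - swapped["priming_dummy"]
        fits_sw = fit_subject_models(swapped)
        a, b = fits["combined"], fits_sw["combined"]
        assert b.r_squared == pytest.approx(a.r_squared, abs=1e-10)
        assert b.coef["pert_x_priming_x_dimension"] == pytest.approx(
            -a.coef["pert_x_priming_x_dimension"], abs=1e-10)
        assert b.coef["pert_x_dimension"] == pytest.approx(
            a.coef["pert_x_dimension"]
            + a.coef["pert_x_priming_x_dimension"], abs=1e-10)


class TestGates:
    def test_r2_gate_nesting(self):
        """Printed R^2 range 0.02..0.41 yields monotone nested subsets and
        an empty set at 0.5."""
        r2 = pd.Series(np.linspace(0.02, 0.41, 33),
                       index=[f"s{i:02d}" for i in range(33)])
        gates = r2_gate(r2, thresholds=(0.0, 0.05, 0.1, 0.15, 0.2))
        subsets = [set(v) for v in gates.values()]
        assert len(subsets[0]) == 33  # threshold 0 retains everyone
        for lo, hi in zip(subsets, subsets[1:]):
            assert hi <= lo
        with pytest.warns(UserWarning, match="no subjects"):
            empty = r2_gate(r2, thresholds=(0.5,))
        assert empty[0.5] == []

    def test_null_agent_non_adapters(self, test_only_schedule):
        """With b0 = kappa = 0 the null model wins the information
        criteria for most subjects and the perturbation coefficient is
        near zero."""
        p = AgentParams(b0_dir=0.0, b0_ext=0.0, kappa=0.0)
        frames = []
        for i in range(8):
            for session, cond in ((1, "arc"), (2, "line")):
                df, _ = simulate_session(test_only_schedule(cond), p,
                                         subject_id=f"s{i:02d}",
                                         session=session, rng=100 + 2 * i
                                         + session, trajectories=False)
                frames.append(df)
        trials = kinematics_table(pd.concat(frames, ignore_index=True), None)
        res = SingleTrialAdaptation.from_trials(trials).fit(per_target=False)
        assert len(res.adapters) <= 2
        coefs = res.coefficients("pert")
        assert abs(coefs.mean()) < 0.1

    def test_adapting_agent_flagged_as_adapter(self, test_only_schedule):
        frames = []
        for session, cond in ((1, "arc"), (2, "line")):
            df, _ = simulate_session(test_only_schedule(cond), AgentParams(),
                                     subject_id="s01", session=session,
                                     rng=session, trajectories=False)
            frames.append(df)
        trials = kinematics_table(pd.concat(frames, ignore_index=True), None)
        res = SingleTrialAdaptation.from_trials(trials).fit(per_target=False)
        assert res.adapters == ["s01"]

    def test_single_condition_raises_named_error(self, test_only_schedule):
        df, _ = simulate_session(test_only_schedule("arc"), AgentParams(),
                                 rng=0, trajectories=False)
        trials = kinematics_table(df, None)
        with pytest.raises(ValueError, match="rank-deficient"):
            SingleTrialAdaptation.from_trials(trials).fit(per_target=False)


def test_summary_mentions_key_results(test_only_schedule):
    frames = []
    for i in range(4):
        for session, cond in ((1, "arc"), (2, "line")):
            df, _ = simulate_session(test_only_schedule(cond), AgentParams(),
                                     subject_id=f"s{i:02d}", session=session,
                                     rng=10 * i + session,
                                     trajectories=False)
            frames.append(df)
    trials = kinematics_table(pd.concat(frames, ignore_index=True), None)
    res = SingleTrialAdaptation.from_trials(trials).fit()
    text = res.summary()
    assert "three-way interaction" in text
    assert "R^2" in text
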