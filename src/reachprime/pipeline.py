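"""End-to-end orchestration: simulate a cohort, compute kinematics, apply
exclusions, build variability and adaptation tables, and run the full set
of group-level tests on one simulated cohort.

All intermediate artifacts are plain tables (CSV on disk), so any stage can
also be run on external trial tables that follow the documented schema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import groupstats
from .adaptation import R2_THRESHOLDS, AdaptationResults, SingleTrialAdaptation
from .agent import AgentParams, Trajectory, simulate_session
from .exclusion import ExclusionReport, apply_exclusions, flag_exclusions
from .kinematics import kinematics_table
from .schedule import SessionSchedule, build_priming_schedule, build_test_schedule
from .variability import explored_variability, phase_variability_table


@dataclass
class RunConfig:
    """Fully reproducible description of one simulated-cohort analysis."""

    n_subjects: int = 33
    seed: int = 0
    params: AgentParams = field(default_factory=AgentParams)
    trajectories: bool = False
    between_subject_cv: float = 0.2     # lognormal SD of per-subject noise
    b0_sd: float = 0.08                 # between-subject SD of learning rates
    explore_sd: float = 0.25            # lognormal SD of exploration factor
    include_veridical: bool = False
    per_target_fits: bool = True
    r2_thresholds: tuple[float, ...] = R2_THRESHOLDS
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "params" in d and isinstance(d["params"], dict):
            p = d["params"]
            for key in ("location_scale_plan_dir", "location_scale_plan_ext"):
                if key in p and p[key] is not None:
                    p[key] = tuple(p[key])
            d["params"] = AgentParams(**p)
        if "r2_thresholds" in d:
            d["r2_thresholds"] = tuple(d["r2_thresholds"])
        return cls(**d)


def draw_subject_params(base: AgentParams, rng: np.random.Generator,
                        between_subject_cv: float, b0_sd: float,
                        explore_sd: float) -> AgentParams:
    """Per-subject parameter draw.

    A lognormal 'exploration propensity' scales planning noise and the
    priming-dependent learning increment together, which induces the
    between-subject coupling of priming effects on variability and on
    learning; independent lognormal factors perturb each dimension's noise,
    and learning rates get additive Gaussian jitter.
    """
    g = float(np.exp(rng.normal(0.0, explore_sd)))
    f_dir = float(np.exp(rng.normal(0.0, between_subject_cv)))
    f_ext = float(np.exp(rng.normal(0.0, between_subject_cv)))
    return replace(
        base,
        sigma_plan_dir=base.sigma_plan_dir * f_dir * g,
        sigma_plan_ext=base.sigma_plan_ext * f_ext * g,
        sigma_exec_dir=base.sigma_exec_dir * f_dir,
        sigma_exec_ext=base.sigma_exec_ext * f_ext,
        b0_dir=float(np.clip(rng.normal(base.b0_dir, b0_sd), 0.0, 1.0)),
        b0_ext=float(np.clip(rng.normal(base.b0_ext, b0_sd), 0.0, 1.0)),
        kappa=base.kappa * g,
    )


def simulate_cohort(config: RunConfig
                    ) -> tuple[pd.DataFrame, dict[str, Trajectory] | None]:
    """Simulate every subject's two sessions.

    The test-phase mini-block order is drawn once per subject and reused in
    both sessions; priming target shape alternates between sessions with
    the arc/line order counterbalanced across subjects.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    trajs: dict[str, Trajectory] | None = {} if config.trajectories else None
    for i in range(config.n_subjects):
        subject = f"s{i + 1:02d}"
        sp = draw_subject_params(config.params, rng,
                                 config.between_subject_cv, config.b0_sd,
                                 config.explore_sd)
        test_mbs = build_test_schedule(rng)
        conditions = ("arc", "line") if i % 2 == 0 else ("line", "arc")
        for session, condition in enumerate(conditions, start=1):
            schedule = SessionSchedule(
                priming_condition=condition,
                priming_trials=build_priming_schedule(condition, rng),
                test_miniblocks=test_mbs)
            df, tr = simulate_session(schedule, sp, subject_id=subject,
                                      session=session, rng=rng,
                                      trajectories=config.trajectories)
            frames.append(df)
            if trajs is not None:
                trajs.update(tr)
    return pd.concat(frames, ignore_index=True), trajs


def threeway_interaction_test(config: RunConfig
                              ) -> groupstats.GroupTestResult:
    """Group-level three-way (perturbation x priming x dimension) test on
    one simulated cohort, using the endpoint-level fast path.

    Only the test phases are simulated (priming reaches do not enter the
    adaptation regression; the priming condition still sets the learning
    rates and carry-over gains), which keeps Monte-Carlo power and type-I
    studies tractable.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for i in range(config.n_subjects):
        subject = f"s{i + 1:02d}"
        sp = draw_subject_params(config.params, rng,
                                 config.between_subject_cv, config.b0_sd,
                                 config.explore_sd)
        test_mbs = build_test_schedule(rng)
        conditions = ("arc", "line") if i % 2 == 0 else ("line", "arc")
        for session, condition in enumerate(conditions, start=1):
            schedule = SessionSchedule(priming_condition=condition,
                                       priming_trials=[],
                                       test_miniblocks=test_mbs)
            df, _ = simulate_session(schedule, sp, subject_id=subject,
                                     session=session, rng=rng,
                                     trajectories=False)
            frames.append(df)
    trials = kinematics_table(pd.concat(frames, ignore_index=True), None)
    results = SingleTrialAdaptation.from_trials(trials).fit(per_target=False)
    return results.group_test("pert_x_priming_x_dimension")


@dataclass
class ResultsBundle:
    """Everything one full run computes."""

    config: RunConfig
    trials: pd.DataFrame                 # kinematics-annotated, all trials
    exclusions: ExclusionReport
    variability_priming: pd.DataFrame
    variability_test: pd.DataFrame
    adaptation: AdaptationResults
    study_table: pd.DataFrame
    rt_analysis: dict


def _test_row(name: str, res, extra: dict | None = None) -> dict:
    row = dict(name=name)
    if isinstance(res, groupstats.GroupTestResult):
        row.update(kind=res.kind, statistic=res.statistic, df=res.df,
                   p_raw=res.p_raw, p_bonferroni=res.p_bonferroni,
                   effect_size=res.effect_size, effect_kind=res.effect_kind,
                   n=res.n)
    elif isinstance(res, groupstats.CorrelationResult):
        row.update(kind="pearson", statistic=res.r, df=res.n - 2,
                   p_raw=res.p_raw, p_bonferroni=res.p_bonferroni,
                   effect_size=res.r_squared, effect_kind="r_squared",
                   n=res.n)
    if extra:
        row.update(extra)
    return row


def _explored_wide(var_table: pd.DataFrame) -> pd.DataFrame:
    """subject x (priming, dimension) explored-variability cells."""
    return var_table.pivot_table(index="subject",
                                 columns=["priming", "dimension"],
                                 values="explored_pct")


def _variability_tests(var_table: pd.DataFrame, phase: str) -> list[dict]:
    rows = []
    sel = var_table[var_table["stage"] == "endpoint"]
    anova = groupstats.rm_anova_2x2(sel, dv="explored_pct",
                                    factor_a="priming", factor_b="dimension")
    rows.append(_test_row(f"{phase}_anova_priming",
                          anova["priming"]))
    rows.append(_test_row(f"{phase}_anova_dimension",
                          anova["dimension"]))
    rows.append(_test_row(f"{phase}_anova_priming_x_dimension",
                          anova["priming x dimension"]))
    wide = _explored_wide(sel)
    t_dir = groupstats.paired_t_bonferroni(
        wide[("arc", "direction")], wide[("line", "direction")],
        family_size=2)
    t_ext = groupstats.paired_t_bonferroni(
        wide[("line", "extent")], wide[("arc", "extent")], family_size=2)
    rows.append(_test_row(
        f"{phase}_direction_arc_vs_line", t_dir,
        dict(mean_a=float(wide[("arc", "direction")].mean()),
             mean_b=float(wide[("line", "direction")].mean()))))
    rows.append(_test_row(
        f"{phase}_extent_line_vs_arc", t_ext,
        dict(mean_a=float(wide[("line", "extent")].mean()),
             mean_b=float(wide[("arc", "extent")].mean()))))
    return rows


def _left_target_effects(bundle_vars: pd.DataFrame, adaptation:
                         AdaptationResults) -> list[dict]:
    """Correlations between priming effects on variability and on learning
    at the left (-30 deg) target, plus dimension-wise follow-ups there."""
    rows = []
    left = -30.0
    for dim in ("direction", "extent"):
        res = adaptation.group_test("pert_x_priming", f"dimwise_{dim}",
                                    target=left, family_size=2)
        rows.append(_test_row(f"left_target_dimwise_{dim}_interaction", res))

    sel = bundle_vars[(bundle_vars["stage"] == "endpoint")]
    denom_col = f"iqr_loc{int(left):+d}"
    for dim, sign, learn_dim in (("direction", -1.0, "direction"),
                                 ("extent", +1.0, "extent")):
        v = sel[sel["dimension"] == dim].pivot_table(
            index="subject", columns="priming", values=denom_col)
        v_pct = v.apply(lambda c: [explored_variability(x, dim) for x in c])
        if dim == "direction":
            var_effect = v_pct["arc"] - v_pct["line"]
        else:
            var_effect = v_pct["line"] - v_pct["arc"]
        coefs = adaptation.coefficients("pert_x_priming",
                                        f"dimwise_{learn_dim}", target=left)
        learn_effect = sign * coefs
        both = pd.concat([var_effect.rename("var"),
                          learn_effect.rename("learn")], axis=1).dropna()
        res = groupstats.pearson_between_subjects(both["var"], both["learn"],
                                                  family_size=2)
        rows.append(_test_row(f"left_target_corr_{dim}", res))
    return rows


def _location_variability_tests(var_priming: pd.DataFrame) -> list[dict]:
    """Left target vs the other two: dimension x location ANOVA on
    priming-phase explored variability, follow-up ts, and the location x
    movement-stage ANOVA for direction variability."""
    rows = []
    sel = var_priming.copy()
    recs = []
    for _, r in sel.iterrows():
        for loc_lab, cols in (("left", ["iqr_loc-30"]),
                              ("other", ["iqr_loc+0", "iqr_loc+30"])):
            iqr_mean = float(np.mean([r[c] for c in cols]))
            recs.append(dict(subject=r["subject"], priming=r["priming"],
                             dimension=r["dimension"], stage=r["stage"],
                             location=loc_lab,
                             explored_pct=explored_variability(
                                 iqr_mean, r["dimension"])))
    long = (pd.DataFrame(recs)
            .groupby(["subject", "dimension", "stage", "location"],
                     as_index=False)["explored_pct"].mean())
    endpoint = long[long["stage"] == "endpoint"]
    anova = groupstats.rm_anova_2x2(endpoint, dv="explored_pct",
                                    factor_a="dimension",
                                    factor_b="location")
    rows.append(_test_row("priming_anova_dimension_x_location",
                          anova["dimension x location"]))
    wide = endpoint.pivot_table(index="subject",
                                columns=["dimension", "location"],
                                values="explored_pct")
    rows.append(_test_row("priming_direction_left_vs_other",
                          groupstats.paired_t_bonferroni(
                              wide[("direction", "left")],
                              wide[("direction", "other")], family_size=2)))
    rows.append(_test_row("priming_extent_left_vs_other",
                          groupstats.paired_t_bonferroni(
                              wide[("extent", "left")],
                              wide[("extent", "other")], family_size=2)))
    direction = long[long["dimension"] == "direction"]
    anova2 = groupstats.rm_anova_2x2(direction, dv="explored_pct",
                                     factor_a="stage", factor_b="location")
    rows.append(_test_row("priming_direction_stage_x_location",
                          anova2["stage x location"]))
    return rows


def replicate_study_table(variability_priming: pd.DataFrame,
                          variability_test: pd.DataFrame,
                          adaptation: AdaptationResults,
                          rt_analysis: dict,
                          r2_thresholds: tuple[float, ...] = R2_THRESHOLDS,
                          ) -> pd.DataFrame:
    """One row per group-level statistical readout of the paradigm."""
    rows: list[dict] = []
    rows += _variability_tests(variability_priming, "priming")
    rows += _variability_tests(variability_test, "test")

    term = "pert_x_priming_x_dimension"
    rows.append(_test_row("threeway_all_subjects",
                          adaptation.group_test(term)))
    gates = adaptation.r2_gate(r2_thresholds)
    for thr, subjects in gates.items():
        if len(subjects) >= 3:
            rows.append(_test_row(
                f"threeway_r2_ge_{thr:g}",
                adaptation.group_test(term, subjects=subjects),
                dict(n_gated=len(subjects))))
    adapters = adaptation.adapters
    if len(adapters) >= 3:
        rows.append(_test_row("threeway_adapters_only",
                              adaptation.group_test(term, subjects=adapters),
                              dict(n_gated=len(adapters))))
    for loc in (-30.0, 0.0, 30.0):
        rows.append(_test_row(f"threeway_target_{int(loc):+d}",
                              adaptation.group_test(term, target=loc,
                                                    family_size=3)))
    rows += _left_target_effects(variability_priming, adaptation)
    rows += _location_variability_tests(variability_priming)

    if rt_analysis:
        rows.append(_test_row("rt_perturbed_vs_test",
                              rt_analysis["rt_change_t"],
                              dict(mean_a=rt_analysis["rt_perturbed_mean_ms"],
                                   mean_b=rt_analysis["rt_test_mean_ms"])))
        for dim in ("direction", "extent"):
            key = f"rt_correction_corr_{dim}"
            if key in rt_analysis:
                rows.append(_test_row(f"rt_correction_{dim}",
                                      rt_analysis[key]))
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> ResultsBundle:
    """Simulate a cohort and run every analysis stage; optionally write all
    artifacts to ``config.out_dir``."""
    trials, trajs = simulate_cohort(config)
    trials = kinematics_table(trials, trajs)
    report = flag_exclusions(trials)
    included = apply_exclusions(trials, report)

    var_priming = phase_variability_table(included, "priming")
    var_test = phase_variability_table(included, "test")

    model = SingleTrialAdaptation.from_trials(
        included, include_veridical=config.include_veridical)
    adaptation = model.fit(per_target=config.per_target_fits)
    rt = groupstats.within_subject_rt_analysis(adaptation.pairs)
    table = replicate_study_table(var_priming, var_test, adaptation, rt,
                                  config.r2_thresholds)

    bundle = ResultsBundle(config=config, trials=trials, exclusions=report,
                           variability_priming=var_priming,
                           variability_test=var_test, adaptation=adaptation,
                           study_table=table, rt_analysis=rt)
    if config.out_dir is not None:
        write_bundle(bundle, Path(config.out_dir))
    return bundle


def summary_text(bundle: ResultsBundle) -> str:
    tab = bundle.study_table.set_index("name")
    three = tab.loc["threeway_all_subjects"]
    lines = ["# Simulated-cohort analysis summary", "",
             f"subjects: {bundle.config.n_subjects}, "
             f"seed: {bundle.config.seed}",
             f"trials simulated: {len(bundle.trials)}, "
             f"excluded: {int(bundle.exclusions.flags['excluded'].sum())}",
             "",
             bundle.adaptation.summary(), "",
             "Priming x dimension interaction on explored variability "
             f"(priming phase): F(1,{int(tab.loc['priming_anova_priming_x_dimension','df'])}) = "
             f"{tab.loc['priming_anova_priming_x_dimension', 'statistic']:.1f}, "
             f"p = {tab.loc['priming_anova_priming_x_dimension', 'p_raw']:.2g}",
             "Three-way interaction (perturbation x priming x dimension): "
             f"t = {three['statistic']:.2f}, p = {three['p_raw']:.3g} -> "
             + ("significant"
                if three["p_raw"] < 0.05 else "not significant"),
             ]
    return "\n".join(lines)


def write_bundle(bundle: ResultsBundle, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out_dir / "config.yaml")
    bundle.trials.to_csv(out_dir / "trials.csv", index=False)
    bundle.exclusions.flags.to_csv(out_dir / "exclusion_flags.csv",
                                   index=False)
    bundle.exclusions.summary.to_csv(out_dir / "exclusion_summary.csv",
                                     index=False)
    pd.concat([bundle.variability_priming, bundle.variability_test]) \
        .to_csv(out_dir / "variability.csv", index=False)
    bundle.adaptation.pairs.to_csv(out_dir / "pair_table.csv", index=False)
    bundle.adaptation.subject_fits.to_csv(out_dir / "subject_fits.csv",
                                          index=False)
    bundle.study_table.to_csv(out_dir / "group_tests.csv", index=False)
    records = bundle.study_table.to_dict(orient="records")
    (out_dir / "group_tests.json").write_text(json.dumps(records, indent=2))
    (out_dir / "summary.md").write_text(summary_text(bundle))


def save_trajectories(trajs: dict[str, Trajectory], path: str | Path) -> None:
    """Write trajectories as one long-format CSV keyed by trial uid."""
    frames = [pd.DataFrame({"trial_uid": uid, "t_ms": t.t_ms,
                            "x_cm": t.x_cm, "y_cm": t.y_cm})
              for uid, t in trajs.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_trajectories(path: str | Path) -> dict[str, Trajectory]:
    df = pd.read_csv(path)
    out = {}
    for uid, g in df.groupby("trial_uid", sort=False):
        out[uid] = Trajectory(t_ms=g["t_ms"].to_numpy(),
                              x_cm=g["x_cm"].to_numpy(),
                              y_cm=g["y_cm"].to_numpy())
    return out
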