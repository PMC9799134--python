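"""Group-level inference: within-subject ANOVA, t tests with Bonferroni
correction, effect sizes, and correlation tests.

Every test is two-tailed at alpha = 0.05.  Effect sizes follow the
summary-statistics conventions of the field: Cohen's d for paired/one-sample
t tests (mean difference divided by the SD of differences) and partial
eta-squared for within-subject ANOVA effects
(SS_effect / (SS_effect + SS_error)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupTestResult:
    kind: str
    statistic: float
    df: float
    p_raw: float
    family: int
    p_bonferroni: float
    effect_size: float
    effect_kind: str
    n: int

    def __str__(self) -> str:
        stat = "F" if self.kind.startswith("anova") else "t"
        return (f"{self.kind}: {stat}({self.df:g}) = {self.statistic:.3f}, "
                f"p = {self.p_raw:.4g} (Bonferroni x{self.family}: "
                f"{self.p_bonferroni:.4g}), {self.effect_kind} = "
                f"{self.effect_size:.3f}, n = {self.n}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_raw: float
    family: int
    p_bonferroni: float
    n: int

    def __str__(self) -> str:
        return (f"pearson: r = {self.r:.3f} (R^2 = {self.r_squared:.3f}), "
                f"p = {self.p_raw:.4g} (Bonferroni x{self.family}: "
                f"{self.p_bonferroni:.4g}), n = {self.n}")


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-corrected p value, capped at 1."""
    return min(1.0, family_size * p)


def _one_sample(values: np.ndarray, kind: str,
                family_size: int) -> GroupTestResult:
    values = np.asarray(values, float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: t undefined")
    t = values.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    d = values.mean() / sd
    return GroupTestResult(kind=kind, statistic=float(t), df=df,
                           p_raw=float(p), family=family_size,
                           p_bonferroni=bonferroni(float(p), family_size),
                           effect_size=float(d), effect_kind="cohen_d", n=n)


def paired_t_bonferroni(x, y, family_size: int = 1) -> GroupTestResult:
    """Two-tailed dependent-samples t test with Bonferroni correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return _one_sample(x - y, "paired_t", family_size)


def one_sample_t_coeffs(coefficients, family_size: int = 1) -> GroupTestResult:
    """Two-tailed one-sample t test of per-subject coefficients against 0."""
    return _one_sample(coefficients, "one_sample_t", family_size)


def rm_anova_2x2(data: pd.DataFrame, dv: str, factor_a: str, factor_b: str,
                 subject: str = "subject") -> dict[str, GroupTestResult]:
    """2x2 repeated-measures ANOVA from the within-subject decomposition.

    Each 1-df effect is computed from its per-subject contrast score; the
    effect F equals the square of the paired t on that contrast, and
    partial eta-squared is SS_effect / (SS_effect + SS_error) =
    t^2 / (t^2 + df).  Requires complete cells for every subject.
    """
    wide = data.pivot_table(index=subject, columns=[factor_a, factor_b],
                            values=dv)
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("incomplete cells: every subject needs all four "
                         f"{factor_a} x {factor_b} combinations")
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    cells = {ab: wide[ab].to_numpy() for ab in wide.columns}
    a1b1 = cells[(a_levels[0], b_levels[0])]
    a1b2 = cells[(a_levels[0], b_levels[1])]
    a2b1 = cells[(a_levels[1], b_levels[0])]
    a2b2 = cells[(a_levels[1], b_levels[1])]

    contrasts = {
        factor_a: (a1b1 + a1b2 - a2b1 - a2b2) / 2.0,
        factor_b: (a1b1 - a1b2 + a2b1 - a2b2) / 2.0,
        f"{factor_a} x {factor_b}": (a1b1 - a1b2) - (a2b1 - a2b2),
    }
    out: dict[str, GroupTestResult] = {}
    for name, c in contrasts.items():
        n = c.size
        sd = c.std(ddof=1)
        if sd == 0.0:
            t2, p = 0.0, 1.0
        else:
            t = c.mean() / (sd / math.sqrt(n))
            t2 = t * t
            p = stats.f.sf(t2, 1, n - 1)
        eta = t2 / (t2 + (n - 1)) if (t2 + n - 1) > 0 else 0.0
        out[name] = GroupTestResult(
            kind="anova_rm", statistic=float(t2), df=n - 1, p_raw=float(p),
            family=1, p_bonferroni=float(p), effect_size=float(eta),
            effect_kind="partial_eta2", n=n)
    return out


def pearson_between_subjects(xs, ys, family_size: int = 1
                             ) -> CorrelationResult:
    """Pearson correlation across subjects, two-tailed p via the t
    transform, Bonferroni-corrected."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.size < 4:
        raise ValueError("need at least 4 paired observations")
    if xs.std(ddof=1) == 0.0 or ys.std(ddof=1) == 0.0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(r=float(r), r_squared=float(r * r),
                             p_raw=float(p), family=family_size,
                             p_bonferroni=bonferroni(float(p), family_size),
                             n=xs.size)


def fisher_z_one_sample(rs, family_size: int = 1) -> GroupTestResult:
    """One-sample t test against zero of Fisher z-transformed per-subject
    correlation coefficients (pooled within-subject correlation test)."""
    z = np.arctanh(np.asarray(rs, float))
    res = _one_sample(z, "fisher_z_t", family_size)
    return res


def within_subject_rt_analysis(pairs: pd.DataFrame) -> dict:
    """Response-time analysis on perturbed->test trial pairs.

    Tests (a) whether per-subject mean response times drop from the
    perturbed to the test trial (paired t) and (b) whether the RT change
    correlates with the magnitude of the motor correction, pooled across
    subjects via Fisher-z one-sample t tests, separately per dimension.
    """
    if pairs["rt_perturbed_ms"].isna().any() or pairs["rt_test_ms"].isna().any():
        import warnings
        warnings.warn("missing response times; RT analysis skipped")
        return {}
    per_subj = pairs.groupby("subject")[["rt_perturbed_ms",
                                         "rt_test_ms"]].mean()
    diffs = (per_subj["rt_perturbed_ms"] - per_subj["rt_test_ms"]).to_numpy()
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
        # constant response times: no change to test
        rt_t = GroupTestResult(kind="paired_t", statistic=0.0,
                               df=diffs.size - 1, p_raw=1.0, family=1,
                               p_bonferroni=1.0, effect_size=0.0,
                               effect_kind="cohen_d", n=diffs.size)
    else:
        rt_t = paired_t_bonferroni(per_subj["rt_perturbed_ms"],
                                   per_subj["rt_test_ms"])
    out: dict = {
        "rt_perturbed_mean_ms": float(per_subj["rt_perturbed_ms"].mean()),
        "rt_test_mean_ms": float(per_subj["rt_test_ms"].mean()),
        "rt_change_t": rt_t,
    }
    for dim, grp in pairs.groupby("dimension"):
        rs, r2s = [], []
        for _, g in grp.groupby("subject"):
            drt = g["rt_test_ms"] - g["rt_perturbed_ms"]
            mag = g["delta_native"].abs()
            if drt.std(ddof=1) == 0.0 or mag.std(ddof=1) == 0.0:
                continue
            r = float(np.corrcoef(drt, mag)[0, 1])
            rs.append(r)
            r2s.append(r * r)
        if len(rs) >= 3:
            out[f"rt_correction_corr_{dim}"] = fisher_z_one_sample(rs)
            out[f"rt_correction_mean_r2_{dim}"] = float(np.mean(r2s))
    return out
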