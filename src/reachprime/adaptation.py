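"""Single-trial adaptation analysis.

Every perturbed mini-block contributes one perturbed->test trial pair: the
change in movement endpoint from the perturbed to the test trial, in the
perturbation's dimension only (direction for rotations, extent for gains),
regressed on the signed perturbation size in cm.  The regression slope is
the single-trial learning rate.  Per-subject ordinary-least-squares models
are fitted (a combined model on standardized responses with priming and
dimension dummies and all interactions, two dimension-wise models on
native-unit responses, and a null/perturbation-only pair for
adaptation-evidence gating); coefficients are then tested at the group
level.

The public surface follows the Model/Results convention:
``SingleTrialAdaptation(pairs).fit()`` returns an
:class:`AdaptationResults` carrying per-subject coefficient tables,
fit-quality gates and group-level tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import groupstats
from .agent import signed_perturbation_cm as _signed_cm
from .schedule import (
    GAIN_DELTAS,
    ROTATION_MAGNITUDES_DEG,
    TARGET_RADIUS_CM,
    Perturbation,
    PerturbationKind,
)

# dummy coding, fixed and documented: arc-priming = 1, line-priming = 0;
# direction dimension = 1, extent dimension = 0
PRIMING_DUMMY = {"arc": 1.0, "line": 0.0}
DIMENSION_DUMMY = {"direction": 1.0, "extent": 0.0}

COMBINED_TERMS = ("intercept", "pert", "priming", "dimension",
                  "pert_x_priming", "pert_x_dimension",
                  "priming_x_dimension", "pert_x_priming_x_dimension")
DIMWISE_TERMS = ("intercept", "pert", "priming", "pert_x_priming")

R2_THRESHOLDS = (0.05, 0.10, 0.15, 0.20)


def signed_perturbation_cm(pert: Perturbation) -> float:
    """Signed perturbation size in cm at the 15 cm target radius.

    Rotations map through ``15*tan(theta)`` (clockwise positive), which
    reproduces the nominal 2.25 / 1.50 cm cursor displacements exactly;
    gains map through ``15*delta`` (overshoot positive).
    """
    if pert.kind is PerturbationKind.NONE:
        raise ValueError("veridical feedback has no perturbation size")
    if pert.kind is PerturbationKind.ROTATION:
        if abs(pert.magnitude) not in ROTATION_MAGNITUDES_DEG:
            raise ValueError(f"disallowed rotation {pert.magnitude}")
    elif pert.magnitude != 0.0 and not any(
            math.isclose(abs(pert.magnitude), g) for g in GAIN_DELTAS):
        raise ValueError(f"disallowed gain delta {pert.magnitude}")
    return _signed_cm(pert)


def _tan_cm(direction_deg: np.ndarray) -> np.ndarray:
    """Tangential cm-equivalent of a direction (deg) at the target radius."""
    return TARGET_RADIUS_CM * np.tan(np.radians(direction_deg))


def build_pair_table(trials: pd.DataFrame,
                     include_veridical: bool = False) -> pd.DataFrame:
    """Build the perturbed->test pair table from an included-trials table.

    One observation per perturbed mini-block whose perturbed and test
    trials both survived exclusion.  Rotation mini-blocks contribute a
    direction observation only, gain mini-blocks an extent observation
    only.  ``delta_native`` is in degrees (direction) or cm (extent);
    ``delta_cm`` expresses direction changes in tangential cm-equivalents.
    ``delta_z`` is the per-subject, per-dimension z-score of
    ``delta_native``.  Veridical mini-blocks are dropped by default (their
    dimension is undefined); with ``include_veridical`` they contribute a
    zero-perturbation observation in both dimensions.
    """
    test = trials[trials["phase"] == "test"]
    keys = ["subject", "session", "miniblock"]
    pert_rows = test[test["role"] == "perturbed"]
    test_rows = test[test["role"] == "test"]
    merged = pert_rows.merge(test_rows, on=keys, suffixes=("_p", "_t"))

    def _frame(m: pd.DataFrame, dim: str) -> pd.DataFrame:
        kind = m["pert_kind_p"].to_numpy()
        mag = m["pert_magnitude_p"].to_numpy(float)
        if dim == "direction":
            d_p = m["endpoint_direction_deg_p"].to_numpy(float)
            d_t = m["endpoint_direction_deg_t"].to_numpy(float)
            delta_native = d_t - d_p
            delta_cm = _tan_cm(d_t) - _tan_cm(d_p)
        else:
            delta_native = (m["endpoint_extent_cm_t"].to_numpy(float)
                            - m["endpoint_extent_cm_p"].to_numpy(float))
            delta_cm = delta_native
        rot = kind == "rotation"
        pert_cm = np.where(
            rot, TARGET_RADIUS_CM * np.tan(np.radians(mag)),
            TARGET_RADIUS_CM * mag)
        pert_cm[kind == "none"] = 0.0
        pert_native = np.where(rot, mag, pert_cm)
        priming = m["priming_p"].to_numpy()
        return pd.DataFrame(dict(
            subject=m["subject"].to_numpy(), session=m["session"].to_numpy(),
            priming=priming,
            priming_dummy=np.where(priming == "arc", 1.0, 0.0),
            dimension=dim, dimension_dummy=DIMENSION_DUMMY[dim],
            target_loc_deg=m["target_loc_deg_p"].to_numpy(float),
            miniblock=m["miniblock"].to_numpy(),
            pert_kind=kind, pert_magnitude=mag,
            signed_perturbation_cm=pert_cm,
            signed_perturbation_native=pert_native,
            delta_native=delta_native, delta_cm=delta_cm,
            rt_perturbed_ms=m["rt_ms_p"].to_numpy(float),
            rt_test_ms=m["rt_ms_t"].to_numpy(float),
        ))

    parts = [_frame(merged[merged["pert_kind_p"] == "rotation"], "direction"),
             _frame(merged[merged["pert_kind_p"] == "gain"], "extent")]
    if include_veridical:
        verid = merged[merged["pert_kind_p"] == "none"]
        parts += [_frame(verid, "direction"), _frame(verid, "extent")]
    pairs = pd.concat([p for p in parts if not p.empty], ignore_index=True)
    if pairs.empty:
        return pairs
    pairs = pairs.sort_values(["subject", "session", "miniblock",
                               "dimension"], ignore_index=True)
    # standardize responses per subject x dimension so direction (deg) and
    # extent (cm) are comparable in the combined model
    z = pairs.groupby(["subject", "dimension"])["delta_native"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=1))
    pairs["delta_z"] = z
    return pairs


@dataclass(frozen=True)
class OLSFit:
    """Lean ordinary-least-squares fit (Gaussian likelihood conventions
    matching statsmodels: k = number of mean parameters)."""

    terms: tuple[str, ...]
    params: np.ndarray
    r_squared: float
    aic: float
    bic: float
    n_obs: int

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.terms, self.params))


def ols_fit(X: np.ndarray, y: np.ndarray, terms: tuple[str, ...]) -> OLSFit:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {k} "
                         "predictors")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(
            "rank-deficient design: a predictor is constant (e.g. only one "
            "priming condition or one dimension present)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    sigma2 = max(ssr / n, np.finfo(float).tiny)
    llf = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return OLSFit(terms=terms, params=beta, r_squared=r2,
                  aic=-2.0 * llf + 2.0 * k,
                  bic=-2.0 * llf + math.log(n) * k, n_obs=n)


def _design(pairs: pd.DataFrame, kind: str) -> tuple[np.ndarray, np.ndarray,
                                                     tuple[str, ...]]:
    p = pairs["signed_perturbation_cm"].to_numpy(float)
    if kind == "combined":
        g = pairs["priming_dummy"].to_numpy(float)
        d = pairs["dimension_dummy"].to_numpy(float)
        X = np.column_stack([np.ones_like(p), p, g, d,
                             p * g, p * d, g * d, p * g * d])
        return X, pairs["delta_z"].to_numpy(float), COMBINED_TERMS
    if kind == "dimensionwise":
        g = pairs["priming_dummy"].to_numpy(float)
        X = np.column_stack([np.ones_like(p), p, g, p * g])
        return X, pairs["delta_native"].to_numpy(float), DIMWISE_TERMS
    if kind == "null":
        return (np.ones((len(p), 1)), pairs["delta_z"].to_numpy(float),
                ("intercept",))
    if kind == "pert_only":
        return (np.column_stack([np.ones_like(p), p]),
                pairs["delta_z"].to_numpy(float), ("intercept", "pert"))
    raise ValueError(kind)


def fit_subject_models(pairs: pd.DataFrame) -> dict:
    """All models for one subject's pair observations."""
    out: dict = {}
    X, y, terms = _design(pairs, "combined")
    out["combined"] = ols_fit(X, y, terms)
    for dim in ("direction", "extent"):
        sub = pairs[pairs["dimension"] == dim]
        X, y, terms = _design(sub, "dimensionwise")
        out[f"dimwise_{dim}"] = ols_fit(X, y, terms)
    for kind in ("null", "pert_only"):
        X, y, terms = _design(pairs, kind)
        out[kind] = ols_fit(X, y, terms)
    null, pert = out["null"], out["pert_only"]
    # non-adapter if either information criterion favors the null model
    out["adapter"] = not (null.bic < pert.bic or null.aic < pert.aic)
    return out


def r2_gate(r_squared: pd.Series,
            thresholds: tuple[float, ...] = R2_THRESHOLDS
            ) -> dict[float, list]:
    """Subjects whose combined-model R^2 meets each threshold."""
    out = {}
    for thr in thresholds:
        subjects = list(r_squared.index[r_squared >= thr])
        if not subjects:
            import warnings
            warnings.warn(f"R^2 gate {thr} leaves no subjects; "
                          "group tests will be skipped")
        out[thr] = subjects
    return out


class SingleTrialAdaptation:
    """Per-subject single-trial adaptation model over a pair table.

    Parameters
    ----------
    pairs : DataFrame from :func:`build_pair_table`.
    """

    def __init__(self, pairs: pd.DataFrame):
        if pairs.empty:
            raise ValueError("empty pair table")
        self.pairs = pairs

    @classmethod
    def from_trials(cls, trials: pd.DataFrame,
                    include_veridical: bool = False) -> "SingleTrialAdaptation":
        return cls(build_pair_table(trials, include_veridical))

    def fit(self, per_target: bool = True) -> "AdaptationResults":
        rows = []
        adapters = []
        targets: list = ["all"]
        if per_target:
            targets += sorted(self.pairs["target_loc_deg"].unique())
        for subject, sp in self.pairs.groupby("subject"):
            for target in targets:
                sub = sp if target == "all" else \
                    sp[sp["target_loc_deg"] == target]
                fits = fit_subject_models(sub)
                for model in ("combined", "dimwise_direction",
                              "dimwise_extent"):
                    f = fits[model]
                    row = dict(subject=subject, target=target, model=model,
                               r_squared=f.r_squared, aic=f.aic, bic=f.bic,
                               n_obs=f.n_obs)
                    row.update({f"b_{t}": v for t, v in f.coef.items()})
                    rows.append(row)
                if target == "all":
                    adapters.append(dict(
                        subject=subject, adapter=fits["adapter"],
                        aic_null=fits["null"].aic,
                        aic_pert=fits["pert_only"].aic,
                        bic_null=fits["null"].bic,
                        bic_pert=fits["pert_only"].bic))
        return AdaptationResults(pairs=self.pairs,
                                 subject_fits=pd.DataFrame(rows),
                                 adapter_table=pd.DataFrame(adapters))


@dataclass
class AdaptationResults:
    """Per-subject fits plus group-level tests on their coefficients."""

    pairs: pd.DataFrame
    subject_fits: pd.DataFrame
    adapter_table: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    def coefficients(self, term: str, model: str = "combined",
                     target="all", subjects=None) -> pd.Series:
        df = self.subject_fits
        sel = df[(df["model"] == model) & (df["target"] == target)]
        sel = sel.set_index("subject")[f"b_{term}"]
        if subjects is not None:
            sel = sel.loc[list(subjects)]
        return sel

    def r_squared(self, model: str = "combined", target="all") -> pd.Series:
        df = self.subject_fits
        sel = df[(df["model"] == model) & (df["target"] == target)]
        return sel.set_index("subject")["r_squared"]

    def group_test(self, term: str, model: str = "combined", target="all",
                   subjects=None, family_size: int = 1
                   ) -> groupstats.GroupTestResult:
        """One-sample t test of a per-subject coefficient against zero."""
        coefs = self.coefficients(term, model, target, subjects)
        return groupstats.one_sample_t_coeffs(coefs.to_numpy(), family_size)

    def r2_gate(self, thresholds: tuple[float, ...] = R2_THRESHOLDS
                ) -> dict[float, list]:
        return r2_gate(self.r_squared(), thresholds)

    @property
    def adapters(self) -> list:
        return list(self.adapter_table.loc[self.adapter_table["adapter"],
                                           "subject"])

    def summary(self) -> str:
        lines = ["Single-trial adaptation model",
                 "=" * 34,
                 f"subjects: {self.subject_fits['subject'].nunique()}, "
                 f"pairs: {len(self.pairs)}"]
        r2 = self.r_squared()
        lines.append(f"combined-model R^2: {r2.min():.3f}..{r2.max():.3f} "
                     f"(mean {r2.mean():.3f}, SD {r2.std(ddof=1):.3f})")
        lines.append(f"adapters (BIC & AIC evidence): "
                     f"{len(self.adapters)}/{len(self.adapter_table)}")
        res = self.group_test("pert_x_priming_x_dimension")
        lines.append(f"three-way interaction (all targets): {res}")
        for target in [t for t in self.subject_fits["target"].unique()
                       if t != "all"]:
            res = self.group_test("pert_x_priming_x_dimension",
                                  target=target, family_size=3)
            lines.append(f"three-way interaction (target {target:+g} deg): "
                         f"{res}")
        return "\n".join(lines)
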