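"""Endpoint-variability statistics.

Variability is the interquartile range (IQR) of movement direction
(degrees) or movement extent (cm), computed separately per target location
and then averaged across the three locations, which removes the influence
of target-specific spatial biases.  IQRs are re-expressed as "explored
variability": the percentage of the full redundant span of the priming
targets (30.56 deg of arc central angle, or 8 cm of line length) that the
IQR covers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .schedule import TARGET_EXTENT_CM, TARGET_LOCATIONS_DEG, TARGET_RADIUS_CM

#: printed central angle of the 8 cm arc; equals deg(8/15 rad) to 2 decimals
DIRECTION_SPAN_DEG = 30.56
EXTENT_SPAN_CM = TARGET_EXTENT_CM

_DIM_COLUMNS = {
    ("direction", "endpoint"): "endpoint_direction_deg",
    ("direction", "peak_velocity"): "peakvel_direction_deg",
    ("extent", "endpoint"): "endpoint_extent_cm",
}


def direction_span_from_geometry() -> float:
    """Arc central angle implied by the target geometry (degrees)."""
    return math.degrees(TARGET_EXTENT_CM / TARGET_RADIUS_CM)


def iqr(values: np.ndarray) -> float:
    """Interquartile range with linear-interpolation quantiles."""
    q75, q25 = np.percentile(np.asarray(values, float), [75, 25])
    return float(q75 - q25)


def iqr_by_target(values: pd.Series | np.ndarray,
                  locations: pd.Series | np.ndarray,
                  min_trials: int = 4) -> tuple[dict[float, float], float]:
    """Per-location IQR and their unweighted mean across the 3 locations."""
    values = np.asarray(values, float)
    locations = np.asarray(locations, float)
    per_loc: dict[float, float] = {}
    for loc in TARGET_LOCATIONS_DEG:
        v = values[locations == loc]
        if v.size < min_trials:
            raise ValueError(f"target location {loc} has only {v.size} "
                             "included trials")
        per_loc[loc] = iqr(v)
    return per_loc, float(np.mean(list(per_loc.values())))


def explored_variability(iqr_native: float, dimension: str) -> float:
    """Convert a native-unit IQR to percent of the redundant target span."""
    if iqr_native < 0:
        raise ValueError("IQR must be non-negative")
    if dimension == "direction":
        return 100.0 * iqr_native / DIRECTION_SPAN_DEG
    if dimension == "extent":
        return 100.0 * iqr_native / EXTENT_SPAN_CM
    raise ValueError(f"unknown dimension {dimension!r}")


def iqr_from_explored(explored_pct: float, dimension: str) -> float:
    """Inverse conversion: percent explored variability to native-unit IQR."""
    if dimension == "direction":
        return explored_pct / 100.0 * DIRECTION_SPAN_DEG
    if dimension == "extent":
        return explored_pct / 100.0 * EXTENT_SPAN_CM
    raise ValueError(f"unknown dimension {dimension!r}")


def phase_variability_table(trials: pd.DataFrame, phase: str,
                            stages: tuple[str, ...] = ("endpoint",
                                                       "peak_velocity"),
                            ) -> pd.DataFrame:
    """Tidy variability table for one phase.

    One row per subject x session x dimension (x stage for direction), with
    per-location IQRs, their mean, and explored variability in percent.
    Expects exclusions to have been applied already.  For the test phase,
    each mini-block's final (test) trial is dropped, because those reaches
    reflect corrections to the preceding feedback.
    """
    df = trials[trials["phase"] == phase]
    if phase == "test":
        df = df[df["role"] != "test"]

    rows = []
    for (subject, session), grp in df.groupby(["subject", "session"]):
        priming = grp["priming"].iloc[0]
        specs = [("extent", "endpoint")]
        for stage in stages:
            specs.append(("direction", stage))
        for dimension, stage in specs:
            col = _DIM_COLUMNS[(dimension, stage)]
            per_loc, mean_iqr = iqr_by_target(grp[col], grp["target_loc_deg"])
            rows.append(dict(
                subject=subject, session=session, priming=priming,
                phase=phase, dimension=dimension, stage=stage,
                iqr_native=mean_iqr,
                explored_pct=explored_variability(mean_iqr, dimension),
                **{f"iqr_loc{int(loc):+d}": v for loc, v in per_loc.items()},
            ))
    return pd.DataFrame(rows)


def confidence_ellipse_axes(x: np.ndarray, y: np.ndarray,
                            coverage: float = 0.68) -> tuple[float, float]:
    """Semi-axes of the endpoint-dispersion ellipse.

    Axes are the principal standard deviations scaled by the two-sided
    normal quantile of ``coverage``; at 68% the scale is ~1, so the axes
    are approximately one standard deviation along each principal
    direction.
    """
    from scipy.stats import norm

    cov = np.cov(np.vstack([x, y]))
    evals = np.linalg.eigvalsh(cov)
    scale = norm.ppf(0.5 + coverage / 2.0)
    return tuple(scale * np.sqrt(np.maximum(evals, 0.0))[::-1])
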