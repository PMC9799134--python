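"""Trial-exclusion rules.

Three independent criteria, each flagged on the full trial set:

* slow: mean movement speed below 20 cm/s (the error-sound threshold);
* curved: maximum normal distance from the home-to-endpoint straight line
  above 2 cm;
* outlier: endpoint more than eight times the interquartile range of
  endpoint-to-median distances away from the componentwise-median endpoint,
  computed within each subject x session x phase x target-location cell.

A trial may trip several flags; ``excluded`` is their union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import CURVED_THRESHOLD_CM

OUTLIER_IQR_FACTOR = 8.0
MIN_CELL_TRIALS = 4

CELL_KEYS = ["subject", "session", "phase", "target_loc_deg"]


@dataclass
class ExclusionReport:
    """Per-trial flags plus a percentage summary per subject and phase."""

    flags: pd.DataFrame          # trial_uid, slow, curved, outlier, excluded
    summary: pd.DataFrame        # subject x condition exclusion percentages

    def rates(self) -> pd.DataFrame:
        """Mean and range of exclusion percentages per condition, in the
        '% of trials (range ...)' reporting format."""
        rows = []
        for cond, grp in self.summary.groupby("condition"):
            for crit in ("slow", "curved", "outlier"):
                pct = grp[f"pct_{crit}"]
                rows.append(dict(condition=cond, criterion=crit,
                                 mean_pct=pct.mean(), sd_pct=pct.std(ddof=1),
                                 min_pct=pct.min(), max_pct=pct.max()))
        return pd.DataFrame(rows)


def _outlier_flags(cell: pd.DataFrame) -> np.ndarray:
    xy = cell[["endpoint_x_cm", "endpoint_y_cm"]].to_numpy(float)
    med = np.median(xy, axis=0)                       # componentwise median
    d = np.hypot(xy[:, 0] - med[0], xy[:, 1] - med[1])
    q75, q25 = np.percentile(d, [75, 25])             # linear interpolation
    return d > OUTLIER_IQR_FACTOR * (q75 - q25)


def flag_exclusions(trials: pd.DataFrame) -> ExclusionReport:
    """Apply the three exclusion criteria to a kinematics-annotated trial
    table. Flags are computed independently on all trials (not
    sequentially); cells with fewer than 4 trials skip the outlier rule."""
    df = trials
    slow = df["slow_flag"].to_numpy(bool)
    curved = df["max_path_deviation_cm"].to_numpy(float) > CURVED_THRESHOLD_CM

    outlier = np.zeros(len(df), dtype=bool)
    for key, cell in df.groupby(CELL_KEYS):
        if len(cell) < MIN_CELL_TRIALS:
            warnings.warn(f"cell {key} has {len(cell)} trials; "
                          "outlier rule skipped")
            continue
        outlier[df.index.get_indexer(cell.index)] = _outlier_flags(cell)

    flags = pd.DataFrame({
        "trial_uid": df["trial_uid"].to_numpy(),
        "slow": slow, "curved": curved, "outlier": outlier,
        "excluded": slow | curved | outlier,
    }, index=df.index)

    # summary per subject x condition (arc-priming / line-priming / test)
    cond = np.where(df["phase"] == "priming",
                    df["priming"].astype(str) + "-priming", "test")
    tmp = flags.assign(subject=df["subject"].to_numpy(), condition=cond)
    summary = (tmp.groupby(["subject", "condition"])
               [["slow", "curved", "outlier", "excluded"]]
               .mean().mul(100.0)
               .rename(columns=lambda c: f"pct_{c}")
               .reset_index())
    return ExclusionReport(flags=flags, summary=summary)


def apply_exclusions(trials: pd.DataFrame,
                     report: ExclusionReport) -> pd.DataFrame:
    """Trial table restricted to included trials (exclusion = masking)."""
    return trials.loc[~report.flags["excluded"].to_numpy(bool)].copy()
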