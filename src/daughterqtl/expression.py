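"""Relative quantification of qPCR data by the 2^-ddCt (Livak) method.

Each sample's target-gene Ct is normalised against a reference gene
(dCt = Ct_target - Ct_reference, technical replicates averaged on the Ct
scale first), then against the mean dCt of a calibrator group
(ddCt = dCt - mean dCt_calibrator); relative quantity RQ = 2^-ddCt, so the
calibrator group's geometric-mean-like construction pins its mean RQ near 1
and exactly 1 on the log scale.  Group comparisons use a two-sample t-test
on the RQ values (Welch by default) plus the ratio of group means as the
fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionTable:
    """Per-sample Ct measurements for a target and a reference gene."""

    data: pd.DataFrame  # columns: sample_id, group, ct_target, ct_reference[, replicate]

    def __post_init__(self) -> None:
        need = {"sample_id", "group", "ct_target", "ct_reference"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"expression table needs columns {sorted(need)}")
        ct = self.data[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be positive and finite "
                             "(missing reference-gene Ct?)")

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())


def relative_quantification(expr: ExpressionTable, calibrator_group: str
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-group RQ = 2^-ddCt against a calibrator group.

    Returns (per_sample, per_group); per_group carries mean RQ, SE and n.
    The calibrator group's ddCt values are centred on 0 by construction.
    """
    df = expr.data.copy()
    if calibrator_group not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")
    # average technical replicates on the Ct scale
    per_sample = (df.groupby(["sample_id", "group"], as_index=False)
                  [["ct_target", "ct_reference"]].mean())
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    # calibrator constant chosen so the calibrator group's arithmetic mean
    # RQ is exactly 1 (the usual "calibrator defined as 1" convention)
    cal_dct = per_sample.loc[per_sample["group"] == calibrator_group, "dct"]
    cal_const = -np.log2((2.0 ** (-cal_dct)).mean())
    per_sample["ddct"] = per_sample["dct"] - cal_const
    per_sample["rq"] = 2.0 ** (-per_sample["ddct"])
    per_group = (per_sample.groupby("group")["rq"]
                 .agg(mean_rq="mean", sd="std", n="count").reset_index())
    per_group["se"] = per_group["sd"] / np.sqrt(per_group["n"])
    return per_sample, per_group


def genotype_expression_test(expr: ExpressionTable, group_a: str, group_b: str,
                             calibrator_group: str | None = None,
                             welch: bool = True) -> tuple[float, float, float]:
    """Fold change mean RQ(a)/mean RQ(b) and two-sided t-test on RQ values.

    With no calibrator given, group_b calibrates (its mean RQ is then ~1 and
    the fold change reads directly as a-relative-to-b).  The t-test needs at
    least 2 samples per group; the fold change alone needs 1.
    """
    cal = calibrator_group or group_b
    per_sample, _ = relative_quantification(expr, cal)
    rq_a = per_sample.loc[per_sample["group"] == group_a, "rq"].to_numpy()
    rq_b = per_sample.loc[per_sample["group"] == group_b, "rq"].to_numpy()
    if len(rq_a) < 1 or len(rq_b) < 1:
        raise ValueError("both groups must have at least one sample")
    mb = rq_b.mean()
    if mb == 0:
        raise ZeroDivisionError("denominator group has zero mean RQ")
    fold = rq_a.mean() / mb
    if len(rq_a) >= 2 and len(rq_b) >= 2:
        t, p = stats.ttest_ind(rq_a, rq_b, equal_var=not welch)
        return float(fold), float(t), float(p)
    return float(fold), np.nan, np.nan


def read_expression_table(path) -> ExpressionTable:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).lower() for c in df.columns]
    return ExpressionTable(df)


def write_expression_table(expr: ExpressionTable, path) -> None:
    expr.data.to_csv(path, sep="\t", index=False)
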