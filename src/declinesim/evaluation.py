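"""Evaluation layer: decline-detection criteria, power, MAPE, and bias.

Two classification pathways exist.  Model-selection ("aic") methods detect a
decline when the selected model includes a recent change and the
contemporary estimate is below the historic one; interval ("ci") methods
detect a decline when the upper 95% CI of the contemporary estimate lies
strictly below the lower 95% CI of the historic estimate.  Infinite
estimates never count as detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InferenceRecord",
    "decline_detected",
    "correctly_inferred",
    "power",
    "mape",
    "log10_ratio",
    "aggregate_report",
]


@dataclass
class InferenceRecord:
    # truth
    scenario: str
    true_ne_c: float
    true_ne_h: float
    declining_truth: bool
    lambda_: float = 1.0
    T_dec: int | None = None
    Ne_H: int = 0
    gen_time: float = 1.0
    # design
    method: str = ""  # e.g. sfs, ld_point, ld_trajectory
    scheme: str = ""
    sample_size: int = 0
    data_type: str = ""
    # estimates
    pathway: str = "ci"  # aic | ci
    ne_c_hat: float = math.nan
    ne_h_hat: float = math.nan
    ne_c_ci: tuple[float, float] | None = None
    ne_h_ci: tuple[float, float] | None = None
    trend: str | None = None  # aic pathway: stable | declining | expanding
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pathway not in ("aic", "ci"):
            raise ValueError("pathway must be 'aic' or 'ci'")
        if self.true_ne_c <= 0 or self.true_ne_h <= 0:
            raise ValueError("true sizes must be positive")

    @property
    def has_infinite(self) -> bool:
        vals = [self.ne_c_hat, self.ne_h_hat]
        return any(np.isinf(v) for v in vals)


def decline_detected(record: InferenceRecord) -> bool:
    if record.pathway == "aic":
        if record.trend is None:
            raise ValueError("aic pathway requires a trend classification")
        return record.trend == "declining"
    if record.ne_c_ci is None or record.ne_h_ci is None:
        raise ValueError("ci pathway requires both confidence intervals")
    if record.has_infinite or any(
        np.isinf(v) for v in (*record.ne_c_ci, *record.ne_h_ci)
    ):
        return False
    # strict inequality: a touching boundary is not a detection
    return record.ne_c_ci[1] < record.ne_h_ci[0]


def correctly_inferred(record: InferenceRecord) -> bool:
    """Detection for declining truth; stability call for constant truth."""
    if record.declining_truth:
        return decline_detected(record)
    if record.pathway == "aic":
        return record.trend == "stable"
    if record.ne_c_ci is None or record.ne_h_ci is None:
        raise ValueError("ci pathway requires both confidence intervals")
    lo = max(record.ne_c_ci[0], record.ne_h_ci[0])
    hi = min(record.ne_c_ci[1], record.ne_h_ci[1])
    return lo <= hi  # overlapping CIs


def power(records: list[InferenceRecord]) -> float:
    if not records:
        raise ValueError("empty record cell")
    truths = {r.declining_truth for r in records}
    if len(truths) > 1:
        raise ValueError("records mix declining and constant truths")
    return sum(correctly_inferred(r) for r in records) / len(records)


def _target_values(record: InferenceRecord, target: str) -> tuple[float, float]:
    if target == "Ne_C":
        return record.ne_c_hat, record.true_ne_c
    if target == "Ne_H":
        return record.ne_h_hat, record.true_ne_h
    raise ValueError("target must be 'Ne_C' or 'Ne_H'")


def mape(records: list[InferenceRecord], target: str) -> float:
    """(100/n) * sum |inferred - simulated| / simulated over the records."""
    if not records:
        raise ValueError("MAPE of an empty cell is undefined")
    total = 0.0
    for r in records:
        inferred, simulated = _target_values(r, target)
        if not np.isfinite(inferred):
            raise ValueError("infinite/undefined estimates must be excluded upstream")
        total += abs(inferred - simulated) / simulated
    return 100.0 * total / len(records)


def log10_ratio(record: InferenceRecord, target: str) -> float:
    inferred, simulated = _target_values(record, target)
    if not np.isfinite(inferred) or inferred <= 0:
        raise ValueError("log ratio requires a positive finite estimate")
    return float(np.log10(inferred / simulated))


def _in_mape_subset(r: InferenceRecord) -> bool:
    """Constant, fast-30, and slow-120 scenarios at generation time 1."""
    if r.gen_time != 1.0:
        return False
    if not r.declining_truth:
        return True
    return (r.lambda_, r.T_dec) in ((0.95, 30), (0.99, 120))


def aggregate_report(
    records: list[InferenceRecord],
    exclude_sample_sizes: dict[str, tuple[int, ...]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables: power per cell, MAPE on the aggregation subset, and
    counts of infinite estimates.

    ``exclude_sample_sizes`` maps method -> sample sizes excluded from MAPE
    (default: the unlinked-pair LD method at n=50, which yields many
    infinite estimates).
    """
    if exclude_sample_sizes is None:
        exclude_sample_sizes = {"ld_point": (50,)}
    rows = []
    for r in records:
        rows.append(
            {
                "scenario": r.scenario,
                "method": r.method,
                "scheme": r.scheme,
                "sample_size": r.sample_size,
                "data_type": r.data_type,
                "declining": r.declining_truth,
                "correct": correctly_inferred(r),
                "infinite": r.has_infinite,
                "in_subset": _in_mape_subset(r),
                "ne_c_hat": r.ne_c_hat,
                "ne_h_hat": r.ne_h_hat,
                "true_ne_c": r.true_ne_c,
                "true_ne_h": r.true_ne_h,
            }
        )
    df = pd.DataFrame(rows)
    cell = ["method", "scenario", "scheme", "sample_size", "data_type"]
    power_tbl = (
        df.groupby(cell, as_index=False)
        .agg(power=("correct", "mean"), n=("correct", "size"))
        .sort_values(cell)
        .reset_index(drop=True)
    )
    inf_tbl = (
        df.groupby(cell, as_index=False)
        .agg(n_infinite=("infinite", "sum"), n=("infinite", "size"))
        .sort_values(cell)
        .reset_index(drop=True)
    )

    sub = df[df["in_subset"] & np.isfinite(df["ne_c_hat"]) & np.isfinite(df["ne_h_hat"])]
    drop = pd.Series(False, index=sub.index)
    for method, sizes in exclude_sample_sizes.items():
        drop |= (sub["method"] == method) & sub["sample_size"].isin(sizes)
    sub = sub[~drop]
    mape_rows = []
    for (method, data_type), grp in sub.groupby(["method", "data_type"]):
        mape_rows.append(
            {
                "method": method,
                "data_type": data_type,
                "mape_ne_c": 100 * (abs(grp.ne_c_hat - grp.true_ne_c) / grp.true_ne_c).mean(),
                "mape_ne_h": 100 * (abs(grp.ne_h_hat - grp.true_ne_h) / grp.true_ne_h).mean(),
                "n": len(grp),
            }
        )
    mape_tbl = pd.DataFrame(
        mape_rows, columns=["method", "data_type", "mape_ne_c", "mape_ne_h", "n"]
    ).sort_values(["method", "data_type"]).reset_index(drop=True)
    return {"power": power_tbl, "mape": mape_tbl, "infinite": inf_tbl}
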