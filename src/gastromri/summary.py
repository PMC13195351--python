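"""Cohort aggregation, inclusion bookkeeping and ground-truth recovery.

Per-record metrics are aggregated across subjects into per-arm,
per-timepoint mean ± SD tables (sample SD, n − 1 denominator, matching
the usual "Mean ± SD" cohort-reporting convention).  Frequency and
velocity only count subjects whose timepoint passed the two-of-three
dominance rule, so each row carries its own ``n_included`` — the analog
of a participant-inclusion table.

Correction-rate accounting mirrors quality-control bookkeeping of
segmentation pipelines (how many sequences needed manual correction),
and :func:`recovery_report` scores estimates against the phantom's
ground-truth table with bias, mean absolute error and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "aggregate_cohort",
    "correction_rate",
    "recovery_report",
]

#: metrics an aggregated cohort table may carry
KNOWN_METRICS = (
    "frequency_cpm",
    "speed_mm_s",
    "occlusion_pct",
    "gcv_ml",
    "delta_gcv_ml",
    "rate_ml_min",
    "rate_kcal_min",
)


@dataclass(frozen=True)
class CohortTable:
    """Tidy cohort summary: one row per (arm, timepoint, metric[, slice]).

    Columns: arm, timepoint_min, metric, (slice_index,) mean, sd,
    n_included.  ``sd`` is NaN when only one subject contributed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"arm", "metric", "mean", "sd", "n_included"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")

    def lookup(self, arm: str, metric: str, timepoint_min: float | None = None):
        df = self.data
        sel = (df["arm"] == arm) & (df["metric"] == metric)
        if timepoint_min is not None:
            sel &= df["timepoint_min"] == timepoint_min
        return df[sel]


def aggregate_cohort(
    per_record: pd.DataFrame,
    value_col: str = "value",
    metric_col: str = "metric",
    extra_keys: tuple[str, ...] = (),
) -> CohortTable:
    """Aggregate per-subject values into mean ± sample SD per group.

    ``per_record`` is tidy with columns subject, arm, timepoint_min,
    ``metric_col``, ``value_col`` (plus any ``extra_keys`` such as
    slice_index).  One value per subject per group is required; duplicate
    (subject, group) keys raise.  NaN values mark excluded records and do
    not count toward ``n_included``.
    """
    keys = ["arm", "timepoint_min", metric_col, *extra_keys]
    required = {"subject", value_col, *keys}
    missing = required - set(per_record.columns)
    if missing:
        raise ValueError(f"per-record table missing columns {sorted(missing)}")
    dup = per_record.duplicated(subset=["subject", *keys])
    if dup.any():
        bad = per_record.loc[dup, ["subject", *keys]].iloc[0].to_dict()
        raise ValueError(f"duplicate record key: {bad}")

    def _agg(grp: pd.DataFrame) -> pd.Series:
        vals = grp[value_col].dropna().to_numpy(dtype=float)
        return pd.Series({
            "mean": vals.mean() if len(vals) else np.nan,
            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n_included": int(len(vals)),
        })

    out = (
        per_record.groupby(keys, sort=True, dropna=False)
        .apply(_agg, include_groups=False)
        .reset_index()
        .rename(columns={metric_col: "metric"})
    )
    out["n_included"] = out["n_included"].astype(int)
    return CohortTable(out)


def correction_rate(n_corrected: int, n_total: int) -> float:
    """Share of sequences needing manual correction, in percent (1 decimal)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_corrected <= n_total:
        raise ValueError("require 0 <= n_corrected <= n_total")
    return round(100.0 * n_corrected / n_total, 1)


def recovery_report(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    keys: tuple[str, ...],
    params: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """Score estimates against phantom ground truth.

    ``params`` maps a report name to ``(estimate_column, truth_column)``.
    Every estimate row must find its truth row on ``keys``; missing truth
    rows raise, listing the offending keys.  Returns one row per
    parameter with bias (mean of estimate − truth), MAE and RMSE over the
    records where the estimate is defined (non-NaN).
    """
    merged = estimates.merge(
        truth, on=list(keys), how="left", suffixes=("", "_truth"), indicator=True
    )
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        missing = orphans[list(keys)].drop_duplicates().to_dict("records")
        raise KeyError(f"missing ground-truth rows for keys: {missing[:5]}")
    rows = []
    for name, (est_col, truth_col) in params.items():
        if truth_col == est_col:
            truth_col = f"{truth_col}_truth"
        err = (merged[est_col] - merged[truth_col]).dropna().to_numpy(dtype=float)
        rows.append({
            "parameter": name,
            "n": len(err),
            "bias": err.mean() if len(err) else np.nan,
            "mae": np.abs(err).mean() if len(err) else np.nan,
            "rmse": np.sqrt((err**2).mean()) if len(err) else np.nan,
        })
    return pd.DataFrame(rows)
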