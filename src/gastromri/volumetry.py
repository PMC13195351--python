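"""Gastric-emptying volumetry from GCV time series.

Gastric content volume (GCV) follows a biphasic postprandial course:
water ingested at t = 0 empties fast and roughly first-order along the
Magenstrasse, after which the caloric meal empties slowly and nearly
linearly.  The volumetric emptying rate is therefore estimated as the
ordinary-least-squares slope of GCV over the late window 41–81 min, by
which time the water phase is over; the sign is flipped so that a
positive rate means emptying.

A caloric rate uses a crude but standardized energy anchor: the
baseline (pre-water, t = −5 min) volume is declared to hold the full
300 kcal of the meal, every volume is rescaled to kcal by
``kcal(t) = anchor × V(t) / V(baseline)``, and the same windowed slope
is taken.  By linearity of OLS this equals the volumetric rate times
``anchor / V(baseline)`` exactly.

ΔGCV(t) = GCV(t) − GCV(baseline) removes the pre-water content so that
volume changes attributable to water plus test meal stand alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import VolumeSeries

__all__ = [
    "EmptyingResult",
    "DeltaGCVSeries",
    "delta_gcv",
    "emptying_rate",
    "caloric_series",
    "caloric_rate",
    "analyze_emptying",
]

DEFAULT_WINDOW_MIN = (41.0, 81.0)
DEFAULT_ANCHOR_KCAL = 300.0


@dataclass(frozen=True)
class EmptyingResult:
    """Windowed emptying rates for one subject × arm volume series."""

    rate_ml_per_min: float
    rate_kcal_per_min: float
    window_min: tuple[float, float]
    anchor_kcal: float
    baseline_label_min: float
    baseline_volume_ml: float
    n_points_in_window: int


@dataclass(frozen=True)
class DeltaGCVSeries:
    """Baseline-corrected GCV; may be negative once the meal has emptied
    below the pre-water content."""

    timepoints_min: np.ndarray
    delta_ml: np.ndarray
    subject: str = ""
    arm: str = ""


def delta_gcv(series: VolumeSeries) -> DeltaGCVSeries:
    """Baseline-corrected series ΔGCV(t) = GCV(t) − GCV(baseline).

    The baseline timepoint maps to exactly 0.
    """
    corrected = series.volumes_ml - series.baseline_volume_ml
    return DeltaGCVSeries(series.timepoints_min, corrected, series.subject, series.arm)


def _window_points(
    series: VolumeSeries, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    inside = (series.timepoints_min >= lo) & (series.timepoints_min <= hi)
    if inside.sum() < 2:
        raise ValueError(
            f"need >= 2 timepoints in window [{lo}, {hi}] min, "
            f"found {int(inside.sum())} among {series.timepoints_min.tolist()}"
        )
    return series.timepoints_min[inside], series.volumes_ml[inside]


def emptying_rate(
    series: VolumeSeries, window: tuple[float, float] = DEFAULT_WINDOW_MIN
) -> float:
    """Volumetric emptying rate ΔV/Δt (mL/min), positive = emptying.

    OLS slope of volume on time over the closed window; with exactly two
    in-window points this coincides with the two-point difference quotient.
    """
    t, v = _window_points(series, window)
    slope = np.polyfit(t, v, 1)[0]
    return float(-slope)


def caloric_series(
    series: VolumeSeries, anchor_kcal: float = DEFAULT_ANCHOR_KCAL
) -> np.ndarray:
    """Energy-equivalent series kcal(t) = anchor × V(t) / V(baseline)."""
    baseline = series.baseline_volume_ml
    if baseline <= 0:
        raise ValueError("caloric anchoring requires a positive baseline volume")
    return anchor_kcal * series.volumes_ml / baseline


def caloric_rate(
    series: VolumeSeries,
    window: tuple[float, float] = DEFAULT_WINDOW_MIN,
    anchor_kcal: float = DEFAULT_ANCHOR_KCAL,
) -> float:
    """Caloric emptying rate Δkcal/Δt (kcal/min) over the window.

    Algebraically identical to ``emptying_rate × anchor / V(baseline)``.
    """
    baseline = series.baseline_volume_ml
    if baseline <= 0:
        raise ValueError("caloric anchoring requires a positive baseline volume")
    kcal = caloric_series(series, anchor_kcal)
    lo, hi = window
    inside = (series.timepoints_min >= lo) & (series.timepoints_min <= hi)
    if inside.sum() < 2:
        raise ValueError(
            f"need >= 2 timepoints in window [{lo}, {hi}] min, "
            f"found {int(inside.sum())}"
        )
    slope = np.polyfit(series.timepoints_min[inside], kcal[inside], 1)[0]
    return float(-slope)


def analyze_emptying(
    series: VolumeSeries,
    window: tuple[float, float] = DEFAULT_WINDOW_MIN,
    anchor_kcal: float = DEFAULT_ANCHOR_KCAL,
) -> EmptyingResult:
    """Convenience wrapper returning both rates plus bookkeeping."""
    lo, hi = window
    inside = (series.timepoints_min >= lo) & (series.timepoints_min <= hi)
    return EmptyingResult(
        rate_ml_per_min=emptying_rate(series, window),
        rate_kcal_per_min=caloric_rate(series, window, anchor_kcal),
        window_min=(lo, hi),
        anchor_kcal=anchor_kcal,
        baseline_label_min=series.baseline_timepoint_min,
        baseline_volume_ml=series.baseline_volume_ml,
        n_points_in_window=int(inside.sum()),
    )
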