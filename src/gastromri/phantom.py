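"""Seeded digital phantom for postprandial gastric MRI mask data.

This module generates everything the analysis pipeline consumes — dynamic
sagittal mask stacks, static volumetric masks, and whole study cohorts —
from known ground truth, so that frequency, speed, occlusion and emptying
estimators can be validated end to end without scanner data.

The generative models:

* Per-slice luminal area: a peristaltic sinusoid at the true contraction
  frequency ``f0`` riding on a baseline area, plus a respiration sinusoid
  (default 15 cycles/min, deliberately outside the 1.8–4.2 cpm detection
  band), a slow linear drift, and additive Gaussian noise; areas are
  clipped at zero.  Per-slice phase offsets are chosen so that one wave
  period traverses the propagation distance spanned by the slices, making
  the frequency-times-geometry apparent speed the generative truth.

* Gastric content volume: the pre-water baseline holds the meal volume;
  from t = 0 the co-ingested water empties first-order (Magenstrasse)
  while the caloric meal empties linearly, giving the characteristic
  biphasic course::

      V(t) = max(0, v_meal0 − r_meal · t) + water0 · exp(−k_water · t) + ε

* Rasterization: areas become filled 2:1 ellipses on the acquisition grid
  (pixel-center membership test), volumes become compact center-out voxel
  balls whose count matches the requested volume to half a voxel.

Every record is reproducible in isolation: per-record seeds derive from
the master seed by a stated, stable hash (SHA-256 of the key string
``"{master}|{subject}|{arm}|{timepoint}|{slice}"``, first 4 bytes).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import (
    AreaTimeCurve,
    VolumeSeries,
    save_mask,
    save_curve_csv,
    write_sidecar,
)
from .motility import SliceGeometry

__all__ = [
    "StudyDesign",
    "RasterSpec",
    "PeristalsisTruth",
    "EmptyingTruth",
    "MealTruth",
    "record_seed",
    "propagation_phases",
    "simulate_area_series",
    "rasterize_mask_sequence",
    "simulate_volume_series",
    "rasterize_volume_mask",
    "generate_cohort",
    "DEFAULT_MEALS",
]


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"parameter '{name}' must be finite, got {value!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: subjects × arms × timepoints × slices.

    Defaults reproduce the two-arm crossover design with 12 subjects,
    6 volumetric timepoints (−5 … 81 min) and 5 real-time timepoints
    (7 … 85 min) of 3 sagittal slices each: 144 volumetric and 360
    dynamic records in total.
    """

    n_subjects: int = 12
    arms: tuple[str, ...] = ("solid", "liquid")
    vol_timepoints_min: tuple[float, ...] = (-5, 3, 21, 41, 61, 81)
    rt_timepoints_min: tuple[float, ...] = (7, 25, 45, 65, 85)
    n_slices: int = 3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        if len(set(self.arms)) != len(self.arms) or not self.arms:
            raise ValueError("arm labels must be non-empty and unique")
        for name in ("vol_timepoints_min", "rt_timepoints_min"):
            tps = getattr(self, name)
            if (np.diff(tps) <= 0).any():
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"sub{i + 1:02d}" for i in range(self.n_subjects))

    @property
    def n_volumetric_records(self) -> int:
        return self.n_subjects * len(self.arms) * len(self.vol_timepoints_min)

    @property
    def n_dynamic_records(self) -> int:
        return (
            self.n_subjects * len(self.arms)
            * len(self.rt_timepoints_min) * self.n_slices
        )


@dataclass(frozen=True)
class RasterSpec:
    """Acquisition raster: grid, field of view, frame rate, voxel dims.

    Defaults mirror the real-time protocol (140 × 140 matrix over a
    200 × 200 mm field of view, 6.24 frames/s for 180 s, 5 mm slices).
    The number of frames is ``floor(duration × frame_rate)`` — the frame
    rate is a literal acquisition constant and a partial final frame is
    never emitted.
    """

    matrix: tuple[int, int] = (140, 140)
    fov_mm: tuple[float, float] = (200.0, 200.0)
    frame_rate_fps: float = 6.24
    duration_s: float = 180.0
    slice_thickness_mm: float = 5.0
    voxel_dims_mm: tuple[float, float, float] = (2.0, 2.0, 4.0)
    vol_matrix: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if min(self.matrix) < 1 or min(self.fov_mm) <= 0:
            raise ValueError("matrix and fov_mm must be positive")
        if self.frame_rate_fps <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate_fps and duration_s must be positive")
        if min(self.voxel_dims_mm) <= 0 or min(self.vol_matrix) < 1:
            raise ValueError("voxel dims and volumetric matrix must be positive")
        if self.n_frames < 16:
            raise ValueError("duration × frame_rate must yield at least 16 frames")

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def pixel_area_mm2(self) -> float:
        px, py = self.pixel_size_mm
        return px * py

    @property
    def n_frames(self) -> int:
        return math.floor(self.duration_s * self.frame_rate_fps)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_fps

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_dims_mm
        return dx * dy * dz / 1000.0


def _per_slice(value, slice_index: int, name: str) -> float:
    """Resolve a scalar-or-per-slice parameter for a 1-based slice index."""
    if np.isscalar(value):
        return float(value)
    seq = np.asarray(value, dtype=float)
    if not 1 <= slice_index <= len(seq):
        raise ValueError(f"slice_index {slice_index} out of range for '{name}'")
    return float(seq[slice_index - 1])


@dataclass(frozen=True)
class PeristalsisTruth:
    """Generative parameters of one dynamic (area-time) record.

    ``mean_area_mm2``, ``amp_mm2`` and ``phase_rad`` may be scalars or
    per-slice sequences.  The oscillation amplitude may not exceed the
    baseline area, so the noiseless target area never goes negative.
    """

    f0_cpm: float = 3.0
    mean_area_mm2: float | tuple = 600.0
    amp_mm2: float | tuple = 150.0
    phase_rad: float | tuple = 0.0
    resp_freq_cpm: float = 15.0
    resp_amp_mm2: float = 0.0
    drift_mm2_per_s: float = 0.0
    noise_sd_mm2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "f0_cpm", "mean_area_mm2", "amp_mm2", "phase_rad",
            "resp_freq_cpm", "resp_amp_mm2", "drift_mm2_per_s", "noise_sd_mm2",
        ):
            _check_finite(name, getattr(self, name))
        mean = np.atleast_1d(np.asarray(self.mean_area_mm2, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amp_mm2, dtype=float))
        if (amp < 0).any():
            raise ValueError("amp_mm2 must be non-negative")
        if (np.broadcast_arrays(amp, mean)[0] > np.broadcast_arrays(amp, mean)[1]).any():
            raise ValueError("amp_mm2 must not exceed mean_area_mm2")
        if self.f0_cpm <= 0:
            raise ValueError("f0_cpm must be positive")
        if self.noise_sd_mm2 < 0 or self.resp_amp_mm2 < 0:
            raise ValueError("noise_sd_mm2 and resp_amp_mm2 must be non-negative")


@dataclass(frozen=True)
class EmptyingTruth:
    """Generative parameters of one subject × arm volume series."""

    v_meal0_ml: float = 298.0
    water0_ml: float = 240.0
    k_water_per_min: float = 0.15
    r_meal_ml_per_min: float = 2.24
    noise_sd_ml: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "v_meal0_ml", "water0_ml", "k_water_per_min",
            "r_meal_ml_per_min", "noise_sd_ml",
        ):
            _check_finite(name, getattr(self, name))
        if self.v_meal0_ml < 0 or self.water0_ml < 0 or self.noise_sd_ml < 0:
            raise ValueError("volumes and noise SD must be non-negative")
        if self.k_water_per_min <= 0:
            raise ValueError("k_water_per_min must be positive")
        if self.r_meal_ml_per_min < 0:
            raise ValueError("r_meal_ml_per_min must be non-negative")


def record_seed(master_seed: int, *key_parts) -> int:
    """Stable per-record seed: first 4 bytes of SHA-256 over the key string.

    ``key = "{master}|{part1}|{part2}|..."`` with parts rendered by str().
    """
    key = "|".join(str(p) for p in (master_seed, *key_parts))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def propagation_phases(geom: SliceGeometry) -> np.ndarray:
    """Per-slice phase offsets placing one wavelength across the slice extent.

    Slice centers are spaced ``thickness + gap`` apart; with the wavelength
    set to the propagation distance D, slice s gets phase
    ``2π · s · (thickness + gap) / D``.  A wave generated with these phases
    traverses D in exactly one period, so the apparent speed computed from
    frequency and geometry is the true generative speed.
    """
    spacing = geom.slice_thickness_mm + geom.inter_slice_distance_mm
    s = np.arange(geom.n_slices)
    return 2.0 * np.pi * s * spacing / geom.propagation_distance_mm


def simulate_area_series(
    truth: PeristalsisTruth, spec: RasterSpec, slice_index: int = 1
) -> AreaTimeCurve:
    """Simulate one slice's area-time curve.

    ``A(t) = μ + drift·t + a·sin(2π f0/60 t − φ) + a_r·sin(2π f_r/60 t) + ε``,
    clipped at 0, sampled at ``t_i = i / frame_rate`` for
    ``floor(duration × frame_rate)`` frames.  Bit-identical for identical
    (truth, spec, slice_index).
    """
    t = spec.times_s
    mu = _per_slice(truth.mean_area_mm2, slice_index, "mean_area_mm2")
    amp = _per_slice(truth.amp_mm2, slice_index, "amp_mm2")
    phase = _per_slice(truth.phase_rad, slice_index, "phase_rad")
    areas = (
        mu
        + truth.drift_mm2_per_s * t
        + amp * np.sin(2.0 * np.pi * (truth.f0_cpm / 60.0) * t - phase)
        + truth.resp_amp_mm2 * np.sin(2.0 * np.pi * (truth.resp_freq_cpm / 60.0) * t)
    )
    if truth.noise_sd_mm2 > 0:
        rng = np.random.default_rng([truth.seed, slice_index])
        areas = areas + rng.normal(0.0, truth.noise_sd_mm2, size=len(t))
    areas = np.maximum(areas, 0.0)
    return AreaTimeCurve(
        t, areas, spec.frame_rate_fps, slice_index=slice_index
    )


def _ellipse_radius2(spec: RasterSpec) -> np.ndarray:
    """Squared elliptical radius (2:1 aspect) of every pixel center, in mm²
    of the equivalent circle: a pixel is inside the ellipse of area A iff
    its value is <= A / (2π)."""
    px, py = spec.pixel_size_mm
    nx, ny = spec.matrix
    x = (np.arange(nx) + 0.5) * px - spec.fov_mm[0] / 2.0
    y = (np.arange(ny) + 0.5) * py - spec.fov_mm[1] / 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")
    # semi-axes (2b, b): area = 2π b²  →  membership (x/2)² + y² <= b²
    return (xx / 2.0) ** 2 + yy**2


def rasterize_mask_sequence(curve: AreaTimeCurve, spec: RasterSpec) -> np.ndarray:
    """Rasterize an area-time curve as a stack of filled 2:1 ellipses.

    Each frame is a centered ellipse whose continuous area equals the
    requested area, discretized by a pixel-center membership test, so the
    pixel-count area differs from the requested one by at most a one-pixel
    boundary ring.  Areas whose ellipse would overflow the field of view
    fall back to a rank-based fill (the N innermost pixels, N = requested
    area / pixel area), which covers the legitimate edge case of a mask
    filling the whole grid.  Returns uint8 of shape (n_frames, nx, ny).
    """
    areas = curve.areas_mm2
    grid_area = spec.fov_mm[0] * spec.fov_mm[1]
    if (areas > grid_area * (1 + 1e-9)).any():
        raise ValueError(
            f"requested area exceeds grid capacity {grid_area} mm²"
        )
    r2 = _ellipse_radius2(spec)
    flat_order = np.argsort(r2, axis=None, kind="stable")
    n_pixels = r2.size
    # largest ellipse fully inside the FOV: semi-x = 2b <= fov_x/2
    b_max = min(spec.fov_mm[0] / 4.0, spec.fov_mm[1] / 2.0)
    area_fit_max = 2.0 * np.pi * b_max**2
    stack = np.empty((len(areas), *spec.matrix), dtype=np.uint8)
    b2 = areas / (2.0 * np.pi)  # squared semi-minor axis per frame
    fits = areas <= area_fit_max
    if fits.any():
        stack[fits] = (r2[None, :, :] <= b2[fits, None, None]).astype(np.uint8)
    for i in np.nonzero(~fits)[0]:
        n_set = int(round(areas[i] / spec.pixel_area_mm2))
        n_set = min(n_set, n_pixels)
        frame = np.zeros(n_pixels, dtype=np.uint8)
        frame[flat_order[:n_set]] = 1
        stack[i] = frame.reshape(spec.matrix)
    return stack


def simulate_volume_series(
    truth: EmptyingTruth, design: StudyDesign
) -> VolumeSeries:
    """Simulate a biphasic GCV series over the design's volumetric timepoints.

    Baseline (t < 0): the bare meal volume.  From t = 0 the meal empties
    linearly (floored at 0) and the water first-order; Gaussian noise is
    added to the post-water measurements and the result clipped at 0.
    """
    tps = np.asarray(design.vol_timepoints_min, dtype=float)
    if not (tps < 0).any():
        raise ValueError("design must include a pre-water baseline timepoint < 0 min")
    post = tps >= 0
    volumes = np.full(len(tps), float(truth.v_meal0_ml))
    t_post = tps[post]
    volumes[post] = (
        np.maximum(0.0, truth.v_meal0_ml - truth.r_meal_ml_per_min * t_post)
        + truth.water0_ml * np.exp(-truth.k_water_per_min * t_post)
    )
    if truth.noise_sd_ml > 0:
        rng = np.random.default_rng(truth.seed)
        volumes[post] = volumes[post] + rng.normal(
            0.0, truth.noise_sd_ml, size=int(post.sum())
        )
    volumes = np.maximum(volumes, 0.0)
    return VolumeSeries(tps, volumes)


_VOL_ORDER_CACHE: dict[tuple, np.ndarray] = {}


def _center_out_order(spec: RasterSpec) -> np.ndarray:
    """Flat voxel indices sorted by distance from the grid center (stable)."""
    key = (spec.vol_matrix, spec.voxel_dims_mm)
    if key not in _VOL_ORDER_CACHE:
        nx, ny, nz = spec.vol_matrix
        dx, dy, dz = spec.voxel_dims_mm
        x = ((np.arange(nx) + 0.5) - nx / 2.0) * dx
        y = ((np.arange(ny) + 0.5) - ny / 2.0) * dy
        z = ((np.arange(nz) + 0.5) - nz / 2.0) * dz
        d2 = (
            x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
        )
        _VOL_ORDER_CACHE[key] = np.argsort(d2, axis=None, kind="stable")
    return _VOL_ORDER_CACHE[key]


def rasterize_volume_mask(volume_ml: float, spec: RasterSpec) -> np.ndarray:
    """Rasterize a volume as a compact center-out voxel ball.

    Exactly ``round(volume / voxel_volume)`` voxels are set, nearest to
    the grid center first (stable tie-break by voxel index), giving a
    single connected component for any positive volume.
    """
    if volume_ml < 0:
        raise ValueError("volume_ml must be non-negative")
    n_set = int(round(volume_ml / spec.voxel_volume_ml))
    n_total = int(np.prod(spec.vol_matrix))
    if n_set > n_total:
        raise ValueError(
            f"volume {volume_ml} mL exceeds grid capacity "
            f"{n_total * spec.voxel_volume_ml} mL"
        )
    mask = np.zeros(n_total, dtype=np.uint8)
    mask[_center_out_order(spec)[:n_set]] = 1
    return mask.reshape(spec.vol_matrix)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MealTruth:
    """Cohort-level distribution of one meal arm's emptying parameters.

    Means and SDs of the pre-water meal volume and of the linear caloric
    emptying rate; subjects draw their individual parameters from these.
    """

    v_meal0_mean_ml: float
    v_meal0_sd_ml: float
    r_meal_mean_ml_per_min: float
    r_meal_sd_ml_per_min: float


#: default meal arms: a solid light meal and an isocaloric liquid meal,
#: parameterized at the reported cohort means (initial volumes 298/263 mL,
#: late linear emptying 2.24/2.23 mL/min).
DEFAULT_MEALS: dict[str, MealTruth] = {
    "solid": MealTruth(298.0, 31.0, 2.24, 0.65),
    "liquid": MealTruth(263.0, 26.0, 2.23, 0.58),
}

#: cohort physiology defaults (see docs/methods.md for rationale)
_F0_MEAN_CPM = 3.1
_F0_SD_CPM = 0.25
_F0_CLIP_CPM = (2.0, 4.0)
_MEAN_AREA_MEAN = 600.0
_MEAN_AREA_SD = 60.0
_AMP_FRACTION_START = 0.22   # early postprandial contraction depth
_AMP_FRACTION_END = 0.55     # late postprandial contraction depth
_RESP_FRACTION = 0.05
_DRIFT_SD = 0.2
_AREA_NOISE_SD = 15.0
_WATER0_ML = 240.0
_K_WATER_RANGE = (0.12, 0.20)
_VOLUME_NOISE_SD = 8.0


def _subject_geometry(rng: np.random.Generator, spec: RasterSpec) -> SliceGeometry:
    factor = float(rng.uniform(1.5, 3.0))
    return SliceGeometry(
        slice_thickness_mm=spec.slice_thickness_mm,
        distance_factor=factor,
    )


def generate_cohort(
    design: StudyDesign,
    master_seed: int,
    out_dir: Path | str,
    spec: RasterSpec | None = None,
    meals: dict[str, MealTruth] | None = None,
    noiseless: bool = False,
    write_masks: bool = True,
    overwrite: bool = False,
) -> dict:
    """Generate a full synthetic cohort bundle on disk.

    The bundle always contains the ground-truth tables, the record
    metadata, per-record area-time curves (tidy CSV) and the volume
    series; with ``write_masks=True`` every record is additionally
    rasterized to a NIfTI mask with a JSON sidecar, and the analysis
    pipeline then re-derives curves and volumes from the masks.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    spec = spec or RasterSpec()
    meals = meals or DEFAULT_MEALS
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
    (out / "masks" / "dynamic").mkdir(parents=True, exist_ok=True)
    (out / "masks" / "volumetric").mkdir(parents=True, exist_ok=True)

    meal_cycle = list(meals.values())
    arm_meals = {
        arm: meal_cycle[i % len(meal_cycle)] for i, arm in enumerate(design.arms)
    }

    truth_dyn_rows: list[dict] = []
    truth_vol_rows: list[dict] = []
    record_rows: list[dict] = []
    volume_rows: list[dict] = []
    curves: list[AreaTimeCurve] = []

    n_rt = len(design.rt_timepoints_min)
    for subject in design.subjects:
        for arm in design.arms:
            sa_seed = record_seed(master_seed, subject, arm)
            sa_rng = np.random.default_rng(sa_seed)
            geom = _subject_geometry(sa_rng, spec)
            geom_with_slices = SliceGeometry(
                geom.slice_thickness_mm, geom.distance_factor, design.n_slices
            )
            phases = propagation_phases(geom_with_slices)
            f0 = float(np.clip(
                sa_rng.normal(_F0_MEAN_CPM, _F0_SD_CPM), *_F0_CLIP_CPM
            ))
            mean_areas = sa_rng.normal(_MEAN_AREA_MEAN, _MEAN_AREA_SD,
                                       size=design.n_slices)
            mean_areas = np.clip(mean_areas, 200.0, None)

            # volumetric series for this subject x arm
            meal = arm_meals[arm]
            vol_seed = record_seed(master_seed, subject, arm, "volumetric")
            emptying = EmptyingTruth(
                v_meal0_ml=max(50.0, float(
                    sa_rng.normal(meal.v_meal0_mean_ml, meal.v_meal0_sd_ml))),
                water0_ml=_WATER0_ML,
                k_water_per_min=float(sa_rng.uniform(*_K_WATER_RANGE)),
                r_meal_ml_per_min=max(0.0, float(
                    sa_rng.normal(meal.r_meal_mean_ml_per_min,
                                  meal.r_meal_sd_ml_per_min))),
                noise_sd_ml=0.0 if noiseless else _VOLUME_NOISE_SD,
                seed=vol_seed,
            )
            series = simulate_volume_series(emptying, design)
            truth_vol_rows.append({
                "subject": subject, "arm": arm, **asdict(emptying),
            })
            for tp, vol in zip(series.timepoints_min, series.volumes_ml):
                volume_rows.append({
                    "subject": subject, "arm": arm,
                    "timepoint_min": float(tp), "volume_ml": float(vol),
                })
                if write_masks:
                    rec_id = f"{subject}_{arm}_t{int(tp):+03d}min"
                    mask = rasterize_volume_mask(vol, spec)
                    path = out / "masks" / "volumetric" / f"{rec_id}.nii.gz"
                    save_mask(path, mask, spec.voxel_dims_mm)
                    write_sidecar(path.with_suffix("").with_suffix(".json"), {
                        "subject": subject, "arm": arm,
                        "timepoint_min": float(tp),
                        "voxel_dims_mm": list(spec.voxel_dims_mm),
                    })

            # dynamic records at real-time timepoints
            for j, tp in enumerate(design.rt_timepoints_min):
                # contraction depth grows over the postprandial period
                frac_lo = _AMP_FRACTION_START + (
                    (_AMP_FRACTION_END - _AMP_FRACTION_START) * j / max(1, n_rt - 1)
                )
                dyn_seed = record_seed(master_seed, subject, arm, tp)
                tp_rng = np.random.default_rng(dyn_seed)
                amp_frac = float(tp_rng.uniform(frac_lo * 0.9, frac_lo * 1.1))
                amp_frac = min(amp_frac, 0.95)
                truth = PeristalsisTruth(
                    f0_cpm=f0,
                    mean_area_mm2=tuple(np.round(mean_areas, 6)),
                    amp_mm2=tuple(np.round(mean_areas * amp_frac, 6)),
                    phase_rad=tuple(np.round(phases, 12)),
                    resp_freq_cpm=15.0,
                    resp_amp_mm2=0.0 if noiseless else float(
                        _RESP_FRACTION * mean_areas.mean()),
                    drift_mm2_per_s=0.0 if noiseless else float(
                        tp_rng.normal(0.0, _DRIFT_SD)),
                    noise_sd_mm2=0.0 if noiseless else _AREA_NOISE_SD,
                    seed=dyn_seed,
                )
                for s in range(1, design.n_slices + 1):
                    rec_id = f"{subject}_{arm}_t{int(tp):+03d}min_s{s}"
                    curve = simulate_area_series(truth, spec, slice_index=s)
                    curve = AreaTimeCurve(
                        curve.times_s, curve.areas_mm2, curve.frame_rate_fps,
                        slice_index=s, source_id=f"{subject}_{arm}_t{int(tp):+03d}min",
                    )
                    curves.append(curve)
                    record_rows.append({
                        "subject": subject, "arm": arm,
                        "timepoint_min": float(tp), "slice_index": s,
                        "source_id": curve.source_id,
                        "distance_factor": geom.distance_factor,
                        "slice_thickness_mm": geom.slice_thickness_mm,
                        "frame_rate_fps": spec.frame_rate_fps,
                        "seed": dyn_seed,
                    })
                    truth_dyn_rows.append({
                        "subject": subject, "arm": arm,
                        "timepoint_min": float(tp), "slice_index": s,
                        "f0_cpm": truth.f0_cpm,
                        "mean_area_mm2": truth.mean_area_mm2[s - 1],
                        "amp_mm2": truth.amp_mm2[s - 1],
                        "phase_rad": truth.phase_rad[s - 1],
                        "resp_freq_cpm": truth.resp_freq_cpm,
                        "resp_amp_mm2": truth.resp_amp_mm2,
                        "drift_mm2_per_s": truth.drift_mm2_per_s,
                        "noise_sd_mm2": truth.noise_sd_mm2,
                        "distance_factor": geom.distance_factor,
                        "seed": dyn_seed,
                    })
                    if write_masks:
                        stack = rasterize_mask_sequence(curve, spec)
                        # store as (x, y, frame)
                        path = out / "masks" / "dynamic" / f"{rec_id}.nii.gz"
                        save_mask(path, np.moveaxis(stack, 0, -1),
                                  spec.pixel_size_mm)
                        write_sidecar(path.with_suffix("").with_suffix(".json"), {
                            "subject": subject, "arm": arm,
                            "timepoint_min": float(tp), "slice_index": s,
                            "frame_rate_fps": spec.frame_rate_fps,
                            "distance_factor": geom.distance_factor,
                            "slice_thickness_mm": geom.slice_thickness_mm,
                            "pixel_size_mm": list(spec.pixel_size_mm),
                        })

    pd.DataFrame(truth_dyn_rows).to_csv(out / "truth_dynamic.csv", index=False)
    pd.DataFrame(truth_vol_rows).to_csv(out / "truth_volumetric.csv", index=False)
    pd.DataFrame(record_rows).to_csv(out / "records_dynamic.csv", index=False)
    pd.DataFrame(volume_rows).to_csv(out / "volumes.csv", index=False)
    save_curve_csv(out / "curves.csv", curves)

    manifest = {
        "package": "gastromri",
        "master_seed": int(master_seed),
        "noiseless": bool(noiseless),
        "write_masks": bool(write_masks),
        "design": asdict(design),
        "raster": asdict(spec),
        "n_dynamic_records": len(record_rows),
        "n_volumetric_records": len(volume_rows),
        "seed_scheme": "sha256('{master}|{subject}|{arm}|{timepoint}|{slice}')[:4] little-endian",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
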