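"""Convert binary segmentation masks to physical measurements.

Two measurement containers are defined here and used throughout the
package:

* :class:`AreaTimeCurve` — per-slice luminal cross-sectional area (mm²)
  sampled at a fixed frame rate, obtained from a dynamic 2D+t mask stack.
* :class:`VolumeSeries` — gastric content volume (GCV, mL) at labeled
  protocol timepoints (minutes), obtained from static 3D masks by voxel
  counting.

Areas and volumes are pure pixel/voxel counts scaled by the physical
pixel/voxel size; no sub-pixel or partial-volume estimation is attempted.
Masks must be strictly binary ({0, 1}); anything else is rejected rather
than thresholded, so upstream segmentation faults surface immediately.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AreaTimeCurve",
    "VolumeSeries",
    "area_from_mask",
    "curve_from_mask_stack",
    "volume_from_mask",
    "load_mask",
    "save_mask",
    "load_curve_csv",
    "save_curve_csv",
]

logger = logging.getLogger(__name__)


def _as_binary(mask: np.ndarray, what: str) -> np.ndarray:
    """Validate that ``mask`` contains only {0, 1} and return it as uint8."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    values = np.unique(arr)
    if not np.isin(values, (0, 1)).all():
        raise ValueError(
            f"{what} is not binary: found values {values[:10].tolist()} "
            "(expected only 0 and 1; refusing to threshold)"
        )
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class AreaTimeCurve:
    """Luminal cross-sectional area of one sagittal slice over time.

    Parameters
    ----------
    times_s : array of sample times in seconds, ``times_s[i] = i / frame_rate``.
    areas_mm2 : luminal areas in mm², one per frame, non-negative and finite.
    frame_rate_fps : acquisition frame rate in frames per second.
    slice_index : 1-based slice number within the sagittal stack.
    source_id : free-form record identifier (subject/arm/timepoint tag).
    """

    times_s: np.ndarray
    areas_mm2: np.ndarray
    frame_rate_fps: float
    slice_index: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        areas = np.asarray(self.areas_mm2, dtype=float)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "areas_mm2", areas)
        if times.ndim != 1 or areas.ndim != 1 or len(times) != len(areas):
            raise ValueError("times_s and areas_mm2 must be 1-D and equally long")
        if len(times) == 0:
            raise ValueError("empty area-time curve")
        if not np.isfinite(areas).all():
            raise ValueError("areas_mm2 contains non-finite values")
        if (areas < 0).any():
            raise ValueError("areas_mm2 contains negative values")
        if not (self.frame_rate_fps > 0 and math.isfinite(self.frame_rate_fps)):
            raise ValueError("frame_rate_fps must be positive and finite")
        expected = np.arange(len(times)) / self.frame_rate_fps
        if not np.allclose(times, expected, atol=1e-6 / self.frame_rate_fps):
            raise ValueError("times_s must be uniform: times[i] = i / frame_rate")

    def __len__(self) -> int:
        return len(self.areas_mm2)

    @property
    def duration_s(self) -> float:
        """Record duration, ``n_frames / frame_rate`` (seconds)."""
        return len(self) / self.frame_rate_fps

    @classmethod
    def from_areas(
        cls,
        areas_mm2: np.ndarray,
        frame_rate_fps: float,
        slice_index: int = 1,
        source_id: str = "",
    ) -> "AreaTimeCurve":
        areas = np.asarray(areas_mm2, dtype=float)
        times = np.arange(len(areas)) / frame_rate_fps
        return cls(times, areas, frame_rate_fps, slice_index, source_id)


@dataclass(frozen=True)
class VolumeSeries:
    """Gastric content volume at labeled protocol timepoints.

    Exactly one timepoint label must be negative: the pre-water baseline
    (default protocol: −5 min) used for ΔGCV correction and the caloric
    anchor.
    """

    timepoints_min: np.ndarray
    volumes_ml: np.ndarray
    subject: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        tps = np.asarray(self.timepoints_min, dtype=float)
        vols = np.asarray(self.volumes_ml, dtype=float)
        object.__setattr__(self, "timepoints_min", tps)
        object.__setattr__(self, "volumes_ml", vols)
        if tps.ndim != 1 or vols.ndim != 1 or len(tps) != len(vols):
            raise ValueError("timepoints_min and volumes_ml must be 1-D, equal length")
        if (np.diff(tps) <= 0).any():
            raise ValueError("timepoints_min must be strictly increasing")
        if not np.isfinite(vols).all() or (vols < 0).any():
            raise ValueError("volumes_ml must be finite and non-negative")
        n_baseline = int((tps < 0).sum())
        if n_baseline != 1:
            raise ValueError(
                f"expected exactly one baseline timepoint < 0 min, found {n_baseline}"
            )

    def __len__(self) -> int:
        return len(self.volumes_ml)

    @property
    def baseline_timepoint_min(self) -> float:
        return float(self.timepoints_min[self.timepoints_min < 0][0])

    @property
    def baseline_volume_ml(self) -> float:
        return float(self.volumes_ml[self.timepoints_min < 0][0])


# ---------------------------------------------------------------------------
# mask -> measurement
# ---------------------------------------------------------------------------

def area_from_mask(mask_frame: np.ndarray, pixel_area_mm2: float) -> float:
    """Luminal area of one binary mask frame: set-pixel count × pixel area."""
    if not pixel_area_mm2 > 0:
        raise ValueError("pixel_area_mm2 must be positive")
    frame = _as_binary(mask_frame, "mask frame")
    if frame.ndim != 2:
        raise ValueError(f"mask frame must be 2-D, got shape {frame.shape}")
    return float(frame.sum(dtype=np.int64)) * float(pixel_area_mm2)


def curve_from_mask_stack(
    stack: np.ndarray,
    pixel_area_mm2: float,
    frame_rate_fps: float,
    slice_index: int = 1,
    source_id: str = "",
) -> AreaTimeCurve:
    """Frame-wise area extraction from a dynamic mask stack.

    ``stack`` has shape (n_frames, ny, nx); all frames must share one shape.
    """
    arr = np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError(f"expected a non-empty (frames, y, x) stack, got {arr.shape}")
    binary = _as_binary(arr, "mask stack")
    counts = binary.reshape(binary.shape[0], -1).sum(axis=1, dtype=np.int64)
    areas = counts.astype(float) * float(pixel_area_mm2)
    return AreaTimeCurve.from_areas(areas, frame_rate_fps, slice_index, source_id)


def volume_from_mask(mask3d: np.ndarray, voxel_volume_ml: float) -> float:
    """Gastric content volume by voxel counting: set voxels × voxel volume."""
    if not voxel_volume_ml > 0:
        raise ValueError("voxel_volume_ml must be positive")
    vol = _as_binary(mask3d, "volumetric mask")
    if vol.ndim != 3:
        raise ValueError(f"volumetric mask must be 3-D, got shape {vol.shape}")
    return float(vol.sum(dtype=np.int64)) * float(voxel_volume_ml)


# ---------------------------------------------------------------------------
# NIfTI and CSV plumbing
# ---------------------------------------------------------------------------

def save_mask(path: Path | str, mask: np.ndarray, spacings_mm: tuple) -> None:
    """Write a binary mask as uint8 NIfTI with the physical spacing in the header.

    Dynamic stacks are stored as (x, y, frame) with the frame axis spacing
    left at 1; volumetric masks as (x, y, z) with voxel dims in mm.
    """
    arr = _as_binary(mask, "mask")
    zooms = list(spacings_mm)[: arr.ndim] + [1.0] * max(0, arr.ndim - len(spacings_mm))
    affine = np.eye(4)
    for i, z in enumerate(zooms[:3]):
        affine[i, i] = z
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(zooms[: arr.ndim])
    nib.save(img, str(path))


def load_mask(path: Path | str, sidecar: dict | None = None) -> tuple[np.ndarray, tuple]:
    """Read a NIfTI mask, returning (uint8 array, header spacings).

    If a metadata ``sidecar`` is given and disagrees with the header
    spacing, the sidecar wins and a warning is logged.
    """
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    binary = _as_binary(arr, f"mask {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[: binary.ndim])
    if sidecar is not None and "pixel_size_mm" in sidecar:
        side = tuple(float(v) for v in sidecar["pixel_size_mm"])
        if not np.allclose(side, zooms[: len(side)], rtol=1e-6):
            logger.warning(
                "pixel size mismatch for %s: header %s vs sidecar %s; using sidecar",
                path, zooms[: len(side)], side,
            )
            zooms = side + zooms[len(side):]
    return binary, zooms


def save_curve_csv(path: Path | str, curves: list[AreaTimeCurve]) -> None:
    """Write curves as tidy CSV: one row per sample.

    Columns: source_id, slice_index, frame, time_s, area_mm2, frame_rate_fps.
    """
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "source_id": c.source_id,
            "slice_index": c.slice_index,
            "frame": np.arange(len(c)),
            "time_s": c.times_s,
            "area_mm2": c.areas_mm2,
            "frame_rate_fps": c.frame_rate_fps,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_curve_csv(path: Path | str) -> list[AreaTimeCurve]:
    """Read curves written by :func:`save_curve_csv`."""
    df = pd.read_csv(path)
    out = []
    for (source_id, slice_index), grp in df.groupby(["source_id", "slice_index"], sort=True):
        grp = grp.sort_values("frame")
        out.append(AreaTimeCurve.from_areas(
            grp["area_mm2"].to_numpy(),
            float(grp["frame_rate_fps"].iloc[0]),
            int(slice_index),
            str(source_id),
        ))
    return out


def write_sidecar(path: Path | str, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_sidecar(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())
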