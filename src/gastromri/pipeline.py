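"""End-to-end analysis of a cohort bundle.

Ties the modules together: extraction (masks → curves/volumes) →
motility (frequency, speed, occlusion) → volumetry (ΔGCV, emptying
rates) → summary (cohort tables, inclusion counts, recovery reports).

Records that cannot be analyzed (all-zero mask, too-short curve) are
skipped, logged with a machine-parsable reason code, and listed in
``exclusions.csv``; the run continues.  Timepoints failing the
two-of-three dominance rule stay in the tables with NaN frequency and
velocity so inclusion counts can be read off directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import motility, volumetry
from .config import RunConfig
from .extraction import (
    AreaTimeCurve,
    VolumeSeries,
    curve_from_mask_stack,
    load_curve_csv,
    load_mask,
    read_sidecar,
    volume_from_mask,
)
from .motility import Band, SliceGeometry
from .summary import aggregate_cohort, recovery_report

__all__ = ["analyze_bundle"]

logger = logging.getLogger(__name__)


def _load_dynamic_curves(bundle: Path, records: pd.DataFrame, use_masks: bool):
    """Yield (record row, AreaTimeCurve or None, reason)."""
    if not use_masks:
        curves = {
            (c.source_id, c.slice_index): c for c in load_curve_csv(bundle / "curves.csv")
        }
    for _, rec in records.iterrows():
        key_id = rec["source_id"]
        s = int(rec["slice_index"])
        if use_masks:
            path = bundle / "masks" / "dynamic" / f"{key_id}_s{s}.nii.gz"
            if not path.exists():
                yield rec, None, "missing_mask"
                continue
            try:
                sidecar = read_sidecar(path.with_suffix("").with_suffix(".json"))
                arr, zooms = load_mask(path, sidecar)
                stack = np.moveaxis(arr, -1, 0)  # (x, y, frame) -> (frame, x, y)
                curve = curve_from_mask_stack(
                    stack,
                    pixel_area_mm2=zooms[0] * zooms[1],
                    frame_rate_fps=float(rec["frame_rate_fps"]),
                    slice_index=s,
                    source_id=key_id,
                )
            except Exception as exc:  # corrupt mask: skip, keep going
                logger.warning("skipping %s slice %d: %s", key_id, s, exc)
                yield rec, None, "corrupt_mask"
                continue
            yield rec, curve, ""
        else:
            curve = curves.get((key_id, s))
            yield rec, curve, "" if curve is not None else "missing_curve"


def _load_volume_series(bundle: Path, use_masks: bool) -> pd.DataFrame:
    if not use_masks:
        return pd.read_csv(bundle / "volumes.csv")
    rows = []
    for path in sorted((bundle / "masks" / "volumetric").glob("*.nii.gz")):
        sidecar = read_sidecar(path.with_suffix("").with_suffix(".json"))
        arr, zooms = load_mask(path)
        voxel_ml = zooms[0] * zooms[1] * zooms[2] / 1000.0
        rows.append({
            "subject": sidecar["subject"],
            "arm": sidecar["arm"],
            "timepoint_min": float(sidecar["timepoint_min"]),
            "volume_ml": volume_from_mask(arr, voxel_ml),
        })
    return pd.DataFrame(rows)


def analyze_bundle(
    bundle_dir: Path | str,
    out_dir: Path | str,
    config: RunConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Run the full analysis over a phantom (or real-mask) bundle.

    Writes per-record, per-timepoint, emptying, cohort, inclusion-count,
    recovery and exclusion tables plus an analysis manifest, and returns
    the manifest dict.
    """
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    bundle_manifest = json.loads((bundle / "manifest.json").read_text())
    use_masks = bool(bundle_manifest.get("write_masks", True))

    band = cfg.band
    records = pd.read_csv(bundle / "records_dynamic.csv")

    per_record_rows: list[dict] = []
    exclusion_rows: list[dict] = []
    for rec, curve, reason in _load_dynamic_curves(bundle, records, use_masks):
        base = {
            "subject": rec["subject"], "arm": rec["arm"],
            "timepoint_min": float(rec["timepoint_min"]),
            "slice_index": int(rec["slice_index"]),
            "source_id": rec["source_id"],
        }
        if curve is None:
            exclusion_rows.append({**base, "reason": reason})
            continue
        try:
            spectrum = motility.band_spectrum(curve, band)
            spec_res = motility.dominant_frequency(spectrum, cfg.dominance_threshold)
            occ = motility.occlusion_series(curve, cfg.top_fraction)
        except ValueError as exc:
            code = ("zero_reference_area" if "reference" in str(exc)
                    else "spectral_failure")
            logger.warning("excluding %s: %s", base["source_id"], exc)
            exclusion_rows.append({**base, "reason": code})
            continue
        per_record_rows.append({
            **base,
            "peak_cpm": spec_res.peak_freq_cpm,
            "dominance_factor": spec_res.dominance_factor,
            "valid": spec_res.valid,
            "mean_occlusion_pct": occ.mean_occlusion_pct,
            "reference_area_mm2": occ.reference_area_mm2,
            "distance_factor": float(rec["distance_factor"]),
            "slice_thickness_mm": float(rec["slice_thickness_mm"]),
        })
    per_record = pd.DataFrame(per_record_rows)

    # per-timepoint frequency (two-of-three rule) and apparent speed
    tp_rows: list[dict] = []
    if len(per_record):
        for (subject, arm, tp), grp in per_record.groupby(
            ["subject", "arm", "timepoint_min"], sort=True
        ):
            results = [
                motility.SpectralResult(
                    peak_freq_hz=row.peak_cpm / 60.0,
                    dominance_factor=row.dominance_factor,
                    valid=bool(row.valid),
                    threshold=cfg.dominance_threshold,
                    n_band_bins=0,
                )
                for row in grp.itertuples()
            ]
            freq = motility.timepoint_frequency(results, cfg.min_valid_slices)
            geom = SliceGeometry(
                slice_thickness_mm=float(grp["slice_thickness_mm"].iloc[0]),
                distance_factor=float(grp["distance_factor"].iloc[0]),
                n_slices=max(2, len(grp)),
            )
            speed = motility.apparent_speed(freq, geom) if freq is not None else np.nan
            tp_rows.append({
                "subject": subject, "arm": arm, "timepoint_min": tp,
                "mean_cpm": freq if freq is not None else np.nan,
                "speed_mm_s": speed,
                "n_valid_slices": int(grp["valid"].sum()),
                "included": freq is not None,
            })
    per_timepoint = pd.DataFrame(tp_rows)

    # volumetry
    volumes = _load_volume_series(bundle, use_masks)
    emptying_rows: list[dict] = []
    gcv_rows: list[dict] = []
    for (subject, arm), grp in volumes.groupby(["subject", "arm"], sort=True):
        grp = grp.sort_values("timepoint_min")
        series = VolumeSeries(
            grp["timepoint_min"].to_numpy(), grp["volume_ml"].to_numpy(),
            subject=subject, arm=arm,
        )
        delta = volumetry.delta_gcv(series)
        for tp, v, dv in zip(series.timepoints_min, series.volumes_ml, delta.delta_ml):
            gcv_rows.append({
                "subject": subject, "arm": arm, "timepoint_min": float(tp),
                "gcv_ml": float(v), "delta_gcv_ml": float(dv),
            })
        res = volumetry.analyze_emptying(series, cfg.window_min, cfg.anchor_kcal)
        emptying_rows.append({
            "subject": subject, "arm": arm,
            "rate_ml_per_min": res.rate_ml_per_min,
            "rate_kcal_per_min": res.rate_kcal_per_min,
            "baseline_volume_ml": res.baseline_volume_ml,
            "n_points_in_window": res.n_points_in_window,
        })
    emptying = pd.DataFrame(emptying_rows)
    gcv = pd.DataFrame(gcv_rows)

    # cohort aggregation: tidy (subject, arm, timepoint, metric, value)
    tidy_parts = []
    if len(per_timepoint):
        tidy_parts.append(per_timepoint.assign(
            metric="frequency_cpm", value=per_timepoint["mean_cpm"]
        )[["subject", "arm", "timepoint_min", "metric", "value"]])
        tidy_parts.append(per_timepoint.assign(
            metric="speed_mm_s", value=per_timepoint["speed_mm_s"]
        )[["subject", "arm", "timepoint_min", "metric", "value"]])
    if len(gcv):
        tidy_parts.append(gcv.assign(metric="gcv_ml", value=gcv["gcv_ml"])
                          [["subject", "arm", "timepoint_min", "metric", "value"]])
        tidy_parts.append(gcv.assign(metric="delta_gcv_ml", value=gcv["delta_gcv_ml"])
                          [["subject", "arm", "timepoint_min", "metric", "value"]])
    cohort = aggregate_cohort(pd.concat(tidy_parts, ignore_index=True)) if tidy_parts else None

    occl_cohort = None
    if len(per_record):
        occl_tidy = per_record.assign(
            metric="occlusion_pct", value=per_record["mean_occlusion_pct"]
        )[["subject", "arm", "timepoint_min", "slice_index", "metric", "value"]]
        occl_cohort = aggregate_cohort(occl_tidy, extra_keys=("slice_index",))

    # inclusion counts (participant bookkeeping per arm x timepoint)
    inclusion = None
    if len(per_timepoint):
        inclusion = (
            per_timepoint.groupby(["arm", "timepoint_min"], sort=True)["included"]
            .sum().astype(int).reset_index(name="n_included")
        )

    # ground-truth recovery
    recovery_dyn = recovery_vol = None
    truth_dyn_path = bundle / "truth_dynamic.csv"
    if truth_dyn_path.exists() and len(per_record):
        truth_dyn = pd.read_csv(truth_dyn_path)
        est = per_record.copy()
        est.loc[~est["valid"].astype(bool), "peak_cpm"] = np.nan
        recovery_dyn = recovery_report(
            est[["subject", "arm", "timepoint_min", "slice_index", "peak_cpm"]],
            truth_dyn[["subject", "arm", "timepoint_min", "slice_index", "f0_cpm"]],
            keys=("subject", "arm", "timepoint_min", "slice_index"),
            params={"frequency_cpm": ("peak_cpm", "f0_cpm")},
        )
    truth_vol_path = bundle / "truth_volumetric.csv"
    if truth_vol_path.exists() and len(emptying):
        truth_vol = pd.read_csv(truth_vol_path)
        recovery_vol = recovery_report(
            emptying[["subject", "arm", "rate_ml_per_min"]],
            truth_vol[["subject", "arm", "r_meal_ml_per_min"]],
            keys=("subject", "arm"),
            params={"rate_ml_per_min": ("rate_ml_per_min", "r_meal_ml_per_min")},
        )

    # write everything
    per_record.to_csv(out / "per_record_motility.csv", index=False)
    per_timepoint.to_csv(out / "per_timepoint_motility.csv", index=False)
    emptying.to_csv(out / "emptying.csv", index=False)
    gcv.to_csv(out / "gcv.csv", index=False)
    pd.DataFrame(
        exclusion_rows,
        columns=["subject", "arm", "timepoint_min", "slice_index",
                 "source_id", "reason"],
    ).to_csv(out / "exclusions.csv", index=False)
    if cohort is not None:
        cohort.data.to_csv(out / "cohort.csv", index=False)
    if occl_cohort is not None:
        occl_cohort.data.to_csv(out / "cohort_occlusion.csv", index=False)
    if inclusion is not None:
        inclusion.to_csv(out / "inclusion_counts.csv", index=False)
    if recovery_dyn is not None:
        recovery_dyn.to_csv(out / "recovery_dynamic.csv", index=False)
    if recovery_vol is not None:
        recovery_vol.to_csv(out / "recovery_volumetric.csv", index=False)

    manifest = {
        "bundle": str(bundle),
        "bundle_master_seed": bundle_manifest.get("master_seed"),
        "config": cfg.to_dict(),
        "n_records_analyzed": int(len(per_record)),
        "n_records_excluded": int(len(exclusion_rows)),
        "complete": len(exclusion_rows) == 0,
    }
    (out / "analysis_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
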