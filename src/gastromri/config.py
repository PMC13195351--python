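"""Run configuration: validated, serializable, round-trippable.

Every analysis default equals the protocol value it models: detection
band 0.03–0.07 Hz, dominance threshold 2.0, two-of-three slice rule,
top-10% occlusion reference, 41–81 min emptying window, 300 kcal anchor,
−5 min baseline, 6.24 fps on a 140 × 140 grid over 200 × 200 mm with
5 mm slices.  Unknown keys in a config file are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .motility import Band
from .phantom import RasterSpec, StudyDesign

__all__ = ["RunConfig", "load_config"]


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulate + analyze run."""

    design: StudyDesign = field(default_factory=StudyDesign)
    raster: RasterSpec = field(default_factory=RasterSpec)
    band: Band = field(default_factory=Band)
    dominance_threshold: float = 2.0
    min_valid_slices: int = 2
    top_fraction: float = 0.10
    window_min: tuple[float, float] = (41.0, 81.0)
    anchor_kcal: float = 300.0
    baseline_label_min: float = -5.0
    master_seed: int = 0
    write_masks: bool = True
    noiseless: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.dominance_threshold < 0:
            raise ValueError("dominance_threshold must be non-negative")
        if not 1 <= self.min_valid_slices <= self.design.n_slices:
            raise ValueError("min_valid_slices must lie in [1, n_slices]")
        if self.window_min[0] >= self.window_min[1]:
            raise ValueError("window_min must be (start, end) with start < end")
        if self.baseline_label_min >= 0:
            raise ValueError("baseline_label_min must be negative (pre-water)")

    def to_dict(self) -> dict:
        """Plain-JSON/YAML-safe dict (tuples rendered as lists)."""

        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key, sub in (("design", StudyDesign), ("raster", RasterSpec), ("band", Band)):
            if key in data and isinstance(data[key], dict):
                data[key] = _build(sub, data[key], key)
        if "window_min" in data:
            data["window_min"] = tuple(data["window_min"])
        return cls(**data)


def load_config(path: Path | str) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON — YAML superset) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(raw)
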