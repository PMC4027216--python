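"""Run configuration: every tunable of the pipeline in one round-trippable
YAML document.  Defaults are the published screen values (N/C ratio 1.05,
form factor 1.48, CV 0.19, 4-SD hit rule)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import Thresholds

__all__ = ["SegmentationParams", "GfpRule", "RunConfig"]

CONFIG_VERSION = "1"


@dataclass(frozen=True)
class SegmentationParams:
    min_area: float = 80.0
    max_area: float = 2000.0
    min_distance: int = 8
    smoothing_sigma: float = 1.0
    inner_gap: int = 1
    ring_width: int = 4


@dataclass(frozen=True)
class GfpRule:
    """How per-cell GFP positivity is called.

    method "mad": threshold = median + k * scaled-MAD of the calibration
    cells' nuclear GFP (cells from wells whose role is in
    ``calibration_roles``).  method "fixed": use ``fixed`` directly.
    """

    method: str = "mad"
    k: float = 3.0
    fixed: float | None = None
    calibration_roles: tuple[str, ...] = ("mock_no_break",)

    def __post_init__(self) -> None:
        if self.method not in ("mad", "fixed"):
            raise ValueError(f"unknown GFP rule method {self.method!r}")
        if self.method == "fixed" and self.fixed is None:
            raise ValueError("fixed GFP rule needs a threshold value")


@dataclass(frozen=True)
class RunConfig:
    image_dir: str = "."
    layout_path: str = "layout.csv"
    manifest_path: str = "manifest.csv"
    output_dir: str = "out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    gfp_rule: GfpRule = field(default_factory=GfpRule)
    min_cells: int = 50
    k_sd: float = 4.0
    min_replicates: int = 2
    dmso_sd_mode: str = "pooled"  # or "dots" (replicate-averaged positions)
    edge_alpha: float = 0.01
    seed: int = 0
    version: str = CONFIG_VERSION

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gfp_rule"]["calibration_roles"] = list(self.gfp_rule.calibration_roles)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "gfp_rule" in d:
            g = dict(d["gfp_rule"])
            if "calibration_roles" in g:
                g["calibration_roles"] = tuple(g["calibration_roles"])
            d["gfp_rule"] = GfpRule(**g)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
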