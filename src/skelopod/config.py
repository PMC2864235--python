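"""Pipeline configuration: all preset parameters in one validated place.

Geometry-dependent thresholds are expressed as fractions of per-frame
cell geometry, following the standard scaling: the short-branch length
threshold and the branch-to-membrane distance threshold scale with the
cell body length (factors 1/10 and 1/6), and the tracking distance
threshold with the cell perimeter (factor 1/10).  They are resolved to
pixels per frame at run time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

_REQUIRED = ("frame_interval_s", "pixel_size_um")


@dataclass
class PipelineConfig:
    # acquisition
    frame_interval_s: float = 10.0
    pixel_size_um: float = 0.2
    modality: str = "fluorescence"
    gradient: dict = field(default_factory=lambda: {"direction_deg": 0.0})
    # segmentation
    min_area_px: int = 50
    # boundary smoothing
    smoothing: bool = True
    n_control: int | None = None     # default: perimeter / 8 px spacing
    spline_iterations: int = 5
    # branch pruning (fractions of body length)
    p_threshold_factor: float = 0.1
    prdist_threshold_factor: float = 1.0 / 6.0
    r_ratio: float = 1.5
    pruning_single_pass: bool = False
    # activity detection
    min_component_area_px: int = 4
    # backward tracking
    T_s: float = 50.0
    alpha: float = 0.5
    beta: float = 0.5
    cell_radius_um: float = 5.0
    dist_threshold_factor: float = 0.1   # fraction of perimeter
    # correlation
    delta_theta_deg: float = 4.0
    band_px: int = 3
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.modality not in ("fluorescence", "phase_contrast", "dic"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.r_ratio <= 1:
            raise ValueError("r_ratio must be > 1")
        if not ("direction_deg" in self.gradient
                or "source_xy" in self.gradient):
            raise ValueError(
                "gradient needs 'direction_deg' or 'source_xy'")

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius_um / self.pixel_size_um

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        missing = [k for k in _REQUIRED if k not in data]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
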