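"""Pipeline configuration: one flat, validated record of every tunable.

Serialized as flat JSON so each analysis run can log the exact
configuration it resolved; unknown keys are rejected rather than
ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

from .quantify import DEFAULT_VISIBILITY_THRESHOLD
from .slab import HALF_CHOROID_WIDTH_UM, SCT_ELIGIBILITY_CUTOFF_UM

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # slab presets (µm, below the outer RPE)
    cc_offset_um: float = 30.0
    cc_width_um: float = 30.0
    hc_width_um: float = HALF_CHOROID_WIDTH_UM
    hc_placement: str = "centered"  # centered | start, relative to SCT/2
    projection: str = "max"  # max | mean depth aggregation
    grayscale: str = "mean"  # mean | rec601 RGB collapse
    # binarization
    bernsen_radius_px: int = 15
    bernsen_contrast: float = 15.0
    # optic-disc exclusion oval (row, col, semi_axis_r, semi_axis_c) or None
    disc_oval: Tuple[float, float, float, float] | None = None
    # cohort / reporting
    eligibility_cutoff_um: float = SCT_ELIGIBILITY_CUTOFF_UM
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cc_offset_um < 0 or self.cc_width_um <= 0 or self.hc_width_um <= 0:
            raise ValueError("slab offsets must be >= 0 and widths > 0")
        if self.hc_placement not in ("centered", "start"):
            raise ValueError("hc_placement must be 'centered' or 'start'")
        if self.projection not in ("max", "mean"):
            raise ValueError("projection must be 'max' or 'mean'")
        if self.grayscale not in ("mean", "rec601"):
            raise ValueError("grayscale must be 'mean' or 'rec601'")
        if self.bernsen_radius_px < 1:
            raise ValueError("bernsen_radius_px must be >= 1")
        if not (0 <= self.bernsen_contrast <= 255):
            raise ValueError("bernsen_contrast must lie in [0, 255]")
        if self.disc_oval is not None:
            self.disc_oval = tuple(float(v) for v in self.disc_oval)
            if len(self.disc_oval) != 4:
                raise ValueError("disc_oval must be (row, col, semi_axis_r, semi_axis_c)")
            if self.disc_oval[2] <= 0 or self.disc_oval[3] <= 0:
                raise ValueError("disc oval semi-axes must be positive")
        if self.eligibility_cutoff_um < 0 or self.visibility_threshold < 0:
            raise ValueError("cutoffs must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["disc_oval"] is not None:
            d["disc_oval"] = list(d["disc_oval"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(json.loads(text))
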