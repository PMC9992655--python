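"""Run configuration: every tunable of both pipelines with its default.

Parseable from YAML or JSON; unknown keys are rejected so typos fail loudly.
All randomness in a run flows from ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import OmmatidiaError


@dataclass
class RunConfig:
    # 2D detection
    n_fundamentals: int = 3
    cutoff_factor: float = 1.25          # low-pass cutoff / max fundamental freq
    min_distance_factor: float = 0.25    # maxima separation / FFT diameter
    prominence_factor: float = 0.25      # maxima height gate / median height
    significance_k: float = 5.0          # reciprocal peak threshold (MADs)
    subpixel: bool = False
    pixel_size_um: float = 1.0
    # 3D pipeline
    voxel_size_um: float = 1.0
    density_range: Optional[tuple] = None
    window_deg: float = 90.0             # rasterization segment size
    lens_diameter_guess_um: Optional[float] = None
    neighborhood_radius: int = 5         # axis averaging, in lens diameters
    section_width: float = 1.0           # IO sectioning, in lens diameters
    vertical_axis: tuple = (0.0, 0.0, 1.0)  # anatomical up in scan coordinates
    projection_radius_mm: float = 100.0  # world-referenced FOV sphere
    seed: int = 0

    def __post_init__(self):
        if self.density_range is not None:
            self.density_range = tuple(self.density_range)
        self.vertical_axis = tuple(self.vertical_axis)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OmmatidiaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
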