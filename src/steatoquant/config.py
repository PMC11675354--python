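"""Centralized pipeline configuration with YAML serialization.

Every tunable of the pipeline lives here with its default, and a run's
config (plus its hash) is embedded in every output bundle for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables; units are um / um^2 unless stated."""

    pixel_size_um: float | None = None  # None -> from file metadata/default
    tissue_min_object_um2: float = 50.0
    min_diameter_um: float = 3.0
    max_diameter_um: float = 200.0
    annulus_width_um: float = 5.0
    max_hole_intensity_ratio: float = 0.5
    max_depth: int = 5
    min_samples_leaf: int = 5
    iou_min: float = 0.5
    min_lumen_diameter_um: float = 40.0
    portal_collagen_fraction_min: float = 0.3
    halo_um: float = 50.0
    perisinusoidal_halo_um: float = 10.0
    macro_threshold_um: float = 15.0
    bin_width_um: float = 2.0
    max_diameter_bin_um: float = 100.0
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)
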