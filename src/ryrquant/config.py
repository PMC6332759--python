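"""Pipeline configuration: every tunable constant in one flat, serializable record.

All lengths are in nanometres unless the field name says otherwise. The
defaults encode the acquisition and analysis conventions of the 3D dSTORM
RyR pipeline: 10 nm rendering voxels scaled to 30 nm analysis voxels (one
RyR tetramer per voxel), a 600 nm axial analysis window, a calibration
constant of 3.3076 blink events per RyR, 100 nm edge-to-edge CRU grouping,
250 nm t-tubules with a 10 nm dyadic cleft and 80 nm jSR padding, and an
idealized elliptic-cylinder cell of 6 x 10 x 130 um.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # rendering / voxelization
    render_voxel_nm: float = 10.0
    analysis_voxel_nm: float = 30.0
    axial_window_nm: float = 600.0
    # acquisition
    n_frames: int = 20_000
    frame_exposure_ms: float = 50.0
    drift_segments: int = 5
    # calibration
    events_per_ryr: float = 3.3076
    grid_nm: float = 30.0
    flat_z_extent_max_nm: float = 450.0
    # CRU grouping
    cru_gap_nm: float = 100.0
    # dyad geometry
    tubule_diameter_nm: float = 250.0
    cleft_nm: float = 10.0
    jsr_padding_nm: float = 80.0
    dyadic_threshold_nm: float = 250.0
    prune_volume_um3: float = 0.03
    ryr_spacing_nm: float = 30.0
    # idealized cell geometry (um)
    cell_short_radius_um: float = 6.0
    cell_long_radius_um: float = 10.0
    cell_length_um: float = 130.0
    cell_shell_um: float = 1.5
    # spark imaging
    spark_frame_interval_ms: float = 1.85
    spark_k_sigma: float = 3.5
    surface_band_um: float = 1.5
    # randomness
    seed: int = 0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "seed":
                continue
            if not v > 0:
                raise ValueError(f"config field {f.name} must be positive, got {v!r}")
        if self.cell_shell_um >= self.cell_short_radius_um:
            raise ValueError("cell_shell_um must be smaller than cell_short_radius_um")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable digest of the configuration, used for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
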