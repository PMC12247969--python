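"""Run configuration: one YAML file, every tunable with its standard default.

The defaults are the measurement conditions of the method: ±10 nm scans at
0.25 nm steps, 12 nm distance-weighted averaging, 8 nm edge exclusion,
12 nm patches, a 24 nm particle-assignment cutoff, and >12 nm separation
between randomized patch centers.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "SurfaceEntry"]


@dataclass
class SurfaceEntry:
    path: str
    label: str = ""
    attribute_table: str | None = None


@dataclass
class RunConfig:
    volume: str = ""
    voxel_size_nm: float | None = None   # overrides the MRC header
    polarity: str = "peaks_bright"       # peaks_bright | peaks_dark | auto
    surfaces: list[SurfaceEntry] = field(default_factory=list)
    particles: str | None = None
    particle_pixel_size_a: float | None = None
    particle_region_label: str | None = None
    output_dir: str = "memthick_out"

    scan_lo_nm: float = -10.0
    scan_hi_nm: float = 10.0
    scan_step_nm: float = 0.25
    avg_radius_nm: float = 12.0
    edge_margin_nm: float = 8.0
    edge_margin_metric: str = "geodesic"
    weight_law: str = "inverse_1plus"
    patch_radius_nm: float = 12.0
    assign_cutoff_nm: float = 24.0
    random_patch_min_sep_nm: float = 12.0
    profile_lo_nm: float = -10.0
    profile_hi_nm: float = 30.0
    quantile_edges: tuple = (0.0, 0.5, 0.9, 0.95, 0.99, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scan_step_nm", "avg_radius_nm", "patch_radius_nm",
                     "assign_cutoff_nm", "random_patch_min_sep_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.edge_margin_nm < 0:
            raise ValueError("edge_margin_nm must be >= 0")
        if self.scan_lo_nm >= self.scan_hi_nm:
            raise ValueError("scan_lo_nm must be < scan_hi_nm")
        if self.weight_law != "inverse_1plus":
            raise ValueError("only the inverse_1plus weight law is supported")
        self.surfaces = [s if isinstance(s, SurfaceEntry) else SurfaceEntry(**s)
                         for s in self.surfaces]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["quantile_edges"] = list(self.quantile_edges)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
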