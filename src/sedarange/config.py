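"""Run configuration shared by every pipeline stage.

A single :class:`RunConfig` carries the time-slicing scheme, the
rarefaction depth and iteration count, the moving-window geometry, the
equal-area grid resolution and the statistical thresholds.  Defaults
follow the study design the pipeline implements: 30 slices of 1000
calendar years BP, rarefaction to 5000 reads repeated 100 times,
5-slice windows advancing by one slice, a 200 km equal-area grid,
|R| > 0.2 sign classification, and a co-occurrence network built from
Spearman r > 0.6 at Benjamini-Hochberg adjusted p < 0.05 after a
10-read / 5-slice family filter.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    slice_width_years: int = 1000
    n_slices: int = 30
    base_count: int = 5000
    n_iterations: int = 100
    window_width_slices: int = 5
    window_step_slices: int = 1
    grid_cell_km: float = 200.0
    r_class_threshold: float = 0.2
    network_r_threshold: float = 0.6
    network_alpha: float = 0.05
    network_min_reads: int = 10
    network_min_slices: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "slice_width_years", "n_slices", "base_count", "n_iterations",
            "window_width_slices", "window_step_slices", "grid_cell_km",
            "r_class_threshold", "network_r_threshold", "network_alpha",
            "network_min_reads", "network_min_slices",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.window_width_slices > self.n_slices:
            raise ConfigError(
                f"window_width_slices ({self.window_width_slices}) exceeds "
                f"n_slices ({self.n_slices})"
            )

    @property
    def grid_cell_m(self) -> float:
        return self.grid_cell_km * 1000.0

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a TOML file; keyword overrides win."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
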