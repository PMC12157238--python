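"""Pipeline configuration with strict YAML round-tripping.

Defaults mirror the method's published operating point: 3 wavelet
decomposition levels with equal fusion weights (alpha = beta = 0.5), a
100-pixel minimum fruit area, K = 8 color clusters, a 2x2 opening kernel
and size-3 median filter for the branch mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class PipelineConfig:
    # fusion
    wavelet: str = "db2"
    levels: int = 3
    alpha: float = 0.5
    beta: float = 0.5
    channel: str = "fused"  # fused | a_channel | i_channel
    # fruit stage
    min_area: int = 100
    fruit_open_kernel: int = 3
    fruit_bright_foreground: bool = True
    # branch stage
    k: int = 8
    branch_open_kernel: int = 2
    median_window: int = 3
    branch_dark_foreground: bool = True
    kmeans_features: str = "lab"  # lab | ab
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-4
    # shared
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ConfigError("alpha and beta must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ConfigError("alpha + beta must equal 1")
        if self.channel not in ("fused", "a_channel", "i_channel"):
            raise ConfigError(f"unknown channel {self.channel!r}")
        if self.min_area < 0:
            raise ConfigError("min_area must be non-negative")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ConfigError("median_window must be an odd integer >= 3")
        if self.kmeans_features not in ("lab", "ab"):
            raise ConfigError(f"unknown kmeans_features {self.kmeans_features!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys by name."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
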