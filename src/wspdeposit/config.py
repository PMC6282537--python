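"""Run configuration: defaults, validation, YAML round-trip.

Defaults mirror a typical study setup: 600 dpi scans, the DepositScan
power-law spread factor (1.06, 0.455), 30% coverage exclusion and a
0.18 µg µL⁻¹ tank mix.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .card_imaging import SegmentationConfig
from .stain_geometry import (
    DEFAULT_BINS,
    DEFAULT_EXPONENT,
    DEFAULT_SF,
    BinnedSpreadFactor,
    ConstantSpreadFactor,
    SpreadFactorModel,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A configuration value failed validation; the message names the field."""


@dataclass
class RunConfig:
    dpi: float = 600.0
    spread_factor_model: str = "constant"  # "constant" | "binned"
    sf: float = DEFAULT_SF
    exponent: float = DEFAULT_EXPONENT
    bins: list = field(default_factory=lambda: [list(b) for b in DEFAULT_BINS])
    threshold_mode: str = "automatic"
    fixed_threshold: int = 128
    connectivity: int = 8
    min_pixels: int = 1
    stains_darker: bool = True
    tank_concentration: float = 0.18
    coverage_threshold: float = 30.0
    correction_factor: float | None = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.dpi <= 0:
            raise ConfigError("dpi must be > 0")
        if self.spread_factor_model not in ("constant", "binned"):
            raise ConfigError("spread_factor_model must be 'constant' or 'binned'")
        if self.sf <= 0:
            raise ConfigError("sf must be > 0")
        if not 0 < self.exponent < 1:
            raise ConfigError("exponent must be in (0, 1)")
        if not 0 <= self.fixed_threshold <= 255:
            raise ConfigError("fixed_threshold must be in [0, 255]")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.min_pixels < 1:
            raise ConfigError("min_pixels must be >= 1")
        if self.tank_concentration < 0:
            raise ConfigError("tank_concentration must be >= 0")
        if not 0 < self.coverage_threshold <= 100:
            raise ConfigError("coverage_threshold must be in (0, 100]")
        if self.correction_factor is not None and self.correction_factor <= 0:
            raise ConfigError("correction_factor must be > 0")
        return self

    def spread_model(self) -> SpreadFactorModel:
        if self.spread_factor_model == "constant":
            return ConstantSpreadFactor(sf=self.sf, exponent=self.exponent).fit()
        return BinnedSpreadFactor(bins=[tuple(b) for b in self.bins]).fit()

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold_mode=self.threshold_mode,
            fixed_threshold=self.fixed_threshold,
            connectivity=self.connectivity,
            min_pixels=self.min_pixels,
            stains_darker=self.stains_darker,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
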