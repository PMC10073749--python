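"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError

VALID_SCENES = ("calibration", "capillary", "artery")


@dataclass
class RunConfig:
    """Validated CLI/YAML configuration.  Unknown keys are rejected."""

    scene: str = "calibration"
    seed: int = 0
    unit_scale: float = 1.0
    noise_sigma: float = 0.0
    noise_floor: float = 0.0
    k: int = 5
    c_ref: Optional[float] = None
    clamp_cb: bool = False
    sheath_correction: bool = True
    medium: Optional[str] = None
    cb_true: Optional[float] = None
    cw_true: Optional[float] = None
    out: Optional[str] = None

    def __post_init__(self):
        if self.scene not in VALID_SCENES:
            raise ConfigError(f"scene must be one of {VALID_SCENES}, got {self.scene!r}")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.noise_sigma < 0 or self.noise_floor < 0:
            raise ConfigError("noise settings must be non-negative")
        if self.unit_scale <= 0:
            raise ConfigError("unit_scale must be positive")
        if self.k < 1:
            raise ConfigError("k must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"configuration file {path} must hold a mapping")
        return cls.from_mapping(doc)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
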