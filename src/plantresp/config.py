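"""Run configuration: defaults, YAML reading/writing, validation."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields as dc_fields
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Physical constants and run flags shared across the package.

    Defaults: canopy decay k = 0.5 per unit LAI, growth coefficient
    r_g = 0.25, Q10 = 2.0, light-inhibition threshold 2 W m^-2, carbon molar
    mass 12.0 g mol^-1, 3.1536e7 s per 365-day year.
    """

    seed: int = 0
    k: float = 0.5
    r_g: float = 0.25
    q10: float = 2.0
    light_threshold: float = 2.0
    light_inhibition_fraction: float = 0.3
    carbon_g_per_mol: float = 12.0
    seconds_per_year: float = 3.1536e7
    eta_root: float = 0.5
    eta_stem: float = 0.4
    beta_on_all: bool = False
    clip_baseline: bool = True
    tg_equals_tl: bool = False
    output_precision: int = 6

    def __post_init__(self) -> None:
        for name in ("k", "q10", "carbon_g_per_mol", "seconds_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.r_g < 1.0:
            raise ValueError("r_g must lie in [0, 1)")
        if self.light_threshold < 0 or not 0 <= self.light_inhibition_fraction <= 1:
            raise ValueError("invalid light-inhibition settings")
        if self.eta_root < 0 or self.eta_stem < 0:
            raise ValueError("nitrogen ratios must be non-negative")


def read_config(path: str | Path) -> RunConfig:
    """Read a YAML config; missing keys take defaults, unknown keys error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a key-value mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration, for output provenance."""
    payload = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
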