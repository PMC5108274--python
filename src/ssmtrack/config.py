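"""Run configuration: YAML binding, validation, and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mcmc_engine import SamplerConfig
from .movement_model import FORMULATIONS, PriorConfig

__all__ = ["RunConfig", "ConfigError", "write_manifest"]

logger = logging.getLogger("ssmtrack")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything needed for a reproducible fit."""

    model: str = "two_state"
    observations: str | None = None
    haulout: str | None = None
    dives: str | None = None
    outdir: str = "ssmtrack_out"
    dt_hours: float = 6.0
    t0_rule: str = "floor_day_boundary"
    error_table: str | None = None
    activity_threshold: float = 0.5
    activity_missing_value: float = 0.5
    log_level: str = "INFO"
    strict: bool = False
    rhat_threshold: float = 1.1
    sampler: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def sampler_config(self, seed: int | None = None) -> SamplerConfig:
        kw = dict(self.sampler)
        preset = kw.pop("preset", "full")
        if seed is not None:
            kw["seed"] = seed
        if preset == "desk":
            return SamplerConfig.desk(**kw)
        return SamplerConfig.full(**kw)

    def prior_config(self) -> PriorConfig:
        return PriorConfig(**self.priors)

    def validate(self) -> None:
        if self.model not in FORMULATIONS:
            raise ConfigError(
                f"model must be one of {FORMULATIONS}, got {self.model!r}"
            )
        if not self.observations:
            raise ConfigError("observations CSV path is required")
        if not Path(self.observations).exists():
            raise ConfigError(f"observations file not found: {self.observations}")
        if self.model == "haulout":
            if not self.haulout:
                raise ConfigError(
                    "model=haulout requires a haulout CSV ('haulout' key)"
                )
            if not Path(self.haulout).exists():
                raise ConfigError(f"haulout file not found: {self.haulout}")
        if self.model == "activity":
            if not self.dives:
                raise ConfigError(
                    "model=activity requires a dive-summary CSV ('dives' key)"
                )
            if not Path(self.dives).exists():
                raise ConfigError(f"dives file not found: {self.dives}")


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: RunConfig, seed: int, outdir: Path, extra: dict | None = None) -> Path:
    import numpy
    import pandas
    import scipy

    from . import __version__

    manifest = {
        "seed": seed,
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "versions": {
            "ssmtrack": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
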