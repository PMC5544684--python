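"""Validated run configuration for the pipeline and CLI.

A single TOML file with sections per stage; unknown keys are rejected so a
typo cannot silently fall back to a default.  All randomness in a run flows
from the single ``seed``.
"""

from __future__ import annotations

import tomllib
from typing import Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class GridSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = 250.0
    stop: float = 700.0
    step: float = 1.0


class NoiseSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_additive: float = 0.002
    baseline_drift_slope: float = 0.0


class RunConfig(BaseModel):
    """Top-level configuration; CLI flags override individual fields."""

    model_config = ConfigDict(extra="forbid")
    grid: GridSpec = GridSpec()
    family: str = "metarhodopsin_like"
    window: str = "auto"
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0
    outdir: Optional[str] = None


def load_config(path: str | None) -> RunConfig:
    """Load and validate a TOML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return RunConfig(**data)
    except (OSError, tomllib.TOMLDecodeError, ValidationError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
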