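"""Declarative experiment configuration.

Experiments differ only in a handful of scalars, so a single YAML file
with either nested sections or flat dotted keys (``controller.gamma: 2``)
describes a full run.  The schema is validated with pydantic before any
computation; CLI flags override file values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .presets import PRESETS
from .sls import NoiseSpec, SLSParameters

__all__ = ["ExperimentConfig", "load_config"]


class PlantConfig(BaseModel):
    preset: str | None = "gelma_7pct"
    lambda1: float | None = None
    lambda2: float | None = None
    tau: float | None = None

    @model_validator(mode="after")
    def _check(self):
        explicit = (self.lambda1, self.lambda2, self.tau)
        if any(v is not None for v in explicit) and not all(
            v is not None for v in explicit
        ):
            raise ValueError("give all of lambda1/lambda2/tau or none")
        if all(v is None for v in explicit) and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        return self

    def build(self) -> SLSParameters:
        if self.lambda1 is not None:
            return SLSParameters(self.lambda1, self.lambda2, self.tau)
        return PRESETS[self.preset]


class ControllerConfig(BaseModel):
    Q: list[float] = Field(default=[10.0, 1.0], description="diagonal of Q")
    R: float = 1.0
    gamma: float = 1e-3
    leak_sigma: float = 0.01
    observer_poles: list[float] | None = None
    basis_order: int = 3


class CommandConfig(BaseModel):
    offset_uN: float = 5.0
    amplitude_uN: float = 5.0
    frequency_Hz: float = 0.01
    n_cycles: int = 3
    dt_s: float | None = None


class NoiseConfig(BaseModel):
    mean_abs_uN: float = 0.277
    kind: str = "gaussian"

    def build(self) -> NoiseSpec:
        return NoiseSpec(self.mean_abs_uN, self.kind)


class OpticsConfig(BaseModel):
    resolution: list[int] = Field(default=[1600, 1200])
    fov_mm: list[float] = Field(default=[7.04, 5.28])
    objective_factor: float = 2.0


class FiberConfig(BaseModel):
    diameter_um: float = 150.0
    L0_um: float = 1000.0


class SimConfig(BaseModel):
    seed: int = 0
    tube_K_uN_per_um: float = 5.0


class ExperimentConfig(BaseModel):
    plant: PlantConfig = PlantConfig()
    controller: ControllerConfig = ControllerConfig()
    command: CommandConfig = CommandConfig()
    noise: NoiseConfig = NoiseConfig()
    vision: OpticsConfig = OpticsConfig()
    fiber: FiberConfig = FiberConfig()
    sim: SimConfig = SimConfig()

    @field_validator("*", mode="before")
    @classmethod
    def _none_to_default(cls, v):
        return v


def _unflatten(d: dict[str, Any]) -> dict[str, Any]:
    """Expand flat dotted keys into nested dicts (mixing both is fine)."""
    out: dict[str, Any] = {}
    for key, val in d.items():
        parts = key.split(".")
        cur = out
        for p in parts[:-1]:
            cur = cur.setdefault(p, {})
        if isinstance(val, dict):
            cur.setdefault(parts[-1], {}).update(_unflatten(val))
        else:
            cur[parts[-1]] = val
    return out


def load_config(
    path: str | Path | None, overrides: dict[str, Any] | None = None
) -> ExperimentConfig:
    """Load and validate a config file, applying flat-key overrides."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        raw.update(loaded)
    merged = _unflatten(raw)
    if overrides:
        for key, val in _unflatten(overrides).items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
    return ExperimentConfig(**merged)
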