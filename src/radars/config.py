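"""Run configuration: schema, validation, YAML/TOML loading, serialization.

A :class:`RunConfig` fully determines a pipeline run — thermodynamic
context, distribution λ, simulation parameters, network options and the
seed — and round-trips through YAML so a saved run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .repertoire import SimulationConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class ThermoSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    temperature: float = Field(310.0, gt=0)
    gas_constant: float = Field(8.314e-3, gt=0)


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape_dim: int = Field(8, ge=2)
    n_antigens: int = Field(60, ge=0)
    influx_per_step: int = Field(20, ge=0)
    b1_fraction: float = Field(0.05, ge=0, le=1)
    b1_mode: str = "low"
    r0_bonds: int = Field(3, ge=1)
    eps0: Optional[float] = Field(None, gt=0)
    gc_trigger: float = Field(0.5, ge=0, le=1)
    gc_mutation_step: float = Field(0.15, gt=0)
    gc_cycles: int = Field(10, ge=1)
    angular_resolution_constant: Optional[float] = Field(None, gt=0)
    cap_coverage: float = Field(0.01, gt=0, lt=1)
    mean_system_dg: Optional[float] = Field(None, ge=0)
    clearance_factor: float = Field(3.0, ge=1)
    rho: float = Field(0.5, gt=0, le=1)
    carrying_capacity: int = Field(1000, ge=1)
    llpc_size: int = Field(10, ge=1)
    n_steps: int = Field(500, ge=0)


class NetworkSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_min: int = Field(3, ge=2)
    lb_min: int = Field(2, ge=2)
    lb_max: int = Field(8, ge=2)
    box_restarts: int = Field(10, ge=1)


class RunConfig(BaseModel):
    """Top-level configuration of a reproducible pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    lam: float = Field(1.6180339887498949, gt=0)
    thermo: ThermoSection = Field(default_factory=ThermoSection)
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    out_dir: str = "radars_run"

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v

    def simulation_config(self) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            shape_dim=s.shape_dim,
            n_antigens=s.n_antigens,
            lam=self.lam,
            influx_per_step=s.influx_per_step,
            b1_fraction=s.b1_fraction,
            b1_mode=s.b1_mode,
            r0_bonds=s.r0_bonds,
            eps0=s.eps0,
            temperature=self.thermo.temperature,
            gc_trigger=s.gc_trigger,
            gc_mutation_step=s.gc_mutation_step,
            gc_cycles=s.gc_cycles,
            angular_resolution_constant=s.angular_resolution_constant,
            cap_coverage=s.cap_coverage,
            mean_system_dg=s.mean_system_dg,
            clearance_factor=s.clearance_factor,
            rho=s.rho,
            carrying_capacity=s.carrying_capacity,
            llpc_size=s.llpc_size,
            seed=self.seed,
            n_steps=s.n_steps,
        )

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: "str | Path | None" = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML or TOML; ``None`` gives all defaults.

    Unknown keys are rejected with the offending names in the error message;
    an empty file yields the default configuration (T = 310 K, λ = φ, D = 8,
    seed = 0).
    """
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.suffix in (".toml",):
        data = tomllib.loads(p.read_text())
    else:
        data = yaml.safe_load(p.read_text())
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: "str | Path") -> None:
    """Write a config as YAML; ``load_config`` of the result is the identity."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
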