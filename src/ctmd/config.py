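"""Flat run configuration for the end-to-end pipeline.

One YAML mapping (or keyword overrides) drives the whole demo pipeline:
thermodynamics, quadrature grid, metadynamics parameters, toy dynamics,
scoring and enrichment settings.  Energies in the config file are in the
toy kT units directly except ``w0_kj_per_mol``, which follows the PLUMED
kJ/mol convention and is converted on load.  Configs hash stably so every
output can be stamped with the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .ct import Grid
from .metad import GAS_CONSTANT_KJ_PER_MOL_K, ThermoParams
from .screen import MetadParams
from .toy_dynamics import DynParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # thermodynamics
    temperature: float = 300.0
    gamma: float = 10.0
    # quadrature grid
    grid_min: float = 0.0
    grid_max: float = 3.81
    grid_points: int = 1000
    # metadynamics
    w0_kj_per_mol: float = 1.2
    sigma: float = 0.02
    pace: int = 500
    # toy dynamics
    dt: float = 1e-3
    friction: float = 1.0
    kT: float = 1.0
    n_steps: int = 500_000
    # library / scoring
    n_binders: int = 5
    n_nonbinders: int = 27
    depth_binder_mean: float = 8.0
    depth_nonbinder_mean: float = 2.0
    depth_sd: float = 1.0
    n_replicas: int = 3
    potential_width: float = 0.5
    wall_position: float = 3.0
    wall_stiffness: float = 50.0
    # enrichment
    subsample_k: int = 5
    subsample_repeats: int = 200
    xx_list: tuple[float, ...] = (10.0, 20.0, 30.0)
    alpha_list: tuple[float, ...] = (20.0,)
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("xx_list", "alpha_list"):
            if key in data:
                data[key] = tuple(float(x) for x in data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["xx_list"] = list(self.xx_list)
        data["alpha_list"] = list(self.alpha_list)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of all fields; stamps pipeline outputs."""
        data = dataclasses.asdict(self)
        data["xx_list"] = list(self.xx_list)
        data["alpha_list"] = list(self.alpha_list)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # --- component parameter bundles -------------------------------------
    @property
    def thermo(self) -> ThermoParams:
        return ThermoParams(beta=1.0 / self.kT, gamma=self.gamma, temperature=self.temperature)

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_min, self.grid_max, self.grid_points)

    @property
    def metad(self) -> MetadParams:
        w0_kt = self.w0_kj_per_mol / (GAS_CONSTANT_KJ_PER_MOL_K * self.temperature)
        return MetadParams(w0=w0_kt, sigma=self.sigma, pace=self.pace)

    @property
    def dyn(self) -> DynParams:
        return DynParams(self.dt, self.friction, self.kT, self.n_steps, self.seed)
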