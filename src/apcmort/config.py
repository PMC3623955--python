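"""Run configuration: one serialisable object per reproducible run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .apc import MCMCConfig
from .lexis import LexisGrid

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides its input files.

    A run is reproducible from config + inputs + seed alone; the config
    hash is logged next to every artifact written.
    """

    grid_age_lower_edges: tuple[int, ...] = tuple(range(30, 80, 5))
    grid_period_start_years: tuple[int, ...] = tuple(range(1976, 2006, 5))
    grid_age_width: int = 5
    grid_period_width: int = 5
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    hyper_shape: float = 1e-3
    hyper_rate: float = 1e-3
    standard_population: str = "who_world"
    projection_horizon: int = 3
    joinpoint_max_k: int = 3
    joinpoint_min_obs: int = 2
    tpu_table_size: int = 40
    seed: int = 0

    def grid(self) -> LexisGrid:
        return LexisGrid(
            age_lower_edges=tuple(self.grid_age_lower_edges),
            period_start_years=tuple(self.grid_period_start_years),
            age_width=self.grid_age_width,
            period_width=self.grid_period_width,
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, mcmc=replace(self.mcmc, seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_age_lower_edges"] = list(self.grid_age_lower_edges)
        d["grid_period_start_years"] = list(self.grid_period_start_years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = MCMCConfig(**d["mcmc"])
        for key in ("grid_age_lower_edges", "grid_period_start_years"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
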