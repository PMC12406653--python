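"""Run configuration: every model constant in one serializable place.

A :class:`RunConfig` gathers the population parameters, dosing policy,
simulation settings, cohort specification and TDM design so that a whole
pipeline run is reproducible from (config, seed).  Round-trips through YAML
without loss; a short hash of the canonical JSON form is logged with every
CLI run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .dosing import DosingPolicy
from .pk_core import PopulationParameters
from .pta_sim import SimulationConfig
from .synthetic_data import CohortSpec, TDMDesign

__all__ = ["RunConfig"]


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    if isinstance(value, dict):
        return {k: _tuplify(v) for k, v in value.items()}
    return value


def _build(cls, payload: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{k: _tuplify(v) for k, v in payload.items()})


@dataclass(frozen=True)
class RunConfig:
    population: PopulationParameters = field(default_factory=PopulationParameters)
    dosing: DosingPolicy = field(default_factory=DosingPolicy)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    tdm: TDMDesign = field(default_factory=TDMDesign)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"population": asdict(self.population),
                "dosing": asdict(self.dosing),
                "simulation": asdict(self.simulation),
                "cohort": asdict(self.cohort),
                "tdm": asdict(self.tdm),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(
            population=_build(PopulationParameters, payload.get("population", {})),
            dosing=_build(DosingPolicy, payload.get("dosing", {})),
            simulation=_build(SimulationConfig, payload.get("simulation", {})),
            cohort=_build(CohortSpec, payload.get("cohort", {})),
            tdm=_build(TDMDesign, payload.get("tdm", {})),
            seed=int(payload.get("seed", 0)),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        return cls.from_dict(payload or {})

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
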