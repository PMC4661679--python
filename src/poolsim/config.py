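"""YAML configuration for the simulation pipeline.

A config file is a plain mapping with up to four sections, each mirroring a
parameter dataclass::

    population:        # PopulationParams fields
      n_pop: 200000
      sigma2_ga: 1.72
    outcome:           # OutcomeParams fields
      aosi_meanlog: 1.4
      aosi_sdlog: 0.75
    allocation:        # PoolAllocation fields
      g: 5
      scale: 1
    scenario:          # ScenarioSpec scalar fields
      model_form: linear
      beta1: 0.25
      sigma2_1: 0.0625
      n_replicates: 1000
      seed: 1

Unknown keys raise a :class:`~poolsim.errors.ParameterError` so that typos do
not silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ParameterError
from .outcomes import OutcomeParams
from .pooling import PoolAllocation
from .popgen import PopulationParams
from .runner import ScenarioSpec

_SCENARIO_SCALARS = (
    "model_form", "beta1", "sigma2_1", "g", "scale",
    "n_replicates", "n_pop", "seed", "alpha",
)


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ParameterError(f"unknown {name} config keys: {sorted(unknown)}")
    kwargs = dict(section)
    for key in ("ga_range", "score_range", "multipliers"):
        if kwargs.get(key) is not None and key in allowed:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path) -> ScenarioSpec:
    """Read a YAML config file into a fully populated :class:`ScenarioSpec`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config file must contain a mapping")
    unknown = set(raw) - {"population", "outcome", "allocation", "scenario"}
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")

    population = _build(PopulationParams, raw.get("population", {}), "population")
    outcome = _build(OutcomeParams, raw.get("outcome", {}), "outcome")
    allocation = _build(PoolAllocation, raw.get("allocation", {}), "allocation")

    scen = raw.get("scenario", {})
    bad = set(scen) - set(_SCENARIO_SCALARS)
    if bad:
        raise ParameterError(f"unknown scenario config keys: {sorted(bad)}")
    spec = ScenarioSpec(
        population=population, outcome=outcome, allocation=allocation, **scen
    )
    # section values double as scenario-level defaults when not overridden
    if "g" not in scen:
        spec.g = allocation.g
    if "scale" not in scen:
        spec.scale = allocation.scale
    if "n_pop" not in scen:
        spec.n_pop = population.n_pop
    if "model_form" not in scen:
        spec.model_form = outcome.model_form
    if "beta1" not in scen:
        spec.beta1 = outcome.beta1
    return spec


def dump_config(spec: ScenarioSpec, path) -> None:
    """Write a ScenarioSpec back to a YAML file (inverse of load_config)."""
    doc = {
        "population": dataclasses.asdict(spec.population),
        "outcome": dataclasses.asdict(spec.outcome),
        "allocation": dataclasses.asdict(spec.allocation),
        "scenario": {k: getattr(spec, k) for k in _SCENARIO_SCALARS
                     if not isinstance(getattr(spec, k), (bytes,))},
    }
    doc["scenario"]["seed"] = (
        spec.seed if isinstance(spec.seed, int) else None
    )
    for section in doc.values():
        for k, v in list(section.items()):
            if isinstance(v, tuple):
                section[k] = list(v)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
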