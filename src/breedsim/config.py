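"""TOML scenario configuration: [genome], [founder], [traits], [plan] with
per-generation [[plan.stages]] blocks.  Shipped plans live in
``breedsim/configs`` and are loaded by name through :func:`load_builtin`.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .errors import ConfigError
from .genome import FounderConfig
from .reproduction import PropagationRule
from .scheduler import (BreedingPlan, CrossingSpec, GenomeConfig,
                        ParentSourceSpec, PhenotypingSpec, Scenario, StageSpec,
                        TraitNoise, TraitsConfig)
from .selection import SelectionRule


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from a TOML file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        return scenario_from_dict(data)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid scenario configuration: {exc}") from exc


def builtin_names() -> list[str]:
    root = resources.files("breedsim") / "configs"
    return sorted(p.name.removesuffix(".toml") for p in root.iterdir()
                  if p.name.endswith(".toml"))


def load_builtin(name: str) -> Scenario:
    """Load one of the shipped plan configurations by name (see
    :func:`builtin_names`)."""
    res = resources.files("breedsim") / "configs" / f"{name}.toml"
    if not res.is_file():
        raise ConfigError(f"no builtin scenario {name!r}; available: {builtin_names()}")
    data = tomllib.loads(res.read_text())
    return scenario_from_dict(data)


def scenario_from_dict(data: dict) -> Scenario:
    genome = GenomeConfig(**data["genome"])
    founder = FounderConfig(**data.get("founder", {}))

    tr = dict(data["traits"])
    noise = {name: TraitNoise(**spec) for name, spec in tr.pop("noise").items()}
    traits = TraitsConfig(noise=noise, **tr)
    missing = set(traits.names) - set(noise)
    if missing:
        raise ConfigError(f"traits without a noise block: {sorted(missing)}")

    pl = dict(data["plan"])
    stages: dict[int, StageSpec] = {}
    for raw in pl.pop("stages", []):
        raw = dict(raw)
        gen = raw.pop("generation")
        phen = [PhenotypingSpec(**p) for p in raw.pop("phenotyping", [])]
        sel = raw.pop("selection", None)
        prop = raw.pop("propagation", None)
        stages[gen] = StageSpec(
            generation=gen,
            phenotyping=phen,
            selection=SelectionRule(**sel) if sel else None,
            propagation=PropagationRule(**prop) if prop else None,
            **raw,
        )
    crossing = CrossingSpec(**pl.pop("crossing"))
    parent_source = ParentSourceSpec(**pl.pop("parent_source"))
    calendar_list = pl.pop("calendar")
    calendar = {g + 1: off for g, off in enumerate(calendar_list)}
    plan = BreedingPlan(name=data.get("name", "scenario"), stages=stages,
                        crossing=crossing, parent_source=parent_source,
                        calendar=calendar, **pl)
    return Scenario(name=data.get("name", "scenario"), genome=genome,
                    founder=founder, traits=traits, plan=plan,
                    n_replicates=data.get("n_replicates", 1))
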