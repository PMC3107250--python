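"""Run configuration: structured YAML with Table-like defaults.

A run configuration has blocks ``geometry``, ``material``,
``potentials``, ``integrator``, ``cargo``, ``run`` and ``output``.  An
empty file resolves to the model defaults (the published parameter set);
unknown keys are rejected by name so typos cannot silently fall back to
defaults.  All physical quantities are in the package's standard units:
nm, kT, cP, kPa, reduced time (0.1 ns), ms for caps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .forcefield import HydrophobicRule, InteractionRuleSet, RepulsiveRule
from .geometry import GeometryConfig, ScaffoldMaterial
from .integrator import IntegratorConfig


class ConfigError(ValueError):
    pass


@dataclass
class CargoConfig:
    diameter: float = 15.0  # nm
    n_spots: int = 8
    standoff: float | None = None  # nm; default one cargo diameter
    arc_center_deg: float = 0.0


@dataclass
class RunBlock:
    n_runs: int = 1
    equilibration_steps: int = 0
    max_time_ms: float | None = None
    seed: int = 0
    l_p: float = 0.43  # nm, FG persistence length
    graft_seed: int = 0


@dataclass
class OutputBlock:
    directory: str = "npcbd_out"
    write_xyz: bool = True
    write_tracks: bool = True


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: ScaffoldMaterial = field(default_factory=ScaffoldMaterial)
    potentials: InteractionRuleSet = field(default_factory=InteractionRuleSet)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    cargo: CargoConfig = field(default_factory=CargoConfig)
    run: RunBlock = field(default_factory=RunBlock)
    output: OutputBlock = field(default_factory=OutputBlock)


def _from_dict(cls, data, path):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {', '.join(unknown)}")
    kwargs = {}
    for name in data:
        val = data[name]
        sub = _NESTED.get((cls, name))
        if sub is not None:
            kwargs[name] = _from_dict(sub, val, f"{path}.{name}")
        else:
            if name == "fg_region_split" and isinstance(val, (list, tuple)):
                val = tuple(val)
            kwargs[name] = val
    return cls(**kwargs)


_NESTED = {
    (RunConfig, "geometry"): GeometryConfig,
    (RunConfig, "material"): ScaffoldMaterial,
    (RunConfig, "potentials"): InteractionRuleSet,
    (RunConfig, "integrator"): IntegratorConfig,
    (RunConfig, "cargo"): CargoConfig,
    (RunConfig, "run"): RunBlock,
    (RunConfig, "output"): OutputBlock,
    (InteractionRuleSet, "fg_fg"): HydrophobicRule,
    (InteractionRuleSet, "kap_fg"): HydrophobicRule,
    (InteractionRuleSet, "repulsion"): RepulsiveRule,
}


def load_config(path) -> RunConfig:
    """Parse, validate and default a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    cfg = _from_dict(RunConfig, data, "config")
    cfg.geometry.validate()
    return cfg


def resolve(data: dict | None) -> RunConfig:
    """Build a RunConfig from an in-memory mapping (None -> defaults)."""
    cfg = _from_dict(RunConfig, data, "config")
    cfg.geometry.validate()
    return cfg


def to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["geometry"]["fg_region_split"] = list(d["geometry"]["fg_region_split"])
    return d


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration (for provenance)."""
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))
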