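"""Strict YAML/JSON run configuration.

One ``physical:`` block carries every fluid/geometry default so the
viscosity choice (water at 25 C) is visible and overridable in one place.
Unknown keys anywhere in the file are a hard error — configs never fail
silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .mesh import DEFAULT_FIRST_WALL_SPACING
from .physical import (Channel, Fluid, FlowConditions, ROOM_TEMPERATURE,
                       WATER_VISCOSITY_25C)

_PHYSICAL_KEYS = {
    "density_kg_m3": 5240.0,
    "viscosity_pa_s": WATER_VISCOSITY_25C,
    "temperature_k": ROOM_TEMPERATURE,
    "diameter_m": 4.0e-3,
    "length_m": 47.0e-3,
    "mean_velocity_m_s": 0.0051,
    "particle_diameter_m": 144.0e-9,
    "inlet_mass_g": None,
}

_MESH_KEYS = {
    "n_axial": 129,
    "n_radial": 97,
    "n_circ": 37,
    "first_wall_spacing": DEFAULT_FIRST_WALL_SPACING,
}

_LAGRANGIAN_KEYS = {
    "n_particles": 10000,
    "time_step_s": None,
}

_TOP_LEVEL = {"physical", "mesh", "lagrangian"}


def _merge_block(name: str, defaults: dict, given: dict | None) -> dict:
    given = given or {}
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(given)
    return merged


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with every default resolved."""

    physical: dict = field(default_factory=lambda: dict(_PHYSICAL_KEYS))
    mesh: dict = field(default_factory=lambda: dict(_MESH_KEYS))
    lagrangian: dict = field(default_factory=lambda: dict(_LAGRANGIAN_KEYS))

    @classmethod
    def from_mapping(cls, raw: dict | None) -> "RunConfig":
        raw = raw or {}
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ConfigurationError(f"unknown top-level config key(s): {sorted(unknown)}")
        return cls(
            physical=_merge_block("physical", _PHYSICAL_KEYS, raw.get("physical")),
            mesh=_merge_block("mesh", _MESH_KEYS, raw.get("mesh")),
            lagrangian=_merge_block("lagrangian", _LAGRANGIAN_KEYS, raw.get("lagrangian")),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text))
        if raw is not None and not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
        return cls.from_mapping(raw)

    def flow_conditions(self) -> FlowConditions:
        p = self.physical
        return FlowConditions(
            fluid=Fluid(p["density_kg_m3"], p["viscosity_pa_s"], p["temperature_k"]),
            channel=Channel(p["diameter_m"], p["length_m"]),
            mean_inlet_velocity=p["mean_velocity_m_s"],
            inlet_mass_label=p["inlet_mass_g"],
        )

    def build_mesh(self):
        from .mesh import build_mesh
        m = self.mesh
        return build_mesh(m["n_axial"], m["n_radial"], m["n_circ"],
                          m["first_wall_spacing"],
                          channel=self.flow_conditions().channel)

    def snapshot(self) -> dict:
        return {"physical": dict(self.physical), "mesh": dict(self.mesh),
                "lagrangian": dict(self.lagrangian)}
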