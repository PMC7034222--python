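"""Fluids, particles, channel geometry and the dimensionless groups.

Everything downstream (mesh, Eulerian and Lagrangian transport, the CLI)
consumes the types defined here.  All quantities are SI internally; helper
constructors convert the bench units (mm, nm, g/mL) at the boundary.

The default working fluid pairs the nanofluid density printed for the flow
experiments (5.24 g/mL) with the dynamic viscosity of water at 25 °C
(8.9e-4 Pa·s); that combination reproduces the study's tube Reynolds
numbers of 120.1 and 127.1 at mean inlet velocities of 5.1 and 5.4 mm/s in
a 4 mm channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError, OutOfRegimeError

BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)

#: dynamic viscosity of water at 25 °C, Pa·s — the default carrier viscosity
WATER_VISCOSITY_25C = 8.9e-4
#: room temperature, K
ROOM_TEMPERATURE = 298.15
#: laminar-turbulent transition Reynolds number for pipe flow
LAMINAR_RE_LIMIT = 2100.0


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if not value > 0.0:
            raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class Fluid:
    """Carrier fluid state.

    Parameters
    ----------
    density : float
        Mass density, kg/m^3.
    dynamic_viscosity : float
        Dynamic (shear) viscosity, Pa·s.
    temperature : float
        Absolute temperature, K.
    """

    density: float
    dynamic_viscosity: float
    temperature: float = ROOM_TEMPERATURE

    def __post_init__(self) -> None:
        _require_positive(
            density=self.density,
            dynamic_viscosity=self.dynamic_viscosity,
            temperature=self.temperature,
        )

    @classmethod
    def nanofluid(cls, density_g_ml: float = 5.24,
                  viscosity_pa_s: float = WATER_VISCOSITY_25C,
                  temperature_k: float = ROOM_TEMPERATURE) -> "Fluid":
        """Nanofluid with density given in bench units of g/mL."""
        return cls(density_g_ml * 1000.0, viscosity_pa_s, temperature_k)


@dataclass(frozen=True)
class Channel:
    """Straight cylindrical flow channel (hydrogel-cast vessel mimic).

    ``internal_diameter`` and ``length`` are in metres; the study channel is
    4 mm by 47 mm.
    """

    internal_diameter: float
    length: float

    def __post_init__(self) -> None:
        _require_positive(internal_diameter=self.internal_diameter, length=self.length)
        if self.length < self.internal_diameter:
            raise InvalidInputError(
                "channel length must be at least its diameter "
                f"(L={self.length}, D={self.internal_diameter})")

    @property
    def radius(self) -> float:
        return 0.5 * self.internal_diameter

    @classmethod
    def from_mm(cls, diameter_mm: float = 4.0, length_mm: float = 47.0) -> "Channel":
        return cls(diameter_mm * 1e-3, length_mm * 1e-3)


@dataclass(frozen=True)
class NanoparticleFormulation:
    """A coated iron-oxide nanoparticle formulation.

    ``label`` carries the ligand ratio (e.g. "0.07 mmol PVP/0.005 mmol PEI"),
    ``hydrodynamic_diameter`` is the DLS size in metres, and
    ``zeta_potential`` (mV) is informational only.
    """

    label: str
    hydrodynamic_diameter: float
    polydispersity_index: float = 0.0
    zeta_potential: float | None = None

    def __post_init__(self) -> None:
        _require_positive(hydrodynamic_diameter=self.hydrodynamic_diameter)
        if not 0.0 <= self.polydispersity_index <= 1.0:
            raise InvalidInputError(
                f"polydispersity_index must lie in [0, 1], got {self.polydispersity_index}")

    @classmethod
    def from_nm(cls, label: str, diameter_nm: float, pdi: float = 0.0,
                zeta_mv: float | None = None) -> "NanoparticleFormulation":
        return cls(label, diameter_nm * 1e-9, pdi, zeta_mv)


#: the four formulations studied, by hydrodynamic size
STUDY_FORMULATIONS = (
    NanoparticleFormulation.from_nm("0.06 mmol PVP/0.007 mmol PEI", 69.0, 0.24),
    NanoparticleFormulation.from_nm("0.09 mmol PVP/0.0017 mmol PEI", 130.0, 0.22),
    NanoparticleFormulation.from_nm("0.05 mmol PVP/0.008 mmol PEI", 140.0, 0.12),
    NanoparticleFormulation.from_nm("0.07 mmol PVP/0.005 mmol PEI", 144.0, 0.17),
)


@dataclass(frozen=True)
class FlowConditions:
    """Fluid + channel + mean inlet velocity defining one simulated run.

    ``inlet_mass_label`` records the grams of Fe in the 1 mL injected dose;
    it is bookkeeping only — linear transport physics is independent of it.
    The laminar regime is asserted at construction (Re < 2100).
    """

    fluid: Fluid
    channel: Channel
    mean_inlet_velocity: float
    inlet_mass_label: float | None = None

    def __post_init__(self) -> None:
        _require_positive(mean_inlet_velocity=self.mean_inlet_velocity)
        re = reynolds_number(self)
        if re >= LAMINAR_RE_LIMIT:
            raise OutOfRegimeError(
                f"Re={re:.1f} is not laminar (limit {LAMINAR_RE_LIMIT:.0f})")


def stokes_einstein_diffusivity(diameter: float, fluid: Fluid) -> float:
    """Brownian diffusivity of a sphere, D_B = k_B T / (3 pi mu d).

    Parameters
    ----------
    diameter : float
        Hydrodynamic diameter, m.
    fluid : Fluid
        Carrier fluid supplying temperature and viscosity.

    Returns
    -------
    float
        Diffusivity in m^2/s; strictly decreasing in both diameter and
        viscosity.
    """
    _require_positive(diameter=diameter)
    import math
    return BOLTZMANN * fluid.temperature / (3.0 * math.pi * fluid.dynamic_viscosity * diameter)


def reynolds_number(fc: FlowConditions) -> float:
    """Tube Reynolds number rho * v_mean * D / mu (diameter-based)."""
    f = fc.fluid
    return f.density * fc.mean_inlet_velocity * fc.channel.internal_diameter / f.dynamic_viscosity


def peclet_number(fc: FlowConditions, diffusivity: float) -> float:
    """Diameter-based Peclet number v_mean * D / D_B.

    The study sits near Pe ~ 6e6: advection dominates everywhere except a
    thin diffusive wall layer, which is why deposition is boundary-layer
    limited.
    """
    _require_positive(diffusivity=diffusivity)
    return fc.mean_inlet_velocity * fc.channel.internal_diameter / diffusivity


def entrance_length(fc: FlowConditions) -> float:
    """Laminar hydrodynamic entrance length L_e = 0.05 Re D.

    Raises :class:`OutOfRegimeError` for turbulent Re.  For the study
    conditions L_e ~ 24-25 mm, more than half the 47 mm channel, which is
    why entry-flow development matters for this geometry.
    """
    re = reynolds_number(fc)
    if re >= LAMINAR_RE_LIMIT:
        raise OutOfRegimeError(f"entrance-length correlation is laminar-only (Re={re:.1f})")
    return 0.05 * re * fc.channel.internal_diameter


def study_flow_conditions(mean_velocity: float = 0.0051,
                          inlet_mass_g: float | None = None,
                          fluid: Fluid | None = None,
                          channel: Channel | None = None) -> FlowConditions:
    """Convenience constructor for the study's standard run conditions."""
    return FlowConditions(
        fluid=fluid or Fluid.nanofluid(),
        channel=channel or Channel.from_mm(),
        mean_inlet_velocity=mean_velocity,
        inlet_mass_label=inlet_mass_g,
    )
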