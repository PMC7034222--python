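"""Steady advection-diffusion of nanoparticle concentration with an absorbing wall.

This is the Graetz problem for a dilute scalar in laminar tube flow:

    u(r, z) dc/dz = D_B (1/r) d/dr (r dc/dr),   c(r, 0) = 1,
    c(R, z) = 0 (deposit on contact),           dc/dr|_{r=0} = 0.

Mass loss over the channel is 1 - (outlet advective flux)/(inlet advective
flux).  Because the problem is linear in c, the *fractional* loss is
independent of the inlet mass — a property the solver asserts and that the
package deliberately reports alongside any experimentally observed
concentration dependence.

Two independent closed forms serve as oracles:

* ``slug_flow_mass_remaining`` — the Bessel eigenseries for a uniform (slug)
  velocity profile;
* ``leveque_mass_loss`` — the Gormley-Kennedy high-Peclet penetration
  asymptote for parabolic flow, valid for small deposition parameter
  h = D_B L / Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jn_zeros

from .errors import InvalidInputError, NumericalFailureError, OutOfRegimeError
from .flow import VelocityField, _radial_operator, _solve_tridiag
from .mesh import StructuredMesh
from .physical import FlowConditions


@dataclass(frozen=True)
class ConcentrationField:
    """Normalized concentration c(r, z) on the solver node set (inlet = 1)."""

    r_nodes: np.ndarray = field(repr=False)
    z_stations: np.ndarray = field(repr=False)
    c: np.ndarray = field(repr=False)  # shape (n_z, n_r)


@dataclass(frozen=True)
class TransportResult:
    """Outcome of one transport computation.

    ``mass_loss_fraction`` is dimensionless in [0, 1];
    ``outlet_flux_profile`` is the per-radius advective flux density
    u*c*r at the outlet normalized to unit inlet flux;  ``method`` tags the
    route (eulerian / lagrangian / leveque); ``diagnostics`` carries solver
    bookkeeping such as the mass-conservation defect.
    """

    mass_loss_fraction: float
    method: str
    outlet_flux_profile: np.ndarray | None = field(default=None, repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)


def slug_flow_mass_remaining(tau: float, n_terms: int = 2000) -> float:
    """Flux fraction surviving a slug-flow tube with absorbing wall.

    ``tau = D_B z / (R^2 v_mean)`` is the dimensionless residence/diffusion
    group.  The eigenseries is  sum 4/beta_n^2 exp(-beta_n^2 tau)  with
    beta_n the zeros of J0 (beta_1 = 2.4048...).
    """
    if tau < 0.0:
        raise InvalidInputError(f"tau must be >= 0, got {tau}")
    if tau == 0.0:
        return 1.0
    beta = jn_zeros(0, n_terms)
    return float(np.sum(4.0 / beta**2 * np.exp(-(beta**2) * tau)))


def leveque_mass_loss(fc: FlowConditions, diffusivity: float,
                      validity_limit: float = 0.02) -> TransportResult:
    """Gormley-Kennedy diffusional-deposition asymptote for laminar tube flow.

    With deposition parameter ``h = D_B L / Q`` (Q the volumetric flow
    rate), the deposited fraction is ``5.50 h^(2/3) - 3.77 h``, valid for
    small h where the concentration boundary layer is thin (the Leveque
    regime).  Outside validity the caller is directed to
    :func:`solve_graetz`.
    """
    if diffusivity < 0.0:
        raise InvalidInputError("diffusivity must be >= 0")
    Q = fc.mean_inlet_velocity * np.pi * fc.channel.radius**2
    h = diffusivity * fc.channel.length / Q
    if h >= validity_limit:
        raise OutOfRegimeError(
            f"deposition parameter h={h:.3g} outside the asymptote's validity "
            f"(h < {validity_limit}); use solve_graetz instead")
    loss = 5.50 * h ** (2.0 / 3.0) - 3.77 * h
    return TransportResult(mass_loss_fraction=float(max(loss, 0.0)),
                           method="leveque",
                           diagnostics={"deposition_parameter": h})


def solve_graetz(fc: FlowConditions, diffusivity: float, velocity_field: VelocityField,
                 mesh: StructuredMesh, dz_max_fraction: float = 1.0 / 500.0,
                 growth: float = 1.02) -> tuple[ConcentrationField, TransportResult]:
    """March the absorbing-wall advection-diffusion problem down the channel.

    Crank-Nicolson in z (with a few backward-Euler startup steps to damp the
    inlet corner discontinuity), an implicit nonuniform-grid radial
    operator, Dirichlet c = 0 at the wall and symmetry at the axis.  The
    axial step starts at the diffusion scale of the wall-adjacent cell and
    grows geometrically to at most ``dz_max_fraction * L``.

    Returns the concentration field sampled at the mesh's axial faces and a
    :class:`TransportResult` whose diagnostics include the relative
    mass-conservation defect (inlet flux - outlet flux - wall deposition).
    """
    if diffusivity <= 0.0:
        raise InvalidInputError("diffusivity must be > 0 for the Eulerian solve")
    r = mesh.radial_nodes_with_boundaries()
    if not np.allclose(r, velocity_field.r_nodes):
        raise InvalidInputError("velocity field and mesh use different radial nodes")
    m = len(r)
    L = fc.channel.length
    lo, di, up = _radial_operator(r)

    def flux(u_prof, c_prof):
        return float(2.0 * np.pi * np.trapezoid(u_prof * c_prof * r, r))

    # axial step control: resolve diffusion across the wall-adjacent cell
    h_wall = r[-1] - r[-2]
    u_inlet = velocity_field.profile_at(0.0)
    u_near_wall = max(float(u_inlet[-2]), 1e-6 * fc.mean_inlet_velocity)
    dz0 = 0.2 * u_near_wall * h_wall**2 / diffusivity
    dz_max = dz_max_fraction * L
    if dz0 <= 0.0 or not np.isfinite(dz0):
        raise NumericalFailureError("axial step control failed (degenerate wall cell)")
    dz0 = min(dz0, dz_max)
    if dz0 < 1e-12 * L:
        raise NumericalFailureError(
            f"Peclet so high the axial step underflows (dz0/L={dz0 / L:.2e}); "
            "coarsen the wall spacing or relax dz_max_fraction")

    c = np.ones(m)
    c[-1] = 0.0
    z = 0.0
    inlet_flux = flux(u_inlet, np.ones(m))
    deposited = 0.0
    z_out = mesh.node_axial
    profiles = np.empty((len(z_out), m))
    profiles[0] = c
    next_out = 1
    dz = dz0
    n_steps = 0
    be_startup = 10  # backward-Euler steps before switching to Crank-Nicolson

    while z < L - 1e-15:
        dz = min(dz, L - z, dz_max)
        u_prof = velocity_field.profile_at(z + 0.5 * dz)
        a = np.maximum(u_prof, 1e-9 * fc.mean_inlet_velocity) / dz
        theta = 1.0 if n_steps < be_startup else 0.5
        A_lo = -theta * diffusivity * lo
        A_up = -theta * diffusivity * up
        A_di = a - theta * diffusivity * di
        # explicit part of the radial operator acting on the old profile
        expl = np.zeros(m)
        if theta < 1.0:
            expl[0] = di[0] * c[0] + up[0] * c[1]
            expl[1:-1] = lo[1:-1] * c[:-2] + di[1:-1] * c[1:-1] + up[1:-1] * c[2:]
            expl *= (1.0 - theta) * diffusivity
        rhs = a * c + expl
        A_lo[-1], A_di[-1], A_up[-1] = 0.0, 1.0, 0.0
        rhs[-1] = 0.0
        c_new = _solve_tridiag(A_lo, A_di, A_up, rhs)
        if not np.all(np.isfinite(c_new)):
            raise NumericalFailureError(f"Graetz march diverged at z={z:.4g} m")
        c_new = np.clip(c_new, 0.0, 1.0)
        # wall deposition flux over this step: D * dc/dr at the wall, one-sided
        grad_mid = 0.5 * ((c[-2] - c[-1]) + (c_new[-2] - c_new[-1])) / h_wall
        deposited += 2.0 * np.pi * r[-1] * diffusivity * grad_mid * dz
        z += dz
        c = c_new
        n_steps += 1
        while next_out < len(z_out) and z >= z_out[next_out] - 1e-15:
            profiles[next_out] = c
            next_out += 1
        dz *= growth

    while next_out < len(z_out):  # guard against float accumulation at z = L
        profiles[next_out] = c
        next_out += 1

    u_out = velocity_field.profile_at(L)
    outlet_flux = flux(u_out, c)
    loss = 1.0 - outlet_flux / inlet_flux
    defect = abs(inlet_flux - outlet_flux - deposited) / inlet_flux
    result = TransportResult(
        mass_loss_fraction=float(np.clip(loss, 0.0, 1.0)),
        method="eulerian",
        outlet_flux_profile=u_out * c * r / inlet_flux,
        diagnostics={
            "conservation_defect": float(defect),
            "n_axial_steps": n_steps,
            "deposited_fraction": float(deposited / inlet_flux),
            "dz0": float(dz0),
        },
    )
    return ConcentrationField(r, z_out, profiles), result
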