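"""Axisymmetric laminar velocity fields: Poiseuille and developing entry flow.

The fully developed profile is the closed-form parabola
``u(r) = 2 v_mean (1 - (r/R)^2)``.  The developing field solves the
parabolized axial-momentum equation

    u du/dz = -(1/rho) dp/dz + nu (1/r) d/dr(r du/dr)

by implicit axial marching, with the (z-dependent) pressure gradient closed
at every station by enforcing the volumetric flux Q = v_mean * pi R^2
exactly.  Radial velocity is neglected in the momentum balance; the scheme
relaxes a uniform inlet profile to the Poiseuille parabola over roughly the
laminar entrance length 0.05 Re D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import InvalidInputError, NumericalFailureError
from .mesh import StructuredMesh
from .physical import FlowConditions, entrance_length


def poiseuille_velocity(r, fc: FlowConditions):
    """Fully developed axial velocity 2 v_mean (1 - (r/R)^2).

    Accepts scalar or array ``r`` in metres; raises
    :class:`InvalidInputError` outside [0, R].
    """
    r = np.asarray(r, dtype=float)
    R = fc.channel.radius
    if np.any(r < 0.0) or np.any(r > R * (1.0 + 1e-12)):
        raise InvalidInputError(f"radius outside [0, R={R}]")
    u = 2.0 * fc.mean_inlet_velocity * (1.0 - np.clip(r / R, 0.0, 1.0) ** 2)
    return float(u) if u.ndim == 0 else u


@dataclass(frozen=True)
class VelocityField:
    """Axisymmetric axial-velocity field sampled on radial nodes x axial stations.

    ``r_nodes`` runs from the axis (0) to the wall (R) and includes both;
    ``z_stations`` spans [0, L].  ``u`` has shape
    ``(len(z_stations), len(r_nodes))`` with u = 0 on the wall column
    (no-slip).  ``development_model`` tags whether the field is the
    closed-form fully developed profile or the marched entry flow.
    """

    r_nodes: np.ndarray = field(repr=False)
    z_stations: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    mean_velocity: float
    development_model: str  # {"fully_developed", "developing", "uniform"}

    @property
    def radius(self) -> float:
        return float(self.r_nodes[-1])

    def axial_velocity(self, r, z):
        """Bilinear sample of u at (r, z); vectorized over arrays."""
        scalar = np.ndim(r) == 0 and np.ndim(z) == 0
        r = np.atleast_1d(np.asarray(r, dtype=float))
        z = np.broadcast_to(np.asarray(z, dtype=float), r.shape)
        if len(self.z_stations) == 1 or self.development_model in ("fully_developed", "uniform"):
            out = np.interp(r, self.r_nodes, self.u[-1])
        else:
            zc = np.clip(z, self.z_stations[0], self.z_stations[-1])
            k = np.clip(np.searchsorted(self.z_stations, zc, side="right") - 1,
                        0, len(self.z_stations) - 2)
            z0, z1 = self.z_stations[k], self.z_stations[k + 1]
            w = np.where(z1 > z0, (zc - z0) / np.where(z1 > z0, z1 - z0, 1.0), 0.0)
            # interpolate radially on the two bracketing stations
            j = np.clip(np.searchsorted(self.r_nodes, r, side="right") - 1,
                        0, len(self.r_nodes) - 2)
            r0, r1 = self.r_nodes[j], self.r_nodes[j + 1]
            t = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
            u_lo = self.u[k, j] * (1 - t) + self.u[k, j + 1] * t
            u_hi = self.u[k + 1, j] * (1 - t) + self.u[k + 1, j + 1] * t
            out = u_lo * (1 - w) + u_hi * w
        return float(out[0]) if scalar else out

    def profile_at(self, z: float) -> np.ndarray:
        """Radial profile u(r_nodes) at axial position z (linear in z)."""
        return np.asarray(self.axial_velocity(self.r_nodes, np.full_like(self.r_nodes, z)))

    def flux_at(self, z: float) -> float:
        """Volumetric flux 2 pi int u r dr at station z (trapezoid)."""
        prof = self.profile_at(z)
        return float(2.0 * np.pi * np.trapezoid(prof * self.r_nodes, self.r_nodes))

    @property
    def target_flux(self) -> float:
        return float(self.mean_velocity * np.pi * self.radius**2)

    @classmethod
    def fully_developed(cls, fc: FlowConditions, mesh: StructuredMesh) -> "VelocityField":
        r = mesh.radial_nodes_with_boundaries()
        z = mesh.node_axial
        u = np.tile(poiseuille_velocity(r, fc), (len(z), 1))
        return cls(r, z, u, fc.mean_inlet_velocity, "fully_developed")

    @classmethod
    def uniform(cls, fc: FlowConditions, mesh: StructuredMesh) -> "VelocityField":
        """Slug (plug) flow at the mean velocity — used by the Graetz oracle."""
        r = mesh.radial_nodes_with_boundaries()
        z = mesh.node_axial
        u = np.full((len(z), len(r)), fc.mean_inlet_velocity)
        return cls(r, z, u, fc.mean_inlet_velocity, "uniform")


def _radial_operator(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three-point stencil for (1/r) d/dr(r d/dr) on a nonuniform node set.

    Returns (lower, diag, upper) for interior nodes 1..m-2 plus the axis row
    (index 0, symmetry: operator -> 4 (u1-u0)/h^2).  The wall row is Dirichlet
    and handled by the caller.
    """
    m = len(r)
    lo = np.zeros(m)
    di = np.zeros(m)
    up = np.zeros(m)
    h0 = r[1] - r[0]
    di[0] = -4.0 / h0**2
    up[0] = 4.0 / h0**2
    hm = r[1:-1] - r[:-2]
    hp = r[2:] - r[1:-1]
    # u'' (exact for quadratics) + u'/r (central)
    lo[1:-1] = 2.0 / (hm * (hm + hp)) - 1.0 / (r[1:-1] * (hm + hp))
    up[1:-1] = 2.0 / (hp * (hm + hp)) + 1.0 / (r[1:-1] * (hm + hp))
    di[1:-1] = -2.0 / (hm * hp)
    return lo, di, up


def _solve_tridiag(lo, di, up, rhs):
    ab = np.zeros((3, len(di)))
    ab[0, 1:] = up[:-1]
    ab[1] = di
    ab[2, :-1] = lo[1:]
    return scipy.linalg.solve_banded((1, 1), ab, rhs)


def developing_flow_field(fc: FlowConditions, mesh: StructuredMesh,
                          n_substeps_min: int = 4) -> VelocityField:
    """March the entry flow from a uniform inlet to the developed parabola.

    At each axial substep the radial diffusion term is treated implicitly,
    axial convection is linearised about the upstream profile, and the
    unknown pressure gradient is eliminated by requiring the discrete flux
    to equal Q exactly (superposition of two tridiagonal solves).  Profiles
    are recorded at the mesh's axial faces.

    Raises
    ------
    NumericalFailureError
        If the marched profile fails to stay positive/bounded (with the
        offending station in the message).
    """
    r = mesh.radial_nodes_with_boundaries()
    m = len(r)
    nu = fc.fluid.dynamic_viscosity / fc.fluid.density
    vbar = fc.mean_inlet_velocity
    Q = vbar * np.pi * fc.channel.radius**2
    lo, di, up = _radial_operator(r)

    def flux(u):
        return float(np.trapezoid(u * r, r) * 2.0 * np.pi)

    z_out = mesh.node_axial
    u = np.full(m, vbar)
    u[-1] = 0.0  # no-slip from the first marched station
    profiles = [np.full(m, vbar)]  # inlet station: uniform (boundary condition)
    # near-wall momentum diffuses fast: resolve the first stations finely
    Le = max(entrance_length(fc), 1e-6)
    for k in range(mesh.n_axial):
        z0, z1 = z_out[k], z_out[k + 1]
        # finer substepping while still inside the entrance region
        n_sub = n_substeps_min
        if z0 < 1.5 * Le:
            n_sub = max(n_substeps_min, int(np.ceil(40 * (z1 - z0) / Le)))
        dz = (z1 - z0) / n_sub
        for _ in range(n_sub):
            a = np.maximum(u, 1e-3 * vbar) / dz  # convective coefficient
            A_lo, A_up = -nu * lo, -nu * up
            A_di = a - nu * di
            rhs0 = a * u
            # Dirichlet wall row
            A_lo[-1], A_di[-1], A_up[-1] = 0.0, 1.0, 0.0
            rhs0[-1] = 0.0
            e = np.ones(m)
            e[-1] = 0.0
            x0 = _solve_tridiag(A_lo, A_di, A_up, rhs0)
            x1 = _solve_tridiag(A_lo, A_di, A_up, e)
            g = (flux(x0) - Q) / flux(x1)  # pressure-gradient / rho
            u = x0 - g * x1
            if not np.all(np.isfinite(u)) or u.max() > 4.0 * vbar:
                raise NumericalFailureError(
                    f"entry-flow march diverged near z={z0:.4g} m "
                    f"(max u = {np.nanmax(u):.3g}, v_mean = {vbar:.3g})")
        profiles.append(u.copy())

    return VelocityField(r, z_out, np.array(profiles), vbar, "developing")


def grid_independence_sweep(fc: FlowConditions, mesh_specs, quantity,
                            threshold: float = 0.005):
    """Run a refinement study of a scalar diagnostic over a mesh ladder.

    Parameters
    ----------
    fc : FlowConditions
    mesh_specs : sequence of StructuredMesh or (n_axial, n_radial, n_circ[, fws]) tuples
        Ordered coarse -> fine.
    quantity : callable(fc, mesh) -> float
        The monitored scalar (e.g. centreline velocity, mass-loss fraction).
    threshold : float
        Relative-change level below which the sweep is flagged converged
        (default 0.5%).

    Returns
    -------
    pandas.DataFrame
        One row per mesh: cells, value, relative change vs the previous
        mesh, and a ``converged`` flag.  Extractor failures are aggregated
        into a single error naming every failing mesh.
    """
    import pandas as pd

    from .mesh import build_mesh

    if len(mesh_specs) < 2:
        raise InvalidInputError("grid sweep needs at least two meshes")
    meshes = []
    for spec in mesh_specs:
        if isinstance(spec, StructuredMesh):
            meshes.append(spec)
        else:
            meshes.append(build_mesh(*spec, channel=fc.channel))

    rows, failures = [], []
    for mesh in meshes:
        label = f"{mesh.n_axial}x{mesh.n_radial}x{mesh.n_circumferential}"
        try:
            rows.append((label, mesh.n_cells, float(quantity(fc, mesh))))
        except Exception as exc:  # aggregate, report all failing meshes at once
            failures.append(f"{label}: {exc}")
    if failures:
        raise NumericalFailureError(
            "quantity extractor failed on: " + "; ".join(failures))

    df = pd.DataFrame(rows, columns=["mesh", "cells", "value"])
    prev = df["value"].shift(1)
    scale = prev.abs().where(prev.abs() > 0.0, 1.0)
    df["rel_change"] = (df["value"] - prev).abs() / scale
    df["converged"] = df["rel_change"] < threshold
    return df
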