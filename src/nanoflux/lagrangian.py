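"""Brownian-dynamics particle tracking with deposit-on-wall-contact.

Particles are advected by the axial velocity field and perturbed by
isotropic Gaussian Brownian displacements (Euler-Maruyama): per step of
length dt,

    x += sigma xi_x,  y += sigma xi_y,  z += u(r, z) dt + sigma xi_z,

with sigma = sqrt(2 D_B dt).  Tracking the transverse position in
Cartesian (x, y) avoids the spurious drift of naive cylindrical-coordinate
updates and makes the symmetry axis trivially reflecting.  A particle whose
radius reaches the absorbing radius is deposited (no reflection — contact
is irreversible); one whose z passes the channel length exits.  The
Monte-Carlo mass-loss estimate deposited/n carries a binomial standard
error and cross-validates the Eulerian solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .eulerian import TransportResult
from .flow import VelocityField
from .physical import FlowConditions

IN_TRANSIT, DEPOSITED, EXITED = 0, 1, 2


@dataclass(frozen=True, eq=False)
class Pathline:
    """Ordered (r, theta, z, t) samples for one tracked particle."""

    r: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    t: np.ndarray
    terminal_status: int

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ParticleEnsemble:
    """Final state of a tracked particle population.

    ``status`` maps each particle to {IN_TRANSIT, DEPOSITED, EXITED};
    the three counts partition ``n_particles``.  ``positions`` holds the
    final (r, theta, z) of every particle.  ``pathlines`` is populated only
    when trajectory recording was requested.
    """

    n_particles: int
    positions: np.ndarray  # (n, 3): r, theta, z
    status: np.ndarray
    rng_seed: int
    time_step: float
    velocity_field: VelocityField = field(repr=False)
    pathlines: list[Pathline] | None = None

    @property
    def n_deposited(self) -> int:
        return int(np.count_nonzero(self.status == DEPOSITED))

    @property
    def n_exited(self) -> int:
        return int(np.count_nonzero(self.status == EXITED))

    @property
    def n_in_transit(self) -> int:
        return int(np.count_nonzero(self.status == IN_TRANSIT))


def sample_inlet_radii(rng: np.random.Generator, n: int,
                       field: VelocityField) -> np.ndarray:
    """Flux-weighted inlet radii: p(r) proportional to u(r, 0) * r.

    Matches the uniform-concentration inlet of the Eulerian stage — a
    uniform concentration advected through the inlet plane arrives
    flux-weighted.  Sampled by numeric inverse-CDF on the field's inlet
    profile.
    """
    r_nodes = field.r_nodes
    u0 = field.profile_at(0.0)
    w = u0 * r_nodes
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(r_nodes))))
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, r_nodes)


def simulate_particles(fc: FlowConditions, diffusivity: float,
                       velocity_field: VelocityField, n_particles: int,
                       time_step: float | None = None, rng_seed: int = 0,
                       record_pathlines: int = 0, record_stride: int = 1,
                       max_steps: int | None = None,
                       absorbing_radius: float | None = None,
                       ) -> tuple[ParticleEnsemble, TransportResult]:
    """Track a Brownian particle ensemble and estimate the deposited fraction.

    Parameters
    ----------
    diffusivity : float
        Brownian diffusivity D_B, m^2/s (0 allowed: deterministic streamlines).
    time_step : float, optional
        Euler-Maruyama step, s.  Defaults to the value at which the RMS
        Brownian step is half the wall-adjacent cell height; an explicit
        value violating sqrt(2 D dt) < wall cell height is rejected.
    record_pathlines : int
        Number of leading particles whose trajectories are recorded.
    absorbing_radius : float, optional
        Deposit when r >= this radius (default: the wall radius R; pass
        R - d_H/2 to account for finite particle size).

    Returns
    -------
    (ParticleEnsemble, TransportResult)
        The transport result's mass_loss_fraction is deposited/n with a
        binomial standard error in its diagnostics; particles still in
        transit at ``max_steps`` are counted separately, never as deposited.
    """
    if n_particles < 1:
        raise InvalidInputError("n_particles must be >= 1")
    if diffusivity < 0.0:
        raise InvalidInputError("diffusivity must be >= 0")
    R = fc.channel.radius
    L = fc.channel.length
    r_abs = R if absorbing_radius is None else float(absorbing_radius)
    h_wall = float(velocity_field.r_nodes[-1] - velocity_field.r_nodes[-2])

    if time_step is None:
        if diffusivity > 0.0:
            time_step = (0.5 * h_wall) ** 2 / (2.0 * diffusivity)
        else:
            time_step = 0.05 * L / fc.mean_inlet_velocity
    elif diffusivity > 0.0 and np.sqrt(2.0 * diffusivity * time_step) >= h_wall:
        raise ConfigurationError(
            f"time_step {time_step:.3g} s gives an RMS Brownian step "
            f">= the wall cell height {h_wall:.3g} m; reduce it")
    if max_steps is None:
        max_steps = int(50 * L / (fc.mean_inlet_velocity * time_step)) + 1000

    rng = np.random.default_rng(rng_seed)
    r0 = sample_inlet_radii(rng, n_particles, velocity_field)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, n_particles)
    x = r0 * np.cos(theta0)
    y = r0 * np.sin(theta0)
    z = np.zeros(n_particles)
    status = np.full(n_particles, IN_TRANSIT, dtype=np.int8)
    sigma = np.sqrt(2.0 * diffusivity * time_step)

    n_rec = min(record_pathlines, n_particles)
    rec: list[list[tuple[float, float, float, float]]] = [[] for _ in range(n_rec)]
    rec_active = np.ones(n_rec, dtype=bool)
    for i in range(n_rec):
        rec[i].append((r0[i], theta0[i], 0.0, 0.0))

    active = np.arange(n_particles)
    t = 0.0
    for step in range(1, max_steps + 1):
        if active.size == 0:
            break
        r = np.hypot(x[active], y[active])
        u = np.asarray(velocity_field.axial_velocity(np.minimum(r, R), z[active]))
        dz = u * time_step
        if sigma > 0.0:
            x[active] += sigma * rng.standard_normal(active.size)
            y[active] += sigma * rng.standard_normal(active.size)
            dz = dz + sigma * rng.standard_normal(active.size)
        z[active] += dz
        t += time_step

        r_new = np.hypot(x[active], y[active])
        hit_wall = r_new >= r_abs
        out_end = (z[active] >= L) & ~hit_wall
        status[active[hit_wall]] = DEPOSITED
        status[active[out_end]] = EXITED
        for i in np.flatnonzero(rec_active):
            finished_i = status[i] != IN_TRANSIT
            if step % record_stride == 0 or finished_i:
                rec[i].append((float(np.hypot(x[i], y[i])),
                               float(np.arctan2(y[i], x[i])), float(z[i]), t))
            if finished_i:
                rec_active[i] = False
        active = active[~(hit_wall | out_end)]

    n_dep = int(np.count_nonzero(status == DEPOSITED))
    n_stuck = int(np.count_nonzero(status == IN_TRANSIT))
    p = n_dep / n_particles
    se = np.sqrt(max(p * (1.0 - p), 1.0 / n_particles) / n_particles)

    pathlines = None
    if record_pathlines:
        pathlines = []
        for i in range(n_rec):
            arr = np.array(rec[i])
            pathlines.append(Pathline(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                                      int(status[i])))

    r_fin = np.hypot(x, y)
    ensemble = ParticleEnsemble(
        n_particles=n_particles,
        positions=np.column_stack([r_fin, np.arctan2(y, x), z]),
        status=status, rng_seed=int(rng_seed), time_step=float(time_step),
        velocity_field=velocity_field, pathlines=pathlines,
    )
    result = TransportResult(
        mass_loss_fraction=p, method="lagrangian",
        diagnostics={
            "n_particles": n_particles, "n_deposited": n_dep,
            "n_exited": ensemble.n_exited, "n_stuck": n_stuck,
            "binomial_se": float(se), "time_step": float(time_step),
            "rng_seed": int(rng_seed),
        },
    )
    return ensemble, result


def export_pathlines(ensemble: ParticleEnsemble, path, sample: int | None = None) -> int:
    """Write recorded pathlines as legacy-VTK polylines with |velocity| point data.

    ``sample`` limits the number of exported pathlines (0 writes a valid
    empty polyline file).  Raises :class:`InvalidInputError` if the
    ensemble was simulated without trajectory recording.
    """
    from .vtkio import write_polylines

    if ensemble.pathlines is None:
        raise InvalidInputError(
            "ensemble was simulated without trajectory recording; "
            "rerun simulate_particles with record_pathlines > 0")
    lines = ensemble.pathlines if sample is None else ensemble.pathlines[:sample]
    vf = ensemble.velocity_field
    polylines, magnitudes = [], []
    for pl in lines:
        xyz = np.column_stack([pl.r * np.cos(pl.theta), pl.r * np.sin(pl.theta), pl.z])
        polylines.append(xyz)
        r_clip = np.minimum(pl.r, vf.radius)
        magnitudes.append(np.asarray(vf.axial_velocity(r_clip, np.clip(pl.z, 0.0, None))))
    write_polylines(path, polylines, {"velocity_magnitude": magnitudes})
    return len(polylines)
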