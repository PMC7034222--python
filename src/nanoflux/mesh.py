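"""Structured cylindrical meshes with wall-clustered radial spacing.

The grid-independence study refines structured meshes of
``n_axial x n_radial x n_circumferential`` cells (65/129/193 stream-wise,
25/49/97 radial, 37 circumferential; the optimum is 129 x 97 x 37 =
462,981 cells).  Radial cell faces follow a geometric stretching law from
the axis towards the wall so that the wall-adjacent cell is no taller than
``first_wall_spacing`` times the channel diameter; axial spacing is
uniform.  The circumferential dimension is bookkeeping/export only — the
physics downstream is axisymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError
from .physical import Channel

#: default dimensionless first wall spacing (fraction of tube diameter)
DEFAULT_FIRST_WALL_SPACING = 3.0e-4

#: maximum admissible geometric stretching ratio between adjacent radial cells
MAX_STRETCH_RATIO = 3.0


@dataclass(frozen=True)
class StructuredMesh:
    """Structured cylindrical mesh.

    ``node_radii`` and ``node_axial`` are the radial and axial cell-face
    coordinates (m), strictly increasing and spanning [0, R] and [0, L].
    ``first_wall_spacing`` is the wall-clustering target as a fraction of
    the diameter.
    """

    n_axial: int
    n_radial: int
    n_circumferential: int
    first_wall_spacing: float
    channel: Channel
    node_radii: np.ndarray = field(repr=False)
    node_axial: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        """Total cell count, the product of the three dimensions."""
        return self.n_axial * self.n_radial * self.n_circumferential

    @property
    def wall_cell_height(self) -> float:
        """Radial extent of the wall-adjacent cell (m)."""
        return float(self.node_radii[-1] - self.node_radii[-2])

    @property
    def radial_centres(self) -> np.ndarray:
        return 0.5 * (self.node_radii[1:] + self.node_radii[:-1])

    @property
    def axial_centres(self) -> np.ndarray:
        return 0.5 * (self.node_axial[1:] + self.node_axial[:-1])

    def radial_nodes_with_boundaries(self) -> np.ndarray:
        """Radial collocation points: axis, cell centres, wall.

        This is the node set the axisymmetric solvers discretise on; it
        keeps the wall Dirichlet point explicit while sampling the interior
        at cell centres.
        """
        return np.concatenate(([0.0], self.radial_centres, [self.channel.radius]))


def _geometric_ratio(n: int, h_wall: float, total: float) -> float:
    """Common ratio q >= 1 with sum_{k=0}^{n-1} h_wall q^k = total."""

    def residual(q: float) -> float:
        if abs(q - 1.0) < 1e-12:
            return n * h_wall - total
        return h_wall * (q**n - 1.0) / (q - 1.0) - total

    if residual(1.0) >= 0.0:  # uniform spacing already no coarser than h_wall
        return 1.0
    if residual(MAX_STRETCH_RATIO) < 0.0:
        raise ConfigurationError(
            f"radial stretching infeasible: wall spacing {h_wall:.3e} m is too small "
            f"for {n} cells over {total:.3e} m (ratio would exceed {MAX_STRETCH_RATIO})")
    return brentq(residual, 1.0 + 1e-12, MAX_STRETCH_RATIO, xtol=1e-14)


def build_mesh(n_axial: int, n_radial: int, n_circumferential: int,
               first_wall_spacing: float = DEFAULT_FIRST_WALL_SPACING,
               channel: Channel | None = None) -> StructuredMesh:
    """Build a wall-clustered structured mesh for a cylindrical channel.

    Parameters
    ----------
    n_axial, n_radial, n_circumferential : int
        Cell counts (all >= 2; the circumferential count is bookkeeping
        only because the solvers are axisymmetric).
    first_wall_spacing : float
        Wall-adjacent radial cell height as a fraction of the internal
        diameter (strictly between 0 and 0.5).  The default 3.0e-4 gives a
        1.2 um wall cell on the 4 mm study channel.
    channel : Channel, optional
        Defaults to the 4 mm x 47 mm study channel.

    Raises
    ------
    ConfigurationError
        If the requested wall spacing cannot be met with the given radial
        count at a stretching ratio below ``MAX_STRETCH_RATIO``.
    """
    channel = channel or Channel.from_mm()
    for name, n in (("n_axial", n_axial), ("n_radial", n_radial),
                    ("n_circumferential", n_circumferential)):
        if int(n) != n or n < 2:
            raise ConfigurationError(f"{name} must be an integer >= 2, got {n!r}")
    if not 0.0 < first_wall_spacing < 0.5:
        raise ConfigurationError(
            f"first_wall_spacing must lie in (0, 0.5), got {first_wall_spacing}")

    R = channel.radius
    h_wall = min(first_wall_spacing * channel.internal_diameter, R / n_radial)
    q = _geometric_ratio(n_radial, h_wall, R)
    # widths ordered from the wall inward, then reversed to run axis -> wall
    widths = h_wall * q ** np.arange(n_radial)
    radii = np.concatenate(([0.0], np.cumsum(widths[::-1])))
    radii *= R / radii[-1]  # absorb the brentq residual so the last face is exactly R
    axial = np.linspace(0.0, channel.length, n_axial + 1)

    return StructuredMesh(
        n_axial=int(n_axial), n_radial=int(n_radial),
        n_circumferential=int(n_circumferential),
        first_wall_spacing=float(first_wall_spacing), channel=channel,
        node_radii=radii, node_axial=axial,
    )
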