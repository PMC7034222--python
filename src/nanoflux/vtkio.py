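"""Legacy ASCII VTK writers for meshes, fields and pathlines.

Only the two structures the package exports are implemented: a cylindrical
STRUCTURED_GRID (mesh + optional cell-centre velocity) and POLYDATA
polylines (pathlines with per-point scalars).  The legacy VTK format is a
plain-text container, written directly.
"""

from __future__ import annotations

import numpy as np


def _header(fh, title: str, dataset: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def write_structured_grid(path, mesh, point_scalars: dict | None = None,
                          title: str = "nanoflux structured mesh") -> None:
    """Write a StructuredMesh as a legacy VTK structured grid.

    Points are the tensor product of radial faces x circumferential angles
    x axial faces.  ``point_scalars`` may map names to arrays of shape
    (n_axial+1, n_radial+1) that are axisymmetrically replicated (e.g. an
    axial-velocity field sampled on faces).
    """
    r = mesh.node_radii
    z = mesh.node_axial
    ntheta = mesh.n_circumferential + 1
    theta = np.linspace(0.0, 2.0 * np.pi, ntheta)
    nr, nz = len(r), len(z)
    with open(path, "w") as fh:
        _header(fh, title, "STRUCTURED_GRID")
        fh.write(f"DIMENSIONS {nr} {ntheta} {nz}\n")
        fh.write(f"POINTS {nr * ntheta * nz} float\n")
        for zk in z:
            for th in theta:
                x = r * np.cos(th)
                y = r * np.sin(th)
                for xi, yi in zip(x, y):
                    fh.write(f"{xi:.6e} {yi:.6e} {zk:.6e}\n")
        if point_scalars:
            fh.write(f"POINT_DATA {nr * ntheta * nz}\n")
            for name, arr in point_scalars.items():
                arr = np.asarray(arr)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for k in range(nz):
                    for _ in range(ntheta):
                        for j in range(nr):
                            fh.write(f"{arr[k, j]:.6e}\n")


def write_polylines(path, polylines: list[np.ndarray],
                    point_scalars: dict[str, list[np.ndarray]] | None = None,
                    title: str = "nanoflux pathlines") -> None:
    """Write polylines (list of (n_i, 3) xyz arrays) as legacy VTK POLYDATA.

    ``point_scalars`` maps scalar names to per-line arrays of length n_i
    (e.g. velocity magnitude along each pathline).  An empty list of
    polylines produces a valid empty file.
    """
    n_points = sum(len(p) for p in polylines)
    with open(path, "w") as fh:
        _header(fh, title, "POLYDATA")
        fh.write(f"POINTS {n_points} float\n")
        for line in polylines:
            for x, y, z in np.asarray(line):
                fh.write(f"{x:.6e} {y:.6e} {z:.6e}\n")
        size = sum(len(p) + 1 for p in polylines)
        fh.write(f"LINES {len(polylines)} {size}\n")
        offset = 0
        for line in polylines:
            ids = " ".join(str(offset + i) for i in range(len(line)))
            fh.write(f"{len(line)} {ids}\n")
            offset += len(line)
        if point_scalars and n_points:
            fh.write(f"POINT_DATA {n_points}\n")
            for name, arrays in point_scalars.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for arr in arrays:
                    for v in np.asarray(arr):
                        fh.write(f"{v:.6e}\n")
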