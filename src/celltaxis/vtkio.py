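"""Minimal legacy-ASCII VTK unstructured-grid writer (and reader for tests).

Keeps the deliverable text-only; files load in standard VTK readers
(ParaView, meshio, pyvista).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fem import HexMesh

__all__ = ["write_vtk_state", "read_vtk_summary"]

# VTK_HEXAHEDRON node order differs from our lexicographic local order
_VTK_ORDER = [0, 1, 3, 2, 4, 5, 7, 6]


def write_vtk_state(path, mesh: HexMesh, modulus: np.ndarray,
                    cell_elements: set[int],
                    displacement: np.ndarray | None = None) -> Path:
    path = Path(path)
    conn = mesh.element_nodes[:, _VTK_ORDER]
    coords = mesh.node_coords
    mask = np.zeros(mesh.n_elems)
    mask[sorted(cell_elements)] = 1.0
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("celltaxis state\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, coords, fmt="%.6g")
        fh.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}\n")
        np.savetxt(fh, np.column_stack([np.full(mesh.n_elems, 8), conn]), fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        np.savetxt(fh, np.full(mesh.n_elems, 12), fmt="%d")
        fh.write(f"CELL_DATA {mesh.n_elems}\n")
        fh.write("SCALARS modulus_kPa float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, modulus, fmt="%.6g")
        fh.write("SCALARS cell_mask float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mask, fmt="%g")
        if displacement is not None:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            fh.write("VECTORS displacement_um float\n")
            np.savetxt(fh, displacement, fmt="%.6g")
    return path


def read_vtk_summary(path) -> dict:
    """Parse the headers of a legacy VTK file (round-trip checks)."""
    out = {"fields": []}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise ValueError("not a legacy VTK file")
    for ln in lines:
        parts = ln.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            out["n_points"] = int(parts[1])
        elif parts[0] == "CELLS":
            out["n_cells"] = int(parts[1])
        elif parts[0] == "SCALARS":
            out["fields"].append(parts[1])
        elif parts[0] == "VECTORS":
            out["fields"].append(parts[1])
    return out
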