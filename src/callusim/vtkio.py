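"""Minimal VTK legacy ASCII structured-points I/O for run snapshots.

Writes cell data (tissue fractions, vascularity, region, strain invariants)
and optional point data (displacements) on the voxel grid, plus a small
reader sufficient to round-trip the files this package writes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np

__all__ = ["write_structured_points", "read_structured_points"]


def _emit_scalars(lines, name, values):
    lines.append(f"SCALARS {name} float 1")
    lines.append("LOOKUP_TABLE default")
    flat = np.asarray(values, float).ravel(order="F")
    for i in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:.9g}" for v in flat[i:i + 6]))


def write_structured_points(path, dims, spacing: float,
                            cell_data: Dict[str, np.ndarray],
                            point_data: Optional[Dict[str, np.ndarray]] = None,
                            ) -> None:
    """Write a VTK legacy STRUCTURED_POINTS file (ASCII).

    ``dims`` are cell counts; arrays in ``cell_data`` must be grid-shaped
    (nx, ny, nz).  ``point_data`` arrays are (n_points, 3) vectors over the
    structured node grid.
    """
    nx, ny, nz = dims
    lines = [
        "# vtk DataFile Version 3.0",
        "callusim snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}",
    ]
    if cell_data:
        lines.append(f"CELL_DATA {nx * ny * nz}")
        for name, values in cell_data.items():
            if values.shape != (nx, ny, nz):
                raise ValueError(f"cell array {name!r} has shape {values.shape}, "
                                 f"expected {(nx, ny, nz)}")
            _emit_scalars(lines, name, values)
    if point_data:
        npts = (nx + 1) * (ny + 1) * (nz + 1)
        lines.append(f"POINT_DATA {npts}")
        for name, values in point_data.items():
            v = np.asarray(values, float).reshape(npts, 3)
            lines.append(f"VECTORS {name} float")
            for i in range(npts):
                lines.append(" ".join(f"{x:.9g}" for x in v[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_structured_points(path):
    """Read back a file written by :func:`write_structured_points`.

    Returns ``(dims, spacing, cell_data, point_data)`` with grid-shaped cell
    arrays.  Supports only the subset of the legacy format this package
    emits.
    """
    lines = Path(path).read_text().split("\n")
    dims = None
    spacing = None
    cell_data: Dict[str, np.ndarray] = {}
    point_data: Dict[str, np.ndarray] = {}
    n_cells = n_points = 0
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("DIMENSIONS"):
            px, py, pz = map(int, ln.split()[1:4])
            dims = (px - 1, py - 1, pz - 1)
            n_cells = dims[0] * dims[1] * dims[2]
            n_points = px * py * pz
        elif ln.startswith("SPACING"):
            spacing = float(ln.split()[1])
        elif ln.startswith("CELL_DATA"):
            mode = "cell"
        elif ln.startswith("POINT_DATA"):
            mode = "point"
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            i += 1  # LOOKUP_TABLE line
            vals = []
            while len(vals) < n_cells:
                i += 1
                vals.extend(float(v) for v in lines[i].split())
            cell_data[name] = np.array(vals).reshape(dims, order="F")
        elif ln.startswith("VECTORS"):
            name = ln.split()[1]
            vals = []
            while len(vals) < 3 * n_points:
                i += 1
                vals.extend(float(v) for v in lines[i].split())
            point_data[name] = np.array(vals).reshape(n_points, 3)
        i += 1
    if dims is None or spacing is None:
        raise ValueError(f"{path} is not a structured-points file")
    return dims, spacing, cell_data, point_data
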