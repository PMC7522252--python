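"""Minimal legacy-VTK ASCII export of the structured water-state fields.

Writes a RECTILINEAR_GRID dataset (the pseudo-2D mesh with a single node
plane out of plane) with nodal point data (pressure head, water content)
and elemental cell data (uptake sink).  The files open directly in
ParaView.  Units: cm, day; noted in the header line.
"""

from __future__ import annotations

import numpy as np

from .soil import SoilGrid

__all__ = ["write_vtk"]


def write_vtk(path, grid: SoilGrid, point_fields: dict | None = None,
              cell_fields: dict | None = None) -> None:
    point_fields = point_fields or {}
    cell_fields = cell_fields or {}
    lines = ["# vtk DataFile Version 3.0",
             "rhizosim fields (units: cm, day)",
             "ASCII",
             "DATASET RECTILINEAR_GRID",
             f"DIMENSIONS {grid.nx + 1} {grid.nz + 1} 1",
             f"X_COORDINATES {grid.nx + 1} float",
             " ".join(f"{x:.9g}" for x in grid.x_nodes),
             f"Y_COORDINATES {grid.nz + 1} float",
             " ".join(f"{z:.9g}" for z in grid.z_nodes),
             "Z_COORDINATES 1 float",
             "0"]
    if point_fields:
        lines.append(f"POINT_DATA {grid.n_nodes}")
        for name, field in point_fields.items():
            field = np.asarray(field, dtype=float).ravel()
            if field.size != grid.n_nodes:
                raise ValueError(f"point field {name!r} has wrong size")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.append(" ".join(f"{v:.9g}" for v in field))
    if cell_fields:
        lines.append(f"CELL_DATA {grid.n_elems}")
        for name, field in cell_fields.items():
            field = np.asarray(field, dtype=float).ravel()
            if field.size != grid.n_elems:
                raise ValueError(f"cell field {name!r} has wrong size")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.append(" ".join(f"{v:.9g}" for v in field))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
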