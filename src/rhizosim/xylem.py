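"""Water flow in the root xylem network and the soil uptake sink.

The xylem is treated as a resistor network in the spirit of Doussan: each
segment carries an axial Darcy flow

    J_x = -K_x ( dh_x/dl + dz/dl )

between its endpoint nodes, and exchanges water radially with the soil at

    q_r = L_r (h_s - h_x),      J_r = 2 pi r q_r l_seg ,

with the radial exchange lumped at the segment's distal node.  Xylem
storage is neglected, so each solve is a steady linear system for the
nodal xylem heads given the soil heads at the segment midpoints and a
prescribed transpiration flux at the collar.  Summing the nodal balances
shows that the total radial uptake equals the collar flux exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .rootsys import SegmentTable
from .soil import SoilGrid

__all__ = ["CollarBoundary", "XylemSolution", "ConditioningError",
           "solve_xylem", "assemble_sink", "split_segment"]


class ConditioningError(RuntimeError):
    """The xylem system is singular (e.g. no radial pathway anywhere)."""


@dataclass(frozen=True)
class CollarBoundary:
    """Transpiration demand applied at the root collar (cm3/day, >= 0)."""

    flux: float = 0.2

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("collar flux must be non-negative")


@dataclass
class XylemSolution:
    """Per-segment solution of one steady xylem solve."""

    h_x: np.ndarray   # xylem pressure head at the distal node, cm
    q_r: np.ndarray   # radial flux density, cm/day
    J_r: np.ndarray   # radial volumetric flow, cm3/day
    J_x: np.ndarray   # axial volumetric flow (positive proximal->distal), cm3/day
    h_collar: float


def solve_xylem(table: SegmentTable, h_soil: np.ndarray, collar: CollarBoundary,
                *, K_x: float = 4.32e-2, L_r: float = 1.73e-4,
                collar_z: float | None = None) -> XylemSolution:
    """Solve the steady xylem network for nodal heads and radial flows.

    ``h_soil`` holds the soil pressure head sampled at each segment
    midpoint.  ``K_x`` (cm3/day) and ``L_r`` (cm/day) are the axial
    conductance and radial conductivity, both per unit segment length.
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty root system")
    h_soil = np.asarray(h_soil, dtype=float)
    if h_soil.shape != (n,):
        raise ValueError("h_soil must have one entry per segment")
    parent = table.parent
    if np.any(parent < -1) or np.any(parent >= n):
        raise ValueError(f"invalid parent links: {parent[(parent < -1) | (parent >= n)]}")

    # node 0 = collar; node i+1 = distal end of segment i
    n_nodes = n + 1
    z = np.empty(n_nodes)
    z[1:] = table.b[:, 1]
    z[0] = table.a[parent == -1, 1][0] if np.any(parent == -1) else table.a[0, 1]
    if collar_z is not None:
        z[0] = collar_z
    p_node = np.where(parent == -1, 0, parent + 1)
    d_node = np.arange(1, n_nodes)

    length = np.maximum(table.length, 1e-12)
    g_ax = K_x / length                       # axial conductance, cm2/day
    gamma = 2.0 * np.pi * table.radius * L_r * length  # radial conductance
    if np.all(gamma <= 0):
        raise ConditioningError("all radial conductances vanish; system singular")

    rows = np.concatenate([p_node, d_node, p_node, d_node, d_node])
    cols = np.concatenate([d_node, p_node, p_node, d_node, d_node])
    vals = np.concatenate([-g_ax, -g_ax, g_ax, g_ax, gamma])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes))

    b = np.zeros(n_nodes)
    np.add.at(b, p_node, g_ax * (z[d_node] - z[p_node]))
    np.add.at(b, d_node, g_ax * (z[p_node] - z[d_node]))
    np.add.at(b, d_node, gamma * h_soil)
    b[0] -= collar.flux

    h = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(h)):
        raise ConditioningError("xylem solve produced non-finite heads")

    h_x = h[1:]
    J_r = gamma * (h_soil - h_x)
    q_r = J_r / (2.0 * np.pi * table.radius * length)
    H = h + z
    J_x = g_ax * (H[p_node] - H[d_node])
    return XylemSolution(h_x=h_x, q_r=q_r, J_r=J_r, J_x=J_x, h_collar=float(h[0]))


def split_segment(grid: SoilGrid, a, b):
    """Partition segment a->b over the elements its midline crosses.

    Returns ``(elem_ids, fractions)`` with fractions summing to 1.  Raises
    if any part of the segment lies outside the grid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for p in (a, b):
        if not (-1e-9 <= p[0] <= grid.Lx + 1e-9 and -1e-9 <= p[1] <= grid.Lz + 1e-9):
            raise ValueError(f"segment endpoint {p} outside grid")
    d = b - a
    ts = [0.0, 1.0]
    for lines, a0, d0 in ((grid.x_nodes, a[0], d[0]), (grid.z_nodes, a[1], d[1])):
        if abs(d0) > 1e-14:
            t = (lines - a0) / d0
            ts.extend(t[(t > 1e-12) & (t < 1 - 1e-12)])
    ts = np.unique(np.asarray(ts))
    mids = a[None, :] + 0.5 * (ts[:-1] + ts[1:])[:, None] * d[None, :]
    fracs = np.diff(ts)
    keep = fracs > 1e-12
    elems = np.asarray([grid.locate(x, zz) for x, zz in mids[keep]])
    return elems, fracs[keep]


def assemble_sink(table: SegmentTable, grid: SoilGrid, J_r: np.ndarray,
                  cache: dict | None = None) -> np.ndarray:
    """Distribute radial flows onto the soil elements as a sink S (1/day).

    Each segment's J_r is split across the elements its midline crosses in
    proportion to the in-element length, then divided by element volume.
    ``cache`` (keyed by the immutable segment geometry) avoids re-clipping
    segments that were already placed in earlier growth steps.
    """
    S = np.zeros(grid.n_elems)
    J_r = np.asarray(J_r, dtype=float)
    for i in range(len(table)):
        key = (table.root_id[i], round(table.a[i, 0], 12), round(table.a[i, 1], 12),
               round(table.b[i, 0], 12), round(table.b[i, 1], 12))
        if cache is not None and key in cache:
            elems, fracs = cache[key]
        else:
            elems, fracs = split_segment(grid, table.a[i], table.b[i])
            if cache is not None:
                cache[key] = (elems, fracs)
        np.add.at(S, elems, J_r[i] * fracs / grid.elem_volume)
    return S
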