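"""Unsaturated water flow in a structured pseudo-2D substrate.

The substrate is a thin rectangular slab (a petri dish or rhizobox filled
with agar) discretised by a structured grid of rectangular prisms, one
element thick in the out-of-plane direction.  Water moves according to the
Richards equation

    dtheta/dt = div( K(h) grad(h + z) ) - S

closed by the Van Genuchten retention curve and the Mualem-Van Genuchten
conductivity function.  ``S`` is the root-uptake sink (per unit volume per
day) supplied by the xylem solver.

Units throughout: lengths in cm, time in days, pressure head ``h`` in cm of
water (negative when unsaturated).  ``z`` increases upward, the origin sits
at the bottom-left corner of the growth plane (x-z).

The transient step uses the mass-conservative ("mixed form") modified
Picard iteration of Celia et al.: each iteration solves a linear system for
the new head with the storage term expanded around the previous iterate, so
that on convergence the discrete mass balance holds to round-off.  The
spatial operator is a node-centred finite-volume discretisation (equivalent
to lumped linear FEM on rectangles), which on a structured grid yields the
usual 5-point stencil with no-flux boundaries arising naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "VanGenuchtenSoil",
    "SoilGrid",
    "WaterState",
    "RichardsConvergenceError",
    "effective_saturation",
    "theta_of_h",
    "k_of_h",
    "water_capacity",
    "hydrostatic_init",
    "richards_step",
]


@dataclass(frozen=True)
class VanGenuchtenSoil:
    """Hydraulic parameters of one substrate material.

    Defaults are the agar-substrate values used for the wheat calibration
    runs (retention shape alpha, n; saturated conductivity K_s) together
    with a bulk density of 1.2 g/cm3, typical of soils.  The Mualem pore
    connectivity exponent ``l_pore`` defaults to 0.5.
    """

    theta_r: float = 0.06
    theta_s: float = 0.41
    alpha: float = 0.03  # 1/cm
    n: float = 2.51
    K_s: float = 10.24  # cm/day
    l_pore: float = 0.5
    rho_b: float = 1.2  # g/cm3

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError("need 0 <= theta_r < theta_s <= 1")
        if self.n <= 1.0:
            raise ValueError("Van Genuchten n must exceed 1")
        if self.alpha <= 0.0 or self.K_s <= 0.0 or self.rho_b <= 0.0:
            raise ValueError("alpha, K_s and rho_b must be positive")

    @property
    def m(self) -> float:
        """Derived retention exponent, m = 1 - 1/n."""
        return 1.0 - 1.0 / self.n


def effective_saturation(theta, soil: VanGenuchtenSoil):
    """Effective saturation Se = (theta - theta_r)/(theta_s - theta_r)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < soil.theta_r - 1e-12) or np.any(theta > soil.theta_s + 1e-12):
        raise ValueError("theta outside [theta_r, theta_s]")
    se = (theta - soil.theta_r) / (soil.theta_s - soil.theta_r)
    return np.clip(se, 0.0, 1.0)[()]


def _se_of_h(h, soil: VanGenuchtenSoil):
    h = np.asarray(h, dtype=float)
    ah = soil.alpha * np.abs(np.minimum(h, 0.0))
    return (1.0 + ah ** soil.n) ** (-soil.m)


def theta_of_h(h, soil: VanGenuchtenSoil):
    """Van Genuchten water retention theta(h); total function of h."""
    se = _se_of_h(h, soil)
    return (soil.theta_r + (soil.theta_s - soil.theta_r) * se)[()]


def k_of_h(h, soil: VanGenuchtenSoil):
    """Mualem-Van Genuchten unsaturated conductivity K(h) in cm/day."""
    se = _se_of_h(h, soil)
    # guard the fractional power at se ~ 1 (saturated branch)
    se = np.clip(se, 1e-300, 1.0)
    term = 1.0 - (1.0 - se ** (1.0 / soil.m)) ** soil.m
    return (soil.K_s * se ** soil.l_pore * term ** 2)[()]


def water_capacity(h, soil: VanGenuchtenSoil):
    """Specific moisture capacity C(h) = dtheta/dh (1/cm); 0 when saturated."""
    h = np.asarray(h, dtype=float)
    ah = soil.alpha * np.abs(np.minimum(h, 0.0))
    num = (soil.theta_s - soil.theta_r) * soil.m * soil.n * soil.alpha
    c = num * ah ** (soil.n - 1.0) * (1.0 + ah ** soil.n) ** (-soil.m - 1.0)
    return np.where(h >= 0.0, 0.0, c)[()]


class SoilGrid:
    """Structured, axis-aligned grid of the pseudo-2D growth domain.

    Nodes live at the corners of rectangular elements; ``nx`` x ``nz``
    elements span ``Lx`` x ``Lz`` cm in the x-z growth plane, each element
    being ``thickness`` cm deep out of plane.  Node ``(i, k)`` (column i,
    row k from the bottom) has flat index ``k*(nx+1) + i``; element
    ``(i, k)`` has flat index ``k*nx + i``.
    """

    def __init__(self, Lx: float, Lz: float, nx: int, nz: int, thickness: float):
        if Lx <= 0 or Lz <= 0 or thickness <= 0:
            raise ValueError("domain extents and thickness must be positive")
        if nx < 1 or nz < 1:
            raise ValueError("need at least one element per direction")
        self.Lx, self.Lz, self.thickness = float(Lx), float(Lz), float(thickness)
        self.nx, self.nz = int(nx), int(nz)
        self.dx, self.dz = self.Lx / nx, self.Lz / nz
        self.x_nodes = np.linspace(0.0, self.Lx, nx + 1)
        self.z_nodes = np.linspace(0.0, self.Lz, nz + 1)
        self.n_nodes = (nx + 1) * (nz + 1)
        self.n_elems = nx * nz
        xx, zz = np.meshgrid(self.x_nodes, self.z_nodes)
        self.node_x = xx.ravel()
        self.node_z = zz.ravel()
        self.elem_cx = np.tile(self.x_nodes[:-1] + self.dx / 2, nz)
        self.elem_cz = np.repeat(self.z_nodes[:-1] + self.dz / 2, nx)
        self.elem_volume = self.dx * self.dz * self.thickness
        self._build_topology()

    # -- topology ---------------------------------------------------------
    def _build_topology(self) -> None:
        nx, nz = self.nx, self.nz
        # effective half-widths of node control volumes
        wx = np.full(nx + 1, self.dx)
        wx[0] = wx[-1] = self.dx / 2
        wz = np.full(nz + 1, self.dz)
        wz[0] = wz[-1] = self.dz / 2
        self.node_volumes = (np.outer(wz, wx) * self.thickness).ravel()
        # horizontal node pairs (i,k)-(i+1,k)
        ii, kk = np.meshgrid(np.arange(nx), np.arange(nz + 1))
        a = kk.ravel() * (nx + 1) + ii.ravel()
        self._pairs_h = np.stack([a, a + 1], axis=1)
        self._tgeo_h = (np.repeat(wz, nx) * self.thickness) / self.dx
        # vertical node pairs (i,k)-(i,k+1)
        ii, kk = np.meshgrid(np.arange(nx + 1), np.arange(nz))
        a = kk.ravel() * (nx + 1) + ii.ravel()
        self._pairs_v = np.stack([a, a + nx + 1], axis=1)
        self._tgeo_v = (np.tile(wx, nz) * self.thickness) / self.dz
        self.pairs = np.vstack([self._pairs_h, self._pairs_v])
        self.tgeo = np.concatenate([self._tgeo_h, self._tgeo_v])
        # element -> 4 corner node indices (ll, lr, ul, ur)
        ie, ke = np.meshgrid(np.arange(nx), np.arange(nz))
        ll = ke.ravel() * (nx + 1) + ie.ravel()
        self.elem_nodes = np.stack([ll, ll + 1, ll + nx + 1, ll + nx + 2], axis=1)
        # node -> representative element (lower-left element, clamped): used to
        # assign a material to each node
        iN, kN = np.meshgrid(np.arange(nx + 1), np.arange(nz + 1))
        ie_n = np.clip(iN.ravel() - 0, 0, nx - 1)
        ke_n = np.clip(kN.ravel() - 0, 0, nz - 1)
        self.node_elem = ke_n * nx + ie_n

    # -- queries ----------------------------------------------------------
    def locate(self, x: float, z: float) -> int:
        """Flat element index containing point (x, z); raises if outside."""
        eps = 1e-9
        if not (-eps <= x <= self.Lx + eps and -eps <= z <= self.Lz + eps):
            raise ValueError(f"point ({x:.4g}, {z:.4g}) outside domain")
        i = min(int(np.clip(x / self.dx, 0, self.nx - 1e-9)), self.nx - 1)
        k = min(int(np.clip(z / self.dz, 0, self.nz - 1e-9)), self.nz - 1)
        return k * self.nx + i

    def interp_nodal(self, field: np.ndarray, x, z):
        """Bilinear interpolation of a nodal field at points (x, z)."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, self.Lx)
        z = np.clip(np.asarray(z, dtype=float), 0.0, self.Lz)
        fx = np.clip(x / self.dx, 0, self.nx - 1e-12)
        fz = np.clip(z / self.dz, 0, self.nz - 1e-12)
        i0 = fx.astype(int)
        k0 = fz.astype(int)
        tx = fx - i0
        tz = fz - k0
        f = field.reshape(self.nz + 1, self.nx + 1)
        v = (f[k0, i0] * (1 - tx) * (1 - tz) + f[k0, i0 + 1] * tx * (1 - tz)
             + f[k0 + 1, i0] * (1 - tx) * tz + f[k0 + 1, i0 + 1] * tx * tz)
        return v[()]

    def elem_mean(self, nodal_field: np.ndarray) -> np.ndarray:
        """Average of the 4 corner values, per element."""
        return nodal_field[self.elem_nodes].mean(axis=1)

    def interp_elem(self, elem_field: np.ndarray, x, z):
        """Bilinear interpolation of an element-centre field (clamped)."""
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        fx = np.clip(x / self.dx - 0.5, 0.0, self.nx - 1.0)
        fz = np.clip(z / self.dz - 0.5, 0.0, self.nz - 1.0)
        i0 = np.minimum(fx.astype(int), self.nx - 2) if self.nx > 1 else np.zeros_like(fx, dtype=int)
        k0 = np.minimum(fz.astype(int), self.nz - 2) if self.nz > 1 else np.zeros_like(fz, dtype=int)
        tx = fx - i0
        tz = fz - k0
        f = elem_field.reshape(self.nz, self.nx)
        i1 = np.minimum(i0 + 1, self.nx - 1)
        k1 = np.minimum(k0 + 1, self.nz - 1)
        v = (f[k0, i0] * (1 - tx) * (1 - tz) + f[k0, i1] * tx * (1 - tz)
             + f[k1, i0] * (1 - tx) * tz + f[k1, i1] * tx * tz)
        return v[()]


@dataclass
class WaterState:
    """Nodal water state at one time plus the elemental uptake sink."""

    time: float
    h: np.ndarray          # nodal pressure head, cm
    theta: np.ndarray      # nodal water content
    K: np.ndarray          # nodal conductivity, cm/day
    sink: np.ndarray       # elemental sink S, 1/day
    picard_iterations: int = 0
    mass_balance_error: float = 0.0
    boundary_flux: float = 0.0  # cm3/day into the domain through Dirichlet nodes

    def copy(self) -> "WaterState":
        return replace(self, h=self.h.copy(), theta=self.theta.copy(),
                       K=self.K.copy(), sink=self.sink.copy())


class RichardsConvergenceError(RuntimeError):
    """Picard iteration failed after substep halving down to the floor."""

    def __init__(self, msg: str, residual: float, dt: float, iterations: int):
        super().__init__(msg)
        self.residual = residual
        self.dt = dt
        self.iterations = iterations


def _node_soils(grid: SoilGrid, soils, elem_mat: np.ndarray):
    """Per-node material index via the node's representative element."""
    return np.asarray(elem_mat)[grid.node_elem]


def _eval_nodal(grid, soils, node_mat, h, fn):
    out = np.empty(grid.n_nodes)
    for mi, soil in enumerate(soils):
        mask = node_mat == mi
        if np.any(mask):
            out[mask] = fn(h[mask], soil)
    return out


def hydrostatic_init(grid: SoilGrid, soils, elem_mat=None,
                     water_table_z: float = 0.0) -> WaterState:
    """Hydrostatic equilibrium state: h(z) = water_table_z - z.

    The total head h + z is uniform, so with no sink this state is a fixed
    point of :func:`richards_step`.  ``soils`` may be a single material or a
    list indexed by ``elem_mat``.
    """
    if isinstance(soils, VanGenuchtenSoil):
        soils = [soils]
    if elem_mat is None:
        elem_mat = np.zeros(grid.n_elems, dtype=int)
    if not (0.0 <= water_table_z <= grid.Lz):
        raise ValueError("water table must lie inside the domain")
    h = water_table_z - grid.node_z
    node_mat = _node_soils(grid, soils, elem_mat)
    theta = _eval_nodal(grid, soils, node_mat, h, theta_of_h)
    K = _eval_nodal(grid, soils, node_mat, h, k_of_h)
    return WaterState(time=0.0, h=h, theta=theta, K=K,
                      sink=np.zeros(grid.n_elems))


def _sink_to_nodes(grid: SoilGrid, sink_elem: np.ndarray) -> np.ndarray:
    """Elemental sink volume rate (cm3/day) lumped equally onto corner nodes."""
    q = np.zeros(grid.n_nodes)
    vol_rate = sink_elem * grid.elem_volume / 4.0
    np.add.at(q, grid.elem_nodes.ravel(), np.repeat(vol_rate, 4))
    return q


def richards_step(grid: SoilGrid, state: WaterState, soils, elem_mat,
                  sink_elem: np.ndarray, dt: float, *,
                  bottom_head: float | None = None,
                  tol: float = 1e-6, max_iter: int = 50,
                  min_substep_frac: float = 1.0 / 64.0) -> WaterState:
    """Advance the water state by ``dt`` days with modified-Picard iteration.

    All outer faces are no-flux; if ``bottom_head`` is given, the bottom row
    of nodes is held at that pressure head (a maintained water table).  On
    Picard failure the step is retried with halved substeps down to
    ``dt * min_substep_frac`` before raising
    :class:`RichardsConvergenceError`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(soils, VanGenuchtenSoil):
        soils = [soils]
    elem_mat = np.asarray(elem_mat)
    node_mat = _node_soils(grid, soils, elem_mat)
    q_node = _sink_to_nodes(grid, sink_elem)

    dirichlet = None
    if bottom_head is not None:
        dirichlet = np.arange(grid.nx + 1)  # bottom row node indices

    h = state.h.copy()
    theta = state.theta.copy()
    t_done, target = 0.0, dt
    sub_dt = dt
    total_iters = 0
    bflux_int = 0.0  # time-integrated Dirichlet boundary inflow, cm3
    last_res = np.inf
    while t_done < target - 1e-15:
        sub_dt = min(sub_dt, target - t_done)
        ok, h_new, theta_new, iters, res, bflux = _picard_substep(
            grid, soils, node_mat, h, theta, q_node, sub_dt,
            dirichlet, bottom_head, tol, max_iter)
        total_iters += iters
        last_res = res
        if ok:
            h, theta = h_new, theta_new
            t_done += sub_dt
            bflux_int += bflux * sub_dt
            sub_dt *= 2.0  # gentle ramp-up after success
        else:
            sub_dt /= 2.0
            if sub_dt < dt * min_substep_frac - 1e-15:
                raise RichardsConvergenceError(
                    f"Picard iteration failed at dt={sub_dt * 2:.3e} d "
                    f"(floor {dt * min_substep_frac:.3e} d), max |dh|={res:.3e} cm",
                    residual=res, dt=sub_dt * 2, iterations=total_iters)

    theta_final = _eval_nodal(grid, soils, node_mat, h, theta_of_h)
    K_final = _eval_nodal(grid, soils, node_mat, h, k_of_h)
    storage = float(np.sum((theta_final - state.theta) * grid.node_volumes))
    sink_vol = float(np.sum(q_node) * dt)
    mb = storage + sink_vol - bflux_int
    denom = max(abs(storage), abs(sink_vol), 1e-9)
    return WaterState(time=state.time + dt, h=h, theta=theta_final, K=K_final,
                      sink=np.asarray(sink_elem, dtype=float).copy(),
                      picard_iterations=total_iters,
                      mass_balance_error=mb / denom,
                      boundary_flux=bflux_int / dt)


def _picard_substep(grid, soils, node_mat, h_old, theta_old, q_node, dt,
                    dirichlet, bottom_head, tol, max_iter):
    """One implicit substep; returns (ok, h, theta, iters, residual, bflux)."""
    h_m = h_old.copy()
    if dirichlet is not None:
        h_m[dirichlet] = bottom_head
    z = grid.node_z
    a, b = grid.pairs[:, 0], grid.pairs[:, 1]
    res = np.inf
    for it in range(1, max_iter + 1):
        K_n = _eval_nodal(grid, soils, node_mat, h_m, k_of_h)
        C_n = _eval_nodal(grid, soils, node_mat, h_m, water_capacity)
        theta_m = _eval_nodal(grid, soils, node_mat, h_m, theta_of_h)
        T = grid.tgeo * 0.5 * (K_n[a] + K_n[b])
        diag_c = C_n * grid.node_volumes / dt

        rows = np.concatenate([a, b, a, b, np.arange(grid.n_nodes)])
        cols = np.concatenate([b, a, a, b, np.arange(grid.n_nodes)])
        vals = np.concatenate([-T, -T, T, T, diag_c])
        rhs = diag_c * h_m - (theta_m - theta_old) * grid.node_volumes / dt - q_node
        grav = np.zeros(grid.n_nodes)
        np.add.at(grav, a, T * (z[b] - z[a]))
        np.add.at(grav, b, T * (z[a] - z[b]))
        rhs += grav

        if dirichlet is not None:
            keep = ~np.isin(rows, dirichlet)
            rows, cols, vals = rows[keep], cols[keep], vals[keep]
            rows = np.concatenate([rows, dirichlet])
            cols = np.concatenate([cols, dirichlet])
            vals = np.concatenate([vals, np.ones(len(dirichlet))])
            rhs[dirichlet] = bottom_head

        A = sp.csr_matrix((vals, (rows, cols)), shape=(grid.n_nodes, grid.n_nodes))
        h_new = spla.spsolve(A, rhs)
        # near saturation C -> 0 leaves the system nearly singular; a wild
        # iterate means the linearisation overshot -> force a smaller substep
        if not np.all(np.isfinite(h_new)) or np.max(np.abs(h_new)) > 1e8:
            return False, h_m, theta_old, it, np.inf, 0.0
        res = float(np.max(np.abs(h_new - h_m)))
        h_m = h_new
        if res < tol:
            bflux = 0.0
            if dirichlet is not None:
                # net inflow from the held bottom row into the interior
                H = h_m + z
                flux_ab = T * (H[a] - H[b])  # flow a -> b
                da = np.isin(a, dirichlet) & ~np.isin(b, dirichlet)
                db = np.isin(b, dirichlet) & ~np.isin(a, dirichlet)
                bflux = float(np.sum(flux_ab[da]) - np.sum(flux_ab[db]))
            theta_new = _eval_nodal(grid, soils, node_mat, h_m, theta_of_h)
            return True, h_m, theta_new, it, res, bflux
    return False, h_m, theta_old, max_iter, res, 0.0
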