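"""Coupled growth simulation.

Each fixed architecture step of length ``dt`` does, in order:

1. emerge scheduled axes and germinate lateral branch points whose delay
   has elapsed;
2. advance every active tip: sample the substrate at the tip (water
   potential, effective saturation, penetration resistance and its
   gradient), evaluate the resistance-limited elongation rate, update the
   growth direction through the obstacle phase machine, and move the tip
   (with collision clamping so no segment ever enters an obstacle);
3. solve the steady xylem network for the current architecture against the
   collar transpiration flux, distribute the radial flows onto the soil
   elements as a sink, and
4. advance the Richards solver over the same interval (with its own
   adaptive substepping).

Everything random flows from one ``numpy`` generator seeded per run, so a
given (config, seed) pair reproduces bit-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .config import SimulationConfig
from .growth import (GRAVITY, HEAD_TO_KPA, direction_update, elongation_rate,
                     resistance_field, resistance_gradient_at, rotate,
                     sample_deviation)
from .obstacles import (ContactState, clamp_to_obstacle, distance_to_obstacle,
                        path_blocked, slide_direction, update_contact_state,
                        w_o_weight)
from .rootsys import BranchPoint, RootSystem
from .soil import SoilGrid, hydrostatic_init, richards_step, _se_of_h
from .xylem import CollarBoundary, assemble_sink, solve_xylem

__all__ = ["Tip", "Trajectory", "Simulation", "simulate"]

_MIN_STEP = 1e-9  # cm; displacements below this are dropped


@dataclass
class Tip:
    """Kinematic state of one growing root apex."""

    root_id: int
    pos: np.ndarray
    direction: np.ndarray
    contact: ContactState
    active: bool = True
    halted: str | None = None
    #: newborn tips take their first step along the scheduled emergence /
    #: insertion direction, so the branching angle is encoded in the geometry
    fresh: bool = True


@dataclass
class Trajectory:
    """Result of one run: snapshots, per-step tip log, contact episodes."""

    config: SimulationConfig
    seed: int
    times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)   # (t, RootSystem copy)
    water: list = field(default_factory=list)       # (t, nodal h copy)
    episodes: list = field(default_factory=list)    # contact episode dicts
    _tip_rows: list = field(default_factory=list)
    system: RootSystem | None = None
    grid: SoilGrid | None = None
    final_state: object = None

    @property
    def tip_log(self) -> pd.DataFrame:
        cols = ["t", "root_id", "order", "x", "z", "dx", "dz", "beta",
                "phase", "w_o", "E"]
        return pd.DataFrame(self._tip_rows, columns=cols)

    def beta_trajectory(self, root_id: int) -> pd.DataFrame:
        """Tip growth angle beta (deg from horizontal, 90 = vertical)."""
        log = self.tip_log
        sel = log[log.root_id == root_id]
        if sel.empty:
            raise ValueError(f"no tip log for root {root_id}")
        return sel[["t", "beta"]].reset_index(drop=True)


def beta_of_direction(d) -> float:
    """Growth angle from horizontal in degrees; 90 = vertical."""
    d = np.asarray(d, dtype=float)
    return float(np.degrees(np.arctan2(abs(d[1]), abs(d[0]))))


class Simulation:
    """One coupled soil-xylem-architecture run."""

    def __init__(self, config: SimulationConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        dom = config.domain
        self.grid = SoilGrid(dom.Lx, dom.Lz, dom.nx, dom.nz, dom.thickness)
        self.soils = [config.soil] + [
            replace(config.soil, K_s=o.K_s, rho_b=o.rho_b)
            for o in config.obstacles]
        from .obstacles import rasterize_obstacles
        self.elem_mat = rasterize_obstacles(config.obstacles, self.grid)
        self.state = hydrostatic_init(self.grid, self.soils, self.elem_mat,
                                      config.water_table_z)
        self.system = RootSystem(config.seed_pos, radius=config.root_radius)
        self.tips: dict[int, Tip] = {}
        self.collar = CollarBoundary(config.collar_flux)
        # contact detection must reach past the one-to-two element halo over
        # which the elemental resistance field smears the obstacle boundary
        self.contact_threshold = config.contact_threshold
        if self.contact_threshold is None:
            self.contact_threshold = max(config.root_radius,
                                         1.5 * max(self.grid.dx, self.grid.dz))
        self._axes_emerged = 0
        self._sink_cache: dict = {}
        self.t = 0.0
        self.traj = Trajectory(config=config, seed=self.seed,
                               system=self.system, grid=self.grid)

    # ------------------------------------------------------------------
    def run(self) -> Trajectory:
        cfg = self.config
        self._record_output(self.t)
        n_steps = int(round(cfg.horizon / cfg.dt))
        next_out = cfg.output_interval
        for _ in range(n_steps):
            self.step()
            if self.t >= next_out - 1e-9 or self.t >= cfg.horizon - 1e-9:
                self._record_output(self.t)
                while next_out <= self.t + 1e-9:
                    next_out += cfg.output_interval
        self.traj.final_state = self.state
        return self.traj

    def step(self) -> None:
        cfg = self.config
        t_new = self.t + cfg.dt
        self.emerge_axes(self.t)
        self.emit_branches(self.t)
        R_elem = resistance_field(self.grid, self.state, self.soils,
                                  self.elem_mat)
        self.advance_tips(self.t, cfg.dt, R_elem)
        sink = self._update_uptake()
        self.state = richards_step(
            self.grid, self.state, self.soils, self.elem_mat, sink, cfg.dt,
            bottom_head=cfg.bottom_head)
        self.t = t_new

    # -- architecture updates -------------------------------------------
    def emerge_axes(self, t: float) -> None:
        for spec in self.config.traits.axes[self._axes_emerged:]:
            if spec.time > t + 1e-9:
                break
            root = self.system.new_root(order=1, birth_time=spec.time,
                                        start_pos=self.config.seed_pos)
            self.tips[root.id] = Tip(
                root_id=root.id, pos=np.asarray(self.config.seed_pos, float),
                direction=spec.direction,
                contact=ContactState(self.config.w_oi, self.config.kappa))
            self._axes_emerged += 1

    def emit_branches(self, t: float) -> None:
        """Create due branch primordia and germinate those past their delay.

        A primordium at arc s_j = j * spacing initiates when the parent tip
        passes the previous branch site s_{j-1} (the root's own germination
        for j = 1) and germinates ``tip_delay`` days later, on alternating
        sides at the configured insertion angle.
        """
        traits = self.config.traits
        for rid in sorted(self.system.roots):
            root = self.system.roots[rid]
            if root.order >= traits.max_order:
                continue
            while root.length > (len(root.branch_points) + 1) * traits.branch_spacing + 1e-12:
                j = len(root.branch_points) + 1
                arc = j * traits.branch_spacing
                create = root.time_at_arc(arc - traits.branch_spacing)
                root.branch_points.append(BranchPoint(
                    arc=arc, pos=root.point_at_arc(arc),
                    create_time=create,
                    activation_time=create + traits.tip_delay,
                    side=1 if j % 2 == 1 else -1,
                    parent_dir=root.direction_at_arc(arc)))
            for bp in root.branch_points:
                if bp.child is None and bp.activation_time <= t + 1e-9:
                    child_dir = rotate(bp.parent_dir,
                                       bp.side * traits.branching_angle)
                    child = self.system.new_root(
                        order=root.order + 1, birth_time=bp.activation_time,
                        start_pos=bp.pos, parent=rid, branch_arc=bp.arc)
                    bp.child = child.id
                    self.tips[child.id] = Tip(
                        root_id=child.id, pos=bp.pos.copy(),
                        direction=child_dir,
                        contact=ContactState(self.config.w_oi,
                                             self.config.kappa))

    def advance_tips(self, t: float, dt: float, R_elem: np.ndarray) -> None:
        cfg, traits = self.config, self.config.traits
        h_elem = self.grid.elem_mean(self.state.h)
        for rid in sorted(self.tips):
            tip = self.tips[rid]
            if not tip.active:
                continue
            root = self.system.roots[rid]
            age = t - root.birth_time
            if age < -1e-9:
                continue
            elem = self.grid.locate(*tip.pos)
            soil = self.soils[self.elem_mat[elem]]
            psi = HEAD_TO_KPA * float(h_elem[elem])
            se = float(_se_of_h(h_elem[elem], soil))
            R_ave = float(R_elem[elem])
            grad = resistance_gradient_at(tip.pos, self.grid, R_elem)
            E = elongation_rate(traits.elongation_max(root.order, age),
                                R_ave, psi)
            step_len = E * dt
            d, w_o = self._tip_direction(tip, t, step_len, grad)
            if step_len > 0:
                self._move_tip(tip, d, step_len, t + dt)
            self.traj._tip_rows.append(
                (t + dt, rid, root.order, tip.pos[0], tip.pos[1],
                 tip.direction[0], tip.direction[1],
                 beta_of_direction(tip.direction), tip.contact.phase, w_o, E))

    def _tip_direction(self, tip: Tip, t: float, step_len: float, grad):
        cfg, traits = self.config, self.config.traits
        if tip.fresh:
            tip.fresh = False
            return tip.direction.copy(), 0.0
        dist, obst, tangent = distance_to_obstacle(tip.pos, cfg.obstacles,
                                                   tip.direction)
        in_contact = dist <= self.contact_threshold
        event = update_contact_state(tip.contact, in_contact, t, tip.direction)
        if event == "recovery_start":
            self.traj.episodes.append({
                "root_id": tip.root_id, "t0": tip.contact.t0,
                "t1": tip.contact.t1, "t2": tip.contact.t2})
        phase = tip.contact.phase
        if phase == "contact":
            # geotropism forced to 1 and random deviation suppressed while
            # sliding along the obstacle
            d = direction_update(tip.direction, GRAVITY, grad, 1.0,
                                 traits.w_r, 0.0)
            if obst is not None and step_len > 0 and path_blocked(
                    tip.pos, d, step_len, obst):
                d = slide_direction(d, tangent, GRAVITY)
            return d, 1.0
        if phase == "recovery":
            w_o = w_o_weight(tip.contact, t)
            hist = tip.contact.history_vector(tip.direction)
            d = direction_update(hist, GRAVITY, grad, traits.w_g, traits.w_r,
                                 0.0, w_hist=w_o)
            return d, w_o
        delta_s = sample_deviation(traits.delta, self.rng)
        d = direction_update(tip.direction, GRAVITY, grad, traits.w_g,
                             traits.w_r, delta_s)
        return d, 0.0

    def _move_tip(self, tip: Tip, d: np.ndarray, step_len: float,
                  t_new: float) -> None:
        cfg = self.config
        # keep free tips from stepping into an obstacle before the contact
        # threshold has triggered
        if tip.contact.phase != "contact":
            for obs in cfg.obstacles:
                step_len = min(step_len, clamp_to_obstacle(
                    tip.pos, d, step_len, obs, self.contact_threshold / 4))
        # clip against the domain box
        s_dom = step_len
        for c, dc, L in ((tip.pos[0], d[0], self.grid.Lx),
                         (tip.pos[1], d[1], self.grid.Lz)):
            if dc > 1e-14:
                s_dom = min(s_dom, (L - c) / dc)
            elif dc < -1e-14:
                s_dom = min(s_dom, -c / dc)
        s_dom = max(s_dom, 0.0)
        hit_boundary = s_dom < step_len - 1e-12
        new_pos = tip.pos + min(step_len, s_dom) * d
        new_pos[0] = float(np.clip(new_pos[0], 0.0, self.grid.Lx))
        new_pos[1] = float(np.clip(new_pos[1], 0.0, self.grid.Lz))
        # never leave an endpoint strictly inside an obstacle
        for obs in cfg.obstacles:
            poly = obs.polygon
            if poly.contains(Point(new_pos)):
                from shapely.ops import nearest_points
                q = nearest_points(poly.exterior, Point(new_pos))[0]
                out = np.asarray([q.x, q.y]) - new_pos
                nn = np.linalg.norm(out)
                new_pos = np.asarray([q.x, q.y]) + (
                    out / nn * 1e-9 if nn > 0 else 0.0)
        moved = float(np.linalg.norm(new_pos - tip.pos))
        if moved > _MIN_STEP:
            self.system.extend(tip.root_id, new_pos, t_new)
            tip.pos = new_pos
        tip.direction = d
        if hit_boundary:
            tip.active = False
            tip.halted = "domain_boundary"

    # -- water ------------------------------------------------------------
    def _update_uptake(self) -> np.ndarray:
        table = self.system.segment_table()
        if len(table) == 0:
            return np.zeros(self.grid.n_elems)
        mids = table.midpoints
        h_s = np.atleast_1d(self.grid.interp_nodal(self.state.h,
                                                   mids[:, 0], mids[:, 1]))
        sol = solve_xylem(table, h_s, self.collar, K_x=self.config.K_x,
                          L_r=self.config.L_r,
                          collar_z=self.config.seed_pos[1])
        self.last_xylem = sol
        self.last_table = table
        return assemble_sink(table, self.grid, sol.J_r, cache=self._sink_cache)

    # -- output -----------------------------------------------------------
    def _record_output(self, t: float) -> None:
        self.traj.times.append(t)
        self.traj.snapshots.append((t, copy.deepcopy(self.system)))
        self.traj.water.append((t, self.state.h.copy()))


def simulate(config: SimulationConfig, seed: int = 0) -> Trajectory:
    """Run one coupled growth simulation and return its trajectory."""
    return Simulation(config, seed=seed).run()
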