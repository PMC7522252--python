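"""Rigid obstacles and the contact/recovery growth response.

Obstacles are inclined rectangles embedded in the growth plane.  In the
water-flow problem they are simply regions of stiffer, less permeable
substrate (high bulk density, low saturated conductivity), so no special
treatment of the field equations is needed; the growth rules additionally
keep tips from penetrating the obstacle polygon by projecting the growth
direction onto the nearest edge tangent while in contact.

Each tip carries a :class:`ContactState` phase machine:

* ``free``      -- normal growth; history term is the previous direction.
* ``contact``   -- the tip is within the contact threshold of an obstacle
  boundary.  Geotropism weight is forced to 1 and the random deviation is
  suppressed; the mean unit growth direction over the contact episode is
  accumulated.
* ``recovery``  -- after contact is lost at time t1, the history term is
  weighted by W_o(t), which jumps from 1 to an initial weight W_oi > 1 and
  decays linearly to 0 at t2 = t1 + kappa (t1 - t0).  The first recovery
  step uses the mean contact direction as the history vector; later steps
  use the previous step's direction.  A new contact cancels recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = ["Obstacle", "ContactState", "StateError", "rasterize_obstacles",
           "distance_to_obstacle", "update_contact_state", "w_o_weight",
           "slide_direction", "path_blocked", "clamp_to_obstacle"]


class StateError(RuntimeError):
    """Inconsistent use of the contact phase machine."""


@dataclass(frozen=True)
class Obstacle:
    """Inclined rectangular obstacle; material defaults are stiff agar-filler.

    ``eta`` is the inclination of the long edge with respect to the
    horizontal, in degrees (the experiments used 0, 30 and 45).
    """

    center: tuple[float, float]
    length: float = 2.0
    width: float = 0.2
    eta: float = 0.0
    rho_b: float = 1.4   # g/cm3
    K_s: float = 5.0     # cm/day

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("obstacle length and width must be positive")

    @property
    def polygon(self) -> Polygon:
        c, s = np.cos(np.radians(self.eta)), np.sin(np.radians(self.eta))
        R = np.array([[c, -s], [s, c]])
        half = np.array([[ self.length / 2,  self.width / 2],
                         [-self.length / 2,  self.width / 2],
                         [-self.length / 2, -self.width / 2],
                         [ self.length / 2, -self.width / 2]])
        corners = half @ R.T + np.asarray(self.center)
        return Polygon(corners)


def rasterize_obstacles(obstacles, grid) -> np.ndarray:
    """Element material map: 0 = substrate, i = obstacles[i-1].

    An element belongs to an obstacle iff its centroid lies inside the
    obstacle rectangle.  Later obstacles in the list take precedence.
    """
    mat = np.zeros(grid.n_elems, dtype=int)
    for idx, obs in enumerate(obstacles, start=1):
        poly = obs.polygon
        minx, miny, maxx, maxy = poly.bounds
        if minx < -1e-9 or miny < -1e-9 or maxx > grid.Lx + 1e-9 or maxy > grid.Lz + 1e-9:
            raise ValueError(f"obstacle {idx} extends outside the domain")
        inside = shapely.contains_xy(poly, grid.elem_cx, grid.elem_cz)
        mat[inside] = idx
    return mat


def _nearest_edge_tangent(poly: Polygon, p: np.ndarray) -> np.ndarray:
    """Unit tangent of the polygon edge closest to p."""
    coords = np.asarray(poly.exterior.coords)
    best_d, best_t = np.inf, None
    for a, b in zip(coords[:-1], coords[1:]):
        ab = b - a
        L2 = ab @ ab
        if L2 == 0:
            continue
        t = np.clip((p - a) @ ab / L2, 0.0, 1.0)
        proj = a + t * ab
        d = np.linalg.norm(p - proj)
        if d < best_d:
            best_d, best_t = d, ab / np.sqrt(L2)
    return best_t


def distance_to_obstacle(pos, obstacles, direction=None):
    """(distance, nearest obstacle, edge tangent) for a tip position.

    The tangent of the nearest edge is returned with its sense aligned with
    ``direction`` when given (so it preserves forward motion).  Returns
    ``(inf, None, None)`` for an empty obstacle list.
    """
    if not obstacles:
        return np.inf, None, None
    p = np.asarray(pos, dtype=float)
    pt = Point(p)
    best = min(obstacles, key=lambda o: o.polygon.exterior.distance(pt))
    dist = best.polygon.exterior.distance(pt)
    tangent = _nearest_edge_tangent(best.polygon, p)
    if direction is not None and tangent is not None:
        if float(np.dot(tangent, direction)) < 0:
            tangent = -tangent
    return float(dist), best, tangent


@dataclass
class ContactState:
    """Per-tip obstacle phase machine (free / contact / recovery)."""

    w_oi: float = 5.0
    kappa: float = 2.0
    phase: str = "free"
    t0: float | None = None
    t1: float | None = None
    t2: float | None = None
    mean_dir: np.ndarray | None = None
    _dir_sum: np.ndarray = field(default_factory=lambda: np.zeros(2))
    _dir_count: int = 0
    _last_t: float = -np.inf
    used_mean: bool = False

    def __post_init__(self) -> None:
        if self.w_oi <= 1.0:
            raise ValueError("W_oi must exceed 1")
        if self.kappa <= 0.0:
            raise ValueError("kappa must be positive")

    def history_vector(self, d_old: np.ndarray) -> np.ndarray:
        """History direction during recovery: the frozen mean contact
        direction on the first call after t1, the previous step's direction
        afterwards."""
        if self.phase == "recovery" and not self.used_mean and self.mean_dir is not None:
            self.used_mean = True
            return self.mean_dir
        return np.asarray(d_old, dtype=float)


def update_contact_state(state: ContactState, in_contact: bool, t: float,
                         direction) -> str | None:
    """Advance the phase machine; returns the transition event (or None).

    Events: ``"contact_start"`` (free/recovery -> contact), ``"recovery_start"``
    (contact -> recovery; freezes t1, t2 and the mean contact direction) and
    ``"recovered"`` (recovery -> free at t >= t2).
    """
    if t < state._last_t - 1e-12:
        raise StateError(f"time regression: {t} after {state._last_t}")
    state._last_t = t
    d = np.asarray(direction, dtype=float)

    if state.phase == "free":
        if in_contact:
            _start_contact(state, t, d)
            return "contact_start"
        return None
    if state.phase == "contact":
        if in_contact:
            state._dir_sum += d
            state._dir_count += 1
            return None
        state.t1 = t
        state.t2 = t + state.kappa * (t - state.t0)
        nrm = np.linalg.norm(state._dir_sum)
        state.mean_dir = (state._dir_sum / nrm) if nrm > 0 else d
        state.phase = "recovery"
        state.used_mean = False
        return "recovery_start"
    # recovery
    if in_contact:
        _start_contact(state, t, d)
        return "contact_start"
    if t >= state.t2 - 1e-12:
        state.phase = "free"
        return "recovered"
    return None


def _start_contact(state: ContactState, t: float, d: np.ndarray) -> None:
    state.phase = "contact"
    state.t0 = t
    state.t1 = state.t2 = None
    state.mean_dir = None
    state.used_mean = False
    state._dir_sum = d.copy()
    state._dir_count = 1


def w_o_weight(state: ContactState, t: float) -> float:
    """History weight W_o(t): 1 during contact, W_oi -> 0 linearly over the
    recovery window [t1, t2], 0 otherwise."""
    if state.phase == "free":
        return 0.0
    if state.t0 is not None and t < state.t0 - 1e-12:
        raise StateError("evaluation before contact start")
    if state.phase == "contact":
        return 1.0
    # recovery
    if t >= state.t2:
        return 0.0
    frac = (t - state.t1) / (state.t2 - state.t1)
    return float(state.w_oi * (1.0 - frac))


# -- geometric helpers for sliding and collision ---------------------------

def path_blocked(pos, direction, step: float, obstacle: Obstacle) -> bool:
    """Would a step of the given length enter the obstacle interior?"""
    p = np.asarray(pos, dtype=float)
    end = p + step * np.asarray(direction, dtype=float)
    inner = obstacle.polygon.buffer(-1e-9)
    return LineString([p, end]).intersects(inner)


def slide_direction(direction, tangent, gravity) -> np.ndarray:
    """Project a blocked growth direction onto the obstacle edge tangent.

    The tangent sense preserving forward motion is chosen; if the direction
    is normal to the edge the sense follows the gravity component along the
    tangent.  Raises when both vanish.
    """
    d = np.asarray(direction, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    proj = float(np.dot(d, tangent))
    if abs(proj) > 1e-10:
        return tangent * np.sign(proj)
    gproj = float(np.dot(np.asarray(gravity, dtype=float), tangent))
    if abs(gproj) > 1e-10:
        return tangent * np.sign(gproj)
    raise StateError("growth direction normal to edge and no gravity tangent")


def clamp_to_obstacle(pos, direction, step: float, obstacle: Obstacle,
                      margin: float) -> float:
    """Largest advance along ``direction`` stopping ``margin`` before entry.

    Returns the clamped step length (possibly 0)."""
    p = np.asarray(pos, dtype=float)
    d = np.asarray(direction, dtype=float)
    line = LineString([p, p + step * d])
    hit = line.intersection(obstacle.polygon.boundary)
    if hit.is_empty:
        return step
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        pts.extend(np.asarray(geom.coords))
    dists = [float(np.dot(np.asarray(q) - p, d)) for q in pts]
    s_hit = min(dv for dv in dists if dv >= -1e-12)
    return max(0.0, s_hit - margin)
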