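"""Discrete root architecture container.

A :class:`RootSystem` is a forest of :class:`Root` polylines rooted at the
seed position.  Each root stores its ordered vertex list together with the
time at which the tip reached each vertex, so arc-length and tip-passage
times can be interpolated exactly.  A flat per-segment view (one segment per
consecutive vertex pair, with parent-segment links suitable for the xylem
network solve) is derived on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BranchPoint", "Root", "RootSystem", "SegmentTable", "TopologyError"]


class TopologyError(ValueError):
    """Raised when parent links do not form a forest rooted at the seed."""


@dataclass
class BranchPoint:
    """A lateral initiation site on a parent root."""

    arc: float               # arc length along the parent, cm
    pos: np.ndarray          # (x, z) position
    create_time: float       # primordium initiation time, day
    activation_time: float   # germination time of the lateral, day
    side: int                # +1 / -1, alternating insertion side
    parent_dir: np.ndarray   # local parent direction at the branch point
    child: int | None = None  # root id of the emitted lateral


@dataclass
class Root:
    """One root (axis or lateral) as a time-stamped polyline."""

    id: int
    order: int
    birth_time: float
    parent: int | None = None      # parent root id (None for axes)
    branch_arc: float = 0.0        # arc position on the parent where attached
    points: list = field(default_factory=list)   # list of (2,) arrays
    times: list = field(default_factory=list)    # tip arrival time per point
    branch_points: list = field(default_factory=list)

    @property
    def cum_arc(self) -> np.ndarray:
        pts = np.asarray(self.points)
        if len(pts) < 2:
            return np.zeros(max(len(pts), 1))
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.cum_arc[-1])

    def time_at_arc(self, arc: float) -> float:
        """Time at which the tip passed the given arc length (clamped)."""
        ca = self.cum_arc
        return float(np.interp(arc, ca, np.asarray(self.times)))

    def point_at_arc(self, arc: float) -> np.ndarray:
        ca = self.cum_arc
        arc = float(np.clip(arc, 0.0, ca[-1]))
        j = int(np.searchsorted(ca, arc, side="right")) - 1
        j = min(max(j, 0), len(self.points) - 2) if len(self.points) > 1 else 0
        if len(self.points) == 1:
            return np.asarray(self.points[0], dtype=float)
        a, b = np.asarray(self.points[j]), np.asarray(self.points[j + 1])
        seg = ca[j + 1] - ca[j]
        t = 0.0 if seg <= 0 else (arc - ca[j]) / seg
        return a + t * (b - a)

    def direction_at_arc(self, arc: float) -> np.ndarray:
        ca = self.cum_arc
        if len(self.points) < 2:
            raise ValueError("root has no extent yet")
        arc = float(np.clip(arc, 0.0, ca[-1]))
        j = int(np.searchsorted(ca, arc, side="right")) - 1
        j = min(max(j, 0), len(self.points) - 2)
        d = np.asarray(self.points[j + 1]) - np.asarray(self.points[j])
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("degenerate segment")
        return d / nrm

    def tip_position(self) -> np.ndarray:
        return np.asarray(self.points[-1], dtype=float)


@dataclass
class SegmentTable:
    """Flat per-segment arrays (one row per polyline edge).

    ``parent[i]`` is the index of the upstream segment, or -1 when the
    segment attaches directly to the collar (seed).
    """

    root_id: np.ndarray
    order: np.ndarray
    parent: np.ndarray
    birth_time: np.ndarray
    a: np.ndarray            # (n, 2) proximal endpoints
    b: np.ndarray            # (n, 2) distal endpoints
    length: np.ndarray
    radius: np.ndarray

    def __len__(self) -> int:
        return len(self.root_id)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)


class RootSystem:
    """Forest of roots growing from a single seed position."""

    def __init__(self, seed_pos, radius: float = 0.03):
        self.seed = np.asarray(seed_pos, dtype=float)
        self.radius = float(radius)
        self.roots: dict[int, Root] = {}
        self._next_id = 1

    # -- construction -----------------------------------------------------
    def new_root(self, order: int, birth_time: float, start_pos,
                 parent: int | None = None, branch_arc: float = 0.0) -> Root:
        if parent is not None and parent not in self.roots:
            raise TopologyError(f"unknown parent root {parent}")
        if parent is not None and order < self.roots[parent].order:
            raise TopologyError("child order must be >= parent order")
        rid = self._next_id
        self._next_id += 1
        root = Root(id=rid, order=order, birth_time=float(birth_time),
                    parent=parent, branch_arc=float(branch_arc),
                    points=[np.asarray(start_pos, dtype=float)],
                    times=[float(birth_time)])
        self.roots[rid] = root
        return root

    def extend(self, root_id: int, new_pos, t: float) -> None:
        r = self.roots[root_id]
        r.points.append(np.asarray(new_pos, dtype=float))
        r.times.append(float(t))

    # -- queries ----------------------------------------------------------
    def axes(self) -> list[Root]:
        return [r for r in self.roots.values() if r.parent is None]

    def descendants(self, root_id: int) -> list[Root]:
        out, stack = [], [root_id]
        while stack:
            rid = stack.pop()
            for r in self.roots.values():
                if r.parent == rid:
                    out.append(r)
                    stack.append(r.id)
        return out

    def total_length(self) -> float:
        return float(sum(r.length for r in self.roots.values()))

    def validate(self) -> None:
        """Check the forest property (acyclic parent links, known parents)."""
        for r in self.roots.values():
            seen = {r.id}
            cur = r.parent
            while cur is not None:
                if cur in seen:
                    raise TopologyError(
                        f"cycle in parent links involving roots {sorted(seen)}")
                if cur not in self.roots:
                    raise TopologyError(f"root {r.id} has unknown ancestor {cur}")
                seen.add(cur)
                cur = self.roots[cur].parent

    # -- flat segment view -------------------------------------------------
    def segment_table(self) -> SegmentTable:
        """Derive the per-segment view with parent-segment links."""
        self.validate()
        root_id, order, parent, birth, A, B = [], [], [], [], [], []
        first_seg: dict[int, int] = {}
        seg_ranges: dict[int, tuple[int, int]] = {}
        # deterministic order: root id
        for rid in sorted(self.roots):
            r = self.roots[rid]
            start = len(root_id)
            for j in range(len(r.points) - 1):
                root_id.append(rid)
                order.append(r.order)
                birth.append(r.times[j + 1])
                A.append(r.points[j])
                B.append(r.points[j + 1])
                parent.append(len(root_id) - 2 if j > 0 else -2)  # -2: fix later
            if len(r.points) > 1:
                first_seg[rid] = start
                seg_ranges[rid] = (start, len(root_id))
        # resolve first-segment parents
        for rid, s0 in first_seg.items():
            r = self.roots[rid]
            if r.parent is None:
                parent[s0] = -1
            else:
                pr = self.roots[r.parent]
                if r.parent not in seg_ranges:
                    raise TopologyError(
                        f"lateral {rid} attached to extentless root {r.parent}")
                ca = pr.cum_arc
                j = int(np.searchsorted(ca, min(r.branch_arc, ca[-1]),
                                        side="right")) - 1
                j = min(max(j, 0), len(pr.points) - 2)
                parent[s0] = seg_ranges[r.parent][0] + j
        a = np.asarray(A, dtype=float).reshape(-1, 2)
        b = np.asarray(B, dtype=float).reshape(-1, 2)
        length = np.linalg.norm(b - a, axis=1) if len(a) else np.zeros(0)
        return SegmentTable(
            root_id=np.asarray(root_id, dtype=int),
            order=np.asarray(order, dtype=int),
            parent=np.asarray(parent, dtype=int),
            birth_time=np.asarray(birth, dtype=float),
            a=a, b=b, length=length,
            radius=np.full(len(a), self.radius))
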