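"""Network indices of a root system architecture.

Three morphological indices summarise an architecture for calibration:
total network length, the foraging area of an axis group (the area of the
convex hull of all its node coordinates), and the branching density (branch
points per unit axis length).  For graph-theoretic comparisons the
architecture is reduced to an undirected weighted tree whose nodes are the
seed, the branch junctions and the tips, with edges weighted by arc length,
on which node connectivity and betweenness centrality are evaluated.  Fan
trees (seed-to-tip stars) and a minimum-spanning-tree approximation of the
Euclidean Steiner minimal tree over the same terminals provide reference
lengths bracketing plausible transport networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint

from .rootsys import RootSystem

__all__ = ["NetworkIndices", "total_length", "foraging_area",
           "branching_density", "to_undirected_graph", "graph_stats",
           "fan_tree_length", "steiner_tree_length_approx",
           "compute_indices", "beta_trajectory"]


@dataclass
class NetworkIndices:
    total_length: float
    foraging_area: float
    branching_density: float
    node_connectivity: float | None = None
    mean_betweenness: float | None = None
    fan_length: float | None = None
    steiner_length: float | None = None


def total_length(system: RootSystem) -> float:
    """Sum of all segment lengths, cm."""
    return system.total_length()


def _group_points(system: RootSystem, axis_ids) -> np.ndarray:
    pts = []
    for aid in axis_ids:
        if aid not in system.roots:
            continue
        for r in [system.roots[aid]] + system.descendants(aid):
            pts.extend(np.asarray(p) for p in r.points)
    if not pts:
        raise ValueError("empty axis group")
    return np.asarray(pts)


def foraging_area(system: RootSystem, axis_ids=None) -> float:
    """Convex-hull area (cm2) of an axis plus its laterals.

    ``axis_ids`` defaults to all axes.  Collinear point sets have zero
    area.
    """
    if axis_ids is None:
        axis_ids = [r.id for r in system.axes()]
    pts = _group_points(system, axis_ids)
    if len(pts) < 3:
        return 0.0
    return float(MultiPoint(pts.tolist()).convex_hull.area)


def branching_density(system: RootSystem, axis_id: int) -> float:
    """Lateral branch points per unit axis length (1/cm)."""
    root = system.roots[axis_id]
    if root.length <= 0:
        raise ValueError("zero-length axis")
    n_bp = sum(1 for bp in root.branch_points if bp.child is not None)
    return n_bp / root.length


def to_undirected_graph(system: RootSystem) -> nx.Graph:
    """Reduce the architecture to a weighted undirected tree.

    Nodes are the seed, every branch junction with an emitted lateral, and
    every tip; edge weights are the arc lengths between consecutive nodes
    along each root.
    """
    G = nx.Graph()
    G.add_node("seed", pos=tuple(system.seed))
    for rid in sorted(system.roots):
        root = system.roots[rid]
        if len(root.points) < 2:
            continue
        if root.parent is None:
            prev, prev_arc = "seed", 0.0
        else:
            prev, prev_arc = ("bp", root.parent, float(root.branch_arc)), 0.0
            if prev not in G:
                G.add_node(prev, pos=tuple(
                    system.roots[root.parent].point_at_arc(root.branch_arc)))
        for bp in sorted(root.branch_points, key=lambda b: b.arc):
            if bp.child is None:
                continue
            node = ("bp", rid, float(bp.arc))
            G.add_node(node, pos=tuple(bp.pos))
            G.add_edge(prev, node, weight=bp.arc - prev_arc)
            prev, prev_arc = node, bp.arc
        tipnode = ("tip", rid)
        G.add_node(tipnode, pos=tuple(root.tip_position()))
        G.add_edge(prev, tipnode, weight=root.length - prev_arc)
    return G


def graph_stats(G: nx.Graph) -> tuple[float, float]:
    """(node connectivity, mean normalised betweenness centrality).

    Betweenness uses networkx's pair normalisation 2/((n-1)(n-2)) with
    edge weights as distances, averaged over all nodes.
    """
    if G.number_of_nodes() == 0 or not nx.is_connected(G):
        raise ValueError("graph must be non-empty and connected")
    if G.number_of_nodes() == 1:
        return 0.0, 0.0
    conn = float(nx.node_connectivity(G))
    bc = nx.betweenness_centrality(G, normalized=True, weight="weight")
    return conn, float(np.mean(list(bc.values())))


def fan_tree_length(seed, tips) -> float:
    """Length of the star network joining the seed to every tip."""
    seed = np.asarray(seed, dtype=float)
    tips = np.asarray(tips, dtype=float).reshape(-1, len(seed))
    if len(tips) == 0:
        return 0.0
    return float(np.linalg.norm(tips - seed, axis=1).sum())


def steiner_tree_length_approx(seed, tips) -> float:
    """Euclidean MST length over {seed} + tips.

    This is the classical 2-approximation of the Euclidean Steiner minimal
    tree (the MST is at most twice, in the plane at most 2/sqrt(3) times,
    the Steiner optimum) and never exceeds the fan-tree length.
    """
    seed = np.asarray(seed, dtype=float).reshape(1, -1)
    tips = np.asarray(tips, dtype=float).reshape(-1, seed.shape[1])
    pts = np.vstack([seed, tips])
    # merge terminals closer than 1e-12 cm: they are the same point, and
    # csgraph would otherwise drop their (denormal) connecting edge
    pts = np.unique(np.round(pts, 12), axis=0)
    if len(pts) < 2:
        return 0.0
    D = cdist(pts, pts)
    return float(minimum_spanning_tree(D).sum())


def compute_indices(system: RootSystem, axis_ids=None,
                    with_graph: bool = True) -> NetworkIndices:
    """All indices for one architecture (area/density per axis group)."""
    if axis_ids is None:
        axis_ids = [r.id for r in system.axes()]
    grown = [aid for aid in axis_ids
             if aid in system.roots and system.roots[aid].length > 0]
    area = foraging_area(system, grown) if grown else 0.0
    dens = (float(np.mean([branching_density(system, aid) for aid in grown]))
            if grown else 0.0)
    idx = NetworkIndices(total_length=total_length(system),
                         foraging_area=area, branching_density=dens)
    tips = [r.tip_position() for r in system.roots.values()
            if len(r.points) > 1]
    idx.fan_length = fan_tree_length(system.seed, tips)
    idx.steiner_length = steiner_tree_length_approx(system.seed, tips)
    if with_graph and system.roots:
        G = to_undirected_graph(system)
        if G.number_of_nodes() > 1:
            idx.node_connectivity, idx.mean_betweenness = graph_stats(G)
    return idx


def beta_trajectory(trajectory, root_id: int):
    """Growth angle beta(t) of a root's tip, degrees from horizontal."""
    return trajectory.beta_trajectory(root_id)


# -- morphological trait measurements on simulated networks -----------------

def branch_spacing_gaps(system: RootSystem, axis_ids=None) -> np.ndarray:
    """Arc-length gaps between consecutive branch points on the given axes."""
    if axis_ids is None:
        axis_ids = [r.id for r in system.axes()]
    gaps = []
    for aid in axis_ids:
        arcs = sorted(bp.arc for bp in system.roots[aid].branch_points)
        gaps.extend(np.diff(arcs))
        if arcs:
            gaps.append(arcs[0])  # seed-to-first gap equals the spacing too
    return np.asarray(gaps)


def insertion_angles(system: RootSystem) -> np.ndarray:
    """Angle (deg) between each lateral's first segment and its parent's
    local direction at the branch point, measured from the geometry."""
    out = []
    for r in system.roots.values():
        if r.parent is None or len(r.points) < 2:
            continue
        d = np.asarray(r.points[1]) - np.asarray(r.points[0])
        nd = np.linalg.norm(d)
        if nd == 0:
            continue
        pdir = system.roots[r.parent].direction_at_arc(r.branch_arc)
        cosang = float(np.clip(np.dot(d / nd, pdir), -1.0, 1.0))
        out.append(np.degrees(np.arccos(cosang)))
    return np.asarray(out)


def first_lateral_delay(system: RootSystem, axis_id: int) -> float:
    """Days between an axis's emergence and its first lateral's germination."""
    root = system.roots[axis_id]
    children = [system.roots[bp.child] for bp in root.branch_points
                if bp.child is not None]
    if not children:
        raise ValueError(f"axis {axis_id} has no germinated lateral")
    first = min(children, key=lambda c: c.birth_time)
    return first.birth_time - root.birth_time
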