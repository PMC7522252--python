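"""RSML (Root System Markup Language) reading and writing.

Root architectures are exchanged as RSML, the community XML format:
``rsml > scene > plant > root`` with nested child roots, per-root
``geometry/polyline`` coordinates and a ``node_time`` function carrying the
time at which the tip reached each vertex.  Order and the arc position of a
lateral on its parent are stored as root properties, which makes the
write/read cycle lossless for geometry, topology, order and birth times.
Coordinates are written in cm with full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from lxml import etree

from .rootsys import BranchPoint, Root, RootSystem, TopologyError

__all__ = ["write_rsml", "read_rsml", "RSMLParseError"]


class RSMLParseError(ValueError):
    """Malformed RSML input; message carries the offending location."""


def _root_element(system: RootSystem, root: Root, children: dict) -> etree._Element:
    el = etree.Element("root", ID=str(root.id), label=f"root_{root.id}")
    props = etree.SubElement(el, "properties")
    for name, value in (("order", root.order),
                        ("birth_time", root.birth_time),
                        ("branch_arc", root.branch_arc)):
        etree.SubElement(props, "property", name=name, value=repr(value))
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for p in root.points:
        etree.SubElement(poly, "point", x=repr(float(p[0])), y=repr(float(p[1])))
    fns = etree.SubElement(el, "functions")
    fn = etree.SubElement(fns, "function", name="node_time", domain="polyline")
    for t in root.times:
        etree.SubElement(fn, "sample", value=repr(float(t)))
    for child in children.get(root.id, []):
        el.append(_root_element(system, child, children))
    return el


def write_rsml(system: RootSystem, path) -> None:
    """Write a root system to an RSML file."""
    system.validate()
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "cm"
    etree.SubElement(meta, "software").text = "rhizosim"
    prop = etree.SubElement(meta, "property-definitions")
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", ID="1", label="plant")
    plant.set("seed_x", repr(float(system.seed[0])))
    plant.set("seed_y", repr(float(system.seed[1])))
    plant.set("radius", repr(float(system.radius)))
    children: dict[int, list[Root]] = {}
    for r in system.roots.values():
        if r.parent is not None:
            children.setdefault(r.parent, []).append(r)
    for lst in children.values():
        lst.sort(key=lambda r: r.id)
    for axis in sorted(system.axes(), key=lambda r: r.id):
        plant.append(_root_element(system, axis, children))
    tree = etree.ElementTree(rsml)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def _parse_root(el, parent_id, out: list) -> None:
    try:
        rid = int(el.get("ID"))
    except (TypeError, ValueError):
        raise RSMLParseError(f"root element without integer ID near line "
                             f"{el.sourceline}")
    props = {p.get("name"): p.get("value")
             for p in el.findall("./properties/property")}
    pts = [(float(p.get("x")), float(p.get("y")))
           for p in el.findall("./geometry/polyline/point")]
    if not pts:
        raise RSMLParseError(f"root {rid} has an empty polyline "
                             f"(line {el.sourceline})")
    times = [float(s.get("value")) for s in el.findall(
        "./functions/function[@name='node_time']/sample")]
    if times and len(times) != len(pts):
        raise RSMLParseError(f"root {rid}: node_time sample count "
                             f"{len(times)} != point count {len(pts)}")
    order = int(float(props.get("order", 1 if parent_id is None else 2)))
    birth = float(props.get("birth_time", times[0] if times else 0.0))
    if not times:
        times = [birth] * len(pts)
    # an explicit parent property (flat files) overrides XML nesting
    pid = props.get("parent")
    pid = int(float(pid)) if pid is not None else parent_id
    out.append(dict(id=rid, parent=pid, order=order, birth=birth,
                    branch_arc=float(props.get("branch_arc", 0.0)),
                    points=pts, times=times))
    for child in el.findall("./root"):
        _parse_root(child, rid, out)


def read_rsml(path) -> RootSystem:
    """Read an RSML file back into a :class:`RootSystem`.

    Rejects malformed XML and cyclic parent links with the offending ids.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise RSMLParseError(f"malformed XML: {exc}") from exc
    rsml = tree.getroot()
    plant = rsml.find("./scene/plant")
    if plant is None:
        raise RSMLParseError("missing scene/plant element")
    seed = (float(plant.get("seed_x", "0.0")), float(plant.get("seed_y", "0.0")))
    radius = float(plant.get("radius", "0.03"))
    raw: list[dict] = []
    for el in plant.findall("./root"):
        _parse_root(el, None, raw)
    system = RootSystem(seed, radius=radius)
    for rec in raw:
        root = Root(id=rec["id"], order=rec["order"], birth_time=rec["birth"],
                    parent=rec["parent"], branch_arc=rec["branch_arc"],
                    points=[np.asarray(p, dtype=float) for p in rec["points"]],
                    times=list(rec["times"]))
        if root.id in system.roots:
            raise RSMLParseError(f"duplicate root id {root.id}")
        system.roots[root.id] = root
    if system.roots:
        system._next_id = max(system.roots) + 1
    try:
        system.validate()
    except TopologyError as exc:
        raise RSMLParseError(str(exc)) from exc
    # rebuild branch-point records from child attachments
    for r in system.roots.values():
        if r.parent is not None:
            parent = system.roots[r.parent]
            parent.branch_points.append(BranchPoint(
                arc=r.branch_arc, pos=parent.point_at_arc(r.branch_arc),
                create_time=r.birth_time, activation_time=r.birth_time,
                side=0, parent_dir=np.array([0.0, -1.0]), child=r.id))
    for r in system.roots.values():
        r.branch_points.sort(key=lambda bp: bp.arc)
    return system
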