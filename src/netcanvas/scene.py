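"""Scene assembly: network/tree + layout + style -> ordered draw primitives.

A :class:`Scene` is the renderer-facing contract: an ordered list of
primitives (``marker`` | ``path`` | ``polygon`` | ``text``), each tagged with
the element it came from and carrying a fully resolved style. Two coordinate
spaces coexist, mirroring how charting libraries keep marker size constant
under zoom:

* positions (marker centres, path segments, polygon rings, label anchors)
  are **data units** and scale with the layout;
* size-like properties (marker size, line width, arrow dimensions, label font
  size) are **figure units** (points at export) and are invariant under zoom.

Primitive order is deterministic: zorder class (grouping < cascade < edge <
arrow < vertex < label), then element index — so two assemblies of identical
inputs serialise byte-identically, which is the equality surface used by the
provider-equivalence guarantee. In 3D, primitives are painter-sorted
far-to-near by depth before the class ordering applies among equal depths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .colors import to_rgb
from .core import LayoutResult, NetworkData, TreeData, validate_layout
from .errors import NodeLookupError, StructuralError
from .geometry import (
    ArcSegment,
    CubicSegment,
    LineSegment,
    Path,
    arc_path,
    arrowhead,
    bezier_path,
    elbow_corner_fraction,
    elbow_path,
    loop_path,
    ports_path,
    split_path,
    straight_path,
    waypoint_path,
)
from .style import flatten_style, get_default_style, resolve_element
from .treelayout import TreeLayoutOptions, leaf_segment, radial_angles

__all__ = [
    "Primitive",
    "Scene",
    "GroupingSpec",
    "assemble_scene",
    "depth_shade",
    "group_hull",
    "cascade_patch",
    "scale_scene",
    "zoom_transform_check",
    "scene_to_json",
    "scene_from_json",
]

ZORDER_CLASSES = {
    "grouping": 0,
    "cascade": 1,
    "edge": 2,
    "arrow": 3,
    "vertex": 4,
    "vertex_label": 5,
    "edge_label": 5,
}

#: style properties that live in figure space (invariant under zoom), per role
FIGURE_SPACE_PROPS = {
    "vertex": ("size", "linewidth"),
    "edge": ("linewidth",),
    "arrow": ("width", "length"),
    "vertex_label": ("size", "hoffset", "voffset"),
    "edge_label": ("size", "hoffset", "voffset"),
    "grouping": (),
    "cascade": (),
}


@dataclass(frozen=True, slots=True)
class Primitive:
    kind: str  # marker | path | polygon | text
    role: str  # vertex | edge | arrow | grouping | cascade | vertex_label | edge_label
    index: int
    element: object
    geometry: dict
    style: dict
    z: float | None = None


@dataclass
class Scene:
    primitives: list[Primitive]
    ndim: int = 2
    colorbar: dict | None = None

    def by_role(self, role: str) -> list[Primitive]:
        return [p for p in self.primitives if p.role == role]

    def __eq__(self, other):
        if not isinstance(other, Scene):
            return NotImplemented
        return scene_to_json(self) == scene_to_json(other)


@dataclass(frozen=True)
class GroupingSpec:
    """Vertex grouping drawn as hulls: a partition (clustering) or a cover."""

    groups: Mapping[Hashable, frozenset]
    mode: str = "partition"

    def __post_init__(self):
        if self.mode not in ("partition", "cover"):
            raise StructuralError(f"grouping mode must be partition|cover, got {self.mode!r}")

    def validate(self, vertex_ids: Sequence[Hashable]) -> None:
        vertex_set = set(vertex_ids)
        for gid, members in self.groups.items():
            unknown = set(members) - vertex_set
            if unknown:
                raise NodeLookupError(f"group {gid!r} references unknown vertices {unknown!r}")
        if self.mode == "partition":
            seen: set = set()
            for members in self.groups.values():
                overlap = seen & set(members)
                if overlap:
                    raise StructuralError(f"partition groups overlap on {overlap!r}")
                seen |= set(members)
            if seen != vertex_set:
                raise StructuralError("partition groups must cover every vertex")


# ---------------------------------------------------------------------------
# Primitive-level operations
# ---------------------------------------------------------------------------

def depth_shade(base_colour, z: float, zmin: float, zmax: float, floor: float = 0.3):
    """Dim a colour with depth: nearest (z = zmax) unchanged, farthest dimmed
    to *floor*. z outside [zmin, zmax] is clamped. Monotone in z per channel.
    """
    if not zmin < zmax:
        raise StructuralError("depth_shade requires zmin < zmax")
    if not 0.0 < floor <= 1.0:
        raise StructuralError("floor must be in (0, 1]")
    z = min(max(z, zmin), zmax)
    factor = floor + (1.0 - floor) * (z - zmin) / (zmax - zmin)
    rgb = to_rgb(base_colour)
    if rgb is None:
        return None
    return tuple(channel * factor for channel in rgb)


def group_hull(points: Sequence, padding: float = 0.0, rounding: bool = True) -> list[tuple]:
    """Convex hull of *points* dilated outward by *padding* (data units).

    Returns the closed exterior ring (first point repeated last). With
    padding > 0 every input point is strictly inside. Rounded joins when
    *rounding*, mitred otherwise.
    """
    import shapely

    pts = [tuple(float(c) for c in p[:2]) for p in points]
    if not pts:
        raise StructuralError("group_hull needs at least one point")
    if padding < 0:
        raise StructuralError("padding must be >= 0")
    hull = shapely.MultiPoint(pts).convex_hull
    if padding > 0:
        join = "round" if rounding else "mitre"
        hull = hull.buffer(padding, quad_segs=32, join_style=join)
    if hull.geom_type == "Polygon":
        ring = list(hull.exterior.coords)
    elif hull.geom_type == "LineString":
        ring = list(hull.coords) + list(hull.coords)[::-1]
    else:  # Point (single input, padding 0)
        ring = [pts[0], pts[0]]
    return [tuple(p) for p in ring]


def cascade_patch(
    tree: TreeData,
    node: Hashable,
    layout: LayoutResult,
    kind: str,
    extent_to: str = "leaves",
    orientation: str = "right",
    tree_opts: TreeLayoutOptions | None = None,
) -> Path:
    """Closed patch behind the subtree rooted at *node*.

    Rectangular: an axis-aligned band over the subtree's cross-axis range
    (leaf segment +- half a leaf spacing) from the node's main-axis coordinate
    out to the farthest leaf (``extent_to='leaves'``) or the subtree's own
    maximum (``extent_to='subtree'``). Radial: the corresponding annular
    sector between the node's radius and the outer radius.
    """
    if node not in tree.children:
        raise NodeLookupError(f"unknown node {node!r}")
    if extent_to not in ("leaves", "subtree"):
        raise StructuralError(f"extent_to must be leaves|subtree, got {extent_to!r}")
    first, last = leaf_segment(tree, node)

    subtree_nodes = []
    stack = [node]
    while stack:
        current = stack.pop()
        subtree_nodes.append(current)
        stack.extend(tree.children[current])

    if kind == "rectangular":
        axis_main, sign_main, axis_cross = {
            "right": (0, 1.0, 1),
            "left": (0, -1.0, 1),
            "up": (1, 1.0, 0),
            "down": (1, -1.0, 0),
        }[orientation]
        main_of = {n: layout.coords[n][axis_main] * sign_main for n in tree.nodes}
        main_lo = main_of[node]
        if extent_to == "leaves":
            main_hi = max(main_of[leaf] for leaf in tree.leaf_order)
        else:
            main_hi = max(main_of[n] for n in subtree_nodes)
        if main_hi == main_lo:
            main_hi = main_lo + 1e-9  # degenerate (node is the farthest tip)
        cross_lo, cross_hi = first - 0.5, last + 0.5

        def to_xy(main, cross):
            main = main * sign_main
            return (main, cross) if axis_main == 0 else (cross, main)

        corners = [
            to_xy(main_lo, cross_lo),
            to_xy(main_hi, cross_lo),
            to_xy(main_hi, cross_hi),
            to_xy(main_lo, cross_hi),
        ]
        segments = [
            LineSegment(corners[i], corners[(i + 1) % 4]) for i in range(4)
        ]
        return Path(segments, closed=True)

    if kind == "radial":
        opts = tree_opts or TreeLayoutOptions(kind="radial")
        angles = radial_angles(tree, opts)
        step = opts.angular_span / tree.n_leaves
        theta_lo = opts.start_angle + first * step - step / 2.0
        theta_hi = opts.start_angle + last * step + step / 2.0
        radius_of = {
            n: float(math.hypot(*layout.coords[n][:2])) for n in tree.nodes
        }
        r_inner = radius_of[node]
        if extent_to == "leaves":
            r_outer = max(radius_of[leaf] for leaf in tree.leaf_order)
        else:
            r_outer = max(radius_of[n] for n in subtree_nodes)
        if r_outer <= r_inner:
            r_outer = r_inner + 1e-9
        del angles  # angles of internal nodes not needed beyond validation
        origin = (0.0, 0.0)
        p_inner_lo = (r_inner * math.cos(theta_lo), r_inner * math.sin(theta_lo))
        p_outer_hi = (r_outer * math.cos(theta_hi), r_outer * math.sin(theta_hi))
        segments = []
        if r_inner > 0:
            segments.append(ArcSegment(origin, r_inner, theta_hi, theta_lo))
            segments.append(
                LineSegment(p_inner_lo, (r_outer * math.cos(theta_lo), r_outer * math.sin(theta_lo)))
            )
        else:
            segments.append(
                LineSegment(origin, (r_outer * math.cos(theta_lo), r_outer * math.sin(theta_lo)))
            )
        segments.append(ArcSegment(origin, r_outer, theta_lo, theta_hi))
        if r_inner > 0:
            segments.append(LineSegment(p_outer_hi, tuple(ArcSegment(origin, r_inner, theta_hi, theta_lo).point(0.0))))
        else:
            segments.append(LineSegment(p_outer_hi, origin))
        return Path(segments, closed=True)

    raise StructuralError(f"unknown cascade kind {kind!r}")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _rgb(style: dict, key: str, cache: dict) -> None:
    value = style.get(key)
    if value is None or isinstance(value, tuple) and len(value) == 3 and all(
        isinstance(c, float) for c in value
    ):
        return
    if isinstance(value, (tuple, list)):
        style[key] = to_rgb(value)
        return
    if value not in cache:
        cache[value] = to_rgb(value)
    style[key] = cache[value]


def _edge_elements(data: NetworkData | TreeData):
    """Uniform (source, target, element_id) edge view for networks and trees."""
    if isinstance(data, TreeData):
        return [
            (data.parent[n], n, n) for n in data.nodes if n != data.root
        ]
    return [(s, t, i) for i, (s, t) in enumerate(data.edges)]


def _has_per_element(props: Mapping) -> bool:
    from .style import SEQUENCE_VALUED

    for prop, value in props.items():
        if isinstance(value, Mapping):
            return True
        if prop not in SEQUENCE_VALUED and isinstance(value, (list, tuple)):
            return True
    return False


def _build_edge_path(source_xy, target_xy, estyle, tree_kind, orientation):
    geometry = estyle.get("geometry", "straight")
    if geometry == "straight":
        return straight_path(source_xy, target_xy)
    if geometry == "arc":
        return arc_path(source_xy, target_xy, float(estyle.get("tension") or 0.0))
    if geometry == "bezier":
        controls = estyle.get("control_points")
        if not controls:
            return straight_path(source_xy, target_xy)
        return bezier_path(source_xy, target_xy, controls)
    if geometry == "ports":
        ports = estyle.get("ports")
        if not ports:
            return straight_path(source_xy, target_xy)
        return ports_path(source_xy, target_xy, float(ports[0]), float(ports[1]))
    if geometry == "waypoints":
        waypoints = estyle.get("waypoints")
        if not waypoints:
            return straight_path(source_xy, target_xy)
        return waypoint_path(source_xy, target_xy, waypoints)
    if geometry == "elbow":
        return elbow_path(
            source_xy, target_xy, tree_kind or "rectangular", orientation=orientation
        )
    raise StructuralError(f"unknown edge geometry {geometry!r}")


def _loop_angle(vertex, coords, neighbours) -> float:
    """Default loop direction: away from the centroid of the neighbours."""
    own = np.asarray(coords[vertex][:2], dtype=float)
    others = [np.asarray(coords[n][:2], dtype=float) for n in neighbours if n != vertex]
    if not others:
        return math.pi / 2.0
    centroid = np.mean(others, axis=0)
    away = own - centroid
    if np.linalg.norm(away) < 1e-12:
        return math.pi / 2.0
    return math.atan2(away[1], away[0])


def _serialise_segment(seg) -> dict:
    if seg.kind == "line":
        return {"kind": "line", "points": [list(seg.p0), list(seg.p1)]}
    if seg.kind == "cubic":
        return {
            "kind": "cubic",
            "points": [list(seg.p0), list(seg.c1), list(seg.c2), list(seg.p1)],
        }
    return {
        "kind": "arc",
        "center": list(seg.center),
        "radius": seg.radius,
        "theta0": seg.theta0,
        "theta1": seg.theta1,
    }


def _path_geometry(path: Path) -> dict:
    return {
        "segments": [_serialise_segment(seg) for seg in path.segments],
        "closed": path.closed,
    }


def assemble_scene(
    data: NetworkData | TreeData,
    layout: LayoutResult | Mapping,
    style: Mapping | None = None,
    grouping: GroupingSpec | None = None,
    tree_kind: str | None = None,
    orientation: str = "right",
    cascades: Sequence[Hashable] | None = None,
    tree_opts: TreeLayoutOptions | None = None,
    colorbar: dict | None = None,
) -> Scene:
    """Resolve data + layout + style into an ordered, deterministic Scene.

    ``style`` must be a flattened complete style (layer fragments over a
    built-in with :func:`flatten_style`); ``None`` means the "default"
    built-in ("tree" built-in for trees). One marker per vertex, one path
    (or split-subpath group) per edge, one polygon per group/cascade, one
    text per requested label.

    The cyclic garbage collector is paused while primitives are built (the
    scene graph is acyclic, and generational collection over a growing object
    graph would otherwise make bulk assembly superlinear in n + m).
    """
    import gc

    gc_was_enabled = gc.isenabled()
    if gc_was_enabled:
        gc.disable()
    try:
        return _assemble_scene(
            data,
            layout,
            style,
            grouping,
            tree_kind,
            orientation,
            cascades,
            tree_opts,
            colorbar,
        )
    finally:
        if gc_was_enabled:
            gc.enable()


def _assemble_scene(
    data,
    layout,
    style,
    grouping,
    tree_kind,
    orientation,
    cascades,
    tree_opts,
    colorbar,
) -> Scene:
    is_tree = isinstance(data, TreeData)
    if style is None:
        style = get_default_style("tree" if is_tree else "default")
    if not isinstance(layout, LayoutResult):
        layout = validate_layout(layout, data)
    else:
        layout = validate_layout(layout.coords, data)
    coords = layout.coords
    ndim = layout.ndim
    if is_tree and tree_kind is None:
        tree_kind = "rectangular"

    vertex_ids = data.nodes if is_tree else data.vertex_ids
    edge_elements = _edge_elements(data)

    colour_cache: dict = {}
    zspan = None
    if ndim == 3:
        zs = [coords[v][2] for v in vertex_ids]
        zmin, zmax = min(zs), max(zs)
        if zmin < zmax:
            zspan = (zmin, zmax)

    def shade(style_dict, key, depth):
        if zspan is not None and depth is not None and style_dict.get(key) is not None:
            style_dict[key] = depth_shade(style_dict[key], depth, *zspan)

    groups_prims: list[Primitive] = []
    cascade_prims: list[Primitive] = []
    edge_prims: list[Primitive] = []
    arrow_prims: list[Primitive] = []
    vertex_prims: list[Primitive] = []
    label_prims: list[Primitive] = []

    # --- grouping hulls ----------------------------------------------------
    if grouping is not None:
        grouping.validate(vertex_ids)
        for gindex, (gid, members) in enumerate(grouping.groups.items()):
            gstyle = resolve_element(style, "grouping", gindex, gid)
            _rgb(gstyle, "facecolor", colour_cache)
            ring = group_hull(
                [coords[v] for v in members],
                padding=float(gstyle.get("padding", 0.0)),
                rounding=bool(gstyle.get("rounding", True)),
            )
            groups_prims.append(
                Primitive(
                    kind="polygon",
                    role="grouping",
                    index=gindex,
                    element=_jsonable(gid),
                    geometry={"points": [list(p) for p in ring]},
                    style=gstyle,
                )
            )

    # --- cascade patches (trees only) -------------------------------------
    if cascades:
        if not is_tree:
            raise StructuralError("cascade patches require a tree")
        for cindex, node in enumerate(cascades):
            cstyle = resolve_element(style, "cascade", cindex, node)
            _rgb(cstyle, "facecolor", colour_cache)
            patch = cascade_patch(
                data,
                node,
                layout,
                tree_kind,
                extent_to=cstyle.get("extent", "leaves"),
                orientation=orientation,
                tree_opts=tree_opts,
            )
            cascade_prims.append(
                Primitive(
                    kind="polygon",
                    role="cascade",
                    index=cindex,
                    element=_jsonable(node),
                    geometry=_path_geometry(patch),
                    style=cstyle,
                )
            )

    # --- edges -------------------------------------------------------------
    edge_props = style.get("edge", {})
    loop_props = style.get("loop", {})
    arrow_props = style.get("arrow", {})
    uniform_edges = not _has_per_element(edge_props)
    shared_estyle = (
        resolve_element(style, "edge", 0, None) if uniform_edges else None
    )
    if shared_estyle is not None:
        _rgb(shared_estyle, "color", colour_cache)
    uniform_arrows = not _has_per_element(arrow_props)
    shared_astyle = (
        resolve_element(style, "arrow", 0, None) if uniform_arrows else None
    )

    neighbour_map: dict | None = None

    # Fast path: undirected straight edges with a shared style need no Path
    # objects at all, keeping assembly linear with a small constant.
    if (
        uniform_edges
        and ndim == 2
        and not is_tree
        and shared_estyle is not None
        and shared_estyle.get("geometry", "straight") == "straight"
        and not shared_estyle.get("split_colors")
        and not (not is_tree and data.directed)
    ):
        loop_indices = []
        append = edge_prims.append
        for eindex, (source, target, eid) in enumerate(edge_elements):
            if source == target:
                loop_indices.append((eindex, source, eid))
                continue
            x0, y0 = coords[source][0], coords[source][1]
            x1, y1 = coords[target][0], coords[target][1]
            append(
                Primitive(
                    kind="path",
                    role="edge",
                    index=eindex,
                    element=_jsonable(eid),
                    geometry={
                        "segments": [
                            {"kind": "line", "points": [[x0, y0], [x1, y1]]}
                        ],
                        "closed": False,
                    },
                    style=shared_estyle,
                )
            )
        for eindex, vertex, eid in loop_indices:
            lstyle = resolve_element(style, "loop", eindex, eid)
            angle = lstyle.get("angle")
            if angle is None:
                if neighbour_map is None:
                    neighbour_map = {}
                    for s, t, _ in edge_elements:
                        neighbour_map.setdefault(s, []).append(t)
                        neighbour_map.setdefault(t, []).append(s)
                angle = _loop_angle(vertex, coords, neighbour_map.get(vertex, []))
            path = loop_path(
                coords[vertex][:2], float(lstyle.get("size", 0.25)), float(angle)
            )
            edge_prims.append(
                Primitive(
                    kind="path",
                    role="edge",
                    index=eindex,
                    element=_jsonable(eid),
                    geometry=_path_geometry(path),
                    style=shared_estyle,
                )
            )
        edge_prims.sort(key=lambda p: p.index)
        edge_elements_iter = []
    else:
        edge_elements_iter = edge_elements

    for eindex, (source, target, eid) in enumerate(edge_elements_iter):
        if uniform_edges and zspan is None:
            estyle = shared_estyle
        else:
            estyle = resolve_element(style, "edge", eindex, eid)
            _rgb(estyle, "color", colour_cache)
        p_source = coords[source]
        p_target = coords[target]
        depth = None
        if ndim == 3:
            depth = 0.5 * (p_source[2] + p_target[2])
            estyle = dict(estyle)
            shade(estyle, "color", depth)

        if source == target:
            lstyle = resolve_element(style, "loop", eindex, eid)
            angle = lstyle.get("angle")
            if angle is None:
                if neighbour_map is None:
                    neighbour_map = {}
                    for s, t, _ in edge_elements:
                        neighbour_map.setdefault(s, []).append(t)
                        neighbour_map.setdefault(t, []).append(s)
                angle = _loop_angle(source, coords, neighbour_map.get(source, []))
            path = loop_path(
                p_source[:2], float(lstyle.get("size", 0.25)), float(angle)
            )
        elif ndim == 3:
            path = Path([LineSegment(tuple(p_source), tuple(p_target))])
        else:
            path = _build_edge_path(
                p_source[:2], p_target[:2], estyle, tree_kind, orientation
            )

        split_colors = estyle.get("split_colors")
        if split_colors:
            fractions = elbow_corner_fraction(path)
            if not fractions:
                k = len(split_colors)
                fractions = [i / k for i in range(1, k)]
            pieces = split_path(path, fractions)
            for sub_i, piece in enumerate(pieces):
                sub_style = dict(estyle)
                sub_style["color"] = to_rgb(split_colors[sub_i % len(split_colors)])
                sub_style.pop("split_colors", None)
                edge_prims.append(
                    Primitive(
                        kind="path",
                        role="edge",
                        index=eindex,
                        element=[_jsonable(eid), sub_i],
                        geometry=_path_geometry(piece),
                        style=sub_style,
                        z=depth,
                    )
                )
        else:
            edge_prims.append(
                Primitive(
                    kind="path",
                    role="edge",
                    index=eindex,
                    element=_jsonable(eid),
                    geometry=_path_geometry(path),
                    style=estyle,
                    z=depth,
                )
            )

        if (not is_tree) and data.directed:
            astyle = shared_astyle if (uniform_arrows and zspan is None) else resolve_element(style, "arrow", eindex, eid)
            tangent = path.tangent_at(1.0)
            angle = math.atan2(tangent[1], tangent[0])
            arrow_prims.append(
                Primitive(
                    kind="polygon",
                    role="arrow",
                    index=eindex,
                    element=_jsonable(eid),
                    geometry={"xy": list(path.end[:2]), "angle": angle},
                    style=astyle,
                    z=depth,
                )
            )

    # --- vertices ----------------------------------------------------------
    vertex_props = style.get("vertex", {})
    uniform_vertices = not _has_per_element(vertex_props)
    shared_vstyle = (
        resolve_element(style, "vertex", 0, None) if uniform_vertices else None
    )
    if shared_vstyle is not None:
        _rgb(shared_vstyle, "facecolor", colour_cache)
        _rgb(shared_vstyle, "edgecolor", colour_cache)
    for vindex, vid in enumerate(vertex_ids):
        if uniform_vertices and zspan is None:
            vstyle = shared_vstyle
        else:
            vstyle = resolve_element(style, "vertex", vindex, vid)
            _rgb(vstyle, "facecolor", colour_cache)
            _rgb(vstyle, "edgecolor", colour_cache)
        depth = coords[vid][2] if ndim == 3 else None
        if ndim == 3:
            vstyle = dict(vstyle)
            shade(vstyle, "facecolor", depth)
        vertex_prims.append(
            Primitive(
                kind="marker",
                role="vertex",
                index=vindex,
                element=_jsonable(vid),
                geometry={"xy": list(coords[vid])},
                style=vstyle,
                z=depth,
            )
        )

    # --- labels ------------------------------------------------------------
    if style.get("vertex_label", {}).get("text") is not None:
        for vindex, vid in enumerate(vertex_ids):
            lstyle = resolve_element(style, "vertex_label", vindex, vid)
            text = lstyle.pop("text", None)
            if text is None:
                continue
            if text == "id":
                text = str(vid)
            _rgb(lstyle, "color", colour_cache)
            label_prims.append(
                Primitive(
                    kind="text",
                    role="vertex_label",
                    index=vindex,
                    element=_jsonable(vid),
                    geometry={"xy": list(coords[vid]), "text": str(text)},
                    style=lstyle,
                    z=coords[vid][2] if ndim == 3 else None,
                )
            )
    if style.get("edge_label", {}).get("text") is not None:
        for eindex, (source, target, eid) in enumerate(edge_elements):
            lstyle = resolve_element(style, "edge_label", eindex, eid)
            text = lstyle.pop("text", None)
            if text is None:
                continue
            _rgb(lstyle, "color", colour_cache)
            mid = 0.5 * (
                np.asarray(coords[source][:2]) + np.asarray(coords[target][:2])
            )
            label_prims.append(
                Primitive(
                    kind="text",
                    role="edge_label",
                    index=eindex,
                    element=_jsonable(eid),
                    geometry={"xy": [float(mid[0]), float(mid[1])], "text": str(text)},
                    style=lstyle,
                )
            )

    primitives = (
        groups_prims + cascade_prims + edge_prims + arrow_prims + vertex_prims + label_prims
    )
    if ndim == 3:
        # painter's algorithm: far-to-near, zorder class among equal depths
        primitives.sort(
            key=lambda p: (
                round(p.z, 9) if p.z is not None else float("-inf"),
                ZORDER_CLASSES[p.role],
                p.index,
            )
        )
    return Scene(primitives=primitives, ndim=ndim, colorbar=colorbar)


def _jsonable(value):
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return str(value)


# ---------------------------------------------------------------------------
# Zoom contract and serialisation
# ---------------------------------------------------------------------------

def _scale_geometry(geometry: dict, scale: float) -> dict:
    out = {}
    for key, value in geometry.items():
        if key in ("xy", "center"):
            out[key] = [c * scale for c in value]
        elif key == "points":
            out[key] = [[c * scale for c in p] for p in value]
        elif key == "segments":
            out[key] = [_scale_geometry(seg, scale) for seg in value]
        elif key == "radius":
            out[key] = value * scale
        else:  # kind, closed, theta0/theta1, angle, text: scale-invariant
            out[key] = value
    return out


def scale_scene(scene: Scene, scale: float) -> Scene:
    """Rescale every data-space coordinate; figure-space attributes untouched.

    This is the zoom operation of the dual coordinate contract.
    """
    if scale <= 0:
        raise StructuralError("scale must be positive")
    primitives = [
        Primitive(
            kind=p.kind,
            role=p.role,
            index=p.index,
            element=p.element,
            geometry=_scale_geometry(p.geometry, scale),
            style=p.style,
            z=p.z * scale if p.z is not None else None,
        )
        for p in scene.primitives
    ]
    return Scene(primitives=primitives, ndim=scene.ndim, colorbar=scene.colorbar)


def zoom_transform_check(scene: Scene, scale: float, atol: float = 0.0) -> bool:
    """True iff zooming by *scale* leaves every figure-space attribute
    unchanged while scaling every data-space coordinate exactly.
    """
    zoomed = scale_scene(scene, scale)
    for before, after in zip(scene.primitives, zoomed.primitives):
        if before.style is not after.style and before.style != after.style:
            return False
        for prop in FIGURE_SPACE_PROPS.get(before.role, ()):
            if before.style.get(prop) != after.style.get(prop):
                return False
        if not _geometry_scaled(before.geometry, after.geometry, scale, atol):
            return False
    return True


def _geometry_scaled(before: dict, after: dict, scale: float, atol: float) -> bool:
    for key, value in before.items():
        if key in ("xy", "center"):
            if any(abs(b * scale - a) > atol for b, a in zip(value, after[key])):
                return False
        elif key == "points":
            for bp, ap in zip(value, after[key]):
                if any(abs(b * scale - a) > atol for b, a in zip(bp, ap)):
                    return False
        elif key == "segments":
            if not all(
                _geometry_scaled(bs, as_, scale, atol)
                for bs, as_ in zip(value, after[key])
            ):
                return False
        elif key == "radius":
            if abs(value * scale - after[key]) > atol:
                return False
        else:
            if value != after[key]:
                return False
    return True


def _round9(obj):
    """Normalise floats to 9 significant digits for deterministic JSON."""
    if isinstance(obj, float):
        if obj == 0.0:
            return 0.0  # collapse -0.0
        return float(f"{obj:.9g}")
    if isinstance(obj, dict):
        return {k: _round9(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round9(v) for v in obj]
    if isinstance(obj, np.floating):
        return _round9(float(obj))
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def scene_to_json(scene: Scene) -> str:
    """Deterministic serialisation: sorted keys, floats at 9 significant
    digits. Byte-equality of this form is the scene-equality surface."""
    payload = {
        "ndim": scene.ndim,
        "colorbar": scene.colorbar,
        "primitives": [
            {
                "kind": p.kind,
                "role": p.role,
                "index": p.index,
                "element": p.element,
                "geometry": p.geometry,
                "style": p.style,
                "z": p.z,
            }
            for p in scene.primitives
        ],
    }
    return json.dumps(_round9(payload), sort_keys=True, separators=(",", ":"))


def scene_from_json(text: str) -> Scene:
    payload = json.loads(text)
    primitives = [
        Primitive(
            kind=entry["kind"],
            role=entry["role"],
            index=entry["index"],
            element=entry["element"],
            geometry=entry["geometry"],
            style=entry["style"],
            z=entry["z"],
        )
        for entry in payload["primitives"]
    ]
    return Scene(
        primitives=primitives, ndim=payload["ndim"], colorbar=payload["colorbar"]
    )
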