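"""Rectangular and radial embeddings of rooted trees.

These are the only layouts the package computes itself; general network
layouts are consumed from providers or passed in explicitly. Conventions
(stated once, used everywhere, including edge ports and loops):

* leaves are spaced 1 data unit apart on the cross axis (rectangular) or by
  ``angular_span / n_leaves`` in angle (radial) — dividing by L rather than
  L - 1 reserves one closing gap so the first and last leaf never collide on
  a full circle;
* an internal node sits at the plain arithmetic mean of its children's cross
  coordinates / angles (no subtree-size weighting);
* the main-axis coordinate (or radius) is the cumulative branch length from
  the root, or the integer depth when ``use_branch_lengths`` is false;
* angles are radians, counterclockwise from the positive x axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable

from .core import LayoutResult, TreeData
from .errors import NodeLookupError, StructuralError

__all__ = [
    "TreeLayoutOptions",
    "layout_rectangular",
    "layout_radial",
    "layout_tree",
    "leaf_segment",
]

_TAU = 2.0 * math.pi


@dataclass(frozen=True)
class TreeLayoutOptions:
    """Layout knobs shared by the rectangular and radial embeddings.

    orientation (rectangular only) maps (main, cross) onto (x, y):
    ``right`` -> (main, cross); ``left`` -> (-main, cross);
    ``up`` -> (cross, main); ``down`` -> (cross, -main).
    """

    kind: str = "rectangular"
    use_branch_lengths: bool = True
    orientation: str = "right"
    angular_span: float = _TAU
    start_angle: float = 0.0

    def __post_init__(self):
        if self.kind not in ("rectangular", "radial"):
            raise StructuralError(f"unknown tree layout kind {self.kind!r}")
        if self.orientation not in ("right", "left", "up", "down"):
            raise StructuralError(f"unknown orientation {self.orientation!r}")
        if not 0.0 < self.angular_span <= _TAU + 1e-12:
            raise StructuralError("angular_span must be in (0, 2*pi]")


def _cross_coordinates(tree: TreeData, spacing: float = 1.0) -> dict[Hashable, float]:
    """Leaf i -> i * spacing; internal node -> mean of its children (postorder)."""
    if tree.n_nodes == 0:
        raise StructuralError("cannot lay out an empty tree")
    cross: dict[Hashable, float] = {
        leaf: i * spacing for i, leaf in enumerate(tree.leaf_order)
    }
    for node in tree.postorder():
        kids = tree.children[node]
        if kids:
            cross[node] = sum(cross[k] for k in kids) / len(kids)
    return cross


def layout_rectangular(tree: TreeData, opts: TreeLayoutOptions | None = None) -> LayoutResult:
    """Rectangular ("phylogram") layout.

    Leaf *i* (in ``leaf_order``) has cross coordinate *i*; internal nodes take
    the mean of their children; the main coordinate is the cumulative branch
    length (or depth) from the root, which sits at 0.
    """
    opts = opts or TreeLayoutOptions(kind="rectangular")
    cross = _cross_coordinates(tree)
    main = tree.depth_from_root(opts.use_branch_lengths)
    coords = {}
    for node in tree.nodes:
        m, c = main[node], cross[node]
        if opts.orientation == "right":
            coords[node] = (m, c)
        elif opts.orientation == "left":
            coords[node] = (-m, c)
        elif opts.orientation == "up":
            coords[node] = (c, m)
        else:  # down
            coords[node] = (c, -m)
    return LayoutResult(coords=coords, ndim=2)


def radial_angles(tree: TreeData, opts: TreeLayoutOptions | None = None) -> dict[Hashable, float]:
    """Angle assignment used by the radial layout (exposed for elbow edges)."""
    opts = opts or TreeLayoutOptions(kind="radial")
    n_leaves = tree.n_leaves
    if n_leaves == 0:
        raise StructuralError("cannot lay out an empty tree")
    step = opts.angular_span / n_leaves
    angles: dict[Hashable, float] = {
        leaf: opts.start_angle + i * step for i, leaf in enumerate(tree.leaf_order)
    }
    for node in tree.postorder():
        kids = tree.children[node]
        if kids:
            angles[node] = sum(angles[k] for k in kids) / len(kids)
    return angles


def layout_radial(tree: TreeData, opts: TreeLayoutOptions | None = None) -> LayoutResult:
    """Radial ("fan") layout: radius = cumulative branch length, angle by leaf index."""
    opts = opts or TreeLayoutOptions(kind="radial")
    angles = radial_angles(tree, opts)
    radius = tree.depth_from_root(opts.use_branch_lengths)
    coords = {
        node: (
            radius[node] * math.cos(angles[node]),
            radius[node] * math.sin(angles[node]),
        )
        for node in tree.nodes
    }
    return LayoutResult(coords=coords, ndim=2)


def layout_tree(tree: TreeData, opts: TreeLayoutOptions) -> LayoutResult:
    if opts.kind == "rectangular":
        return layout_rectangular(tree, opts)
    return layout_radial(tree, opts)


def leaf_segment(tree: TreeData, node: Hashable) -> tuple[int, int]:
    """(first, last) index in ``leaf_order`` of the leaves under *node*.

    The range is contiguous because ``leaf_order`` is a depth-first traversal;
    cascade patches rely on this.
    """
    if node not in tree.children:
        raise NodeLookupError(f"unknown node {node!r}")
    index = {leaf: i for i, leaf in enumerate(tree.leaf_order)}
    if not tree.children[node]:
        return (index[node], index[node])
    leaves = []
    stack = [node]
    while stack:
        current = stack.pop()
        kids = tree.children[current]
        if not kids:
            leaves.append(index[current])
        else:
            stack.extend(kids)
    return (min(leaves), max(leaves))
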