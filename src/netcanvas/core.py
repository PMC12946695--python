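"""Canonical in-memory model: networks, rooted trees, and layouts.

Every input provider normalises into these containers and every downstream
stage (style resolution, edge geometry, scene assembly) consumes only them.
That single funnel is what guarantees identical rendering regardless of which
analysis library produced the graph.

Identity is by vertex/node label, never by index, but per-element styling maps
by *insertion order*: the edge list is an ordered sequence in which self-loops
and parallel edges are kept verbatim, each occupying its own style slot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .errors import (
    AttributeLengthError,
    LayoutCoverageError,
    LayoutDimensionError,
    LayoutValueError,
    NodeLookupError,
    StructuralError,
)

__all__ = [
    "NetworkData",
    "TreeData",
    "LayoutResult",
    "build_network",
    "build_tree",
    "validate_layout",
]


@dataclass(frozen=True)
class NetworkData:
    """An ordered vertex/edge container with optional per-element attributes.

    Attributes
    ----------
    vertex_ids:
        Unique hashable labels in a stable order; the order defines each
        vertex's style index.
    edges:
        Ordered ``(source, target)`` pairs. Self-loops and parallel edges are
        legal and keep their position (positional style identity).
    directed:
        Whether edges are directed (controls arrowheads downstream).
    vertex_attrs / edge_attrs:
        Mapping attribute name -> tuple of per-element values, aligned with
        ``vertex_ids`` / ``edges``.
    """

    vertex_ids: tuple[Hashable, ...]
    edges: tuple[tuple[Hashable, Hashable], ...]
    directed: bool = False
    vertex_attrs: Mapping[str, tuple] = field(default_factory=dict)
    edge_attrs: Mapping[str, tuple] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertex_index(self, vertex_id: Hashable) -> int:
        try:
            return self.vertex_ids.index(vertex_id)
        except ValueError as exc:
            raise NodeLookupError(f"unknown vertex {vertex_id!r}") from exc


@dataclass(frozen=True)
class TreeData:
    """A rooted tree with branch lengths and a deterministic leaf order.

    ``branch_length[node]`` is the length of the edge *above* the node (the
    root carries 0). ``leaf_order`` is the depth-first order of the leaves
    respecting each node's child order; tree layouts space leaves by this
    order, so it is part of the visual contract.
    """

    nodes: tuple[Hashable, ...]
    root: Hashable
    parent: Mapping[Hashable, Hashable]
    children: Mapping[Hashable, tuple[Hashable, ...]]
    branch_length: Mapping[Hashable, float]
    leaf_order: tuple[Hashable, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def is_leaf(self, node: Hashable) -> bool:
        if node not in self.children:
            raise NodeLookupError(f"unknown node {node!r}")
        return not self.children[node]

    def preorder(self) -> Iterable[Hashable]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children[node]))

    def postorder(self) -> Iterable[Hashable]:
        out: list[Hashable] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return reversed(out)

    def depth_from_root(self, use_branch_lengths: bool = True) -> dict[Hashable, float]:
        """Cumulative distance from the root to each node."""
        dist: dict[Hashable, float] = {self.root: 0.0}
        for node in self.preorder():
            if node == self.root:
                continue
            step = self.branch_length[node] if use_branch_lengths else 1.0
            dist[node] = dist[self.parent[node]] + step
        return dist


@dataclass(frozen=True)
class LayoutResult:
    """Vertex -> coordinate mapping in data units, tagged 2D or 3D."""

    coords: Mapping[Hashable, tuple[float, ...]]
    ndim: int

    def __post_init__(self):
        if self.ndim not in (2, 3):
            raise LayoutDimensionError(f"ndim must be 2 or 3, got {self.ndim}")

    def bounds(self) -> tuple[tuple[float, float], ...]:
        """(min, max) per axis over all coordinates."""
        cols = list(zip(*self.coords.values()))
        return tuple((min(c), max(c)) for c in cols)


def build_network(
    edges: Sequence[tuple[Hashable, Hashable]],
    vertex_ids: Sequence[Hashable] | None = None,
    directed: bool = False,
    vertex_attrs: Mapping[str, Sequence] | None = None,
    edge_attrs: Mapping[str, Sequence] | None = None,
) -> NetworkData:
    """Build a :class:`NetworkData` from an ordered edge list.

    When ``vertex_ids`` is omitted it defaults to the edge endpoints in
    first-appearance order. The edge sequence is preserved verbatim (order,
    multiplicity, self-loops).
    """
    edges = tuple((s, t) for s, t in edges)
    if vertex_ids is None:
        seen: dict[Hashable, None] = {}
        for s, t in edges:
            seen.setdefault(s)
            seen.setdefault(t)
        vertex_tuple = tuple(seen)
    else:
        vertex_tuple = tuple(vertex_ids)
        if len(set(vertex_tuple)) != len(vertex_tuple):
            raise StructuralError("vertex_ids contains duplicates")
        known = set(vertex_tuple)
        for s, t in edges:
            if s not in known or t not in known:
                raise StructuralError(
                    f"edge ({s!r}, {t!r}) references a vertex not in vertex_ids"
                )

    def _check_attrs(attrs, n, what):
        out = {}
        for name, values in (attrs or {}).items():
            values = tuple(values)
            if len(values) != n:
                raise AttributeLengthError(
                    f"{what} attribute {name!r} has {len(values)} values, expected {n}"
                )
            out[name] = values
        return out

    return NetworkData(
        vertex_ids=vertex_tuple,
        edges=edges,
        directed=bool(directed),
        vertex_attrs=_check_attrs(vertex_attrs, len(vertex_tuple), "vertex"),
        edge_attrs=_check_attrs(edge_attrs, len(edges), "edge"),
    )


def build_tree(
    parent_map: Mapping[Hashable, Hashable],
    branch_lengths: Mapping[Hashable, float] | None = None,
) -> TreeData:
    """Build a :class:`TreeData` from a child -> parent mapping.

    Children are ordered by the first appearance of each child in
    ``parent_map`` (insertion order of the mapping). Missing branch lengths
    default to 1.0, so topology-only trees still lay out.
    """
    if not parent_map:
        raise StructuralError("parent_map is empty")
    children: dict[Hashable, list[Hashable]] = {}
    nodes_seen: dict[Hashable, None] = {}
    for child, parent in parent_map.items():
        nodes_seen.setdefault(child)
        nodes_seen.setdefault(parent)
        children.setdefault(parent, []).append(child)
        children.setdefault(child, [])
    roots = [n for n in nodes_seen if n not in parent_map]
    if len(roots) != 1:
        raise StructuralError(
            f"tree must have exactly one root, found {len(roots)}: {roots!r}"
        )
    root = roots[0]

    # Preorder walk; also detects cycles / disconnection (unreached nodes).
    order: list[Hashable] = []
    stack = [root]
    visited: set[Hashable] = set()
    while stack:
        node = stack.pop()
        if node in visited:
            raise StructuralError(f"cycle detected at node {node!r}")
        visited.add(node)
        order.append(node)
        stack.extend(reversed(children[node]))
    if len(visited) != len(nodes_seen):
        missing = [n for n in nodes_seen if n not in visited]
        raise StructuralError(f"nodes unreachable from root {root!r}: {missing!r}")

    lengths: dict[Hashable, float] = {root: 0.0}
    for node in order:
        if node == root:
            continue
        value = 1.0 if branch_lengths is None else float(branch_lengths.get(node, 1.0))
        if value < 0:
            raise StructuralError(f"negative branch length for node {node!r}")
        lengths[node] = value

    leaf_order = tuple(n for n in order if not children[n])
    return TreeData(
        nodes=tuple(order),
        root=root,
        parent=dict(parent_map),
        children={n: tuple(c) for n, c in children.items()},
        branch_length=lengths,
        leaf_order=leaf_order,
    )


def validate_layout(
    layout: Mapping[Hashable, Sequence[float]] | LayoutResult,
    data: NetworkData | TreeData,
    ndim_hint: int | None = None,
) -> LayoutResult:
    """Validate a raw vertex->coordinate mapping against *data*.

    The dimension is inferred from the tuple lengths (3D only when every tuple
    has length 3); coverage of all vertices and finiteness of every value are
    enforced. Validating a :class:`LayoutResult`'s own ``coords`` returns an
    equal result (idempotence).
    """
    raw = layout.coords if isinstance(layout, LayoutResult) else layout
    if isinstance(data, TreeData):
        required = data.nodes
    else:
        required = data.vertex_ids

    coords: dict[Hashable, tuple[float, ...]] = {}
    ndim: int | None = None
    for vid in required:
        if vid not in raw:
            raise LayoutCoverageError(f"layout missing coordinate for vertex {vid!r}")
        point = tuple(float(c) for c in raw[vid])
        if ndim is None:
            ndim = len(point)
            if ndim not in (2, 3):
                raise LayoutDimensionError(
                    f"coordinates must be 2D or 3D, got length {ndim} for {vid!r}"
                )
            if ndim_hint is not None and ndim != ndim_hint:
                raise LayoutDimensionError(
                    f"layout is {ndim}D but {ndim_hint}D was requested"
                )
        elif len(point) != ndim:
            raise LayoutDimensionError(
                f"mixed coordinate dimensions: {vid!r} has length {len(point)}, "
                f"expected {ndim}"
            )
        if not all(math.isfinite(c) for c in point):
            raise LayoutValueError(f"non-finite coordinate for vertex {vid!r}: {point}")
        coords[vid] = point
    if ndim is None:
        raise LayoutCoverageError("cannot infer dimension of an empty layout")
    return LayoutResult(coords=coords, ndim=ndim)
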