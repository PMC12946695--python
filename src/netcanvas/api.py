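"""High-level entry points: ``network``, ``tree``, and ``tree_pair``.

Each detects a provider for the input object, normalises it into the internal
model, layers style fragments over a built-in default, assembles a Scene, and
wraps it in a :class:`RenderHandle` that can export SVG (deterministic),
JSON (deterministic, round-trips), or PNG (via the matplotlib backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from .backends import MatplotlibBackend, NullBackend, get_backend
from .core import LayoutResult, NetworkData, TreeData, validate_layout
from .errors import (
    ExportFormatError,
    MissingLayoutError,
    NodeLookupError,
    StructuralError,
)
from .geometry import LineSegment, Path
from .ingestion import ProviderRegistry, default_registry
from .scene import (
    GroupingSpec,
    Primitive,
    Scene,
    ZORDER_CLASSES,
    assemble_scene,
    scene_to_json,
    _jsonable,
    _path_geometry,
)
from .style import flatten_style, get_default_style, resolve_element
from .svgexport import scene_to_svg
from .treelayout import TreeLayoutOptions, layout_tree

__all__ = ["RenderHandle", "network", "tree", "tree_pair", "export"]


@dataclass
class RenderHandle:
    """A rendered scene plus its backend binding.

    Exporting the same handle twice yields identical bytes for the svg and
    json formats (determinism contract); png goes through the raster backend.
    """

    scene: Scene
    backend: object = field(default_factory=NullBackend)

    def to_svg(self) -> str:
        return scene_to_svg(self.scene)

    def to_json(self) -> str:
        return scene_to_json(self.scene)

    def export(self, path: str, format: str | None = None) -> None:
        export(self, path, format=format)

    def draw(self, ax=None):
        """Render through the matplotlib backend; returns the Figure."""
        backend = (
            self.backend
            if isinstance(self.backend, MatplotlibBackend)
            else MatplotlibBackend()
        )
        return backend.draw(self.scene, ax=ax)


def _flatten_over(base: str, style) -> dict:
    if style is None:
        fragments = []
    elif isinstance(style, Mapping):
        fragments = [style]
    else:
        fragments = list(style)
    return flatten_style([get_default_style(base), *fragments])


def network(
    obj,
    layout: Mapping | LayoutResult | None = None,
    style: Mapping | Sequence[Mapping] | None = None,
    grouping: GroupingSpec | Mapping | None = None,
    registry: ProviderRegistry | None = None,
    backend: str = "null",
    colorbar: dict | None = None,
) -> RenderHandle:
    """Visualise any network a provider understands.

    ``layout`` may be omitted when the provider extracts one from the object;
    otherwise a vertex -> (x, y[, z]) mapping is required.
    """
    registry = registry or default_registry
    data, provider_layout = registry.normalise(obj, kind="network")
    if layout is None:
        layout = provider_layout
    if layout is None:
        raise MissingLayoutError(
            "no layout given and the provider does not supply one"
        )
    if isinstance(grouping, Mapping) and not isinstance(grouping, GroupingSpec):
        grouping = GroupingSpec(groups=grouping, mode="cover")
    flat = _flatten_over("default", style)
    scene = assemble_scene(data, layout, flat, grouping=grouping, colorbar=colorbar)
    return RenderHandle(scene=scene, backend=get_backend(backend))


def tree(
    obj,
    kind: str = "rectangular",
    opts: TreeLayoutOptions | None = None,
    style: Mapping | Sequence[Mapping] | None = None,
    cascades: Sequence[Hashable] | None = None,
    leaf_labels: bool = False,
    registry: ProviderRegistry | None = None,
    backend: str = "null",
) -> RenderHandle:
    """Visualise a rooted tree with an internally computed layout."""
    if kind not in ("rectangular", "radial"):
        raise StructuralError(f"unknown tree layout kind {kind!r}")
    registry = registry or default_registry
    data, _ = registry.normalise(obj, kind="tree")
    opts = opts or TreeLayoutOptions(kind=kind)
    if opts.kind != kind:
        opts = TreeLayoutOptions(
            kind=kind,
            use_branch_lengths=opts.use_branch_lengths,
            orientation=opts.orientation,
            angular_span=opts.angular_span,
            start_angle=opts.start_angle,
        )
    layout = layout_tree(data, opts)
    fragments = [style] if isinstance(style, Mapping) else list(style or [])
    if leaf_labels:
        fragments.append(
            {
                "vertex_label": {
                    "text": {leaf: str(leaf) for leaf in data.leaf_order},
                    "hoffset": 6.0,
                }
            }
        )
    flat = _flatten_over("tree", fragments)
    scene = assemble_scene(
        data,
        layout,
        flat,
        tree_kind=kind,
        orientation=opts.orientation,
        cascades=cascades,
        tree_opts=opts,
    )
    return RenderHandle(scene=scene, backend=get_backend(backend))


def tree_pair(
    tree1_obj,
    tree2_obj,
    links: Sequence[tuple[Hashable, Hashable]] = (),
    style: Mapping | Sequence[Mapping] | None = None,
    gap: float = 2.0,
    registry: ProviderRegistry | None = None,
    backend: str = "null",
) -> RenderHandle:
    """Tanglegram: two rectangular trees facing each other with leaf links.

    The first tree points right, the second is mirrored (orientation left)
    and offset horizontally; each link joins the two leaves' layout
    coordinates exactly.
    """
    registry = registry or default_registry
    data1, _ = registry.normalise(tree1_obj, kind="tree")
    data2, _ = registry.normalise(tree2_obj, kind="tree")

    opts1 = TreeLayoutOptions(kind="rectangular", orientation="right")
    layout1 = layout_tree(data1, opts1)
    opts2 = TreeLayoutOptions(kind="rectangular", orientation="left")
    layout2_raw = layout_tree(data2, opts2)
    depth1 = max(c[0] for c in layout1.coords.values())
    depth2 = max(-c[0] for c in layout2_raw.coords.values())
    offset = depth1 + gap + depth2
    layout2 = LayoutResult(
        coords={n: (c[0] + offset, c[1]) for n, c in layout2_raw.coords.items()},
        ndim=2,
    )

    flat = _flatten_over("tree", style)
    scene1 = assemble_scene(
        data1, layout1, flat, tree_kind="rectangular", orientation="right"
    )
    scene2 = assemble_scene(
        data2, layout2, flat, tree_kind="rectangular", orientation="left"
    )

    leaves1 = set(data1.leaf_order)
    leaves2 = set(data2.leaf_order)
    link_prims: list[Primitive] = []
    link_style = resolve_element(flat, "edge", 0, None)
    link_style = dict(link_style)
    link_style.update(geometry="straight", linestyle="dotted")
    from .colors import to_rgb

    link_style["color"] = to_rgb(link_style.get("color") or "gray")
    for li, (leaf1, leaf2) in enumerate(links):
        if leaf1 not in leaves1:
            raise NodeLookupError(f"link endpoint {leaf1!r} is not a leaf of tree 1")
        if leaf2 not in leaves2:
            raise NodeLookupError(f"link endpoint {leaf2!r} is not a leaf of tree 2")
        p1 = layout1.coords[leaf1]
        p2 = layout2.coords[leaf2]
        path = Path([LineSegment(tuple(p1), tuple(p2))])
        link_prims.append(
            Primitive(
                kind="path",
                role="edge",
                index=li,
                element=["link", _jsonable(leaf1), _jsonable(leaf2)],
                geometry=_path_geometry(path),
                style=link_style,
            )
        )

    # merge by zorder class so the combined scene stays deterministic
    primitives: list[Primitive] = []
    for cls in sorted(set(ZORDER_CLASSES.values())):
        for source in (scene1, scene2):
            primitives.extend(
                p for p in source.primitives if ZORDER_CLASSES[p.role] == cls
            )
        if cls == ZORDER_CLASSES["edge"]:
            primitives.extend(link_prims)
    scene = Scene(primitives=primitives, ndim=2)
    return RenderHandle(scene=scene, backend=get_backend(backend))


def export(handle: RenderHandle, path: str, format: str | None = None) -> None:
    """Write svg / json / png. svg and json are byte-deterministic."""
    if format is None:
        format = str(path).rsplit(".", 1)[-1].lower()
    if format == "svg":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(handle.to_svg())
    elif format == "json":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(handle.to_json())
    elif format == "png":
        fig = handle.draw()
        fig.savefig(path, dpi=100)
        import matplotlib.pyplot as plt

        plt.close(fig)
    else:
        raise ExportFormatError(
            f"unsupported format {format!r}; supported: svg, json, png"
        )
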