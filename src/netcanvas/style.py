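"""Declarative cascading style grammar.

A style document is a two-level nested mapping: element-type key (``vertex``,
``edge``, ``arrow``, ``loop``, ``vertex_label``, ``edge_label``, ``cascade``,
``grouping``) -> property key -> value. A property value is either

* a scalar — applied globally to every element of that type,
* an ordered sequence — positional per-element, recycled by ``index %
  len(sequence)`` when shorter than the element count (grammar-of-graphics
  recycling), or
* a mapping — per-element by id, falling back to the default style's value
  for ids not listed.

Properties that are *inherently* sequence-valued for a single element
(``waypoints``, ``ports``, ``control_points``, ``fractions``, ``colors``)
are exempt from positional recycling: a sequence there is one global value,
and per-element variation uses an id mapping.

Cascading: ``flatten_style`` deep-merges an ordered list of fragments, later
layers overriding earlier ones key-by-key at the property level (sequences
and mappings replace their predecessor wholesale). Layering user fragments
over a complete built-in style yields a complete spec, which is what
``resolve_element`` requires.
"""

from __future__ import annotations

import copy
import difflib
from typing import Hashable, Mapping, Sequence

import numpy as np

from .errors import DegenerateRangeError, StyleGrammarError, StyleLookupError

__all__ = [
    "ELEMENT_TYPES",
    "PROPERTY_VOCABULARY",
    "get_default_style",
    "available_styles",
    "flatten_style",
    "resolve_element",
    "map_quantity_to_colour",
]

ELEMENT_TYPES = (
    "vertex",
    "edge",
    "arrow",
    "loop",
    "vertex_label",
    "edge_label",
    "cascade",
    "grouping",
)

#: Minimum property vocabulary per element type; every built-in style defines
#: all of these, so any element resolves with no missing property.
PROPERTY_VOCABULARY: dict[str, tuple[str, ...]] = {
    "vertex": ("size", "shape", "facecolor", "edgecolor", "linewidth", "zorder"),
    "edge": (
        "color",
        "linewidth",
        "linestyle",
        "geometry",
        "tension",
        "ports",
        "control_points",
        "waypoints",
        "offset",
        "split_colors",
    ),
    "arrow": ("marker", "width", "length"),
    "loop": ("size", "angle"),
    "vertex_label": ("text", "size", "color", "hoffset", "voffset"),
    "edge_label": ("text", "size", "color", "hoffset", "voffset"),
    "cascade": ("facecolor", "alpha", "extent"),
    "grouping": ("facecolor", "alpha", "padding", "rounding"),
}

#: Properties whose value for ONE element is itself a sequence; positional
#: recycling does not apply to these (use an id mapping instead).
SEQUENCE_VALUED = frozenset(
    {"ports", "control_points", "waypoints", "split_colors"}
)

_DEFAULT_STYLES: dict[str, dict] = {
    "default": {
        "vertex": {
            "size": 18.0,
            "shape": "circle",
            "facecolor": "#1f77b4",
            "edgecolor": "black",
            "linewidth": 1.0,
            "zorder": 4,
        },
        "edge": {
            "color": "black",
            "linewidth": 1.5,
            "linestyle": "solid",
            "geometry": "straight",
            "tension": 0.0,
            "ports": None,
            "control_points": None,
            "waypoints": None,
            "offset": 0.0,
            "split_colors": None,
        },
        "arrow": {"marker": "triangle", "width": 6.0, "length": 9.0},
        "loop": {"size": 0.25, "angle": None},
        "vertex_label": {
            "text": None,
            "size": 10.0,
            "color": "black",
            "hoffset": 0.0,
            "voffset": 0.0,
        },
        "edge_label": {
            "text": None,
            "size": 9.0,
            "color": "black",
            "hoffset": 0.0,
            "voffset": 0.0,
        },
        "cascade": {"facecolor": "silver", "alpha": 0.35, "extent": "leaves"},
        "grouping": {
            "facecolor": "yellow",
            "alpha": 0.3,
            "padding": 0.3,
            "rounding": True,
        },
    },
}

_DEFAULT_STYLES["minimal"] = copy.deepcopy(_DEFAULT_STYLES["default"])
_DEFAULT_STYLES["minimal"]["vertex"].update(
    size=6.0, facecolor="black", edgecolor="none", linewidth=0.0
)
_DEFAULT_STYLES["minimal"]["edge"].update(linewidth=0.8, color="gray")

_DEFAULT_STYLES["tree"] = copy.deepcopy(_DEFAULT_STYLES["default"])
_DEFAULT_STYLES["tree"]["edge"].update(geometry="elbow", linewidth=1.2)
_DEFAULT_STYLES["tree"]["vertex"].update(size=0.0, edgecolor="none", linewidth=0.0)


def available_styles() -> list[str]:
    return sorted(_DEFAULT_STYLES)


def get_default_style(name: str = "default") -> dict:
    """Return a complete built-in style ("default", "minimal" or "tree")."""
    try:
        template = _DEFAULT_STYLES[name]
    except KeyError:
        raise StyleLookupError(
            f"unknown style {name!r}; available: {available_styles()}"
        ) from None
    return copy.deepcopy(template)


def _freeze(value):
    if isinstance(value, Mapping):
        return {k: _freeze(v) for k, v in value.items()}
    if isinstance(value, list):
        return tuple(_freeze(v) for v in value)
    return value


def flatten_style(layers: Sequence[Mapping]) -> dict:
    """Deep-merge an ordered sequence of style fragments.

    Later layers override earlier ones at the property-key level; a sequence
    or mapping value replaces (never merges element-wise with) whatever came
    before. Unknown element-type keys raise :class:`StyleGrammarError` naming
    the offending key and its nearest valid key. The merge is associative.
    """
    merged: dict[str, dict] = {}
    for layer in layers:
        if layer is None:
            continue
        for etype, props in layer.items():
            if etype not in ELEMENT_TYPES:
                hint = difflib.get_close_matches(str(etype), ELEMENT_TYPES, n=1)
                suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                raise StyleGrammarError(
                    f"unknown style element type {etype!r}"
                    f" (valid: {', '.join(ELEMENT_TYPES)}){suggestion}"
                )
            if not isinstance(props, Mapping):
                raise StyleGrammarError(
                    f"style entry for {etype!r} must be a mapping of properties"
                )
            bucket = merged.setdefault(etype, {})
            for prop, value in props.items():
                bucket[prop] = _freeze(value)
    return merged


def _is_positional_sequence(value, prop: str) -> bool:
    if prop in SEQUENCE_VALUED:
        return False
    return isinstance(value, (list, tuple, np.ndarray)) and not isinstance(value, str)


def resolve_element(
    style: Mapping,
    element_type: str,
    index: int,
    element_id: Hashable = None,
    fallback: Mapping | None = None,
) -> dict:
    """Resolve the concrete style of one element.

    ``style`` must be flattened and complete for *element_type* (e.g. layered
    over a built-in). Scalars pass through; positional sequences recycle by
    ``index % len``; id-mappings look up ``element_id`` and fall back to the
    "default" built-in's value (or *fallback* when given). The result is a
    fully scalar flat mapping and the call is pure.
    """
    if element_type not in ELEMENT_TYPES:
        raise StyleGrammarError(f"unknown style element type {element_type!r}")
    props = style.get(element_type, {})
    defaults = fallback if fallback is not None else _DEFAULT_STYLES["default"].get(element_type, {})
    resolved: dict = {}
    for prop, value in props.items():
        if isinstance(value, Mapping):
            value = value.get(element_id, defaults.get(prop))
        elif _is_positional_sequence(value, prop):
            if len(value) == 0:
                value = defaults.get(prop)
            else:
                value = value[index % len(value)]
        resolved[prop] = value
    return resolved


def map_quantity_to_colour(
    values: Sequence[float],
    colourmap: str = "viridis",
    norm: tuple[float, float] | None = None,
):
    """Map real values to colours through a named colour map.

    Values are normalised linearly onto [0, 1] (default vmin/vmax from the
    data) and looked up in the matplotlib colour map *colourmap*. Returns
    ``(colours, record)`` where colours are RGB triples and the record keeps
    the normalisation (``cmap``, ``vmin``, ``vmax``) so a colour bar can be
    drawn later.
    """
    import matplotlib

    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateRangeError("cannot colour-map an empty value sequence")
    if not np.all(np.isfinite(arr)):
        raise DegenerateRangeError("values must be finite")
    if norm is None:
        vmin, vmax = float(arr.min()), float(arr.max())
        if vmin == vmax:
            raise DegenerateRangeError(
                "constant values give a degenerate colour range; pass an explicit norm"
            )
    else:
        vmin, vmax = float(norm[0]), float(norm[1])
        if not vmin < vmax:
            raise DegenerateRangeError("norm must satisfy vmin < vmax")
    unit = np.clip((arr - vmin) / (vmax - vmin), 0.0, 1.0)
    cmap = matplotlib.colormaps[colourmap]
    colours = [tuple(float(c) for c in cmap(float(u))[:3]) for u in unit]
    record = {"cmap": colourmap, "vmin": vmin, "vmax": vmax}
    return colours, record
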