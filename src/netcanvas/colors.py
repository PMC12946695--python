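"""Backend-independent colour handling.

Scenes carry colours as RGB triples in [0, 1] so that serialisation and the
provider-equivalence guarantee never depend on a rendering library's colour
tables. Named colours resolve through the fixed CSS basic table below; hex
strings and numeric triples are also accepted.
"""

from __future__ import annotations

from .errors import NetcanvasError

# CSS 2.1 basic colour keywords (fixed, backend independent).
CSS_BASIC: dict[str, tuple[float, float, float]] = {
    "black": (0.0, 0.0, 0.0),
    "silver": (0.75, 0.75, 0.75),
    "gray": (0.5, 0.5, 0.5),
    "grey": (0.5, 0.5, 0.5),
    "white": (1.0, 1.0, 1.0),
    "maroon": (0.5, 0.0, 0.0),
    "red": (1.0, 0.0, 0.0),
    "purple": (0.5, 0.0, 0.5),
    "fuchsia": (1.0, 0.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "green": (0.0, 0.5, 0.0),
    "lime": (0.0, 1.0, 0.0),
    "olive": (0.5, 0.5, 0.0),
    "yellow": (1.0, 1.0, 0.0),
    "navy": (0.0, 0.0, 0.5),
    "blue": (0.0, 0.0, 1.0),
    "teal": (0.0, 0.5, 0.5),
    "aqua": (0.0, 1.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
    "orange": (1.0, 0.647, 0.0),
    "none": None,  # type: ignore[dict-item]
}


class ColorError(NetcanvasError, ValueError):
    pass


def to_rgb(value) -> tuple[float, float, float] | None:
    """Resolve *value* to an RGB triple in [0,1], or None for 'none'.

    Accepts CSS basic names, '#rrggbb' / '#rgb' hex strings, and length-3
    sequences of numbers in [0, 1].
    """
    if value is None:
        return None
    if isinstance(value, str):
        key = value.strip().lower()
        if key in CSS_BASIC:
            return CSS_BASIC[key]
        if key.startswith("#"):
            hexpart = key[1:]
            if len(hexpart) == 3:
                hexpart = "".join(c * 2 for c in hexpart)
            if len(hexpart) == 6:
                try:
                    return tuple(int(hexpart[i : i + 2], 16) / 255.0 for i in (0, 2, 4))  # type: ignore[return-value]
                except ValueError:
                    pass
        raise ColorError(f"unknown colour {value!r}; known names: {sorted(CSS_BASIC)}")
    try:
        rgb = tuple(float(c) for c in value)
    except TypeError as exc:
        raise ColorError(f"cannot interpret {value!r} as a colour") from exc
    if len(rgb) not in (3, 4) or not all(0.0 <= c <= 1.0 for c in rgb):
        raise ColorError(f"colour components must be 3 or 4 values in [0,1], got {value!r}")
    return rgb[:3]
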