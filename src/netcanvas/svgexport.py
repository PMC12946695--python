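"""Deterministic SVG writer.

The writer is a pure function of the Scene: equal scenes yield byte-identical
SVG. One ``<g>`` group per zorder class; positions go through a single
data->pixel transform while figure-space sizes (marker size, line width,
arrow dims, font size) are written in pixels one-to-one with points, so the
dual coordinate contract survives in the output.
"""

from __future__ import annotations

import math

from .scene import Scene

_CLASS_ORDER = ["grouping", "cascade", "edge", "arrow", "vertex", "label"]


def _fmt(value: float) -> str:
    return f"{value:.6g}"


def _hex_colour(rgb) -> str:
    if rgb is None:
        return "none"
    r, g, b = (max(0, min(255, round(255 * c))) for c in rgb[:3])
    return f"#{r:02x}{g:02x}{b:02x}"


_DASHES = {"solid": None, "dashed": "6,4", "dotted": "1.5,3", "dashdot": "6,3,1.5,3"}


class _Transform:
    """Affine data->pixel map with y flipped (SVG y grows downward)."""

    def __init__(self, scene: Scene, width: float, height: float, margin: float):
        xs, ys = [], []
        for prim in scene.primitives:
            geom = prim.geometry
            if "xy" in geom:
                xs.append(geom["xy"][0])
                ys.append(geom["xy"][1])
            for p in geom.get("points", []):
                xs.append(p[0])
                ys.append(p[1])
            for seg in geom.get("segments", []):
                for p in seg.get("points", []):
                    xs.append(p[0])
                    ys.append(p[1])
                if seg.get("kind") == "arc":
                    cx, cy = seg["center"][:2]
                    r = seg["radius"]
                    xs.extend([cx - r, cx + r])
                    ys.extend([cy - r, cy + r])
        if not xs:
            xs, ys = [0.0, 1.0], [0.0, 1.0]
        self.xmin, self.xmax = min(xs), max(xs)
        self.ymin, self.ymax = min(ys), max(ys)
        span_x = self.xmax - self.xmin or 1.0
        span_y = self.ymax - self.ymin or 1.0
        self.scale = min((width - 2 * margin) / span_x, (height - 2 * margin) / span_y)
        self.ox = margin
        self.oy = margin

    def __call__(self, x: float, y: float) -> tuple[float, float]:
        return (
            self.ox + (x - self.xmin) * self.scale,
            self.oy + (self.ymax - y) * self.scale,
        )


def _path_d(geometry: dict, tf: _Transform) -> str:
    parts = []
    started = False
    for seg in geometry["segments"]:
        kind = seg["kind"]
        if kind == "arc":
            cx, cy = seg["center"][:2]
            r = seg["radius"]
            t0, t1 = seg["theta0"], seg["theta1"]
            x0, y0 = tf(cx + r * math.cos(t0), cy + r * math.sin(t0))
            sweep = t1 - t0
            # split sweeps >= 2*pi is unnecessary for edge arcs; clamp safely
            x1, y1 = tf(cx + r * math.cos(t1), cy + r * math.sin(t1))
            if not started:
                parts.append(f"M {_fmt(x0)} {_fmt(y0)}")
                started = True
            large = 1 if abs(sweep) > math.pi else 0
            # data-space ccw becomes clockwise after the y flip -> sweep flag 0
            flag = 0 if sweep > 0 else 1
            rpx = r * tf.scale
            parts.append(
                f"A {_fmt(rpx)} {_fmt(rpx)} 0 {large} {flag} {_fmt(x1)} {_fmt(y1)}"
            )
        else:
            pts = [tf(p[0], p[1]) for p in seg["points"]]
            if not started:
                parts.append(f"M {_fmt(pts[0][0])} {_fmt(pts[0][1])}")
                started = True
            if kind == "line":
                parts.append(f"L {_fmt(pts[1][0])} {_fmt(pts[1][1])}")
            else:  # cubic
                coords = " ".join(f"{_fmt(x)} {_fmt(y)}" for x, y in pts[1:])
                parts.append(f"C {coords}")
    if geometry.get("closed"):
        parts.append("Z")
    return " ".join(parts)


def scene_to_svg(scene: Scene, width: float = 640.0, height: float = 480.0,
                 margin: float = 40.0) -> str:
    tf = _Transform(scene, width, height, margin)
    groups: dict[str, list[str]] = {name: [] for name in _CLASS_ORDER}

    for prim in scene.primitives:
        style = prim.style
        cls = "label" if prim.role.endswith("_label") else prim.role
        if cls not in groups:
            cls = "edge"
        if prim.kind == "marker":
            x, y = tf(prim.geometry["xy"][0], prim.geometry["xy"][1])
            size = float(style.get("size", 10.0))
            if size <= 0:
                continue
            fill = _hex_colour(style.get("facecolor"))
            stroke = _hex_colour(style.get("edgecolor"))
            sw = float(style.get("linewidth", 1.0))
            if style.get("shape") == "square":
                half = size / 2.0
                groups[cls].append(
                    f'<rect x="{_fmt(x - half)}" y="{_fmt(y - half)}" '
                    f'width="{_fmt(size)}" height="{_fmt(size)}" fill="{fill}" '
                    f'stroke="{stroke}" stroke-width="{_fmt(sw)}"/>'
                )
            else:
                groups[cls].append(
                    f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(size / 2.0)}" '
                    f'fill="{fill}" stroke="{stroke}" stroke-width="{_fmt(sw)}"/>'
                )
        elif prim.kind == "path":
            d = _path_d(prim.geometry, tf)
            colour = _hex_colour(style.get("color"))
            sw = float(style.get("linewidth", 1.0))
            dash = _DASHES.get(style.get("linestyle", "solid"))
            dash_attr = f' stroke-dasharray="{dash}"' if dash else ""
            groups[cls].append(
                f'<path d="{d}" fill="none" stroke="{colour}" '
                f'stroke-width="{_fmt(sw)}"{dash_attr}/>'
            )
        elif prim.kind == "polygon":
            if prim.role == "arrow":
                x, y = tf(prim.geometry["xy"][0], prim.geometry["xy"][1])
                # data-space angle; the y flip negates it on screen
                angle = -prim.geometry["angle"]
                w = float(style.get("width", 6.0))
                length = float(style.get("length", 9.0))
                ca, sa = math.cos(angle), math.sin(angle)
                tip = (x, y)
                base = (x - length * ca, y - length * sa)
                normal = (-sa, ca)
                left = (base[0] + 0.5 * w * normal[0], base[1] + 0.5 * w * normal[1])
                right = (base[0] - 0.5 * w * normal[0], base[1] - 0.5 * w * normal[1])
                pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in (tip, left, right))
                colour = _hex_colour(style.get("color") or (0.0, 0.0, 0.0))
                groups[cls].append(f'<polygon points="{pts}" fill="{colour}"/>')
            else:
                fill = _hex_colour(style.get("facecolor"))
                alpha = float(style.get("alpha", 1.0))
                if "points" in prim.geometry:
                    pts = " ".join(
                        f"{_fmt(px)},{_fmt(py)}"
                        for px, py in (tf(p[0], p[1]) for p in prim.geometry["points"])
                    )
                    groups[cls].append(
                        f'<polygon points="{pts}" fill="{fill}" '
                        f'fill-opacity="{_fmt(alpha)}"/>'
                    )
                else:  # closed path geometry (cascade patches)
                    d = _path_d(prim.geometry, tf)
                    groups[cls].append(
                        f'<path d="{d}" fill="{fill}" fill-opacity="{_fmt(alpha)}"/>'
                    )
        elif prim.kind == "text":
            x, y = tf(prim.geometry["xy"][0], prim.geometry["xy"][1])
            x += float(style.get("hoffset", 0.0))
            y -= float(style.get("voffset", 0.0))
            size = float(style.get("size", 10.0))
            colour = _hex_colour(style.get("color") or (0.0, 0.0, 0.0))
            text = _escape(prim.geometry.get("text", ""))
            groups[cls].append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(size)}" '
                f'fill="{colour}" dominant-baseline="middle">{text}</text>'
            )

    body = []
    for name in _CLASS_ORDER:
        if groups[name]:
            body.append(f'<g id="{name}">')
            body.extend(groups[name])
            body.append("</g>")
    content = "\n".join(body)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        f"{content}\n</svg>\n"
    )


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )
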