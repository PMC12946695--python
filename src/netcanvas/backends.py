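"""Rendering-backend bridge.

The backend contract is deliberately narrow: draw a marker, a path, a
polygon, or a text label, with positions in data space and size-like
attributes in figure space. :class:`NullBackend` only records the calls — it
keeps the whole geometry/test surface independent of any plotting stack.
:class:`MatplotlibBackend` binds the same contract to matplotlib for raster
(PNG) output and for composing scenes with other charts.
"""

from __future__ import annotations

import math

from .scene import Scene

__all__ = ["NullBackend", "MatplotlibBackend", "get_backend"]


class NullBackend:
    """Records draw calls; the default for tests and JSON/SVG export."""

    name = "null"

    def __init__(self):
        self.calls: list[tuple] = []

    def draw(self, scene: Scene):
        self.calls = [(p.kind, p.role, p.index) for p in scene.primitives]
        return self.calls


def _arc_to_cubics(center, radius, theta0, theta1, max_step=math.pi / 2):
    """Approximate a circular arc by <=90-degree cubic pieces (render only)."""
    sweep = theta1 - theta0
    n = max(1, int(math.ceil(abs(sweep) / max_step)))
    step = sweep / n
    k = 4.0 / 3.0 * math.tan(step / 4.0)
    cx, cy = center[:2]
    pieces = []
    for i in range(n):
        a0 = theta0 + i * step
        a1 = a0 + step
        p0 = (cx + radius * math.cos(a0), cy + radius * math.sin(a0))
        p3 = (cx + radius * math.cos(a1), cy + radius * math.sin(a1))
        c1 = (p0[0] - k * radius * math.sin(a0), p0[1] + k * radius * math.cos(a0))
        c2 = (p3[0] + k * radius * math.sin(a1), p3[1] - k * radius * math.cos(a1))
        pieces.append((p0, c1, c2, p3))
    return pieces


class MatplotlibBackend:
    """Draw a Scene onto a matplotlib Axes."""

    name = "matplotlib"

    def __init__(self):
        self.figure = None
        self.axes = None

    def draw(self, scene: Scene, ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.path import Path as MplPath
        from matplotlib.patches import PathPatch, Polygon as MplPolygon

        if ax is None:
            fig, ax = plt.subplots(figsize=(6.4, 4.8))
        else:
            fig = ax.figure
        self.figure, self.axes = fig, ax

        for prim in scene.primitives:
            style = prim.style
            if prim.kind == "marker":
                size = float(style.get("size", 10.0))
                if size <= 0:
                    continue
                x, y = prim.geometry["xy"][:2]
                ax.scatter(
                    [x],
                    [y],
                    s=size**2,
                    marker="s" if style.get("shape") == "square" else "o",
                    facecolors=[style.get("facecolor") or "none"],
                    edgecolors=[style.get("edgecolor") or "none"],
                    linewidths=float(style.get("linewidth", 1.0)),
                    zorder=float(style.get("zorder", 4)),
                )
            elif prim.kind == "path":
                verts, codes = self._mpl_path(prim.geometry)
                patch = PathPatch(
                    MplPath(verts, codes),
                    fill=False,
                    edgecolor=style.get("color") or "black",
                    linewidth=float(style.get("linewidth", 1.0)),
                    linestyle=style.get("linestyle", "solid"),
                    zorder=2,
                )
                ax.add_patch(patch)
            elif prim.kind == "polygon":
                if prim.role == "arrow":
                    # dims are figure points; approximate at the data scale so
                    # raster output stays visually sensible
                    x, y = prim.geometry["xy"][:2]
                    angle = prim.geometry["angle"]
                    span = max(
                        ax.dataLim.width or 1.0, ax.dataLim.height or 1.0, 1.0
                    )
                    unit = span / 300.0
                    length = float(style.get("length", 9.0)) * unit
                    width = float(style.get("width", 6.0)) * unit
                    ca, sa = math.cos(angle), math.sin(angle)
                    base = (x - length * ca, y - length * sa)
                    normal = (-sa, ca)
                    tri = [
                        (x, y),
                        (base[0] + 0.5 * width * normal[0], base[1] + 0.5 * width * normal[1]),
                        (base[0] - 0.5 * width * normal[0], base[1] - 0.5 * width * normal[1]),
                    ]
                    ax.add_patch(MplPolygon(tri, closed=True, facecolor="black", zorder=3))
                elif "points" in prim.geometry:
                    ax.add_patch(
                        MplPolygon(
                            [p[:2] for p in prim.geometry["points"]],
                            closed=True,
                            facecolor=style.get("facecolor") or "gray",
                            alpha=float(style.get("alpha", 1.0)),
                            zorder=0,
                        )
                    )
                else:
                    verts, codes = self._mpl_path(prim.geometry)
                    patch = PathPatch(
                        MplPath(verts, codes),
                        facecolor=style.get("facecolor") or "gray",
                        alpha=float(style.get("alpha", 1.0)),
                        edgecolor="none",
                        zorder=1,
                    )
                    ax.add_patch(patch)
            elif prim.kind == "text":
                x, y = prim.geometry["xy"][:2]
                ax.annotate(
                    prim.geometry.get("text", ""),
                    (x, y),
                    xytext=(
                        float(style.get("hoffset", 0.0)),
                        float(style.get("voffset", 0.0)),
                    ),
                    textcoords="offset points",
                    fontsize=float(style.get("size", 10.0)),
                    color=style.get("color") or "black",
                    zorder=5,
                    va="center",
                )
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.axis("off")
        return fig

    @staticmethod
    def _mpl_path(geometry: dict):
        from matplotlib.path import Path as MplPath

        verts: list[tuple] = []
        codes: list[int] = []
        for seg in geometry["segments"]:
            kind = seg["kind"]
            if kind == "arc":
                cubics = _arc_to_cubics(
                    seg["center"], seg["radius"], seg["theta0"], seg["theta1"]
                )
                if not verts:
                    verts.append(cubics[0][0])
                    codes.append(MplPath.MOVETO)
                for _, c1, c2, p3 in cubics:
                    verts.extend([c1, c2, p3])
                    codes.extend([MplPath.CURVE4] * 3)
            else:
                pts = [tuple(p[:2]) for p in seg["points"]]
                if not verts:
                    verts.append(pts[0])
                    codes.append(MplPath.MOVETO)
                if kind == "line":
                    verts.append(pts[1])
                    codes.append(MplPath.LINETO)
                else:
                    verts.extend(pts[1:])
                    codes.extend([MplPath.CURVE4] * 3)
        if geometry.get("closed"):
            verts.append(verts[0])
            codes.append(MplPath.CLOSEPOLY)
        return verts, codes


def get_backend(name: str):
    if name == "null":
        return NullBackend()
    if name == "matplotlib":
        return MatplotlibBackend()
    raise ValueError(f"unknown backend {name!r}")
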