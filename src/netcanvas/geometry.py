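"""Edge-path geometry engine.

Every edge geometry the style grammar names is computed here: straight lines,
circular arcs, cubic Beziers (with exact quadratic elevation), incidence-angle
"ports", waypoint polylines, self-loop lobes, elbow edges for tree drawings,
plus marker clipping, arrowheads, and arc-length path splitting.

A :class:`Path` is a sequence of analytic segments — ``line``, ``cubic`` or
``arc`` (exact circular parameterisation; arcs are converted to SVG arc
commands or cubics only at export). Keeping arcs exact is what lets the
semicircle test hold to 1e-9 instead of the ~1e-4 error of a cubic
approximation.

Conventions: coordinates are data units; angles are radians counterclockwise
from the positive x axis; arc ``tension`` is dimensionless (the bulge as a
fraction of the chord length, positive = left of the direction of travel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ArityError,
    DegenerateEdgeError,
    FullyClippedError,
    GeometryRangeError,
)

__all__ = [
    "Path",
    "LineSegment",
    "CubicSegment",
    "ArcSegment",
    "straight_path",
    "arc_path",
    "bezier_path",
    "ports_path",
    "waypoint_path",
    "loop_path",
    "elbow_path",
    "clip_at_marker",
    "arrowhead",
    "split_path",
]

# Gauss-Legendre nodes/weights (16 points) for cubic arc-length quadrature.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


def _as_point(p) -> np.ndarray:
    return np.asarray(p, dtype=float)


@dataclass(frozen=True)
class LineSegment:
    p0: tuple
    p1: tuple
    kind = "line"

    def point(self, t: float) -> np.ndarray:
        a, b = _as_point(self.p0), _as_point(self.p1)
        return a + t * (b - a)

    def tangent(self, t: float) -> np.ndarray:
        return _as_point(self.p1) - _as_point(self.p0)

    def length(self) -> float:
        return float(np.linalg.norm(_as_point(self.p1) - _as_point(self.p0)))

    def partial_length(self, t: float) -> float:
        return t * self.length()

    def split(self, t: float):
        mid = tuple(self.point(t))
        return LineSegment(self.p0, mid), LineSegment(mid, self.p1)

    def transformed(self, fn):
        return LineSegment(tuple(fn(self.p0)), tuple(fn(self.p1)))

    def control_points(self):
        return [self.p0, self.p1]


@dataclass(frozen=True)
class CubicSegment:
    p0: tuple
    c1: tuple
    c2: tuple
    p1: tuple
    kind = "cubic"

    def point(self, t: float) -> np.ndarray:
        p0, c1, c2, p1 = map(_as_point, (self.p0, self.c1, self.c2, self.p1))
        u = 1.0 - t
        return u**3 * p0 + 3 * u**2 * t * c1 + 3 * u * t**2 * c2 + t**3 * p1

    def tangent(self, t: float) -> np.ndarray:
        p0, c1, c2, p1 = map(_as_point, (self.p0, self.c1, self.c2, self.p1))
        u = 1.0 - t
        return 3 * u**2 * (c1 - p0) + 6 * u * t * (c2 - c1) + 3 * t**2 * (p1 - c2)

    def partial_length(self, t: float) -> float:
        if t <= 0.0:
            return 0.0
        # Gauss-Legendre quadrature of |B'(s)| over [0, t].
        half = t / 2.0
        s = half * (_GL_NODES + 1.0)
        speeds = np.array([float(np.linalg.norm(self.tangent(si))) for si in s])
        return float(half * np.dot(_GL_WEIGHTS, speeds))

    def length(self) -> float:
        return self.partial_length(1.0)

    def split(self, t: float):
        # de Casteljau subdivision: both halves reproduce the curve exactly.
        p0, c1, c2, p1 = map(_as_point, (self.p0, self.c1, self.c2, self.p1))
        q0 = p0 + t * (c1 - p0)
        q1 = c1 + t * (c2 - c1)
        q2 = c2 + t * (p1 - c2)
        r0 = q0 + t * (q1 - q0)
        r1 = q1 + t * (q2 - q1)
        s0 = r0 + t * (r1 - r0)
        left = CubicSegment(tuple(p0), tuple(q0), tuple(r0), tuple(s0))
        right = CubicSegment(tuple(s0), tuple(r1), tuple(q2), tuple(p1))
        return left, right

    def transformed(self, fn):
        return CubicSegment(
            tuple(fn(self.p0)), tuple(fn(self.c1)), tuple(fn(self.c2)), tuple(fn(self.p1))
        )

    def control_points(self):
        return [self.p0, self.c1, self.c2, self.p1]


@dataclass(frozen=True)
class ArcSegment:
    """Circular arc from angle theta0 to theta1 (signed sweep) about *center*."""

    center: tuple
    radius: float
    theta0: float
    theta1: float
    kind = "arc"

    def point(self, t: float) -> np.ndarray:
        theta = self.theta0 + t * (self.theta1 - self.theta0)
        c = _as_point(self.center)
        return c + self.radius * np.array([math.cos(theta), math.sin(theta)])

    def tangent(self, t: float) -> np.ndarray:
        theta = self.theta0 + t * (self.theta1 - self.theta0)
        sweep = self.theta1 - self.theta0
        return sweep * self.radius * np.array([-math.sin(theta), math.cos(theta)])

    def length(self) -> float:
        return abs(self.theta1 - self.theta0) * self.radius

    def partial_length(self, t: float) -> float:
        return t * self.length()

    def split(self, t: float):
        theta = self.theta0 + t * (self.theta1 - self.theta0)
        return (
            ArcSegment(self.center, self.radius, self.theta0, theta),
            ArcSegment(self.center, self.radius, theta, self.theta1),
        )

    def transformed(self, fn):
        # Only similarity transforms keep a circular arc circular; probe the
        # map with the center and two boundary points to recover the image arc.
        c = np.asarray(fn(self.center), dtype=float)
        a = np.asarray(fn(tuple(self.point(0.0))), dtype=float)
        b = np.asarray(fn(tuple(self.point(1.0))), dtype=float)
        radius = float(np.linalg.norm(a - c))
        t0 = math.atan2(a[1] - c[1], a[0] - c[0])
        t1 = math.atan2(b[1] - c[1], b[0] - c[0])
        sweep = self.theta1 - self.theta0
        # keep the signed sweep magnitude; re-anchor the end angle near t0
        t1 = t0 + sweep if abs(sweep) >= 2 * math.pi else t0 + _wrap_to(sweep, t1 - t0)
        return ArcSegment(tuple(c), radius, t0, t1)

    def control_points(self):
        return [tuple(self.point(0.0)), tuple(self.point(1.0))]


def _wrap_to(sweep: float, measured: float) -> float:
    """Return the angle congruent to *measured* (mod 2pi) with sweep's sign."""
    two_pi = 2 * math.pi
    m = measured % two_pi
    if sweep >= 0:
        return m if m != 0 else (two_pi if abs(sweep) > 1e-9 else 0.0)
    m = m - two_pi if m != 0 else 0.0
    return m if m != 0 else (-two_pi if abs(sweep) > 1e-9 else 0.0)


class Path:
    """An ordered sequence of analytic segments with arc-length utilities."""

    def __init__(self, segments: Sequence, closed: bool = False):
        if not segments:
            raise GeometryRangeError("a Path needs at least one segment")
        self.segments = list(segments)
        self.closed = bool(closed)

    # -- basic accessors ---------------------------------------------------
    @property
    def start(self) -> tuple:
        return tuple(self.segments[0].point(0.0))

    @property
    def end(self) -> tuple:
        return tuple(self.segments[-1].point(1.0))

    @property
    def points(self) -> list[tuple]:
        """Defining points: polyline vertices plus Bezier control points."""
        out = [tuple(self.segments[0].control_points()[0])]
        for seg in self.segments:
            out.extend(tuple(p) for p in seg.control_points()[1:])
        return out

    def length(self) -> float:
        return sum(seg.length() for seg in self.segments)

    def segment_lengths(self) -> list[float]:
        return [seg.length() for seg in self.segments]

    # -- sampling ----------------------------------------------------------
    def sample(self, num: int = 64) -> np.ndarray:
        """Dense polyline approximation: *num* points per segment (with shared
        segment endpoints de-duplicated)."""
        chunks = []
        for i, seg in enumerate(self.segments):
            ts = np.linspace(0.0, 1.0, num)
            pts = np.array([seg.point(t) for t in ts])
            if i > 0:
                pts = pts[1:]
            chunks.append(pts)
        return np.vstack(chunks)

    def point_at(self, t: float) -> np.ndarray:
        """Point at global arc-length fraction t in [0, 1]."""
        seg, local = self._locate(t)
        return seg.point(local)

    def tangent_at(self, t: float) -> np.ndarray:
        seg, local = self._locate(t)
        tan = seg.tangent(local)
        norm = np.linalg.norm(tan)
        if norm == 0.0:
            return tan
        return tan / norm

    def _locate(self, t: float):
        t = min(max(t, 0.0), 1.0)
        lengths = self.segment_lengths()
        total = sum(lengths)
        if total == 0.0:
            return self.segments[0], 0.0
        target = t * total
        acc = 0.0
        for seg, seg_len in zip(self.segments, lengths):
            if target <= acc + seg_len or seg is self.segments[-1]:
                remaining = target - acc
                return seg, _invert_arclength(seg, remaining, seg_len)
            acc += seg_len
        return self.segments[-1], 1.0

    # -- structure ---------------------------------------------------------
    def split_at_fractions(self, fractions: Sequence[float]) -> list["Path"]:
        return split_path(self, fractions)

    def transformed(self, fn: Callable) -> "Path":
        """Apply a similarity map (rotation + uniform scale + translation)."""
        return Path([seg.transformed(fn) for seg in self.segments], closed=self.closed)

    def translated(self, offset) -> "Path":
        off = _as_point(offset)
        return self.transformed(lambda p: tuple(_as_point(p) + off))

    def rotated(self, angle: float, about=(0.0, 0.0)) -> "Path":
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        origin = _as_point(about)

        def fn(p):
            q = rot @ (_as_point(p) - origin) + origin
            return tuple(q)

        return self.transformed(fn)

    def __eq__(self, other):
        if not isinstance(other, Path):
            return NotImplemented
        return self.closed == other.closed and self.segments == other.segments

    def __repr__(self):
        kinds = "+".join(s.kind for s in self.segments)
        return f"Path({kinds}, closed={self.closed})"


def _invert_arclength(seg, target_length: float, seg_len: float, tol: float = 1e-13) -> float:
    """Local parameter t with partial_length(t) == target_length (bisection)."""
    if seg_len == 0.0:
        return 0.0
    if target_length <= 0.0:
        return 0.0
    if target_length >= seg_len:
        return 1.0
    if seg.kind in ("line", "arc"):
        return target_length / seg_len
    lo, hi = 0.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if seg.partial_length(mid) < target_length:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Geometry constructors
# ---------------------------------------------------------------------------

def _require_distinct(p1, p2):
    if np.array_equal(_as_point(p1), _as_point(p2)):
        raise DegenerateEdgeError(
            f"coincident endpoints {tuple(p1)}; use loop_path for self-loops"
        )


def straight_path(p1, p2) -> Path:
    """Single line segment p1 -> p2."""
    _require_distinct(p1, p2)
    return Path([LineSegment(tuple(p1), tuple(p2))])


def arc_path(p1, p2, tension: float) -> Path:
    """Circular arc whose midpoint bulges ``tension * |chord|`` left of the chord.

    ``tension=0`` degenerates to :func:`straight_path`; ``tension=0.5`` on any
    chord is an exact semicircle. Positive tension bulges left of the p1->p2
    direction of travel.
    """
    _require_distinct(p1, p2)
    if abs(tension) > 10.0:
        raise GeometryRangeError(f"|tension| must be <= 10, got {tension}")
    if tension == 0.0:
        return straight_path(p1, p2)
    a, b = _as_point(p1)[:2], _as_point(p2)[:2]
    chord = b - a
    chord_len = float(np.linalg.norm(chord))
    mid = 0.5 * (a + b)
    left = np.array([-chord[1], chord[0]]) / chord_len
    apex = mid + tension * chord_len * left
    # circle through a, apex, b: centre on the chord's perpendicular bisector
    sagitta = abs(tension) * chord_len
    radius = (chord_len**2 / 4.0 + sagitta**2) / (2.0 * sagitta)
    sign = 1.0 if tension > 0 else -1.0
    center = mid + sign * (sagitta - radius) * left
    t0 = math.atan2(a[1] - center[1], a[0] - center[0])
    t_apex = math.atan2(apex[1] - center[1], apex[0] - center[0])
    t1 = math.atan2(b[1] - center[1], b[0] - center[0])
    two_pi = 2 * math.pi
    ccw_total = (t1 - t0) % two_pi
    ccw_apex = (t_apex - t0) % two_pi
    if ccw_apex <= ccw_total:  # counterclockwise sweep passes through the apex
        sweep = ccw_total
    else:
        sweep = -((t0 - t1) % two_pi)
    return Path([ArcSegment(tuple(center), radius, t0, t0 + sweep)])


def bezier_path(p1, p2, controls: Sequence) -> Path:
    """Cubic Bezier from p1 to p2.

    One control point is treated as a quadratic Bezier and elevated exactly
    (``c1 = p1 + 2/3 (q - p1)``, ``c2 = p2 + 2/3 (q - p2)``); two control
    points give the cubic directly.
    """
    _require_distinct(p1, p2)
    controls = [tuple(c) for c in controls]
    if len(controls) == 1:
        q = _as_point(controls[0])
        a, b = _as_point(p1), _as_point(p2)
        c1 = a + 2.0 / 3.0 * (q - a)
        c2 = b + 2.0 / 3.0 * (q - b)
        return Path([CubicSegment(tuple(p1), tuple(c1), tuple(c2), tuple(p2))])
    if len(controls) == 2:
        return Path([CubicSegment(tuple(p1), controls[0], controls[1], tuple(p2))])
    raise ArityError(f"bezier_path needs 1 or 2 control points, got {len(controls)}")


def ports_path(p1, p2, theta_out: float, theta_in: float, strength: float = 1.0 / 3.0) -> Path:
    """Cubic Bezier leaving p1 at angle theta_out and arriving at p2 from
    direction theta_in (the arrival tangent points opposite theta_in).

    Control points sit ``strength * |chord|`` along the port directions — the
    standard cubic heuristic with default strength 1/3.
    """
    _require_distinct(p1, p2)
    if strength <= 0:
        raise GeometryRangeError("ports strength must be positive")
    a, b = _as_point(p1)[:2], _as_point(p2)[:2]
    chord_len = float(np.linalg.norm(b - a))
    c1 = a + strength * chord_len * np.array([math.cos(theta_out), math.sin(theta_out)])
    c2 = b + strength * chord_len * np.array([math.cos(theta_in), math.sin(theta_in)])
    return Path([CubicSegment(tuple(a), tuple(c1), tuple(c2), tuple(b))])


def waypoint_path(p1, p2, waypoints: Sequence) -> Path:
    """Polyline p1 -> each waypoint in order -> p2."""
    waypoints = [tuple(w) for w in waypoints]
    if not waypoints:
        raise ArityError("waypoint_path needs at least one waypoint (use straight)")
    stops = [tuple(p1), *waypoints, tuple(p2)]
    segments = [LineSegment(stops[i], stops[i + 1]) for i in range(len(stops) - 1)]
    return Path(segments)


_LOOP_HALF_ANGLE = 0.6  # lobe half-opening in radians; narrow enough that
# opposite loops on one vertex never overlap


def loop_path(p, loop_size: float, loop_angle: float) -> Path:
    """Self-loop lobe leaving and re-entering *p*.

    The lobe is a single closed cubic whose farthest point lies exactly
    ``loop_size`` data units from *p* in direction ``loop_angle``.
    """
    if loop_size <= 0:
        raise GeometryRangeError(f"loop_size must be positive, got {loop_size}")
    a = _as_point(p)[:2]
    phi = _LOOP_HALF_ANGLE
    # apex distance of the symmetric closed cubic is (3/4) * reach * cos(phi)
    reach = loop_size / (0.75 * math.cos(phi))
    u_plus = np.array([math.cos(loop_angle + phi), math.sin(loop_angle + phi)])
    u_minus = np.array([math.cos(loop_angle - phi), math.sin(loop_angle - phi)])
    c1 = a + reach * u_plus
    c2 = a + reach * u_minus
    return Path([CubicSegment(tuple(a), tuple(c1), tuple(c2), tuple(a))], closed=True)


def elbow_path(parent_coord, child_coord, kind: str, orientation: str = "right",
               center=(0.0, 0.0)) -> Path:
    """Tree elbow edge.

    Rectangular: a cross-axis move at the parent's main-axis coordinate, then
    a main-axis move to the child (corner = (parent main, child cross)).
    Radial: a circular sweep at the parent's radius from the parent's angle to
    the child's, then a radial segment outward to the child.
    """
    a = _as_point(parent_coord)[:2]
    b = _as_point(child_coord)[:2]
    if kind == "rectangular":
        if orientation in ("right", "left"):
            corner = np.array([a[0], b[1]])
        else:
            corner = np.array([b[0], a[1]])
        segments = []
        if not np.array_equal(corner, a):
            segments.append(LineSegment(tuple(a), tuple(corner)))
        if not np.array_equal(corner, b) or not segments:
            segments.append(LineSegment(tuple(corner), tuple(b)))
        return Path(segments)
    if kind == "radial":
        c = _as_point(center)[:2]
        r_parent = float(np.linalg.norm(a - c))
        if r_parent < 1e-12:
            return Path([LineSegment(tuple(a), tuple(b))])
        theta_parent = math.atan2(a[1] - c[1], a[0] - c[0])
        theta_child = math.atan2(b[1] - c[1], b[0] - c[0])
        sweep = (theta_child - theta_parent + math.pi) % (2 * math.pi) - math.pi
        segments = []
        corner = c + r_parent * np.array(
            [math.cos(theta_child), math.sin(theta_child)]
        )
        if abs(sweep) > 1e-12:
            segments.append(
                ArcSegment(tuple(c), r_parent, theta_parent, theta_parent + sweep)
            )
        if not np.allclose(corner, b) or not segments:
            segments.append(LineSegment(tuple(corner), tuple(b)))
        return Path(segments)
    raise GeometryRangeError(f"unknown elbow kind {kind!r}")


# ---------------------------------------------------------------------------
# Marker clipping, arrowheads, splitting
# ---------------------------------------------------------------------------

def _signed_outside(point, center, shape: str, size: float) -> float:
    """Positive outside the marker boundary, negative inside, 0 on it.

    *size* is the circle radius or the square half-width.
    """
    d = _as_point(point)[:2] - _as_point(center)[:2]
    if shape == "circle":
        return float(np.linalg.norm(d) - size)
    if shape == "square":
        return float(max(abs(d[0]), abs(d[1])) - size)
    raise GeometryRangeError(f"unknown marker shape {shape!r}")


def clip_at_marker(path: Path, marker_shape: str, marker_size: float,
                   end: str = "target", center=None, tol: float = 1e-12) -> Path:
    """Trim *path* where it crosses the boundary of a marker centred on one of
    its endpoints, so arrowheads stay visible outside the marker.

    *center* defaults to the corresponding path endpoint (the vertex
    position); pass it explicitly when re-clipping a path whose endpoint has
    already been moved onto the boundary — with the same center the operation
    is idempotent, because an endpoint on the boundary counts as outside.
    The crossing is located by a sampled march plus bisection on the global
    arc-length parameter (tolerance well below 1e-9 in position).
    """
    if end not in ("start", "target"):
        raise GeometryRangeError("end must be 'start' or 'target'")
    if center is None:
        center = path.end if end == "target" else path.start
    anchor_t = 1.0 if end == "target" else 0.0

    if _signed_outside(path.point_at(anchor_t), center, marker_shape, marker_size) >= -1e-9:
        return path  # endpoint already on/outside the boundary

    n_probe = 64 * len(path.segments)
    ts = np.linspace(0.0, 1.0, n_probe + 1)
    values = [
        _signed_outside(path.point_at(t), center, marker_shape, marker_size) for t in ts
    ]
    # walk from the clipped end toward the other end, find the first probe
    # interval containing a boundary crossing
    order = range(n_probe, 0, -1) if end == "target" else range(1, n_probe + 1)
    bracket = None
    for i in order:
        lo_i, hi_i = i - 1, i
        if end == "target":
            inside_side, outside_side = values[hi_i], values[lo_i]
        else:
            inside_side, outside_side = values[lo_i], values[hi_i]
        if inside_side < 0.0 <= outside_side:
            bracket = (ts[lo_i], ts[hi_i])
            break
    if bracket is None:
        raise FullyClippedError("marker swallows the entire path")

    lo, hi = bracket
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        v = _signed_outside(path.point_at(mid), center, marker_shape, marker_size)
        if end == "target":
            if v >= 0:
                lo = mid
            else:
                hi = mid
        else:
            if v >= 0:
                hi = mid
            else:
                lo = mid
        if hi - lo < tol:
            break
    crossing = 0.5 * (lo + hi)
    pieces = split_path(path, [crossing])
    return pieces[0] if end == "target" else pieces[1]


def arrowhead(path: Path, width: float, length: float):
    """Arrowhead triangle at the path's terminal point, plus the shortened path.

    The isoceles triangle's tip is the terminal point, its axis the terminal
    tangent; the path is shortened by *length* (arc length) so it abuts the
    triangle base. Width/length are in the same units as the path coordinates.
    """
    total = path.length()
    if length >= total:
        raise FullyClippedError(
            f"arrow length {length} exceeds path length {total}"
        )
    tip = _as_point(path.end)[:2]
    tangent = path.tangent_at(1.0)[:2]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        raise GeometryRangeError("terminal tangent is degenerate")
    tangent = tangent / norm
    normal = np.array([-tangent[1], tangent[0]])
    base_center = tip - length * tangent
    triangle = [
        tuple(tip),
        tuple(base_center + 0.5 * width * normal),
        tuple(base_center - 0.5 * width * normal),
    ]
    shortened = split_path(path, [(total - length) / total])[0]
    return triangle, shortened


def split_path(path: Path, fractions: Sequence[float]) -> list[Path]:
    """Partition *path* by arc-length fractions (strictly increasing, in (0,1)).

    The pieces cover the path in order and conserve total arc length; cubic
    segments are subdivided by de Casteljau at the parameter solving the
    arc-length equation, so concatenated geometry reproduces the original.
    An empty fraction list returns the path unchanged (single piece).
    """
    fractions = list(fractions)
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise GeometryRangeError(f"split fraction {f} outside (0, 1)")
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise GeometryRangeError("split fractions must be strictly increasing")
    if not fractions:
        return [Path(list(path.segments), closed=path.closed)]

    total = path.length()
    targets = [f * total for f in fractions]

    pieces: list[Path] = []
    current: list = []
    remaining = list(path.segments)
    rem_lengths = [seg.length() for seg in remaining]
    consumed = 0.0
    for target in targets:
        while remaining:
            seg_len = rem_lengths[0]
            if consumed + seg_len <= target + 1e-12:
                # whole segment fits before (or exactly at) the cut
                current.append(remaining.pop(0))
                rem_lengths.pop(0)
                consumed += seg_len
                if abs(consumed - target) <= 1e-12:
                    break
                continue
            local = _invert_arclength(remaining[0], target - consumed, seg_len)
            left, right = remaining[0].split(local)
            left_len = left.length()
            current.append(left)
            remaining[0] = right
            rem_lengths[0] = seg_len - left_len
            consumed += left_len
            break
        pieces.append(Path(current))
        current = []
    pieces.append(Path(current + remaining))
    return pieces


def elbow_corner_fraction(path: Path) -> list[float]:
    """Arc-length fractions of the interior segment joints (elbow corners)."""
    lengths = path.segment_lengths()
    total = sum(lengths)
    if total == 0 or len(lengths) < 2:
        return []
    acc = 0.0
    fractions = []
    for seg_len in lengths[:-1]:
        acc += seg_len
        f = acc / total
        if 0.0 < f < 1.0:
            fractions.append(f)
    return fractions
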