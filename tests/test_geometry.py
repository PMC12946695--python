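import math

import numpy as np
import pytest

from netcanvas.errors import (
    ArityError,
    DegenerateEdgeError,
    FullyClippedError,
    GeometryRangeError,
)
from netcanvas.geometry import (
    arc_path,
    arrowhead,
    bezier_path,
    clip_at_marker,
    elbow_corner_fraction,
    elbow_path,
    loop_path,
    ports_path,
    split_path,
    straight_path,
    waypoint_path,
)

from oracles import de_casteljau


class TestStraight:
    def test_two_point_line(self):
        path = straight_path((0, 0), (2, 0))
        assert path.start == (0.0, 0.0)
        assert path.end == (2.0, 0.0)
        assert len(path.segments) == 1

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateEdgeError):
            straight_path((0, 0), (0, 0))

    def test_length_is_euclidean_distance(self):
        path = straight_path((1, 2), (4, 6))
        assert path.length() == pytest.approx(5.0, abs=1e-12)


class TestArc:
    def test_zero_tension_is_straight(self):
        arc = arc_path((0, 0), (2, 1), 0.0)
        chord = straight_path((0, 0), (2, 1))
        assert np.allclose(arc.sample(50), chord.sample(50))

    def test_half_tension_is_a_semicircle(self):
        arc = arc_path((0, 0), (2, 0), 0.5)
        samples = arc.sample(721)
        # passes within 1e-9 of the apex (1, 1)
        apex_error = np.linalg.norm(samples - [1.0, 1.0], axis=1).min()
        assert apex_error < 1e-9
        # every sampled point is on the circle centred (1,0) with radius 1
        radii = np.linalg.norm(samples - [1.0, 0.0], axis=1)
        assert np.abs(radii - 1.0).max() < 1e-9

    def test_reversed_arc_is_the_reflected_point_set(self):
        # swapping endpoints flips "left of travel": arc(p2, p1, t) traces the
        # mirror image, so arc(p2, p1, -t) covers the same point set
        forward = arc_path((0, 0), (2, 1), 0.3).sample(201)
        backward = arc_path((2, 1), (0, 0), -0.3).sample(201)
        assert np.allclose(forward, backward[::-1], atol=1e-9)

    def test_negative_tension_bulges_right_of_travel(self):
        arc = arc_path((0, 0), (2, 0), -0.5)
        mid = arc.point_at(0.5)
        assert mid[1] == pytest.approx(-1.0, abs=1e-9)

    def test_extreme_tension_rejected(self):
        with pytest.raises(GeometryRangeError):
            arc_path((0, 0), (1, 0), 10.5)

    @pytest.mark.parametrize("tension", [1e-3, 1e-6])
    def test_deviation_vanishes_with_tension(self, tension):
        arc = arc_path((0, 0), (2, 0), tension)
        deviation = np.abs(arc.sample(101)[:, 1]).max()
        assert deviation <= tension * 2.0 + 1e-12


class TestBezier:
    def test_collinear_controls_degenerate_to_chord(self):
        path = bezier_path((0, 0), (2, 0), [(0, 0), (2, 0)])
        assert np.abs(path.sample(101)[:, 1]).max() == 0.0

    def test_midpoint_matches_de_casteljau(self):
        path = bezier_path((0, 0), (2, 0), [(0, 1), (2, 1)])
        seg = path.segments[0]
        assert tuple(seg.point(0.5)) == pytest.approx((1.0, 0.75), abs=1e-15)
        oracle = de_casteljau([(0, 0), (0, 1), (2, 1), (2, 0)], 0.5)
        assert tuple(seg.point(0.5)) == pytest.approx(tuple(oracle), abs=1e-15)

    def test_quadratic_elevation_is_exact(self):
        quadratic = bezier_path((0, 0), (2, 0), [(1, 1)])
        for t in np.linspace(0, 1, 33):
            expected = de_casteljau([(0, 0), (1, 1), (2, 0)], t)
            actual = quadratic.segments[0].point(t)
            assert np.abs(actual - expected).max() < 1e-12

    @pytest.mark.parametrize("controls", [[], [(0, 1), (1, 1), (2, 1)]])
    def test_wrong_control_count_rejected(self, controls):
        with pytest.raises(ArityError):
            bezier_path((0, 0), (2, 0), controls)


class TestPorts:
    def test_collinear_ports_follow_the_chord(self):
        path = ports_path((0, 0), (2, 0), 0.0, math.pi)
        assert np.abs(path.sample(101)[:, 1]).max() < 1e-12

    def test_control_point_formula(self):
        path = ports_path((0, 0), (2, 0), math.pi / 2, math.pi / 2)
        seg = path.segments[0]
        assert seg.c1 == pytest.approx((0.0, 2.0 / 3.0), abs=1e-12)
        assert seg.c2 == pytest.approx((2.0, 2.0 / 3.0), abs=1e-12)

    def test_departure_tangent_matches_port_angle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p1 = rng.normal(size=2)
            p2 = p1 + rng.normal(size=2)
            if np.linalg.norm(p2 - p1) < 1e-6:
                continue
            theta_out = float(rng.uniform(-math.pi, math.pi))
            theta_in = float(rng.uniform(-math.pi, math.pi))
            path = ports_path(tuple(p1), tuple(p2), theta_out, theta_in)
            tangent = path.segments[0].tangent(0.0)
            angle = math.atan2(tangent[1], tangent[0])
            diff = (angle - theta_out + math.pi) % (2 * math.pi) - math.pi
            assert abs(diff) < 1e-9

    def test_nonpositive_strength_rejected(self):
        with pytest.raises(GeometryRangeError):
            ports_path((0, 0), (1, 0), 0.0, 0.0, strength=0.0)


class TestWaypoints:
    def test_single_waypoint_polyline(self):
        path = waypoint_path((0, 0), (2, 0), [(1, 1)])
        assert path.points == [(0.0, 0.0), (1.0, 1.0), (2.0, 0.0)]

    def test_collinear_waypoints_preserve_chord_length(self):
        path = waypoint_path((0, 0), (2, 0), [(0.5, 0), (1.5, 0)])
        assert path.length() == pytest.approx(2.0, abs=1e-12)

    def test_empty_waypoints_rejected(self):
        with pytest.raises(ArityError):
            waypoint_path((0, 0), (2, 0), [])


class TestLoop:
    def test_apex_direction_and_distance(self):
        path = loop_path((1.0, 1.0), 0.5, math.pi / 2)
        samples = path.sample(4001)
        distances = np.linalg.norm(samples - [1.0, 1.0], axis=1)
        apex = samples[distances.argmax()]
        assert distances.max() == pytest.approx(0.5, abs=1e-9)
        assert apex == pytest.approx((1.0, 1.5), abs=1e-6)

    def test_opposite_loops_are_disjoint_away_from_the_vertex(self):
        from scipy.spatial.distance import cdist

        near = loop_path((0, 0), 0.4, 0.0).sample(500)
        far = loop_path((0, 0), 0.4, math.pi).sample(500)
        # the lobes share only the vertex itself; outside a small disc around
        # it the two point sets are well separated
        near = near[np.linalg.norm(near, axis=1) > 0.1]
        far = far[np.linalg.norm(far, axis=1) > 0.1]
        assert cdist(near, far).min() > 0.1

    def test_starts_and_ends_at_vertex(self):
        path = loop_path((2, 3), 0.3, 1.0)
        assert path.start == (2.0, 3.0)
        assert path.end == (2.0, 3.0)
        assert path.closed

    def test_nonpositive_size_rejected(self):
        with pytest.raises(GeometryRangeError):
            loop_path((0, 0), 0.0, 0.0)


class TestElbow:
    def test_rectangular_corner(self):
        path = elbow_path((0, 1.25), (1, 2), "rectangular")
        assert path.points == [(0.0, 1.25), (0.0, 2.0), (1.0, 2.0)]

    def test_shared_cross_coordinate_collapses_to_line(self):
        path = elbow_path((0, 1), (2, 1), "rectangular")
        assert len(path.segments) == 1

    def test_radial_sweep_stays_on_parent_radius(self):
        parent = (math.cos(0.3), math.sin(0.3))
        child = (2 * math.cos(1.1), 2 * math.sin(1.1))
        path = elbow_path(parent, child, "radial")
        arc_points = np.array(
            [path.segments[0].point(t) for t in np.linspace(0, 1, 64)]
        )
        radii = np.linalg.norm(arc_points, axis=1)
        assert np.abs(radii - 1.0).max() < 1e-9
        assert path.end == pytest.approx(child, abs=1e-12)

    def test_radial_root_at_origin_is_straight(self):
        path = elbow_path((0, 0), (1, 1), "radial")
        assert len(path.segments) == 1


class TestClipAtMarker:
    def test_circle_clip_on_axis(self):
        path = straight_path((0, 0), (2, 0))
        clipped = clip_at_marker(path, "circle", 0.5, "target")
        assert clipped.end == pytest.approx((1.5, 0.0), abs=1e-9)

    def test_square_clip_on_axis(self):
        path = straight_path((0, 0), (2, 0))
        clipped = clip_at_marker(path, "square", 0.5, "target")
        assert clipped.end == pytest.approx((1.5, 0.0), abs=1e-9)

    def test_start_end_clip(self):
        path = straight_path((0, 0), (2, 0))
        clipped = clip_at_marker(path, "circle", 0.25, "start")
        assert clipped.start == pytest.approx((0.25, 0.0), abs=1e-9)
        assert clipped.end == (2.0, 0.0)

    def test_marker_swallowing_path_rejected(self):
        path = straight_path((0, 0), (2, 0))
        with pytest.raises(FullyClippedError):
            clip_at_marker(path, "circle", 3.0, "target")

    def test_idempotent_with_fixed_center(self):
        path = straight_path((0, 0), (2, 0))
        once = clip_at_marker(path, "circle", 0.5, "target", center=(2, 0))
        twice = clip_at_marker(once, "circle", 0.5, "target", center=(2, 0))
        assert twice.end == once.end
        assert len(twice.segments) == len(once.segments)

    def test_clips_curved_paths(self):
        path = arc_path((0, 0), (2, 0), 0.5)
        clipped = clip_at_marker(path, "circle", 0.5, "target")
        boundary_distance = np.linalg.norm(np.asarray(clipped.end) - [2, 0])
        assert boundary_distance == pytest.approx(0.5, abs=1e-9)


class TestArrowhead:
    def test_horizontal_arrow_geometry(self):
        path = straight_path((0, 0), (1.5, 0))
        triangle, shortened = arrowhead(path, width=0.2, length=0.2)
        assert triangle[0] == pytest.approx((1.5, 0.0), abs=1e-12)
        base_center = 0.5 * (np.asarray(triangle[1]) + np.asarray(triangle[2]))
        assert base_center == pytest.approx((1.3, 0.0), abs=1e-9)
        assert shortened.end == pytest.approx((1.3, 0.0), abs=1e-9)

    def test_triangle_area(self):
        path = straight_path((0, 0), (3, 4))
        triangle, _ = arrowhead(path, width=0.4, length=0.6)
        a, b, c = (np.asarray(p) for p in triangle)
        u, v = b - a, c - a
        area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        assert area == pytest.approx(0.5 * 0.4 * 0.6, abs=1e-12)

    def test_arrow_longer_than_path_rejected(self):
        with pytest.raises(FullyClippedError):
            arrowhead(straight_path((0, 0), (0.1, 0)), 0.2, 0.5)


class TestSplitPath:
    def test_straight_halves(self):
        path = straight_path((0, 0), (2, 0))
        first, second = split_path(path, [0.5])
        assert first.length() == pytest.approx(1.0, abs=1e-12)
        assert second.length() == pytest.approx(1.0, abs=1e-12)
        assert first.end == second.start

    def test_elbow_corner_split(self):
        path = elbow_path((0, 1.25), (1, 2), "rectangular")
        fractions = elbow_corner_fraction(path)
        first, second = split_path(path, fractions)
        assert first.length() == pytest.approx(0.75, abs=1e-12)
        assert second.length() == pytest.approx(1.0, abs=1e-12)
        assert first.end == (0.0, 2.0)

    def test_empty_fractions_identity(self):
        path = straight_path((0, 0), (2, 0))
        (only,) = split_path(path, [])
        assert only.points == path.points

    def test_out_of_range_fraction_rejected(self):
        path = straight_path((0, 0), (2, 0))
        with pytest.raises(GeometryRangeError):
            split_path(path, [1.2])
        with pytest.raises(GeometryRangeError):
            split_path(path, [0.5, 0.5])

    @pytest.mark.parametrize("make", [
        lambda: straight_path((0, 0), (3, 1)),
        lambda: arc_path((0, 0), (2, 0), 0.4),
        lambda: bezier_path((0, 0), (2, 0), [(0, 1), (2, 1)]),
        lambda: waypoint_path((0, 0), (3, 0), [(1, 1), (2, -1)]),
    ])
    def test_length_conserved(self, make):
        path = make()
        pieces = split_path(path, [0.25, 0.6, 0.9])
        total = sum(p.length() for p in pieces)
        assert total == pytest.approx(path.length(), abs=1e-9)
        # pieces abut
        for left, right in zip(pieces, pieces[1:]):
            assert np.allclose(left.end, right.start, atol=1e-12)


class TestEquivariance:
    """All constructors commute with translations and rotations."""

    @pytest.mark.parametrize("seed", range(5))
    def test_translation_and_rotation(self, seed):
        rng = np.random.default_rng(seed)
        p1 = tuple(rng.normal(size=2))
        p2 = tuple(np.asarray(p1) + rng.normal(size=2) + 3.0)
        angle = float(rng.uniform(0, 2 * math.pi))
        shift = rng.normal(size=2)

        def transform_point(p):
            c, s = math.cos(angle), math.sin(angle)
            x, y = p[0], p[1]
            return (c * x - s * y + shift[0], s * x + c * y + shift[1])

        cases = [
            straight_path(p1, p2),
            arc_path(p1, p2, 0.4),
            bezier_path(p1, p2, [(0.0, 1.0), (1.0, 1.0)]),
            ports_path(p1, p2, 0.7, 2.1),
            waypoint_path(p1, p2, [(0.5, 0.5)]),
            loop_path(p1, 0.5, 1.0),
        ]
        for path in cases:
            transformed = path.rotated(angle).translated(shift)
            expected = np.array([transform_point(p) for p in path.sample(101)])
            assert np.allclose(transformed.sample(101), expected, atol=1e-9)

    def test_endpoint_contract(self):
        p1, p2 = (0.3, -1.2), (2.5, 0.7)
        for path in [
            straight_path(p1, p2),
            arc_path(p1, p2, -0.8),
            bezier_path(p1, p2, [(1, 1)]),
            ports_path(p1, p2, 1.0, -2.0),
            waypoint_path(p1, p2, [(1, 0)]),
        ]:
            assert np.allclose(path.start, p1, atol=1e-12)
            assert np.allclose(path.end, p2, atol=1e-12)
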