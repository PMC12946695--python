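import math

import numpy as np
import pytest

from netcanvas.core import build_network, build_tree
from netcanvas.errors import NodeLookupError, StructuralError
from netcanvas.fixtures import erdos_renyi, random_layout, random_tree
from netcanvas.scene import (
    GroupingSpec,
    assemble_scene,
    cascade_patch,
    depth_shade,
    group_hull,
    scale_scene,
    scene_from_json,
    scene_to_json,
    zoom_transform_check,
)
from netcanvas.style import flatten_style, get_default_style
from netcanvas.treelayout import TreeLayoutOptions, layout_radial, layout_rectangular


class TestAssembly:
    def test_triangle_scene_orders_edges_below_vertices(
        self, triangle_network, triangle_layout
    ):
        scene = assemble_scene(triangle_network, triangle_layout)
        kinds = [(p.kind, p.role) for p in scene.primitives]
        assert kinds[:3] == [("path", "edge")] * 3
        assert kinds[3:] == [("marker", "vertex")] * 3

    def test_directed_graph_gets_arrow_polygons(self):
        net = build_network([("A", "B")], directed=True)
        scene = assemble_scene(net, {"A": (0, 0), "B": (1, 0)})
        roles = [p.role for p in scene.primitives]
        assert roles == ["edge", "arrow", "vertex", "vertex"]
        arrow = scene.by_role("arrow")[0]
        assert arrow.geometry["xy"] == [1.0, 0.0]
        assert arrow.geometry["angle"] == pytest.approx(0.0)

    def test_primitive_count_invariant(self):
        # n markers + (m - loops) paths + loops loop-paths + directed ? m : 0
        net = build_network(
            [("A", "B"), ("B", "B"), ("B", "C"), ("A", "C"), ("A", "A")],
            directed=True,
        )
        layout = {"A": (0, 0), "B": (2, 0), "C": (1, 2)}
        scene = assemble_scene(net, layout)
        assert len(scene.by_role("vertex")) == 3
        assert len(scene.by_role("edge")) == 5
        assert len(scene.by_role("arrow")) == 5

    def test_assembly_is_deterministic(self):
        net = erdos_renyi(30, 60, seed=9)
        layout = random_layout(net, seed=10)
        a = scene_to_json(assemble_scene(net, layout))
        b = scene_to_json(assemble_scene(net, layout))
        assert a == b

    def test_per_element_edge_styles_resolve_positionally(self):
        net = build_network([("A", "B"), ("B", "C"), ("C", "A")])
        layout = {"A": (0, 0), "B": (1, 0), "C": (0, 1)}
        style = flatten_style(
            [get_default_style("default"), {"edge": {"color": ["red", "blue"]}}]
        )
        scene = assemble_scene(net, layout, style)
        colours = [p.style["color"] for p in scene.by_role("edge")]
        assert colours == [(1.0, 0.0, 0.0), (0.0, 0.0, 1.0), (1.0, 0.0, 0.0)]

    def test_loop_edges_use_loop_geometry(self):
        net = build_network([("A", "A"), ("A", "B")])
        layout = {"A": (0, 0), "B": (1, 0)}
        scene = assemble_scene(net, layout)
        loop_prim = scene.by_role("edge")[0]
        kinds = {seg["kind"] for seg in loop_prim.geometry["segments"]}
        assert kinds == {"cubic"}
        assert loop_prim.geometry["closed"]

    def test_default_loop_points_away_from_neighbours(self):
        net = build_network([("A", "A"), ("A", "B")])
        layout = {"A": (0, 0), "B": (1, 0)}
        scene = assemble_scene(net, layout)
        loop_prim = scene.by_role("edge")[0]
        xs = [p[0] for seg in loop_prim.geometry["segments"] for p in seg["points"]]
        assert max(xs) <= 0.0  # neighbour sits at +x, loop bulges to -x

    def test_vertex_labels_emitted_on_request(self, triangle_network, triangle_layout):
        style = flatten_style(
            [get_default_style("default"), {"vertex_label": {"text": "id"}}]
        )
        scene = assemble_scene(triangle_network, triangle_layout, style)
        labels = scene.by_role("vertex_label")
        assert [p.geometry["text"] for p in labels] == ["A", "B", "C"]
        assert all(
            p.index >= max(q.index for q in scene.by_role("vertex")) or True
            for p in labels
        )
        # labels come after vertices in the primitive order
        roles = [p.role for p in scene.primitives]
        assert roles.index("vertex_label") > roles.index("vertex")

    def test_split_edge_styling_on_tree_elbows(self, caterpillar_tree):
        layout = layout_rectangular(caterpillar_tree)
        style = flatten_style(
            [
                get_default_style("tree"),
                {"edge": {"split_colors": ["red", "blue"]}},
            ]
        )
        scene = assemble_scene(
            caterpillar_tree, layout, style, tree_kind="rectangular"
        )
        # edge to leaf A has an elbow corner -> two sub-paths, red then blue
        sub = [p for p in scene.by_role("edge") if p.element[0] == "A"]
        assert len(sub) == 2
        assert sub[0].style["color"] == (1.0, 0.0, 0.0)
        assert sub[1].style["color"] == (0.0, 0.0, 1.0)

    def test_grouping_hulls_drawn_below_edges(self, triangle_network, triangle_layout):
        grouping = GroupingSpec(
            groups={"g1": frozenset({"A", "B"}), "g2": frozenset({"C"})},
            mode="partition",
        )
        scene = assemble_scene(
            triangle_network, triangle_layout, grouping=grouping
        )
        roles = [p.role for p in scene.primitives]
        assert roles[:2] == ["grouping", "grouping"]

    def test_partition_validation(self, triangle_network, triangle_layout):
        overlapping = GroupingSpec(
            groups={"g1": frozenset({"A", "B"}), "g2": frozenset({"B", "C"})},
            mode="partition",
        )
        with pytest.raises(StructuralError):
            assemble_scene(
                triangle_network, triangle_layout, grouping=overlapping
            )
        # the same groups are fine as a cover
        cover = GroupingSpec(
            groups=dict(overlapping.groups), mode="cover"
        )
        scene = assemble_scene(triangle_network, triangle_layout, grouping=cover)
        assert len(scene.by_role("grouping")) == 2


class TestThreeD:
    def test_painter_sorting_far_to_near(self):
        net = build_network([("A", "B"), ("B", "C")])
        layout = {"A": (0, 0, 0.0), "B": (1, 0, 1.0), "C": (2, 0, 2.0)}
        scene = assemble_scene(net, layout)
        assert scene.ndim == 3
        zs = [p.z for p in scene.primitives]
        assert zs == sorted(zs)

    def test_depth_shading_applied_to_markers(self):
        net = build_network([("A", "B")])
        layout = {"A": (0, 0, 0.0), "B": (1, 0, 1.0)}
        style = flatten_style(
            [get_default_style("default"), {"vertex": {"facecolor": "red"}}]
        )
        scene = assemble_scene(net, layout, style)
        shades = {p.element: p.style["facecolor"] for p in scene.by_role("vertex")}
        assert shades["B"] == (1.0, 0.0, 0.0)  # nearest unchanged
        assert shades["A"] == pytest.approx((0.3, 0.0, 0.0))  # floor


class TestDepthShade:
    def test_fixed_points(self):
        assert depth_shade((1.0, 0.0, 0.0), 1.0, 0.0, 1.0) == (1.0, 0.0, 0.0)
        assert depth_shade((1.0, 0.0, 0.0), 0.0, 0.0, 1.0) == (0.3, 0.0, 0.0)
        mid = depth_shade((1.0, 1.0, 1.0), 0.5, 0.0, 1.0)
        assert mid == pytest.approx((0.65, 0.65, 0.65))

    def test_monotone_in_z(self):
        zs = np.linspace(-2, 2, 41)
        shades = [depth_shade((0.8, 0.5, 0.2), z, -2, 2) for z in zs]
        for channel in range(3):
            values = [s[channel] for s in shades]
            assert all(a <= b + 1e-15 for a, b in zip(values, values[1:]))

    def test_out_of_range_clamped(self):
        below = depth_shade((1.0, 1.0, 1.0), -99.0, 0.0, 1.0)
        above = depth_shade((1.0, 1.0, 1.0), 99.0, 0.0, 1.0)
        assert below == (0.3, 0.3, 0.3)
        assert above == (1.0, 1.0, 1.0)


class TestGroupHull:
    def test_triangle_with_zero_padding(self):
        ring = group_hull([(0, 0), (1, 0), (0, 1)], padding=0.0)
        assert set(ring) == {(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)}

    def test_single_point_becomes_a_disc(self):
        ring = np.array(group_hull([(2.0, 3.0)], padding=0.5))
        radii = np.linalg.norm(ring - [2.0, 3.0], axis=1)
        assert radii.max() <= 0.5 + 1e-9
        assert radii.min() >= 0.5 * math.cos(math.pi / 64)  # inscribed polygon

    def test_members_strictly_inside_padded_hull(self):
        import shapely

        rng = np.random.default_rng(0)
        points = rng.normal(size=(12, 2))
        ring = group_hull(points, padding=0.3)
        polygon = shapely.Polygon(ring)
        for p in points:
            assert polygon.contains(shapely.Point(p))

    def test_dilation_grows_area(self):
        import shapely

        points = [(0, 0), (2, 0), (1, 2)]
        small = shapely.Polygon(group_hull(points, padding=0.0))
        big = shapely.Polygon(group_hull(points, padding=0.4))
        assert big.area > small.area

    def test_empty_rejected(self):
        with pytest.raises(StructuralError):
            group_hull([], padding=0.1)


class TestCascade:
    def test_rectangular_band_for_internal_node(self, caterpillar_tree):
        layout = layout_rectangular(caterpillar_tree)
        patch = cascade_patch(
            caterpillar_tree, "i", layout, "rectangular", extent_to="subtree"
        )
        xs = [p[0] for p in patch.points]
        ys = [p[1] for p in patch.points]
        assert (min(xs), max(xs)) == (1.0, 2.0)
        assert (min(ys), max(ys)) == (-0.5, 1.5)

    def test_leaf_band_is_one_leaf_spacing_wide(self, caterpillar_tree):
        layout = layout_rectangular(caterpillar_tree)
        patch = cascade_patch(caterpillar_tree, "C", layout, "rectangular")
        ys = [p[1] for p in patch.points]
        assert (min(ys), max(ys)) == (1.5, 2.5)

    def test_sibling_bands_do_not_overlap(self):
        tree = random_tree(n_leaves=8, seed=2)
        layout = layout_rectangular(tree)
        for node in tree.nodes:
            kids = [k for k in tree.children[node] if tree.children[k]]
            if len(kids) < 2:
                continue
            bands = []
            for kid in kids:
                patch = cascade_patch(tree, kid, layout, "rectangular")
                ys = [p[1] for p in patch.points]
                bands.append((min(ys), max(ys)))
            bands.sort()
            for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
                assert hi1 <= lo2 + 1e-12

    def test_radial_sector_spans_subtree_angles(self, caterpillar_tree):
        opts = TreeLayoutOptions(kind="radial")
        layout = layout_radial(caterpillar_tree, opts)
        patch = cascade_patch(
            caterpillar_tree, "i", layout, "radial", tree_opts=opts
        )
        assert patch.closed
        arcs = [s for s in patch.segments if s.kind == "arc"]
        assert arcs  # annular sector contains at least the outer arc

    def test_unknown_node_rejected(self, caterpillar_tree):
        layout = layout_rectangular(caterpillar_tree)
        with pytest.raises(NodeLookupError):
            cascade_patch(caterpillar_tree, "zzz", layout, "rectangular")


class TestZoomContract:
    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
    def test_zoom_preserves_figure_space_attributes(self, scale):
        net = erdos_renyi(15, 30, seed=3)
        layout = random_layout(net, seed=4)
        scene = assemble_scene(net, layout)
        assert zoom_transform_check(scene, scale)

    def test_data_coordinates_scale_exactly(self, triangle_network, triangle_layout):
        scene = assemble_scene(triangle_network, triangle_layout)
        zoomed = scale_scene(scene, 10.0)
        marker = scene.by_role("vertex")[1]
        zoomed_marker = zoomed.by_role("vertex")[1]
        assert zoomed_marker.geometry["xy"] == [
            c * 10.0 for c in marker.geometry["xy"]
        ]
        # figure-space marker size untouched
        assert zoomed_marker.style["size"] == marker.style["size"]

    def test_label_font_size_survives_zoom(self, triangle_network, triangle_layout):
        style = flatten_style(
            [get_default_style("default"), {"vertex_label": {"text": "id"}}]
        )
        scene = assemble_scene(triangle_network, triangle_layout, style)
        zoomed = scale_scene(scene, 7.0)
        for before, after in zip(
            scene.by_role("vertex_label"), zoomed.by_role("vertex_label")
        ):
            assert before.style["size"] == after.style["size"]


class TestSerialisation:
    def test_json_round_trip_preserves_equality(self):
        net = erdos_renyi(10, 20, seed=1)
        layout = random_layout(net, seed=2)
        scene = assemble_scene(net, layout)
        text = scene_to_json(scene)
        assert scene_from_json(text) == scene
        assert scene_to_json(scene_from_json(text)) == text

    def test_negative_zero_collapsed(self):
        net = build_network([("A", "B")])
        scene = assemble_scene(net, {"A": (-0.0, 0.0), "B": (1.0, 0.0)})
        assert "-0.0" not in scene_to_json(scene)
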