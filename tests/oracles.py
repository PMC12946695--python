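"""Independent brute-force oracles used by the tests.

These are written against the *definitions* (recursive means, cumulative
branch lengths, de Casteljau evaluation), not against the library's own code
paths, so they stay a genuinely independent check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_rectangular(tree, use_branch_lengths=True):
    """Recursive oracle: leaf i -> cross i; internal -> mean of children;
    main = cumulative branch length from root."""
    cross: dict = {}
    next_leaf = [0]

    def assign_cross(node):
        kids = tree.children[node]
        if not kids:
            cross[node] = float(next_leaf[0])
            next_leaf[0] += 1
            return cross[node]
        values = [assign_cross(k) for k in kids]
        cross[node] = sum(values) / len(values)
        return cross[node]

    assign_cross(tree.root)

    main: dict = {}

    def assign_main(node, acc):
        main[node] = acc
        for kid in tree.children[node]:
            step = tree.branch_length[kid] if use_branch_lengths else 1.0
            assign_main(kid, acc + step)

    assign_main(tree.root, 0.0)
    return {node: (main[node], cross[node]) for node in tree.nodes}


def brute_force_radial(tree, angular_span=2 * math.pi, start_angle=0.0,
                       use_branch_lengths=True):
    """Angle by closed-form leaf formula + recursive child means; radius =
    cumulative branch length. Returns node -> (x, y)."""
    n_leaves = len(tree.leaf_order)
    step = angular_span / n_leaves
    angle: dict = {
        leaf: start_angle + i * step for i, leaf in enumerate(tree.leaf_order)
    }

    def assign_angle(node):
        kids = tree.children[node]
        if not kids:
            return angle[node]
        values = [assign_angle(k) for k in kids]
        angle[node] = sum(values) / len(values)
        return angle[node]

    assign_angle(tree.root)

    radius: dict = {}

    def assign_radius(node, acc):
        radius[node] = acc
        for kid in tree.children[node]:
            step_r = tree.branch_length[kid] if use_branch_lengths else 1.0
            assign_radius(kid, acc + step_r)

    assign_radius(tree.root, 0.0)
    return {
        node: (
            radius[node] * math.cos(angle[node]),
            radius[node] * math.sin(angle[node]),
        )
        for node in tree.nodes
    }


def de_casteljau(points, t):
    """Evaluate a Bezier curve of any degree by repeated interpolation."""
    pts = [np.asarray(p, dtype=float) for p in points]
    while len(pts) > 1:
        pts = [(1 - t) * a + t * b for a, b in zip(pts, pts[1:])]
    return pts[0]


def polyline_length(points):
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
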