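"""Synthetic graph/tree generators and a toy Newick reader.

Everything here is seeded and deterministic so tests and benchmarks need no
downloads. The Erdos-Renyi generator is the G(n, m) model (m distinct edges
uniform without replacement), matching benchmarks parameterised by node and
edge counts. The package deliberately has no general file readers — analysis
libraries own parsing — so the Newick reader supports only the toy subset
used by fixtures and the CLI: nested parentheses, labels, ``:length``, and a
terminating ``;`` (no comments, no quoted labels).
"""

from __future__ import annotations

import numpy as np

from .core import NetworkData, TreeData, build_network, build_tree
from .errors import GeometryRangeError, NewickParseError

__all__ = [
    "erdos_renyi",
    "random_tree",
    "random_layout",
    "parse_newick_toy",
    "write_newick",
]


def erdos_renyi(n: int, m: int, seed: int) -> NetworkData:
    """G(n, m): *m* distinct undirected edges sampled uniformly without
    replacement among the C(n, 2) vertex pairs. Deterministic per seed."""
    max_edges = n * (n - 1) // 2
    if not 0 <= m <= max_edges:
        raise GeometryRangeError(
            f"m={m} outside [0, {max_edges}] for n={n} vertices"
        )
    rng = np.random.default_rng(seed)
    vertex_ids = list(range(n))
    if m == 0:
        return build_network([], vertex_ids=vertex_ids)
    if m > max_edges // 2:
        # dense regime: sample pair indices without replacement
        chosen = rng.choice(max_edges, size=m, replace=False)
        chosen.sort()
        edges = [_pair_from_index(int(k), n) for k in chosen]
    else:
        # sparse regime: rejection sampling on pairs, insertion-ordered
        seen: dict[tuple[int, int], None] = {}
        while len(seen) < m:
            draw = rng.integers(0, n, size=2 * (m - len(seen)) + 8)
            for i in range(0, len(draw) - 1, 2):
                a, b = int(draw[i]), int(draw[i + 1])
                if a == b:
                    continue
                pair = (a, b) if a < b else (b, a)
                if pair not in seen:
                    seen[pair] = None
                    if len(seen) == m:
                        break
        edges = list(seen)
    return build_network(edges, vertex_ids=vertex_ids)


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """Decode linear index k into the k-th pair (i, j), i < j, row-major."""
    i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
    # guard against floating point at row boundaries
    while k >= (i + 1) * n - (i + 1) * (i + 2) // 2:
        i += 1
    while i > 0 and k < i * n - i * (i + 1) // 2:
        i -= 1
    offset = k - (i * n - i * (i + 1) // 2)
    return (i, i + 1 + offset)


def random_layout(data: NetworkData, seed: int, ndim: int = 2) -> dict:
    """Seeded uniform layout in the unit square/cube (a stand-in for the
    provider-computed embeddings the package normally consumes)."""
    rng = np.random.default_rng(seed)
    points = rng.random((data.n_vertices, ndim))
    return {
        vid: tuple(float(c) for c in points[i])
        for i, vid in enumerate(data.vertex_ids)
    }


def random_tree(n_leaves: int, seed: int) -> TreeData:
    """Random binary tree grown by sequential leaf attachment.

    Starting from a cherry (two leaves), each step picks a uniform random
    leaf and replaces it with an internal node carrying the old leaf and a
    fresh one, so a tree on L >= 2 leaves has exactly L - 1 internal nodes.
    Branch lengths are uniform(0.5, 1.5) — bounded away from zero so layouts
    never degenerate. Deterministic per seed.
    """
    if n_leaves < 1:
        raise GeometryRangeError("n_leaves must be >= 1")
    rng = np.random.default_rng(seed)
    if n_leaves == 1:
        parent_map = {"L0": "root"}
        lengths = {"L0": float(rng.uniform(0.5, 1.5))}
        return build_tree(parent_map, lengths)

    parent_map: dict[str, str] = {"L0": "root", "L1": "root"}
    leaves = ["L0", "L1"]
    next_leaf = 2
    next_internal = 0
    for _ in range(n_leaves - 2):
        victim = leaves[int(rng.integers(0, len(leaves)))]
        internal = f"I{next_internal}"
        next_internal += 1
        fresh = f"L{next_leaf}"
        next_leaf += 1
        old_parent = parent_map[victim]
        # splice: victim's slot is taken by the new internal node
        new_map: dict[str, str] = {}
        for child, parent in parent_map.items():
            if child == victim:
                new_map[internal] = old_parent
                new_map[victim] = internal
            else:
                new_map[child] = parent
        new_map[fresh] = internal
        parent_map = new_map
        leaves.append(fresh)  # victim stays a leaf under the new internal
    lengths = {
        node: float(rng.uniform(0.5, 1.5)) for node in parent_map
    }
    return build_tree(parent_map, lengths)


# ---------------------------------------------------------------------------
# Toy Newick subset
# ---------------------------------------------------------------------------

def parse_newick_toy(text: str) -> TreeData:
    """Parse the toy Newick subset into a :class:`TreeData`.

    Unlabelled internal nodes are auto-named ``_1``, ``_2``, ... in the order
    their closing parenthesis appears (deterministic).
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"missing terminating ';' at position {len(text)}"
        )
    body = stripped[:-1]
    pos = 0
    counter = [0]
    parent_entries: list[tuple[str, str]] = []  # (child, parent), input order
    lengths: dict[str, float] = {}

    def fail(message: str, at: int):
        raise NewickParseError(f"{message} at position {at}")

    def parse_clade() -> str:
        nonlocal pos
        children: list[str] = []
        if pos < len(body) and body[pos] == "(":
            pos += 1
            while True:
                children.append(parse_clade())
                if pos >= len(body):
                    fail("unbalanced parentheses: unexpected end of input", pos)
                if body[pos] == ",":
                    pos += 1
                    continue
                if body[pos] == ")":
                    pos += 1
                    break
                fail(f"unexpected character {body[pos]!r}", pos)
        # label
        start = pos
        while pos < len(body) and body[pos] not in "(),:;":
            pos += 1
        label = body[start:pos].strip()
        if not label:
            if not children:
                fail("empty leaf label", start)
            counter[0] += 1
            label = f"_{counter[0]}"
        # branch length
        if pos < len(body) and body[pos] == ":":
            pos += 1
            start = pos
            while pos < len(body) and body[pos] not in "(),:;":
                pos += 1
            try:
                lengths[label] = float(body[start:pos])
            except ValueError:
                fail(f"invalid branch length {body[start:pos]!r}", start)
        for child in children:
            parent_entries.append((child, label))
        return label

    root = parse_clade()
    if pos != len(body):
        fail(f"trailing characters {body[pos:]!r}", pos)
    if not parent_entries:
        # single node "A;": model as a root with one leaf is impossible
        # without an edge; treat as a root-only tree via a synthetic edge-free
        # structure is unsupported — require at least one pair of parentheses.
        raise NewickParseError("tree must contain at least one clade at position 0")

    # children order follows appearance order within each clade: entries were
    # appended per clade after recursion, preserving sibling order
    parent_map = dict(parent_entries)
    _ = root
    return build_tree(parent_map, lengths if lengths else None)


def write_newick(tree: TreeData, include_lengths: bool = True) -> str:
    """Inverse of :func:`parse_newick_toy` (topology and lengths round-trip)."""

    def render(node) -> str:
        kids = tree.children[node]
        label = str(node)
        inner = f"({','.join(render(k) for k in kids)})" if kids else ""
        suffix = ""
        if include_lengths and node != tree.root:
            suffix = f":{tree.branch_length[node]:g}"
        shown = "" if label.startswith("_") and kids else label
        return f"{inner}{shown}{suffix}"

    return render(tree.root) + ";"
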