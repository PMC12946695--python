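# netcanvas

Backend-agnostic rendering middleware for networks and trees.

Network analysis libraries (for gene-regulatory networks, protein–protein
interactions, ecological webs, phylogenies, …) are excellent at statistics
and layouts but thin on visualisation, and every one of them draws a graph
slightly differently. `netcanvas` sits between analysis and rendering: any
input a *provider* understands is normalised into one canonical data model,
styled through a single declarative cascading grammar, routed through a
computational-geometry engine (straight edges, circular arcs, cubic Beziers,
incidence-angle "ports", waypoints, self-loop lobes, tree elbows), and
assembled into a deterministic **Scene** of draw primitives. Two scenes built
from the same abstract graph are byte-identical regardless of which library
supplied it.

## Core ideas

**Dual coordinate spaces.** Positions (vertex centres, edge paths, hull
rings) live in *data units* and scale under zoom; size-like properties
(marker size, line width, arrow dimensions, font size) live in *figure
units* (points) and are zoom-invariant — the behaviour users expect from any
charting library.

**Cascading styles.** A style document maps element type → property →
value, where a value is a scalar (global), a sequence (positional
per-element, recycled as `index mod len`), or a mapping (per-element by id).
Fragments are deep-merged over a complete built-in style (`default`,
`minimal`, `tree`), later layers winning key-by-key.

**Tree layouts.** Rectangular and radial embeddings are computed internally:
leaf *i* sits at cross-coordinate *i* (or angle `start + i·span/L`), internal
nodes at the mean of their children, and the main axis (or radius) is the
cumulative branch length from the root. General network layouts are consumed
from providers, not computed.

**Geometry is exact.** Arcs use an exact circular parameterisation (a
tension-0.5 arc on a chord of length 2 passes through the perpendicular
point at height 1 to better than 1e-9); quadratic Beziers are elevated to
cubics exactly; paths are split by arc length with de Casteljau subdivision.

## Worked example

```python
import netcanvas as nc

graph = {
    "edges": [("gene1", "gene2"), ("gene2", "gene3"),
              ("gene3", "gene1"), ("gene3", "gene3")],
    "layout": {"gene1": (0, 0), "gene2": (2, 0), "gene3": (1, 1.5)},
}
handle = nc.network(graph, style={"edge": {"geometry": "arc", "tension": 0.3}})
scene = handle.scene
print("primitives:", [(p.kind, p.role) for p in scene.primitives])
print("edge 0 segment kind:", scene.by_role("edge")[0].geometry["segments"][0]["kind"])
print("svg bytes:", len(handle.to_svg()))

th = nc.tree("((A:1,B:2):0.5,C:3);", kind="rectangular", leaf_labels=True)
coords = {p.element: p.geometry["xy"] for p in th.scene.by_role("vertex")}
for leaf in ("A", "B", "C"):
    print(f"leaf {leaf}: x = {coords[leaf][0]}, y = {coords[leaf][1]}")
```

prints

```
primitives: [('path', 'edge'), ('path', 'edge'), ('path', 'edge'), ('path', 'edge'), ('marker', 'vertex'), ('marker', 'vertex'), ('marker', 'vertex')]
edge 0 segment kind: arc
svg bytes: 885
leaf A: x = 1.5, y = 0.0
leaf B: x = 2.5, y = 1.0
leaf C: x = 3.0, y = 2.0
```

The four edges include a self-loop on `gene3`, drawn as a closed cubic lobe
pointing away from its neighbours; edges sort below vertices (fixed stacking:
grouping < cascade < edge < arrow < vertex < label). The tree's leaf x
coordinates are the cumulative branch lengths from the root (1.5 = 0.5 + 1,
2.5 = 0.5 + 2, 3.0), and the y coordinates are the uniform unit leaf
spacing.

Other entry points: `nc.tree_pair(t1, t2, links=...)` draws a tanglegram
(two facing rectangular trees with straight leaf-to-leaf links), and
`nc.register_provider(...)` plugs in adapters for foreign graph objects.
`handle.export("out.svg" | "out.json" | "out.png")` writes files; svg and
json are byte-deterministic. A thin CLI mirrors this:

```sh
netcanvas network --edges edges.tsv --layout layout.tsv --style style.json --out out.svg
netcanvas tree --newick tree.nwk --kind radial --out out.svg
```

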