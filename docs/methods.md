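# Methods

## Data model

A network is an ordered vertex list plus an ordered edge list (`NetworkData`);
a tree is a parent/children structure with per-node branch lengths and a
derived depth-first leaf order (`TreeData`); a layout is a vertex →
coordinate mapping tagged 2D or 3D (`LayoutResult`). Vertex identity is by
label, but per-element styling addresses elements *positionally* by their
insertion order, so self-loops and parallel edges are distinct styleable
elements. This positional rule is what makes rendering independent of the
provider: two providers that emit the same ordered edge list produce
byte-identical scenes, which is the package's central guarantee and is
checked end-to-end in the tests and the acceptance script.

Providers are (matcher, converter, optional layout-extractor) triples held
in a registry. Discovery is registry precedence — user-registered providers
are tried before the built-ins (`internal`, `internal_tree`, `edgelist`,
`newick`), first match wins — rather than import probing, which keeps
detection deterministic and side-effect-free. The package ships no adapters
for specific third-party graph libraries; those are extension points, and
the built-in edge-list dialect (`{"edges": ..., "vertices": ...,
"directed": ..., "vertex_attrs": ..., "edge_attrs": ..., "layout": ...}`)
is the reference foreign format.

## Style grammar

Element types: `vertex`, `edge`, `arrow`, `loop`, `vertex_label`,
`edge_label`, `cascade`, `grouping`. Property values may be scalars,
positional sequences (recycled by `index mod len`, the grammar-of-graphics
convention for short lists), or id-keyed mappings (missing ids fall back to
the `default` built-in's value). Precedence is: per-element value over
global scalar within a layer; later layer over earlier; built-in defaults
lowest. `flatten_style` is associative (property-tested), and sequence or
mapping values replace — never merge element-wise with — their
predecessors.

One wrinkle the grammar must resolve: some properties are *inherently*
sequences for a single element (`waypoints`, `ports`, `control_points`,
`split_colors`). For these, a sequence is one global value and per-element
variation requires an id mapping; positional recycling applies to everything
else.

The property vocabulary is a deliberate minimum that covers the feature set
(geometry kind, tension, ports, waypoints, split styling, loop size/angle,
label offsets, cascade extent, hull padding/rounding); it is not an attempt
to clone any particular package's property names. Quantitative colouring
goes through matplotlib's named colormaps with a linear norm (default
vmin/vmax from the data; constant data without an explicit norm is an
error); the normalisation record is kept on the Scene so a colour bar can be
drawn later. Named colours resolve through the fixed CSS basic table so
scenes never depend on a backend's colour database.

## Edge geometry

Paths are sequences of analytic segments: lines, cubic Beziers, and exact
circular arcs (centre, radius, signed angle sweep). Arcs are kept exact
internally and converted to SVG arc commands or ≤90° cubic pieces only at
export; this is why the semicircle oracle holds to 1e-9 rather than the
~1e-4 of a cubic approximation.

Conventions (the original parameterisations are not published, so these are
declared conventions of this package):

* **Tension** is dimensionless: the arc's midpoint bulge as a fraction of
  chord length, positive to the left of travel. Scale-invariant and
  sign-unambiguous; tension 0 degenerates to the straight line, |tension| is
  capped at 10 to avoid numerically absurd circles.
* **Ports** are radians counterclockwise from +x in data space; control
  points sit at `strength × |chord|` along the port directions with default
  strength ⅓ (the standard cubic heuristic). The departure tangent equals
  θ_out exactly; the arrival tangent opposes θ_in.
* **Quadratic elevation** is exact: `c1 = p1 + ⅔(q − p1)`, `c2 = p2 + ⅔(q −
  p2)`.
* **Self-loops** are a single closed cubic with control points at half-angle
  0.6 rad about the loop direction, scaled so the farthest point of the lobe
  lies exactly `loop_size` data units from the vertex (the apex of the
  symmetric closed cubic is at ¾·reach·cos φ). The default direction points
  away from the centroid of the vertex's neighbours, falling back to +90°
  for isolated vertices — no placement rule is published, so this heuristic
  simply keeps loops out of the graph body.
* **Elbows**: rectangular tree edges are cross-then-main two-segment paths
  (corner at (parent main, child cross)); radial tree edges sweep an exact
  arc at the parent's radius then run radially outward.

Marker clipping and arrowheads: clipping locates the first boundary crossing
(walking from the clipped end) by a 64-sample-per-segment march plus
bisection on the global arc-length parameter to a tolerance of 1e-12 in
parameter (far below 1e-9 in position); this one mechanism covers circles,
squares, and any curved path uniformly instead of special-casing the
line/circle intersection. An endpoint already on the boundary counts as
outside, so re-clipping with the same marker centre is a no-op. Arc-length
computations on cubics use 16-point Gauss–Legendre quadrature; splitting a
cubic at an arc-length fraction solves the inverse problem by bisection and
subdivides by de Casteljau, so total length is conserved to 1e-9 and
concatenated pieces reproduce the curve.

## Tree layouts

Leaf spacing is fixed at one data unit (cross axis) or one angular step
`span / L` (radial; dividing by L rather than L−1 reserves a closing gap so
leaf 0 and leaf L−1 never collide on a full circle). Internal nodes take the
plain arithmetic mean of their children's cross coordinates/angles — not a
subtree-size-weighted mean; the weighting variant is not specified anywhere,
and the plain mean is the simplest deterministic choice. Main-axis
coordinates are cumulative branch lengths (or integer depth when
`use_branch_lengths=False`; absent branch lengths default to 1.0 so
topology-only trees still lay out). Both layouts are linear in a global
branch-length rescaling, and both induce the same leaf order — properties
verified against an independent recursive oracle in the tests.

Cascade patches use the contiguity of `leaf_segment` (leaves under a node
form a contiguous index range in depth-first order): a rectangular patch is
the axis-aligned band over that range ± half a leaf spacing, from the node's
main coordinate to the farthest leaf (or the subtree's own maximum); a
radial patch is the corresponding annular sector built from exact arcs.

## Scene assembly

Primitives are ordered by fixed stacking classes — grouping < cascade <
edge < arrow < vertex < label — then by element index; the published figures
show edges under vertices but never state a rule, so the class order is
fixed here once. In 3D, primitives are painter-sorted far-to-near on depth
(z rounded to 9 significant digits) before the class order applies among
equal depths, and vertex/edge colours are dimmed by the depth factor
`floor + (1 − floor)(z − zmin)/(zmax − zmin)` with floor 0.3 (out-of-range z
clamps rather than errors). Projection is delegated to the backend.

Grouping hulls are convex hulls (shapely) dilated by the `padding` style
property with round or mitred joins; a single point dilates to a disc.
Partition-mode groupings must be disjoint and covering; cover mode allows
overlaps.

Arrow primitives store (tip, tangent angle) in data space and width/length
in figure space; materialising the triangle is the backend's job, because a
data-space triangle would change size under zoom and break the dual
coordinate contract. The standalone `arrowhead()` geometry operation, by
contrast, works entirely in path units and returns the explicit triangle.

Determinism: the scene serialises to JSON with sorted keys and floats
normalised to 9 significant digits (negative zero collapsed); byte equality
of this form is the scene-equality surface used by the provider-equivalence
and determinism checks. The SVG writer is likewise a pure function of the
scene (one `<g>` per stacking class).

The cyclic garbage collector is paused (and restored in a `finally`) while
primitives are built: the scene graph is acyclic, and generational
collection over a steadily growing object graph otherwise makes bulk
assembly measurably superlinear. With the pause, assembly time per element
is constant and the per-decade runtime ratio on G(n, 2n) benchmarks sits
near the nominal 10.

## Synthetic data

`erdos_renyi(n, m, seed)` is the G(n, m) model — m distinct undirected
edges uniform without replacement (index-decoding in the dense regime,
rejection sampling in the sparse regime), matching benchmarks parameterised
by node and edge counts. `random_tree` grows a binary tree by sequential
leaf attachment with branch lengths uniform(0.5, 1.5), bounded away from
zero so layouts never degenerate. `random_layout` is a seeded uniform
embedding standing in for the provider-computed layouts the package normally
consumes. These fixtures exercise structure, determinism, and scaling; they
do not emulate the degree distributions, communities, or layout quality of
real biological networks, so passing tests demonstrate correctness of the
rendering pipeline, not fitness of any layout algorithm.

The toy Newick reader exists only for fixtures and the CLI (subset: nested
parentheses, labels, `:length`, terminating `;`; no comments or quoted
labels) — general file parsing is deliberately left to the analysis
libraries that already own it.

## Problem sizes and limitations

The scalability benchmark uses n = 10³, 10⁴, 10⁵ with m = 2n (best of a few
repeats per size); the provider-equivalence check uses 100 seeded graphs
with n = 25, m = 50; geometry and tree oracles use 10²–10³ randomised cases.

Known limitations: no edge bundling, collision-avoiding routing, unrooted
tree layouts, or ladderisation; 3D scenes restrict edges to straight
segments; PNG output is a backend rasterisation with no byte-determinism
guarantee (arrow sizes in raster output use a heuristic data-scale
conversion); the CLI reads only the toy TSV/Newick formats.
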