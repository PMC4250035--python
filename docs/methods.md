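# Methods

## Data model

A network is a symmetric, non-negative-or-signed weight matrix `W` bound to
an *ordering*: a plain-text list of region names in which line *k* names
row/column *k*.  All networks are undirected; an asymmetric input is either
rejected or, on request, coerced to `(A + Aᵀ)/2`, which preserves total
edge weight and is deterministic.  Diagonal entries are zeroed at
construction — self-connections carry no meaning for any statistic or view
here.  Symmetry is enforced to within `1e-8` after construction.

The spatial embedding comes from a parcellation in one of three forms:

1. **Surface parcels** — a triangulated cortical mesh plus a per-vertex
   annotation.  A node's center is the arithmetic mean of its parcel's
   vertex coordinates.  The mean can fall off the mesh for deeply folded
   parcels, so a `nearest_vertex` option snaps the center to the closest
   member vertex instead; the mean is the default because it is smooth,
   parameter-free, and stable under mesh refinement.
2. **Labeled volumes** — integer segmentation images for structures that
   surface annotations do not cover (subcortex).  The centroid of the
   voxel *indices* carrying a label is mapped through the image affine
   under the voxel-center convention (index `i` maps to coordinate `i`, no
   half-voxel shift); the convention is stated explicitly because imaging
   ecosystems disagree on it.  The shipped label lookup covers the standard
   FreeSurfer aseg codes for thalamus, caudate, putamen, pallidum,
   hippocampus, amygdala, accumbens (left/right) and brainstem, and is
   config-extendable, since no canonical "subcortical set" exists.
3. **Coordinate tables** — name plus three stereotaxic coordinates per
   row, for electrode-style parcellations.

Region names are matched exact-first, then case-insensitively after
canonicalizing hemisphere markers: `lh_X`, `lh.X`, `X-lh`, and `Left-X`
all reduce to the key `(lh, x)`.  A parcellation may not contain two nodes
with the same canonical key.  An optional 4×4 homogeneous registration
matrix (bottom row `[0,0,0,1]`, invertible) maps volume-derived centers
into the anatomical surface space.

## Thresholding

Whole-brain matrices are dense; drawing every entry is illegible and slow.
The default threshold keeps the **500 strongest connections** (undirected
edges, counted once), a cutoff that balances legibility and rendering cost
at typical whole-brain scales; count, proportion, and absolute-value modes
expose full control.  "Strongest" defaults to the signed weight, with a
magnitude option for correlation networks whose negative couplings are
meaningful.  Rank ties break by ascending `(i, j)` index so thresholded
edge sets — and therefore rendered images — are reproducible byte for
byte.  Whether a "connection count" should mean undirected edges or matrix
entries is ambiguous in general; this package fixes undirected edges.

## Statistics

Formulas are the standard forms used throughout the brain-connectivity
literature:

* **strength** — `s_i = Σ_j W_ij` (weighted degree);
* **clustering** — Watts–Strogatz `C_i = 2 t_i / (k_i (k_i − 1))` on the
  graph binarized at `w > 0`; the weighted variant replaces each triangle
  with the geometric mean of its three max-normalized weights (Onnela);
  degree < 2 yields 0;
* **efficiency** — Latora–Marchiori: mean of `1/d_ij` over ordered pairs
  with `1/∞ = 0`; weighted path lengths use `1/w`; local efficiency of a
  node is the global efficiency of the subgraph induced on its neighbors;
* **betweenness** — Brandes dependency accumulation, unnormalized,
  endpoints excluded, each unordered pair counted once;
* **eigenvector centrality** — principal eigenvector of `W` by power
  iteration (tolerance `1e-10`, diagonal shift to guarantee a dominant
  eigenvalue on bipartite-like graphs), normalized to unit maximum; on a
  disconnected network it is computed on the largest component with zeros
  elsewhere and a warning, since the statistic is undefined across
  components;
* **modularity** — Newman–Girvan
  `Q = (1/2m) Σ_ij (W_ij − s_i s_j / 2m) δ(c_i, c_j)`.

Weighted variants reduce exactly to binary ones when all weights are 1
(property-tested).  Negative weights are rejected by the path-based and
modularity operations with guidance to threshold or take absolute values
first; signed-network statistics have no single accepted definition and
are not silently approximated.

### Module detection

Communities are found by recursive spectral bisection: split a group along
the sign of the leading eigenvector of the (generalized) modularity matrix
`B_ij = W_ij − s_i s_j / 2m`, where within a subgroup the diagonal is
adjusted so rows sum to zero.  After each bisection a Kernighan–Lin-style
fine-tuning pass repeatedly moves the single node whose switch most
increases `Q`, stopping when no move gains more than `1e-12`; the scan
order is ascending node index, so the pass is deterministic.  Recursion
stops when the leading eigenvalue or the split's `Q` contribution is not
positive (tolerance `1e-10`), which guarantees the result never scores
below the trivial single-module partition (`Q = 0` exactly, an analytic
identity).  The seed enters only to break the sign of eigenvector entries
that are numerically zero; on generic inputs the algorithm is fully
deterministic.  Eigenvector sign is fixed by making the largest-magnitude
entry positive.

## Views

One `Scene` — parcellation, network, active edge set, optional scalars,
optional partition, optional surface, style — feeds all three renderers,
which is how the "linked views" behave in a non-interactive setting: any
isolation or mapping is applied to the scene once and appears in all
exports.  Interactive gestures (clicking a node, picking a module) are
API/CLI parameters instead.  Each renderer emits a JSON draw log; the
logged connection count equals the active edge set size in all three by
construction, and the tests verify it.

* **3-D brain** — orthographic projection with a painter's algorithm:
  surface triangles, edge segments, and node discs are depth-sorted and
  rasterized through the Agg backend.  There is no GPU or scene-graph
  dependency, and a fixed scene + camera + style yields byte-identical
  PNGs.  Camera presets: left/right-lateral, dorsal, ventral, anterior,
  posterior, or explicit azimuth/elevation.  The cortical mesh defaults to
  opacity 0.15.
* **Matrix** — `n × n` heatmap in ordering order; cells outside the active
  edge set carry the background color; per-node anatomical-group colors
  band both axes.  The drawn cell array is exposed separately
  (`matrix_cell_colors`) so ordering equivariance is testable on values
  rather than pixels.
* **Circle** — node *k* sits at angle `start − 360k/n` degrees (start 90°,
  i.e. the top, proceeding clockwise), so an ordering listing the left
  hemisphere first, swept front → parietal → occipital → temporal, groups
  short-range connections into adjacent arcs.  Edges are cubic Béziers
  whose interior control points sit at the endpoint angles but at radius
  `r·(1 − g/180°)`, clamped to `[0.05r, 0.95r]`, where `g` is the angular
  separation: adjacent nodes get shallow arcs, antipodal ones pass through
  the center.  This is a simple, deterministic stand-in for hierarchical
  edge bundling, which is out of scope.

Edge colors map weight **rank** (robust to outlier weights; a linear mode
is available) through a yellow→red profile by default, with a blue→orange
alternative for correlation matrices.  Scalar node mapping is linear from
the scalar's min/max onto the radius range (default 2–7 mm) and a
light-to-dark-green colormap; a constant scalar maps to the midpoint.
Module display draws each module in a distinct color from a seeded random
palette; isolating a module keeps only edges with *both* endpoints inside
it and recolors in-module nodes purple versus blue elsewhere.

## Synthetic data

The fixture generator emulates the *structure* of real inputs, not their
content: two mirrored ellipsoid "hemispheres" (icosphere meshes scaled to
28 × 65 × 45 mm semi-axes) are parcellated into nearest-seed angular
sectors grouped into four lobes; a 24³ 2 mm volume holds two subcortical
blobs per hemisphere under real aseg codes; networks are planted-partition
graphs (defaults `p_in = 0.9`, `p_out = 0.05`, uniform (0,1] weights) or a
distance-decay background with boosted homologous left/right pairs, the
signature of interhemispheric functional connectivity.  The default scale
is 33 nodes per hemisphere (~66 cortical nodes), mirroring the coarsest
whole-brain parcellations in common use; tests mostly run an 8-per-
hemisphere variant on the 42-vertex icosphere.

Passing tests on these fixtures demonstrates correct geometry handling,
format round-trips, statistic values, and recovery of planted structure.
They do not demonstrate robustness to real-data pathologies — motion or
susceptibility artifacts, parcel size imbalance, negative correlation
tails, or mesh topology defects — and module recovery rates on planted
partitions say nothing about the detectability of modules in empirical
networks.

## Verification

Every statistic is checked against an independent brute-force oracle
(exhaustive Floyd–Warshall relaxation, triangle enumeration, the direct
modularity double sum, a dense eigensolver, and networkx's reference
betweenness) on 200 random graphs of up to 8 nodes, plus analytic
identities: `Q` of a single module is 0, clustering and efficiency of a
complete graph are 1, a 3-node path has binary efficiency 5/6, and two
disconnected triangles partitioned by component have `Q = 1/2`.  Module
detection must split twin 5-cliques exactly and recover a planted
2-module partition (n = 40, `p_in = 0.9`, `p_out = 0.05`) up to relabeling
in at least 95 of 100 seeds; it achieves 100.  Linked-view consistency is
checked over 50 random scenes, and the acceptance script re-measures a
20-scene sample.  These problem sizes keep the full suite under half a
minute while exercising every code path; all sizes are stated in the
tests and in `scripts/acceptance.py`.

## Known limitations

* Only single-edged, undirected, static networks: no directed effective
  connectivity, no multigraphs (e.g. per-frequency-band MEG edges), no
  dynamic networks.
* No connectivity estimation, group statistics, permutation testing, or
  surface reconstruction — all upstream or downstream of this tool.
* Signed networks are supported for thresholding/rendering (absolute
  ranking) but not for path-based statistics or modularity.
* The 3-D renderer's painter's algorithm sorts whole primitives; mutually
  intersecting translucent triangles can draw in slightly wrong order, an
  accepted artifact of GPU-free deterministic rendering.
* GIFTI surfaces store float32 coordinates, so surface round-trips are
  exact only to ~1e-3 mm; text, NIFTI, and annotation round-trips are
  exact to 1e-12 or bit-exact.
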