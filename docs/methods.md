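# Methods

This note records the models, conventions and design decisions behind
the engine, in enough detail to predict its output exactly.

## The scene model

All layout emits primitives in a single normalized coordinate system:
the unit square with the origin at the bottom-left and y pointing up.
A primitive is a rect, line, polyline, text or marker with style fields
(8-digit lowercase hex RGBA colors, stroke widths in figure fractions)
and optional semantic tags (heatmap cells carry their row/column ids;
renderers drop tags). Coordinates may bleed at most 0.01 outside the
unit square, a tolerance reserved for label text.

Serialization is canonical: JSON with sorted keys and floats rounded to
1e-6. Two layouts are equal iff their documents are byte-identical,
which is what the determinism and composition tests assert. Rendering
(SVG written directly, PNG via matplotlib) only maps coordinates to
pixels and never re-decides geometry.

The figure body occupies x ∈ [0, 0.85]; the right column is reserved
for legends. Within a body region the heatmap plot rectangle sits at
fractions (0.18, 0.16) to (0.82, 0.80), leaving fixed margins for
annotation tracks and dendrograms. These constants are arbitrary but
frozen, so scene-level tests can assert exact geometry.

## Data conventions

Matrices, annotation tables and long-form tables are read from
delimited UTF-8 text with a header row; the first column holds row ids,
kept as opaque strings in file order (no numeric coercion, which could
silently reorder). Missing-value tokens on input are the empty string,
"NA" and "NaN", case-insensitive. Cells of the numeric matrix that fail
to parse become missing rather than erroring, matching common usage;
cells are parsed with correctly-rounded `float()` so a write/read
round-trip is exact. Annotation columns are auto-tagged *numeric* when
every non-missing cell parses as a real number, else *categorical*;
categorical level order is first-appearance order, because split panels
and legends inherit it. Alteration tables are MAF-like with
configurable column names (defaults `Tumor_Sample_Barcode`,
`Hugo_Symbol`, `Variant_Classification`); rows with an empty category
are dropped and counted.

In data space, cell (i, j) occupies [j, j+1) × [i, i+1) with **row 0 at
the top**; one affine map per panel takes data space to figure space.
A single convention everywhere avoids off-by-one drift between the
heatmap, its tracks and its trees.

## Clustering

Distances are computed pairwise-complete over co-observed entries;
a pair of items sharing no observations is an error, never a silent
zero. The correlation metric is 1 − Pearson r; zero-variance items are
rejected by name. Supported linkages are single, complete, average
(UPGMA) and Ward — all monotone, so merge heights are non-decreasing —
via Lance–Williams updates on a full distance matrix (squared distances
for Ward; heights are the square roots, matching the usual convention
for euclidean input).

The agglomerator is implemented in-package rather than delegated,
because display order must be bit-reproducible and the tie rule is part
of the contract: among equally close cluster pairs, merge the pair whose
(lower node id, higher node id) is lexicographically smallest (leaves
are nodes 0..n−1, merges n..2n−2). Cost is O(n³), irrelevant at heatmap
sizes. The test suite checks exact equivalence — merge structure, leaf
order and every tree cut — against a brute-force oracle that recomputes
cluster distances from the original pairwise distances at each step
(for Ward, via the closed form
D²(A,B) = 2|A||B|/(|A|+|B|) · [mean cross d² − within-A term − within-B term]),
and additionally cross-checks flat clusters against
`scipy.cluster.hierarchy` on tie-free euclidean data.

**Leaf order** is a depth-first traversal in which the left child of
every internal node is the subtree containing the smaller original leaf
index, so leaf 0 is always leftmost. (An id-at-merge-time rule was
considered; the min-leaf rule was chosen because it reproduces the
intended ordering on the worked 3-point example and is stable under
tree shape.) **Tree cuts** undo the last k−1 merges; cluster labels are
numbered by first appearance in leaf order.

**Split resolution.** A split request is either nothing (one group, in
leaf order when clustered), an integer k (cut of the global tree;
groups ordered by leaf order, members in leaf order — the concatenation
is exactly the global leaf order), or a categorical vector (groups in
first-appearance or user-given order). When a categorical split
coexists with clustering, each group is re-clustered *on its own
submatrix* with the same method/metric, so every block is internally
ordered; the per-group trees are drawn in place of a global dendrogram.
An integer split keeps the single global tree, drawn spanning the panel
gaps. Missing entries in a categorical split are an error listing the
offending ids.

## Panels, tracks, dendrograms, labels

`compute_grid` partitions the plot rectangle: panel extents are
proportional to group sizes after subtracting fixed gaps (default 1% of
the plot extent per gap); panels plus gaps tile the plot exactly (the
suite asserts 1e-9). Annotation tracks stack outward from the plot edge
with a small fixed pad, spanning the plot's full cross-axis extent
(including gaps) so annotation cells align with split panels. The value
axis of a track runs across its depth from the inner (heatmap-side)
edge outward.

* *Simple* tracks paint one rect per position; with `add_text`, one
  text per contiguous same-value block, white on fills whose WCAG
  relative luminance is below 0.5, black otherwise.
* *Bar* tracks auto-switch: one named vector gives plain bars scaled to
  [0, max] (the axis starts at 0 so bar area is meaningful; a negative
  minimum extends the axis below zero); two or more vectors give a
  stacked bar scaled to the maximum row sum, segments in column order.
  Negative values in stacked mode are an error naming position and
  column. One value axis is shared across split panels for
  cross-panel comparability.
* *Box* tracks use type-7 (linear-interpolation) quartiles and Tukey
  whiskers at the most extreme samples within 1.5·IQR; points beyond
  are outlier markers. Box and scatter tracks share one value axis over
  [data min, data max] mapped to the full track depth — endpoints sit
  exactly on the track edges.
* *Label* tracks optionally merge maximal runs of consecutive equal
  labels into one anchor at the run center, then distribute m slot
  centers evenly: with `extend`, at L·(i−0.5)/m over the whole axis;
  without, over the anchor span padded by half the mean run width
  (taken as (last−first)/m, the axis length when m = 1) and clipped to
  the axis. Slots preserve anchor order, so the three-segment leaders
  (25% stub, 50% diagonal, 25% stub of the track depth) cannot cross;
  a minimum slot width guard rejects overfull axes. Vertical sides
  reuse the same code path with the axis reversed.

Dendrograms are rectangular brackets (3 segments per merge, n−1
polylines), leaves on the inner edge at cell centers, depth normalized
to the track extent with the root at the outer edge; they are drawn
outermost on their side (rows left, columns top).

## Figure assembly

`build_clustermap` is the pipeline standardize → cluster → resolve
splits → grid → paint cells → tracks → dendrograms → legends.
Standardization (off by default) z-scores rows or columns with
population variance; constant axes become all-zero and their ids are
returned as a report. Every cell is painted — missing values in the
designated missing color (default `#bfbfbfff`) — so cell count always
equals n_rows × n_cols. Continuous color scales default to data
min/max (an optional robust flag clips to the 1st/99th percentiles);
a constant vector maps to the ramp midpoint rather than erroring, so
degenerate fixtures still render. Ramps are defined by explicit
control-point tables (viridis-like, jet-like, turbo-like,
coolwarm-like) with linear RGB interpolation — backend-independent and
bit-stable, intentionally not identical to any plotting library's
ramps. Unmapped categories take colors from a fixed 10-color palette in
first-appearance order, or error if the fallback is disabled.

Legends are models, not pixels: one per distinct (title, kind, entries),
deduplicated in first-use order with the main heatmap's scale first;
the renderer draws them into the reserved column. Dot-size legends show
three reference radii at v_min, midpoint and v_max.

**Dot heatmaps** pivot the long table on first-appearance keys; absent
pairs are missing cells (no dot). One dot per cell: a cell fed by two
records — even with different hues — is rejected by name (multi-dot
cells are out of scope). Clustering operates on the pivoted value grid.
Radii are area-linear with the radius additionally capped at 0.45 of
the cell extent so adjacent dots can never touch; a value at v_min has
radius 0 and draws nothing. Hue levels map to the fixed marker
vocabulary (circle, square, triangle, diamond, cross, star) in
first-appearance order; the marker legend is omitted when only one hue
exists.

**oncoPrint** cells show the category set of a (gene, sample) pair as
equal horizontal bands over a neutral background covering 90% of the
cell; an optional per-category (band fraction, offset) table enables
the classic full-height-CNV / middle-third-SNV style. The memo sort
ranks genes by alteration frequency (ties keep input order) and sorts
samples by descending lexicographic comparison of their binary
alteration vectors in gene order; the sort is stable, so duplicate
columns stay adjacent in input order. It is validated against an
exhaustive permutation search on small grids. Percent-altered labels
round to the nearest integer.

**Composition** builds the main panel first and imposes its resolved
order and grouping (as id lists) on the other panels, which skip their
own clustering on the shared axis and suppress their dendrogram there —
one coherent blocking, one tree. Panel regions divide the body along
the join axis proportionally to `width_ratios` (default: axis sizes)
with 2% gaps; legends from all panels are merged and deduplicated.
A single-panel composite returns the standalone build unchanged, making
the identity contract exact. Non-main panels are reordered, never
re-clustered.

## Synthetic data

The fixture generators define the demonstration conditions: a
standard-normal matrix whose contiguous column groups are mean-shifted
by g·`group_shift` (defaults 30×10, two groups, shift 1) with a
categorical group label and a uniform numeric score; a Bernoulli
alteration profile (per-gene rates defaulting to 0.6→0.1 across genes,
categories uniform over SNV/AMP/DEL) — rates in the range reported for
recurrently altered genes in tumor cohorts; and a dense dot table with
uniform sizes, independent normal color values and cyclic hues. All
draw from NumPy's PCG64 (`default_rng`) seeded per call, so equal seeds
give bitwise-equal fixtures. They emulate group structure and sparsity,
not real-data features like correlated probes, batch effects or
mutation signatures — green tests certify the *geometry and algorithms*,
not biological recovery on real cohorts.

Problem sizes in the verification suite (200 matrices up to 8×8 for the
clustering oracle, 1000 random anchor sets for label placement, 18×10
conservation figures) were chosen as the smallest sizes that exercise
every code path many times over; the whole suite runs in seconds.

## Known limitations

* No optimal leaf ordering; the leaf order is the deterministic
  traversal described above.
* Ward linkage is defined by the Lance–Williams recursion for any
  metric, as in common implementations; its variance interpretation
  only holds for euclidean input.
* Label slots are strictly even and text-width-agnostic; very long
  labels can collide visually even though their slots are disjoint.
* One dot per cell; no pies, no polar layouts, no interactivity.
* The SVG/PNG renderers aim for fidelity to the scene, not for
  typographic refinement; text metrics are not measured.
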