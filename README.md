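# scenemap

Annotated cluster heatmaps for multimodal genomics data, built as a
**layout engine**: every figure is first computed as a *scene* — a flat,
canonical list of styled drawing primitives (rects, lines, texts,
markers) in normalized figure coordinates — and only then rendered to
SVG or PNG. Because the scene serializes byte-stably, every geometric
claim about a figure (panel tiling, label spacing, cell ordering, legend
coverage) is mechanically testable.

The package is for computational biologists who outgrow
`seaborn.clustermap`: methylation matrices with per-sample metadata,
variant profiles, correlation matrices of CpG modules — anything that
needs a clustered matrix plus rich marginal annotation.

## What it does

* **Clustered, split heatmaps.** Agglomerative clustering of rows and
  columns (single / complete / average / Ward linkage; euclidean /
  cityblock / correlation distances, pairwise-complete over missing
  values). Rows or columns can be split into gapped panels either by a
  categorical metadata vector or by cutting the clustering tree into
  *k* groups; panel extents are proportional to group sizes.
* **Annotation tracks on all four sides** — the five classic flavors:
  simple color bars (with optional in-block text), bar / stacked-bar,
  boxplot (type-7 quartiles, Tukey 1.5·IQR whiskers), scatter, and label
  tracks. Label tracks merge runs of equal labels and distribute the
  slots *evenly* along the axis with three-segment leader lines that
  provably never cross.
* **Dot heatmaps** encoding up to five variables at once: row, column,
  dot size (area-linear: r = r_max·√((v−v_min)/(v_max−v_min))), fill
  color, and marker shape.
* **oncoPrint** alteration grids: gene × sample category glyphs (equal
  horizontal bands per cell), genes ranked by alteration frequency,
  samples ordered by the mutual-exclusivity waterfall ("memo") sort —
  descending lexicographic comparison of binary alteration vectors read
  in gene order — plus stacked count bars and percent-altered labels.
* **Composition**: several heatmaps joined horizontally or vertically;
  the *main* panel's clustered order and grouping are imposed on every
  other panel, and legends are merged and deduplicated.

All randomized demo inputs come from seeded generators in
`scenemap.fixtures` (group-shifted normal matrices, Bernoulli alteration
profiles, dense dot tables), so everything here reproduces exactly.

## Worked example

```python
import scenemap as sm

matrix, annotation = sm.make_fixture_matrix(
    n_rows=30, n_cols=10, n_col_groups=2, group_shift=2.0, seed=11)
groups = annotation.mapping("group")

model = sm.build_clustermap(sm.ClustermapSpec(
    matrix=matrix,
    row_split=2,               # cut the row tree into two blocks
    col_split=groups,          # split columns by metadata
    top_tracks=[sm.Track(kind="simple", name="group", data=groups,
                         add_text=True)],
))
sm.render(model.scene, "clustermap.svg", legends=model.legends)
```

Running `python examples/basic_clustermap.py` prints:

```
cells painted: 300 (= 30 rows x 10 cols)
row blocks (tree cut k=2): sizes [29, 1]
column blocks (metadata): ['A', 'B'] sizes [5, 5]
display column order: ['s1', 's4', 's5', 's2', 's3', 's6', 's9', 's7', 's10', 's8']
legends: ['heatmap', 'group', 'score']
```

Every matrix cell became exactly one tagged rect (300 = 30×10). The
column metadata split keeps groups A and B in contiguous panels, with
columns re-clustered inside each group — which is why the display order
interleaves within but never across groups. The k=2 tree cut on pure
noise yields a 29/1 block: undoing the top merge of an average-linkage
tree over unstructured rows typically peels off a single outlier, which
is the honest geometry of these data. Each distinct color scale and
category set appears as exactly one legend.

The other capabilities each have a narrative script under `examples/`:
`annotation_tracks.py` (all five track flavors + annotation-only mode),
`dot_heatmap.py` (five-channel dots), `oncoprint_waterfall.py`
(memo-sorted alteration grid), and `composite_panels.py` (joined panels
sharing one row order).

## Command line

```sh
scenemap fixtures --kind matrix --seed 7 --out demo/
scenemap clustermap --matrix demo/matrix.tsv --col-annot demo/col_annotation.tsv \
    --row-split 2 --col-split group --out fig.svg --dump-scene scene.json
```

`--dump-scene` writes the canonical scene document (sorted keys, floats
at 1e-6), which is byte-identical across repeated identical invocations;
the effective configuration is echoed into its header. `dotmap`,
`oncoprint` and `compose` subcommands cover the other figure kinds.

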