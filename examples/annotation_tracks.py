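"""All five annotation flavors around one heatmap, plus annotation-only mode.

Attaches a simple color bar, a stacked bar, a boxplot, a scatter and a
merged label track to the fixture matrix, mirroring the classic
"annotations on all four sides" layout, then rebuilds the column tracks
standalone (no heatmap body).
"""

from pathlib import Path

import numpy as np

import scenemap as sm

out = Path("example_output")
out.mkdir(exist_ok=True)

matrix, annotation = sm.make_fixture_matrix(20, 8, 2, 1.0, seed=3)
groups = annotation.mapping("group")
rng = np.random.default_rng(3)

# per-column boxplot samples and a stacked composition
box_data = {c: list(rng.standard_normal(25)) for c in matrix.col_ids}
stacked = {
    part: {c: float(rng.uniform(0.5, 3.0)) for c in matrix.col_ids}
    for part in ("exonic", "intronic", "intergenic")
}
# per-row scatter values; label the rows exceeding 1.0 (selected features)
row_vals = {r: float(v) for r, v in zip(matrix.row_ids, matrix.values[:, 3])}
labels = {r: (r if v > 1.0 else None) for r, v in row_vals.items()}

spec = sm.ClustermapSpec(
    matrix=matrix,
    top_tracks=[
        sm.Track(kind="simple", name="group", data=groups, add_text=True),
        sm.Track(kind="box", name="signal", data=box_data),
    ],
    bottom_tracks=[sm.Track(kind="bar", name="composition", data=stacked)],
    right_tracks=[
        sm.Track(kind="scatter", name="sample 4", data=row_vals),
        sm.Track(kind="label", name="hits", data=labels, merge=True),
    ],
)
model = sm.build_clustermap(spec)

n_labels = len([p for p in model.scene.by_kind("text")
                if p.tags.get("track") == "hits"])
print(f"selected-feature labels placed: {n_labels} "
      f"(rows with sample-4 value > 1.0, evenly slotted with leader lines)")
q1, med, q3, *_ = sm.box_stats(box_data[matrix.col_ids[0]])
print(f"first column box: q1={q1:.2f} median={med:.2f} q3={q3:.2f}")
print(f"legends collected: {[l.title for l in model.legends]}")

sm.render(model.scene, out / "annotated.svg", legends=model.legends)

# the same column tracks, plotted without the heatmap body
solo = sm.annotation_only(spec.top_tracks, axis=1, order=model.col_order)
print(f"annotation-only scene: {len(solo.scene.primitives)} primitives, "
      f"{len(solo.legends)} legend(s)")
sm.render(solo.scene, out / "annotation_only.svg", legends=solo.legends)
print(f"wrote {out / 'annotated.svg'} and {out / 'annotation_only.svg'}")
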