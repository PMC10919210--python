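"""Two heatmaps joined horizontally under one row order.

Two matrices over the same rows (think: SNP pattern vs methylation beta
values for the same probes) are built as separate panels; the composite
imposes the main (left) panel's clustered row order and row blocking on
the right panel and merges the legends.
"""

from pathlib import Path

import numpy as np

import scenemap as sm

out = Path("example_output")
out.mkdir(exist_ok=True)

rng = np.random.default_rng(31)
rows = [f"probe{i + 1}" for i in range(14)]
left = sm.LabeledMatrix(rng.standard_normal((14, 6)), rows,
                        [f"snp{j + 1}" for j in range(6)])
right = sm.LabeledMatrix(rng.uniform(0, 1, (14, 9)), rows,
                         [f"s{j + 1}" for j in range(9)])

model = sm.composite(sm.CompositeSpec(
    specs=[
        sm.ClustermapSpec(matrix=left, name="snp pattern", row_split=2),
        sm.ClustermapSpec(matrix=right, name="beta value",
                          cmap=sm.ColorSpec.continuous(ramp_name="coolwarm-like")),
    ],
    main=0, axis="horizontal",
))

print(f"shared row order (from the main panel): {model.row_order}")
print(f"row blocks imposed on both panels: sizes {model.row_split.sizes()}")
print(f"merged legends: {[l.title for l in model.legends]}")
left_cells = [p for p in model.scene.tagged(cell='1') if p.tags['col'] == 'snp1']
right_cells = [p for p in model.scene.tagged(cell='1') if p.tags['col'] == 's1']
same = [p.tags['row'] for p in sorted(left_cells, key=lambda p: -p.y)] == \
       [p.tags['row'] for p in sorted(right_cells, key=lambda p: -p.y)]
print(f"panels share one row permutation: {same}")

sm.render(model.scene, out / "composite.svg", legends=model.legends)
print(f"wrote {out / 'composite.svg'}")
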