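"""oncoPrint of a synthetic tumor alteration profile.

Genes are ranked by alteration frequency; samples are waterfall-sorted
(memo sort) so mutually exclusive alterations line up visually. The top
bar stacks per-sample alteration counts by category; the right bar
prints each gene's percent-altered.
"""

from pathlib import Path

import scenemap as sm

out = Path("example_output")
out.mkdir(exist_ok=True)

table = sm.make_fixture_alterations(
    n_samples=40, n_genes=6,
    per_gene_rates=[0.6, 0.45, 0.3, 0.2, 0.15, 0.1], seed=13,
)
model = sm.build_oncoprint(sm.OncoprintSpec(alterations=table))

print(f"grid: {len(model.row_order)} genes x {len(model.col_order)} samples, "
      f"{len(table.records)} alteration records")
print(f"gene order (by frequency): {model.row_order}")
pcts = {p.tags["freq_label"]: p.text for p in model.scene.by_kind("text")
        if "freq_label" in p.tags}
print("percent altered:", {g: pcts[g] for g in model.row_order})
print(f"categories: {table.categories} (equal horizontal bands per cell)")

sm.render(model.scene, out / "oncoprint.svg", legends=model.legends)
print(f"wrote {out / 'oncoprint.svg'}")
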