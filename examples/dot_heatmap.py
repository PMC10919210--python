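"""Five-dimensional dot heatmap.

Each cell's dot binds five independent variables: row, column, size
(area-linear in value), fill color (an unrelated continuous variable)
and marker shape (a categorical hue). Legends document the three
non-positional channels.
"""

from pathlib import Path

import scenemap as sm

out = Path("example_output")
out.mkdir(exist_ok=True)

table = sm.make_fixture_dots(n_rows=8, n_cols=8, n_hues=3, seed=21)
model = sm.build_dotmap(sm.DotmapSpec(table=table))

dots = model.scene.tagged(dot="1")
print(f"dots drawn: {len(dots)} of {len(table.records)} records "
      f"(cells at the size-scale minimum draw no dot)")
print(f"marker shapes used: {sorted({p.shape for p in dots})}")
print(f"radius range: {min(p.radius for p in dots):.4f} "
      f"to {max(p.radius for p in dots):.4f} (figure fraction; area ~ value)")
print(f"legends: {[(l.title, l.kind) for l in model.legends]}")

sm.render(model.scene, out / "dotmap.svg", legends=model.legends)
print(f"wrote {out / 'dotmap.svg'}")
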