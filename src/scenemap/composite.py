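"""Joining several heatmaps into one figure with a governing main panel.

For a horizontal join all panels must cover the same row-id set; the
main panel is built first and its final row order and row grouping are
imposed on every other panel (their own row clustering is skipped and
their row dendrograms suppressed, so the joint figure shows one coherent
row blocking). Vertical joins share column ids symmetrically. Legends
from all panels are merged and deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustermap import ClustermapSpec, FigureModel, LEGEND_X, build_clustermap
from .datamodel import SceneMapError
from .dotmap import DotmapSpec, build_dotmap
from .layout import Rect
from .oncoprint import OncoprintSpec, build_oncoprint
from .scene import Scene, build_legends

#: Gap between composed panels, as a fraction of the figure width/height.
PANEL_GAP = 0.02

_BUILDERS = {
    ClustermapSpec: build_clustermap,
    DotmapSpec: build_dotmap,
    OncoprintSpec: build_oncoprint,
}


@dataclass
class CompositeSpec:
    specs: list  # ClustermapSpec | DotmapSpec | OncoprintSpec
    main: int = 0
    axis: str = "horizontal"
    width_ratios: list[float] | None = None
    legend_side: str = "right"


def _axis_ids(spec, axis: str) -> list[str]:
    if isinstance(spec, ClustermapSpec):
        return spec.matrix.row_ids if axis == "horizontal" else spec.matrix.col_ids
    if isinstance(spec, DotmapSpec):
        return spec.table.row_keys if axis == "horizontal" else spec.table.col_keys
    if isinstance(spec, OncoprintSpec):
        return (
            spec.alterations.genes if axis == "horizontal" else spec.alterations.samples
        )
    raise SceneMapError(f"cannot compose object of type {type(spec).__name__}")


def _build(spec, region: Rect, **kw) -> FigureModel:
    for cls, builder in _BUILDERS.items():
        if isinstance(spec, cls):
            return builder(spec, region=region, **kw)
    raise SceneMapError(f"cannot compose object of type {type(spec).__name__}")


def _imposed_groups(model: FigureModel, axis: str) -> list[tuple[str, list[str]]]:
    res = model.row_split if axis == "horizontal" else model.col_split
    ids = model.row_order if axis == "horizontal" else model.col_order
    if res is None:
        return [("all", list(ids))]
    # translate the split's positional groups to ids via the display order
    out: list[tuple[str, list[str]]] = []
    pos = 0
    for label, members in res.groups:
        out.append((label, list(ids[pos : pos + len(members)])))
        pos += len(members)
    return out


def composite(spec: CompositeSpec) -> FigureModel:
    """Join panels along one axis under the main panel's order.

    A single-panel composite is identical to building that panel alone.
    """
    specs = list(spec.specs)
    if not specs:
        raise SceneMapError("composite needs at least one panel")
    if not 0 <= spec.main < len(specs):
        raise SceneMapError(
            f"main index {spec.main} out of range for {len(specs)} panels"
        )
    if spec.axis not in ("horizontal", "vertical"):
        raise SceneMapError("axis must be 'horizontal' or 'vertical'")

    # shared-axis id sets must match exactly
    ref = set(_axis_ids(specs[spec.main], spec.axis))
    for i, s in enumerate(specs):
        ids = set(_axis_ids(s, spec.axis))
        if ids != ref:
            diff = sorted(ids.symmetric_difference(ref))
            what = "row" if spec.axis == "horizontal" else "column"
            raise SceneMapError(
                f"panel {i} does not share the main panel's {what} ids; "
                f"symmetric difference: {', '.join(diff)}"
            )

    ratios = spec.width_ratios
    if ratios is None:
        other = "vertical" if spec.axis == "horizontal" else "horizontal"
        ratios = [max(1, len(_axis_ids(s, other))) for s in specs]
    if len(ratios) != len(specs) or any(r <= 0 for r in ratios):
        raise SceneMapError("width_ratios must be positive, one per panel")

    if len(specs) == 1:
        return _build(specs[0], region=Rect(0.0, 0.0, LEGEND_X, 1.0))

    # carve the body into panel regions along the join axis
    total = float(sum(ratios))
    n = len(specs)
    if spec.axis == "horizontal":
        extent = LEGEND_X - PANEL_GAP * (n - 1)
        regions = []
        x = 0.0
        for r in ratios:
            w = extent * r / total
            regions.append(Rect(x, 0.0, w, 1.0))
            x += w + PANEL_GAP
    else:
        extent = 1.0 - PANEL_GAP * (n - 1)
        regions = []
        y = 1.0
        for r in ratios:
            h = extent * r / total
            regions.append(Rect(0.0, y - h, LEGEND_X, h))
            y -= h + PANEL_GAP

    main_model = _build(specs[spec.main], region=regions[spec.main])
    imposed = _imposed_groups(main_model, spec.axis)

    models: list[FigureModel | None] = [None] * n
    models[spec.main] = main_model
    for i, s in enumerate(specs):
        if i == spec.main:
            continue
        if spec.axis == "horizontal":
            models[i] = _build(
                s, region=regions[i], imposed_rows=imposed,
                suppress_row_dendrogram=True,
            )
        else:
            models[i] = _build(
                s, region=regions[i], imposed_cols=imposed,
                suppress_col_dendrogram=True,
            )

    merged = Scene(meta={
        "kind": "composite",
        "axis": spec.axis,
        "main": spec.main,
        "panels": [m.scene.meta for m in models],
    })
    legend_requests = []
    for m in models:
        merged.add(m.scene.primitives)
        legend_requests.extend(m.legends)
    merged.validate()
    return FigureModel(
        grid=main_model.grid,
        scene=merged,
        legends=build_legends(legend_requests),
        row_order=main_model.row_order,
        col_order=main_model.col_order,
        row_split=main_model.row_split,
        col_split=main_model.col_split,
    )
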