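"""Dot (bubble) cluster heatmap: up to five variables in one figure.

A long-form table is pivoted to a grid; rows and columns are clustered
and split exactly like a clustermap; each present cell becomes one
marker whose radius encodes ``value`` (area-linear), whose fill encodes
``color_value`` (numeric ramp or categorical mapping) and whose shape
encodes ``hue``. Together with row and column position, that is five
independently bindable channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .colors import ColorSpec, SizeScale, map_colors, map_sizes, marker_assignment
from .datamodel import DotTable, LabeledMatrix, SceneMapError
from .layout import DEFAULT_GAP, Rect
from .scene import Legend, Scene, build_legends
from .clustermap import (
    DEFAULT_REGION,
    FigureModel,
    _default_plot_rect,
    _dendrogram_prims,
    _resolve_axis,
    _track_ctx,
    _main_legend,
)
from .layout import allocate_tracks, compute_grid
from .tracks import Track, render_track
from . import scene as sc
from . import clustermap as _cm

#: Radius cap: dots never exceed 0.45 of the cell extent (0.9 of the
#: half-extent), so adjacent dots cannot touch even across zero gaps.
RADIUS_CAP = 0.9


@dataclass
class DotmapSpec:
    """A dot heatmap: the long table plus channel scales and layout options."""

    table: DotTable
    name: str = "dotmap"
    size_scale: SizeScale | None = None  # default: data min/max, r_max capped
    color: ColorSpec | None = None  # bound to color_value
    top_tracks: list[Track] = field(default_factory=list)
    bottom_tracks: list[Track] = field(default_factory=list)
    left_tracks: list[Track] = field(default_factory=list)
    right_tracks: list[Track] = field(default_factory=list)
    row_split: Any = None
    col_split: Any = None
    cluster_rows: bool = True
    cluster_cols: bool = True
    method: str = "average"
    metric: str = "euclidean"
    row_gap: float = DEFAULT_GAP
    col_gap: float = DEFAULT_GAP
    show_row_dendrogram: bool = True
    show_col_dendrogram: bool = True

    def tracks_on(self, side: str) -> list[Track]:
        return getattr(self, f"{side}_tracks")


def pivot(table: DotTable) -> tuple[LabeledMatrix, np.ndarray, np.ndarray]:
    """Pivot the long table to a value grid plus aligned color/hue grids.

    Rows and columns appear in first-appearance order; absent (row, col)
    pairs are missing (no dot). One dot per cell: a cell fed by more than
    one record (even with different hues) is an error.
    """
    rows = table.row_keys
    cols = table.col_keys
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    values = np.full((len(rows), len(cols)), np.nan)
    color_vals = np.full((len(rows), len(cols)), None, dtype=object)
    hues = np.full((len(rows), len(cols)), None, dtype=object)
    for rec in table.records:
        i, j = ri[rec.row_key], ci[rec.col_key]
        if not math.isnan(values[i, j]):
            raise SceneMapError(
                f"more than one dot record for cell ({rec.row_key!r}, {rec.col_key!r})"
            )
        values[i, j] = rec.value
        color_vals[i, j] = rec.color_value if rec.color_value is not None else rec.value
        hues[i, j] = rec.hue
    return LabeledMatrix(values, rows, cols), color_vals, hues


def build_dotmap(
    spec: DotmapSpec,
    region: Rect = DEFAULT_REGION,
    imposed_rows: list[tuple[str, list[str]]] | None = None,
    imposed_cols: list[tuple[str, list[str]]] | None = None,
    suppress_row_dendrogram: bool = False,
    suppress_col_dendrogram: bool = False,
) -> FigureModel:
    """Build the dot cluster heatmap for ``spec`` inside ``region``.

    Clustering and splitting operate on the pivoted value grid with
    pairwise-complete distances; cells whose value sits at the scale
    minimum get radius zero and draw no dot.
    """
    matrix, color_vals, hues = pivot(spec.table)
    row_res, row_link = _resolve_axis(
        matrix, "rows", spec.row_split, spec.cluster_rows, spec.method,
        spec.metric, imposed_rows,
    )
    col_res, col_link = _resolve_axis(
        matrix, "cols", spec.col_split, spec.cluster_cols, spec.method,
        spec.metric, imposed_cols,
    )
    row_idx = row_res.order()
    col_idx = col_res.order()

    plot_rect = _default_plot_rect(region)
    grid = compute_grid(
        row_res.sizes(), col_res.sizes(), plot_rect,
        row_gap=spec.row_gap * region.h, col_gap=spec.col_gap * region.w,
    )
    scene = Scene(meta={"kind": "dotmap", "name": spec.name,
                        "method": spec.method, "metric": spec.metric})
    legend_requests: list[Legend] = []

    finite = matrix.values[np.isfinite(matrix.values)]
    if spec.size_scale is not None:
        size_scale = spec.size_scale
    else:
        vmin = float(finite.min()) if finite.size else 0.0
        vmax = float(finite.max()) if finite.size else 1.0
        if vmax <= vmin:
            vmax = vmin + 1.0
        size_scale = SizeScale(vmin=vmin, vmax=vmax, r_max=RADIUS_CAP)
    size_scale = SizeScale(
        vmin=size_scale.vmin, vmax=size_scale.vmax,
        r_max=min(size_scale.r_max, RADIUS_CAP),
    )

    observed_colors = [
        color_vals[i, j]
        for i in range(matrix.shape[0])
        for j in range(matrix.shape[1])
        if np.isfinite(matrix.values[i, j])
    ]
    numeric_color = all(isinstance(c, (int, float, np.floating)) for c in observed_colors)
    cspec = spec.color or (
        ColorSpec.continuous(ramp_name="coolwarm-like") if numeric_color else ColorSpec.categorical()
    )
    cspec = cspec.resolved(observed_colors)

    hue_levels: list[str] = []
    for rec in spec.table.records:
        if rec.hue is not None and rec.hue not in hue_levels:
            hue_levels.append(rec.hue)
    markers = marker_assignment(hue_levels) if hue_levels else {}

    col_ivals = grid.col_cell_intervals()
    row_ivals = grid.row_cell_intervals()
    min_half = min(
        min((b - a) / 2.0 for a, b in col_ivals),
        min((b - a) / 2.0 for a, b in row_ivals),
    )
    for di, i in enumerate(row_idx):
        y0, y1 = row_ivals[di]
        for dj, j in enumerate(col_idx):
            v = matrix.values[i, j]
            if not np.isfinite(v):
                continue
            r = float(map_sizes([v], size_scale)[0]) * min_half
            if r <= 0.0:
                continue
            x0, x1 = col_ivals[dj]
            fill = map_colors([color_vals[i, j]], cspec)[0]
            shape = markers.get(hues[i, j], "circle")
            scene.add([
                sc.marker(
                    (x0 + x1) / 2.0, (y0 + y1) / 2.0, shape=shape, radius=r,
                    fill=fill,
                    tags={"dot": "1", "row": matrix.row_ids[i], "col": matrix.col_ids[j]},
                )
            ])

    legend_requests.append(_main_legend(spec.name, cspec))
    mid = (size_scale.vmin + size_scale.vmax) / 2.0
    legend_requests.append(
        Legend.make(
            f"{spec.name} size",
            "size_set",
            [
                (f"{v:g}", {"radius": float(map_sizes([v], size_scale)[0])})
                for v in (size_scale.vmin, mid, size_scale.vmax)
            ],
        )
    )
    if len(hue_levels) > 1:
        legend_requests.append(
            Legend.make(
                f"{spec.name} hue",
                "marker_set",
                [(lev, {"marker": markers[lev]}) for lev in hue_levels],
            )
        )

    # annotation tracks + dendrograms reuse the clustermap chassis
    row_order = [matrix.row_ids[i] for i in row_idx]
    col_order = [matrix.col_ids[j] for j in col_idx]
    dendro_rects: dict[str, Rect] = {}
    for side in ("top", "bottom", "left", "right"):
        tracks = spec.tracks_on(side)
        scale = region.h if side in ("top", "bottom") else region.w
        extents = [t.extent * scale for t in tracks]
        want_dendro = (
            side == "top" and spec.cluster_cols and spec.show_col_dendrogram
            and not suppress_col_dendrogram and imposed_cols is None
            and (col_link is not None or any(l is not None for l in col_res.group_links))
        ) or (
            side == "left" and spec.cluster_rows and spec.show_row_dendrogram
            and not suppress_row_dendrogram and imposed_rows is None
            and (row_link is not None or any(l is not None for l in row_res.group_links))
        )
        if want_dendro:
            extents = extents + [_cm._DENDRO_EXTENT * scale]
        rects = allocate_tracks(plot_rect, side, extents, pad=_cm._TRACK_PAD * scale)
        if want_dendro:
            dendro_rects[side] = rects[-1]
            rects = rects[:-1]
        order = col_order if side in ("top", "bottom") else row_order
        for track, rect in zip(tracks, rects):
            ctx = _track_ctx(rect, side, grid)
            prims, legs = render_track(track, order, ctx)
            scene.add(prims)
            legend_requests.extend(legs)
    for side, rect in dendro_rects.items():
        axis_res = col_res if side == "top" else row_res
        axis_link = col_link if side == "top" else row_link
        ivals = col_ivals if side == "top" else row_ivals
        centers = [(a + b) / 2.0 for a, b in ivals]
        scene.add(_dendrogram_prims(axis_res, axis_link, side, rect, centers))

    scene.validate()
    return FigureModel(
        grid=grid,
        scene=scene,
        legends=build_legends(legend_requests),
        row_order=row_order,
        col_order=col_order,
        row_split=row_res,
        col_split=col_res,
    )
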