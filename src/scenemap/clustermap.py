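"""Assembly of the full annotated cluster heatmap.

``build_clustermap`` runs the whole pipeline — standardize, cluster each
axis, resolve splits, lay out panels and annotation tracks, paint cells,
draw dendrograms and collect legends — into a :class:`FigureModel`. Cells
carry (row, col) id tags in the scene so ordering and coverage are
mechanically checkable; renderers drop the tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .clustering import (
    LinkageResult,
    SplitResolution,
    linkage,
    pairwise_distance,
    resolve_split,
)
from .colors import ColorSpec, map_colors
from .datamodel import LabeledMatrix, SceneMapError
from .layout import (
    DEFAULT_GAP,
    PanelGrid,
    Rect,
    allocate_tracks,
    compute_grid,
    dendrogram_geometry,
)
from .scene import Legend, Scene, build_legends, polyline
from .tracks import Track, TrackContext, render_track
from . import scene as sc

#: Figure real estate: the body (heatmap + annotations) spans x in
#: [0, LEGEND_X); the right legend column occupies the rest.
LEGEND_X = 0.85
DEFAULT_REGION = Rect(0.0, 0.0, LEGEND_X, 1.0)

# plot_rect placement within a region, as region fractions
_PLOT_FRACTIONS = (0.18, 0.16, 0.64, 0.64)
_DENDRO_EXTENT = 0.08
_TRACK_PAD = 0.004


@dataclass
class ClustermapSpec:
    """Everything needed to build one annotated cluster heatmap."""

    matrix: LabeledMatrix
    name: str = "heatmap"
    cmap: ColorSpec | None = None
    top_tracks: list[Track] = field(default_factory=list)
    bottom_tracks: list[Track] = field(default_factory=list)
    left_tracks: list[Track] = field(default_factory=list)
    right_tracks: list[Track] = field(default_factory=list)
    row_split: Any = None  # None | int | sequence | dict id -> label
    col_split: Any = None
    cluster_rows: bool = True
    cluster_cols: bool = True
    method: str = "average"
    metric: str = "euclidean"
    standardize: str = "none"  # none | rows | cols
    show_row_dendrogram: bool = True
    show_col_dendrogram: bool = True
    row_gap: float = DEFAULT_GAP
    col_gap: float = DEFAULT_GAP

    def tracks_on(self, side: str) -> list[Track]:
        return getattr(self, f"{side}_tracks")


@dataclass
class FigureModel:
    """A built figure: panel grid, scene, legends and resolved orders."""

    grid: PanelGrid | None
    scene: Scene
    legends: list[Legend]
    row_order: list[str]
    col_order: list[str]
    row_split: SplitResolution | None = None
    col_split: SplitResolution | None = None
    constant_axes: list[str] = field(default_factory=list)


def standardize(matrix: LabeledMatrix, mode: str) -> tuple[LabeledMatrix, list[str]]:
    """Z-score rows or columns (population std, ddof=0).

    Returns the standardized matrix and the ids of constant axes, which
    become all-zero rather than dividing by zero.
    """
    if mode not in ("none", "rows", "cols"):
        raise SceneMapError(f"standardize mode must be none|rows|cols, got {mode!r}")
    if mode == "none":
        return matrix, []
    v = matrix.values.astype(float).copy()
    axis = 1 if mode == "rows" else 0
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(v, axis=axis, keepdims=True)
        std = np.nanstd(v, axis=axis, ddof=0, keepdims=True)
    constant = (std == 0.0) | ~np.isfinite(std)
    safe_std = np.where(constant, 1.0, std)
    out = (v - mean) / safe_std
    out = np.where(np.broadcast_to(constant, out.shape), np.where(np.isnan(v), np.nan, 0.0), out)
    ids = matrix.row_ids if mode == "rows" else matrix.col_ids
    flagged = [ids[i] for i in range(len(ids)) if constant.ravel()[i]]
    return LabeledMatrix(out, list(matrix.row_ids), list(matrix.col_ids)), flagged


def _normalize_split(split: Any, ids: Sequence[str]) -> Any:
    """Accept dicts keyed by id and return an axis-aligned vector."""
    if isinstance(split, dict):
        missing = [i for i in ids if i not in split]
        if missing:
            raise SceneMapError(
                "split mapping is missing ids: " + ", ".join(map(str, missing))
            )
        return [split[i] for i in ids]
    return split


def _resolve_axis(
    matrix: LabeledMatrix,
    axis: str,
    split: Any,
    cluster: bool,
    method: str,
    metric: str,
    imposed: list[tuple[str, list[str]]] | None = None,
) -> tuple[SplitResolution, LinkageResult | None]:
    ids = matrix.row_ids if axis == "rows" else matrix.col_ids
    if imposed is not None:
        id_index = {i: p for p, i in enumerate(ids)}
        unknown = [i for _, mem in imposed for i in mem if i not in id_index]
        if unknown:
            raise SceneMapError(
                "imposed order references unknown ids: " + ", ".join(unknown)
            )
        groups = [(lab, [id_index[i] for i in mem]) for lab, mem in imposed]
        return SplitResolution(groups=groups), None
    split = _normalize_split(split, ids)
    link = None
    n = len(ids)
    if cluster and n >= 2:
        d = pairwise_distance(matrix, axis=axis, metric=metric)
        link = linkage(d, method=method, n_leaves=n, metric=metric)
    if isinstance(split, (int, np.integer)) and link is None:
        raise SceneMapError(
            f"integer {axis} split requires clustering on that axis"
        )
    return resolve_split(matrix, axis, split, link=link), link


def _track_ctx(
    rect: Rect, side: str, grid: PanelGrid
) -> TrackContext:
    intervals = (
        grid.col_cell_intervals() if side in ("top", "bottom") else grid.row_cell_intervals()
    )
    return TrackContext(rect=rect, intervals=intervals, side=side)


def _default_plot_rect(region: Rect) -> Rect:
    fx, fy, fw, fh = _PLOT_FRACTIONS
    return Rect(
        region.x + fx * region.w,
        region.y + fy * region.h,
        fw * region.w,
        fh * region.h,
    )


def build_clustermap(
    spec: ClustermapSpec,
    region: Rect = DEFAULT_REGION,
    imposed_rows: list[tuple[str, list[str]]] | None = None,
    imposed_cols: list[tuple[str, list[str]]] | None = None,
    suppress_row_dendrogram: bool = False,
    suppress_col_dendrogram: bool = False,
) -> FigureModel:
    """Build the annotated cluster heatmap for ``spec`` inside ``region``.

    ``imposed_rows``/``imposed_cols`` override clustering and splitting on
    that axis with an externally resolved (label, ids) grouping — used by
    the composite operation to impose the main figure's order.
    """
    matrix, flagged = standardize(spec.matrix, spec.standardize)
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
    row_order = [matrix.row_ids[i] for i in row_idx]
    col_order = [matrix.col_ids[j] for j in col_idx]

    plot_rect = _default_plot_rect(region)
    grid = compute_grid(
        row_res.sizes(), col_res.sizes(), plot_rect,
        row_gap=spec.row_gap * region.h, col_gap=spec.col_gap * region.w,
    )

    scene = Scene(meta=_spec_meta(spec))
    legend_requests: list[Legend] = []

    # main heatmap cells
    cmap = (spec.cmap or ColorSpec.continuous(title=spec.name)).resolved(
        matrix.values.ravel().tolist()
    )
    col_ivals = grid.col_cell_intervals()
    row_ivals = grid.row_cell_intervals()
    values = matrix.values
    for di, i in enumerate(row_idx):
        row_vals = values[i, :]
        fills = map_colors([row_vals[j] for j in col_idx], cmap)
        y0, y1 = row_ivals[di]
        for dj, j in enumerate(col_idx):
            x0, x1 = col_ivals[dj]
            scene.add([
                sc.rect(
                    x0, y0, x1 - x0, y1 - y0,
                    fill=fills[dj],
                    tags={"cell": "1", "row": matrix.row_ids[i], "col": matrix.col_ids[j]},
                )
            ])
    legend_requests.append(_main_legend(spec.name, cmap))

    # annotation tracks + dendrograms
    dendro_rects: dict[str, Rect] = {}
    for side in ("top", "bottom", "left", "right"):
        tracks = spec.tracks_on(side)
        scale = region.h if side in ("top", "bottom") else region.w
        extents = [t.extent * scale for t in tracks]
        want_dendro = (
            side == "top"
            and spec.cluster_cols
            and spec.show_col_dendrogram
            and not suppress_col_dendrogram
            and imposed_cols is None
            and (col_link is not None or any(l is not None for l in col_res.group_links))
        ) or (
            side == "left"
            and spec.cluster_rows
            and spec.show_row_dendrogram
            and not suppress_row_dendrogram
            and imposed_rows is None
            and (row_link is not None or any(l is not None for l in row_res.group_links))
        )
        if want_dendro:
            extents = extents + [_DENDRO_EXTENT * scale]
        rects = allocate_tracks(plot_rect, side, extents, pad=_TRACK_PAD * scale)
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
        centers_all = [(a + b) / 2.0 for a, b in ivals]
        scene.add(
            _dendrogram_prims(axis_res, axis_link, side, rect, centers_all)
        )

    scene.validate()
    legends = build_legends(legend_requests)
    return FigureModel(
        grid=grid,
        scene=scene,
        legends=legends,
        row_order=row_order,
        col_order=col_order,
        row_split=row_res,
        col_split=col_res,
        constant_axes=flagged,
    )


def _dendrogram_prims(
    res: SplitResolution,
    global_link: LinkageResult | None,
    side: str,
    rect: Rect,
    centers: list[float],
) -> list:
    """Tree brackets: the global tree spans split gaps for integer/none
    splits; categorical splits draw one tree per re-clustered group."""
    prims = []
    if any(l is not None for l in res.group_links):
        offset = 0
        for (_, members), glink in zip(res.groups, res.group_links):
            if glink is not None:
                group_centers = centers[offset : offset + len(members)]
                for pts in dendrogram_geometry(glink, side, rect, group_centers):
                    prims.append(polyline(pts, stroke="#333333ff", tags={"dendrogram": side}))
            offset += len(members)
    elif global_link is not None:
        for pts in dendrogram_geometry(global_link, side, rect, centers):
            prims.append(polyline(pts, stroke="#333333ff", tags={"dendrogram": side}))
    return prims


def _main_legend(name: str, cmap: ColorSpec) -> Legend:
    if cmap.mode == "continuous":
        return Legend.make(
            name,
            "colorbar",
            [
                ("min", {"value": cmap.vmin, "ramp": cmap.ramp_name}),
                ("max", {"value": cmap.vmax, "ramp": cmap.ramp_name}),
            ],
        )
    return Legend.make(
        name, "categorical_patches",
        [(cat, {"color": col}) for cat, col in (cmap.mapping or {}).items()],
    )


def _spec_meta(spec: ClustermapSpec) -> dict:
    def split_desc(s: Any) -> str:
        if s is None:
            return "none"
        if isinstance(s, (int, np.integer)):
            return f"tree:{int(s)}"
        return "categorical"

    return {
        "kind": "clustermap",
        "name": spec.name,
        "method": spec.method,
        "metric": spec.metric,
        "standardize": spec.standardize,
        "cluster_rows": spec.cluster_rows,
        "cluster_cols": spec.cluster_cols,
        "row_split": split_desc(spec.row_split),
        "col_split": split_desc(spec.col_split),
        "row_gap": spec.row_gap,
        "col_gap": spec.col_gap,
    }


def annotation_only(
    tracks: list[Track],
    axis: int,
    order: Sequence[str],
    region: Rect = DEFAULT_REGION,
) -> FigureModel:
    """Plot annotation tracks without a heatmap body.

    ``axis=1`` lays horizontal lanes (per-column data, stacked upward);
    ``axis=0`` lays vertical lanes (per-row data, stacked rightward).
    Legends are collected exactly as in the joint figure.
    """
    if not tracks:
        raise SceneMapError("annotation_only needs at least one track")
    order = [str(i) for i in order]
    n = len(order)
    if n == 0:
        raise SceneMapError("empty axis order")
    if axis == 1:
        base = Rect(region.x + 0.08 * region.w, region.y + 0.10 * region.h,
                    0.84 * region.w, 0.0)
        side = "top"
        scale = region.h
        ivals = [
            (base.x + base.w * k / n, base.x + base.w * (k + 1) / n) for k in range(n)
        ]
    elif axis == 0:
        base = Rect(region.x + 0.10 * region.w, region.y + 0.08 * region.h,
                    0.0, 0.84 * region.h)
        side = "right"
        scale = region.w
        # top-to-bottom positions, matching heatmap row convention
        ivals = [
            (base.y1 - base.h * (k + 1) / n, base.y1 - base.h * k / n)
            for k in range(n)
        ]
    else:
        raise SceneMapError("axis must be 0 (rows) or 1 (columns)")
    rects = allocate_tracks(base, side, [t.extent * scale for t in tracks],
                            pad=_TRACK_PAD * scale)
    scene = Scene(meta={"kind": "annotation_only", "axis": axis})
    legend_requests: list[Legend] = []
    for track, rect in zip(tracks, rects):
        ctx = TrackContext(rect=rect, intervals=ivals, side=side)
        prims, legs = render_track(track, order, ctx)
        scene.add(prims)
        legend_requests.extend(legs)
    scene.validate()
    return FigureModel(
        grid=None,
        scene=scene,
        legends=build_legends(legend_requests),
        row_order=order if axis == 0 else [],
        col_order=order if axis == 1 else [],
    )
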