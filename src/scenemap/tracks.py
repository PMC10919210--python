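"""Annotation tracks: simple color bars, (stacked) bars, boxes, scatter
points and leader-line labels rendered into scene primitives.

Each renderer receives the display order of ids, the allocated track
rectangle and the per-position cell intervals along the bound axis
(which already reflect split gaps), and emits primitives plus the legend
models it needs. The same code path serves all four sides: the track's
value axis runs across the rectangle's depth, from the edge nearest the
heatmap (inner) to the far edge (outer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np

from .colors import ColorSpec, map_colors, text_contrast_color
from .datamodel import SceneMapError
from .layout import LabelPlacement, Rect, distribute_labels, merge_label_runs
from .scene import Legend, Primitive
from . import scene as sc

TRACK_KINDS = ("simple", "bar", "box", "scatter", "label")

DEFAULT_EXTENTS = {
    "simple": 0.025,
    "bar": 0.06,
    "box": 0.06,
    "scatter": 0.06,
    "label": 0.07,
}


@dataclass
class Track:
    """One annotation lane bound to per-row or per-column data.

    ``data`` is keyed by axis ids: one value per id for simple/scatter/
    label tracks, an ordered mapping of named vectors for bar tracks, and
    a sample list per id for box tracks.
    """

    kind: str
    name: str
    data: Any
    color: ColorSpec | None = None
    extent: float | None = None
    add_text: bool = False
    merge: bool = False
    extend: bool = True
    rotation: float = 0.0
    min_slot: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise SceneMapError(f"unknown track kind {self.kind!r}")
        if self.extent is None:
            self.extent = DEFAULT_EXTENTS[self.kind]
        if self.extent <= 0:
            raise SceneMapError("track extent must be positive")


@dataclass
class TrackContext:
    """Geometry a renderer needs: the track rect, the per-position cell
    intervals along the bound axis, and which side of the heatmap."""

    rect: Rect
    intervals: list[tuple[float, float]]
    side: str  # top | bottom | left | right

    @property
    def horizontal(self) -> bool:
        return self.side in ("top", "bottom")

    def depth_point(self, axis_coord: float, depth: float) -> tuple[float, float]:
        """Map (axis coordinate, depth in [0,1] from inner edge) to figure
        coordinates."""
        r = self.rect
        if self.side == "top":
            return (axis_coord, r.y + depth * r.h)
        if self.side == "bottom":
            return (axis_coord, r.y1 - depth * r.h)
        if self.side == "right":
            return (r.x + depth * r.w, axis_coord)
        return (r.x1 - depth * r.w, axis_coord)

    def cell_rect(self, pos: int, d0: float, d1: float, shrink: float = 0.0) -> Rect:
        """Rectangle covering cell ``pos`` between depths d0 < d1, optionally
        shrunk symmetrically along the axis by ``shrink`` (fraction of cell)."""
        lo, hi = self.intervals[pos]
        pad = (hi - lo) * shrink / 2.0
        lo, hi = lo + pad, hi - pad
        x0, y0 = self.depth_point(lo, d0)
        x1, y1 = self.depth_point(hi, d1)
        return Rect(min(x0, x1), min(y0, y1), abs(x1 - x0), abs(y1 - y0))


def _ordered_values(track_data: Mapping[str, Any], order: Sequence[str], what: str) -> list:
    out = []
    for i in order:
        if i not in track_data:
            raise SceneMapError(f"{what}: no data for id {i!r}")
        out.append(track_data[i])
    return out


def _rect_prim(r: Rect, fill: str, tags=None) -> Primitive:
    return sc.rect(r.x, r.y, r.w, r.h, fill=fill, tags=tags)


def render_simple(
    track: Track, order: Sequence[str], ctx: TrackContext
) -> tuple[list[Primitive], list[Legend]]:
    """Simple color bar: one filled rect per position; with ``add_text``,
    one text per contiguous same-value block, colored for contrast."""
    values = _ordered_values(track.data, order, f"simple track {track.name!r}")
    spec = track.color or _default_spec(values)
    spec = spec.resolved(values)
    colors = map_colors(values, spec)
    prims: list[Primitive] = []
    for pos, (v, c) in enumerate(zip(values, colors)):
        r = ctx.cell_rect(pos, 0.0, 1.0)
        prims.append(_rect_prim(r, c, tags={"track": track.name, "id": str(order[pos])}))
    if track.add_text:
        pos = 0
        n = len(values)
        while pos < n:
            j = pos
            while j + 1 < n and values[j + 1] == values[pos] and not _is_missing(values[pos]):
                j += 1
            if not _is_missing(values[pos]):
                lo = ctx.intervals[pos][0]
                hi = ctx.intervals[j][1]
                x, y = ctx.depth_point((lo + hi) / 2.0, 0.5)
                prims.append(
                    sc.text(
                        x, y, str(values[pos]), anchor="middle",
                        rotation=track.rotation,
                        fill=text_contrast_color(colors[pos]),
                        tags={"track": track.name},
                    )
                )
            pos = j + 1
    return prims, [_color_legend(track.name, spec)]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _default_spec(values: Sequence) -> ColorSpec:
    numeric = all(_is_missing(v) or isinstance(v, (int, float, np.floating)) for v in values)
    return ColorSpec.continuous() if numeric else ColorSpec.categorical()


def _color_legend(title: str, spec: ColorSpec) -> Legend:
    if spec.mode == "categorical":
        entries = [(cat, {"color": col}) for cat, col in (spec.mapping or {}).items()]
        return Legend.make(title, "categorical_patches", entries)
    return Legend.make(
        title,
        "colorbar",
        [
            ("min", {"value": spec.vmin, "ramp": spec.ramp_name}),
            ("max", {"value": spec.vmax, "ramp": spec.ramp_name}),
        ],
    )


def render_bar(
    track: Track, order: Sequence[str], ctx: TrackContext
) -> tuple[list[Primitive], list[Legend]]:
    """Bar annotation; one named vector gives simple bars, several give a
    stacked bar (segment per vector, in column order).

    The value axis starts at 0 on the inner edge so bar area is
    meaningful; a single vector scales to [0, max], stacked bars to the
    maximum row sum. Stacked mode requires non-negative values.
    """
    data: Mapping[str, Mapping[str, float]] = track.data
    names = list(data.keys())
    if not names:
        raise SceneMapError(f"bar track {track.name!r} has no vectors")
    columns = {
        nm: [float(v) for v in _ordered_values(data[nm], order, f"bar track {track.name!r}")]
        for nm in names
    }
    stacked = len(names) > 1
    n = len(order)
    if stacked:
        for nm in names:
            for pos, v in enumerate(columns[nm]):
                if v < 0:
                    raise SceneMapError(
                        f"negative value in stacked bar track {track.name!r} "
                        f"at position {order[pos]!r}, column {nm!r}"
                    )
        totals = [sum(columns[nm][p] for nm in names) for p in range(n)]
        vmax = max(totals) if max(totals) > 0 else 1.0
        vmin = 0.0
    else:
        vals = columns[names[0]]
        vmax = max(max(vals), 0.0)
        vmin = min(min(vals), 0.0)
        if vmax == vmin:
            vmax = vmin + 1.0
    span = vmax - vmin

    seg_colors = (
        map_colors(names, (track.color or ColorSpec.categorical()).resolved(names))
        if stacked
        else None
    )
    single_color = None
    if not stacked:
        spec = track.color
        if spec is not None and spec.mode == "categorical":
            spec = None
        if spec is not None:
            single_color = map_colors(columns[names[0]], spec.resolved(columns[names[0]]))
        else:
            single_color = ["#4c72b0ff"] * n

    prims: list[Primitive] = []
    for pos in range(n):
        base = (0.0 - vmin) / span
        if stacked:
            acc = base
            for k, nm in enumerate(names):
                v = columns[nm][pos]
                dh = v / span
                if dh > 0:
                    r = ctx.cell_rect(pos, acc, acc + dh, shrink=0.2)
                    prims.append(
                        _rect_prim(
                            r, seg_colors[k],
                            tags={"track": track.name, "id": str(order[pos]), "segment": nm},
                        )
                    )
                acc += dh
        else:
            v = columns[names[0]][pos]
            d0, d1 = sorted((base, base + v / span))
            if d1 > d0:
                r = ctx.cell_rect(pos, d0, d1, shrink=0.2)
                prims.append(
                    _rect_prim(
                        r, single_color[pos],
                        tags={"track": track.name, "id": str(order[pos])},
                    )
                )
    legends = []
    if stacked:
        spec = (track.color or ColorSpec.categorical()).resolved(names)
        legends.append(_color_legend(track.name, spec))
    return prims, legends


def box_stats(samples: Sequence[float]) -> tuple[float, float, float, float, float, list[float]]:
    """Five-number summary with Tukey whiskers.

    Quartiles use linear interpolation between order statistics (the
    "type 7" rule); whiskers reach the most extreme samples within
    1.5 * IQR of the box, and anything beyond is an outlier.
    """
    vals = np.asarray([s for s in samples if np.isfinite(s)], dtype=float)
    if vals.size == 0:
        raise SceneMapError("box_stats needs at least one finite sample")
    q1, med, q3 = (float(q) for q in np.percentile(vals, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    whisker_lo = float(inside.min())
    whisker_hi = float(inside.max())
    outliers = sorted(float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)])
    return q1, med, q3, whisker_lo, whisker_hi, outliers


def _value_axis(all_values: Sequence[float]) -> tuple[float, float]:
    vals = [v for v in all_values if np.isfinite(v)]
    if not vals:
        raise SceneMapError("no finite values for value axis")
    lo, hi = min(vals), max(vals)
    return lo, hi


def render_box(
    track: Track, order: Sequence[str], ctx: TrackContext
) -> tuple[list[Primitive], list[Legend]]:
    """Box annotation: box + median line + whiskers + outlier markers per
    position, on one value axis shared across positions (data min to max,
    mapped inner to outer edge)."""
    samples = _ordered_values(track.data, order, f"box track {track.name!r}")
    lo, hi = _value_axis([v for s in samples for v in s])
    span = hi - lo

    def to_depth(v: float) -> float:
        return 0.5 if span == 0 else (v - lo) / span

    fill = "#9ecae1ff"
    prims: list[Primitive] = []
    for pos, s in enumerate(samples):
        q1, med, q3, wlo, whi, out = box_stats(s)
        tags = {"track": track.name, "id": str(order[pos])}
        box_r = ctx.cell_rect(pos, to_depth(q1), to_depth(q3), shrink=0.3)
        if box_r.w > 0 and box_r.h > 0:
            prims.append(_rect_prim(box_r, fill, tags=tags))
        clo, chi = ctx.intervals[pos]
        pad = (chi - clo) * 0.15
        med_a, med_b = clo + pad, chi - pad
        prims.append(
            sc.line(
                ctx.depth_point(med_a, to_depth(med)),
                ctx.depth_point(med_b, to_depth(med)),
                stroke="#000000ff",
                tags=tags,
            )
        )
        center = (clo + chi) / 2.0
        for a, b in ((wlo, q1), (q3, whi)):
            if b > a:
                prims.append(
                    sc.polyline(
                        [ctx.depth_point(center, to_depth(a)), ctx.depth_point(center, to_depth(b))],
                        stroke="#000000ff",
                        tags=tags,
                    )
                )
        for o in out:
            x, y = ctx.depth_point(center, to_depth(o))
            prims.append(sc.marker(x, y, shape="circle", radius=0.0025, fill="#555555ff", tags=tags))
    return prims, []


def render_scatter(
    track: Track, order: Sequence[str], ctx: TrackContext
) -> tuple[list[Primitive], list[Legend]]:
    """Scatter annotation: one marker per position at its value on the
    shared [min, max] axis; axis endpoints sit exactly on the track's
    inner and outer edges."""
    values = [float(v) for v in _ordered_values(track.data, order, f"scatter track {track.name!r}")]
    lo, hi = _value_axis(values)
    span = hi - lo
    prims: list[Primitive] = []
    colors = (
        map_colors(values, track.color.resolved(values))
        if track.color is not None
        else ["#4c72b0ff"] * len(values)
    )
    for pos, v in enumerate(values):
        if not np.isfinite(v):
            continue
        depth = 0.5 if span == 0 else (v - lo) / span
        clo, chi = ctx.intervals[pos]
        x, y = ctx.depth_point((clo + chi) / 2.0, depth)
        prims.append(
            sc.marker(
                x, y, shape="circle", radius=0.004, fill=colors[pos],
                tags={"track": track.name, "id": str(order[pos])},
            )
        )
    return prims, []


def render_label(
    track: Track, order: Sequence[str], ctx: TrackContext
) -> tuple[list[Primitive], list[Legend]]:
    """Label annotation: merge runs (optional), distribute slots evenly,
    and emit leader polylines plus rotated texts.

    Anchors are panel-adjusted: run centers in position units are mapped
    through the cell intervals, so labels follow their cells across split
    gaps.
    """
    values = _ordered_values(track.data, order, f"label track {track.name!r}")
    labels_vec = [None if _is_missing(v) else str(v) for v in values]
    if track.merge:
        pos_anchors, labels = merge_label_runs(labels_vec)
    else:
        pos_anchors = [i + 0.5 for i, v in enumerate(labels_vec) if v is not None]
        labels = [v for v in labels_vec if v is not None]
    if not labels:
        return [], []
    anchors = [_position_to_axis(a, ctx.intervals) for a in pos_anchors]
    if ctx.horizontal:
        interval = (ctx.rect.x, ctx.rect.x1)
    else:
        # row positions run top to bottom, i.e. decreasing y: reverse so
        # anchors are strictly increasing for the placement algorithm
        anchors, labels = anchors[::-1], labels[::-1]
        interval = (ctx.rect.y, ctx.rect.y1)
    placement = distribute_labels(
        anchors, labels, interval, extend=track.extend,
        min_slot=track.min_slot, rotation=track.rotation,
    )
    return _label_primitives(track, placement, ctx), []


def _position_to_axis(pos: float, intervals: list[tuple[float, float]]) -> float:
    """Map a fractional position-unit coordinate through the cell intervals
    (piecewise linear; handles split gaps)."""
    n = len(intervals)
    i = min(int(math.floor(pos)), n - 1)
    frac = pos - i
    lo, hi = intervals[i]
    return lo + frac * (hi - lo)


def _label_primitives(
    track: Track, placement: LabelPlacement, ctx: TrackContext
) -> list[Primitive]:
    prims: list[Primitive] = []
    vertical_axis = not ctx.horizontal
    for slot in placement.slots:
        pts = [ctx.depth_point(a, d) for a, d in slot.leader]
        prims.append(
            sc.polyline(pts, stroke="#444444ff", tags={"track": track.name, "label": slot.text})
        )
        tx, ty = ctx.depth_point(slot.slot, 1.0)
        if ctx.side == "top":
            anchor = "start" if slot.rotation else "middle"
        elif ctx.side == "bottom":
            anchor = "end" if slot.rotation else "middle"
        elif ctx.side == "right":
            anchor = "start"
        else:
            anchor = "end"
        prims.append(
            sc.text(
                tx, ty, slot.text, anchor=anchor, rotation=slot.rotation,
                tags={"track": track.name, "label": slot.text},
            )
        )
    return prims


RENDERERS = {
    "simple": render_simple,
    "bar": render_bar,
    "box": render_box,
    "scatter": render_scatter,
    "label": render_label,
}


def render_track(
    track: Track, order: Sequence[str], ctx: TrackContext
) -> tuple[list[Primitive], list[Legend]]:
    return RENDERERS[track.kind](track, order, ctx)
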