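"""Pure layout geometry: split panel grids, annotation-track stacking,
dendrogram brackets and even label distribution with leader lines.

Coordinate conventions. Figure space is the unit square, origin at the
bottom-left, y up. In data space, cell (i, j) occupies the half-open unit
square [j, j+1) x [i, i+1) with row 0 at the TOP of the plot; an affine
map per panel takes data space to figure space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .clustering import LinkageResult, leaf_order
from .datamodel import SceneMapError

SIDES = ("top", "bottom", "left", "right")

#: Default gap between split panels, as a fraction of the plot extent.
DEFAULT_GAP = 0.01


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in figure coordinates (x, y = lower-left)."""

    x: float
    y: float
    w: float
    h: float

    @property
    def x1(self) -> float:
        return self.x + self.w

    @property
    def y1(self) -> float:
        return self.y + self.h

    def contains(self, other: "Rect", tol: float = 1e-9) -> bool:
        return (
            self.x - tol <= other.x
            and self.y - tol <= other.y
            and other.x1 <= self.x1 + tol
            and other.y1 <= self.y1 + tol
        )

    def intersects(self, other: "Rect", tol: float = 1e-9) -> bool:
        return not (
            other.x >= self.x1 - tol
            or other.x1 <= self.x + tol
            or other.y >= self.y1 - tol
            or other.y1 <= self.y + tol
        )


def _partition(extent: float, sizes: Sequence[int], gap: float) -> list[tuple[float, float]]:
    """Split ``extent`` into |sizes| spans proportional to sizes with fixed
    gaps between; returns (offset, width) pairs from the start."""
    g = len(sizes)
    total_gap = gap * (g - 1)
    if total_gap >= extent:
        raise SceneMapError(
            f"gaps ({total_gap:.4g}) do not fit in extent {extent:.4g}"
        )
    usable = extent - total_gap
    total = float(sum(sizes))
    out: list[tuple[float, float]] = []
    pos = 0.0
    for s in sizes:
        w = usable * s / total
        out.append((pos, w))
        pos += w + gap
    return out


@dataclass
class PanelGrid:
    """The heatmap body area: split panels plus per-side track rectangles.

    ``panels[(ri, ci)]`` is the rectangle of row group ri (0 = top) and
    column group ci (0 = left). ``track_rects[side]`` stacks outward from
    ``plot_rect``.
    """

    plot_rect: Rect
    row_sizes: list[int]
    col_sizes: list[int]
    row_gap: float
    col_gap: float
    panels: dict[tuple[int, int], Rect] = field(default_factory=dict)
    track_rects: dict[str, list[Rect]] = field(
        default_factory=lambda: {s: [] for s in SIDES}
    )

    @property
    def n_rows(self) -> int:
        return int(sum(self.row_sizes))

    @property
    def n_cols(self) -> int:
        return int(sum(self.col_sizes))

    def col_cell_intervals(self) -> list[tuple[float, float]]:
        """Figure-x interval (lo, hi) of each display column, left to right,
        respecting split gaps."""
        spans = _partition(self.plot_rect.w, self.col_sizes, self.col_gap)
        out: list[tuple[float, float]] = []
        for (off, w), size in zip(spans, self.col_sizes):
            cw = w / size
            for j in range(size):
                lo = self.plot_rect.x + off + j * cw
                out.append((lo, lo + cw))
        return out

    def row_cell_intervals(self) -> list[tuple[float, float]]:
        """Figure-y interval (lo, hi) of each display row, TOP to bottom."""
        spans = _partition(self.plot_rect.h, self.row_sizes, self.row_gap)
        out: list[tuple[float, float]] = []
        top = self.plot_rect.y1
        for (off, h), size in zip(spans, self.row_sizes):
            ch = h / size
            for i in range(size):
                hi = top - off - i * ch
                out.append((hi - ch, hi))
        return out


def compute_grid(
    row_group_sizes: Sequence[int],
    col_group_sizes: Sequence[int],
    plot_rect: Rect,
    row_gap: float = DEFAULT_GAP,
    col_gap: float = DEFAULT_GAP,
) -> PanelGrid:
    """Panel rectangles for a split heatmap.

    Panel widths are proportional to column-group sizes and heights to
    row-group sizes; row group 0 sits at the top. Gaps are absolute
    figure fractions. Panels plus gaps tile ``plot_rect`` exactly.
    """
    row_group_sizes = [int(s) for s in row_group_sizes]
    col_group_sizes = [int(s) for s in col_group_sizes]
    if any(s <= 0 for s in row_group_sizes + col_group_sizes):
        raise SceneMapError("group sizes must be positive")
    col_spans = _partition(plot_rect.w, col_group_sizes, col_gap)
    row_spans = _partition(plot_rect.h, row_group_sizes, row_gap)
    panels: dict[tuple[int, int], Rect] = {}
    for ri, (roff, rh) in enumerate(row_spans):
        for ci, (coff, cw) in enumerate(col_spans):
            panels[(ri, ci)] = Rect(
                x=plot_rect.x + coff,
                y=plot_rect.y1 - roff - rh,
                w=cw,
                h=rh,
            )
    return PanelGrid(
        plot_rect=plot_rect,
        row_sizes=row_group_sizes,
        col_sizes=col_group_sizes,
        row_gap=row_gap,
        col_gap=col_gap,
        panels=panels,
    )


def allocate_tracks(
    plot_rect: Rect,
    side: str,
    track_extents: Sequence[float],
    pad: float = 0.004,
) -> list[Rect]:
    """Stack annotation-track rectangles outward from the plot on one side.

    The first track is adjacent to the heatmap; each rectangle spans the
    plot's full cross-axis extent (including split gaps, so annotation
    blocks align with the panels).
    """
    if side not in SIDES:
        raise SceneMapError(f"side must be one of {SIDES}, got {side!r}")
    if any(e <= 0 for e in track_extents):
        raise SceneMapError("track extents must be positive")
    rects: list[Rect] = []
    offset = pad
    for extent in track_extents:
        if side == "top":
            r = Rect(plot_rect.x, plot_rect.y1 + offset, plot_rect.w, extent)
        elif side == "bottom":
            r = Rect(plot_rect.x, plot_rect.y - offset - extent, plot_rect.w, extent)
        elif side == "left":
            r = Rect(plot_rect.x - offset - extent, plot_rect.y, extent, plot_rect.h)
        else:
            r = Rect(plot_rect.x1 + offset, plot_rect.y, extent, plot_rect.h)
        rects.append(r)
        offset += pad + extent
    for r in rects:
        if r.x < -1e-9 or r.y < -1e-9 or r.x1 > 1 + 1e-9 or r.y1 > 1 + 1e-9:
            raise SceneMapError(
                f"track stack on side {side!r} extends outside the figure"
            )
    return rects


def dendrogram_geometry(
    link: LinkageResult,
    orientation: str,
    rect: Rect,
    leaf_centers: Sequence[float] | None = None,
) -> list[list[tuple[float, float]]]:
    """Rectangular dendrogram brackets for one merge tree.

    Returns n-1 polylines of 3 segments each. Leaves sit on the inner
    edge (the edge facing the heatmap) at ``leaf_centers`` along the leaf
    axis (figure coordinates; default: evenly spaced cell centers across
    the rect); merge depth is proportional to height, with the root at
    the outer edge.
    """
    if orientation not in SIDES:
        raise SceneMapError(f"orientation must be one of {SIDES}")
    n = link.n_leaves
    horiz = orientation in ("top", "bottom")  # leaf axis horizontal
    if leaf_centers is None:
        lo = rect.x if horiz else rect.y
        span = rect.w if horiz else rect.h
        leaf_centers = [lo + span * (i + 0.5) / n for i in range(n)]
    if len(leaf_centers) != n:
        raise SceneMapError("one leaf center per leaf required")
    order = leaf_order(link)
    pos: dict[int, float] = {leaf: leaf_centers[p] for p, leaf in enumerate(order)}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    max_h = max((h for *_xy, h in link.merges), default=0.0)
    for t, (l, r, h) in enumerate(link.merges):
        node = n + t
        pos[node] = 0.5 * (pos[l] + pos[r])
        height[node] = h

    def depth_to_fig(h: float) -> float:
        frac = 0.0 if max_h == 0 else h / max_h
        if orientation == "top":
            return rect.y + frac * rect.h
        if orientation == "bottom":
            return rect.y1 - frac * rect.h
        if orientation == "left":
            return rect.x1 - frac * rect.w
        return rect.x + frac * rect.w

    polylines: list[list[tuple[float, float]]] = []
    for t, (l, r, h) in enumerate(link.merges):
        d = depth_to_fig(h)
        dl = depth_to_fig(height[l])
        dr = depth_to_fig(height[r])
        xl, xr = pos[l], pos[r]
        if horiz:
            pts = [(xl, dl), (xl, d), (xr, d), (xr, dr)]
        else:
            pts = [(dl, xl), (d, xl), (d, xr), (dr, xr)]
        polylines.append(pts)
    return polylines


def merge_label_runs(
    labels_per_position: Sequence[str | None],
) -> tuple[list[float], list[str]]:
    """Collapse maximal runs of consecutive equal labels to one anchor each.

    Positions occupy unit cells [i, i+1); a run over positions i..j gets
    one anchor at its center (i + j + 1) / 2. Unlabeled positions (None or
    empty) produce nothing and break runs. Non-adjacent equal labels stay
    separate anchors.
    """
    anchors: list[float] = []
    merged: list[str] = []
    i = 0
    n = len(labels_per_position)
    while i < n:
        lab = labels_per_position[i]
        if lab is None or str(lab) == "":
            i += 1
            continue
        j = i
        while j + 1 < n and labels_per_position[j + 1] == lab:
            j += 1
        anchors.append((i + j + 1) / 2.0)
        merged.append(str(lab))
        i = j + 1
    return anchors, merged


@dataclass
class LabelSlot:
    anchor: float  # data-axis coordinate of the feature
    slot: float  # axis coordinate of the text
    leader: list[tuple[float, float]]  # (axis, depth in [0,1]) polyline
    text: str
    rotation: float


@dataclass
class LabelPlacement:
    """Placed labels: disjoint, order-preserving slots with 3-segment
    leaders from anchor (depth 0) to text (depth 1)."""

    slots: list[LabelSlot]
    interval: tuple[float, float]


def distribute_labels(
    anchors: Sequence[float],
    labels: Sequence[str],
    axis_interval: tuple[float, float],
    extend: bool = True,
    min_slot: float = 0.0,
    rotation: float = 0.0,
) -> LabelPlacement:
    """Place labels evenly along the axis without overlap.

    With ``extend`` the m slot centers are L * (i - 0.5) / m over the full
    axis interval; without it, the same even spacing is applied over the
    anchor span padded by half the mean run width and clipped to the axis.
    Slots keep the anchors' left-to-right order, so leaders never cross.
    Each leader is a vertical stub from the anchor (25% of track depth), a
    diagonal to the slot (50%), and a vertical stub to the text (25%).
    """
    m = len(anchors)
    if m == 0 or m != len(labels):
        raise SceneMapError("need one label per anchor, at least one")
    for a, b in zip(anchors, anchors[1:]):
        if not a < b:
            raise SceneMapError("anchors must be strictly increasing")
    lo, hi = float(axis_interval[0]), float(axis_interval[1])
    L = hi - lo
    if L <= 0:
        raise SceneMapError("axis interval must have positive length")
    if m * min_slot > L + 1e-12:
        raise SceneMapError(
            f"{m} labels at min slot {min_slot:.4g} exceed the axis interval "
            f"({L:.4g}); reduce the number of labels"
        )
    if extend:
        s_lo, s_hi = lo, hi
    else:
        mean_run = (anchors[-1] - anchors[0]) / m if m > 1 else L
        s_lo = max(lo, anchors[0] - mean_run / 2.0)
        s_hi = min(hi, anchors[-1] + mean_run / 2.0)
        if s_hi - s_lo < m * min_slot:
            s_lo, s_hi = lo, hi
    span = s_hi - s_lo
    slots: list[LabelSlot] = []
    for i, (a, lab) in enumerate(zip(anchors, labels), start=1):
        s = s_lo + span * (i - 0.5) / m
        leader = [(a, 0.0), (a, 0.25), (s, 0.75), (s, 1.0)]
        slots.append(LabelSlot(anchor=float(a), slot=s, leader=leader, text=lab, rotation=rotation))
    return LabelPlacement(slots=slots, interval=(s_lo, s_hi))
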