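"""oncoPrint: genes x samples alteration glyphs with frequency side-bars.

Each cell shows the set of alteration categories for one (gene, sample)
pair as equal horizontal bands over a neutral background; genes are
ranked by alteration frequency and samples ordered by the waterfall
("memo") sort that exposes mutual exclusivity. A stacked top bar counts
alterations per sample by category; a right bar shows the percentage of
samples altered per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

from .clustering import SplitResolution
from .colors import ColorSpec
from .datamodel import AlterationTable, SceneMapError
from .layout import DEFAULT_GAP, Rect, allocate_tracks, compute_grid
from .scene import Legend, Scene, build_legends
from .clustermap import DEFAULT_REGION, FigureModel, _default_plot_rect, _track_ctx
from .tracks import Track, render_track
from . import scene as sc
from . import clustermap as _cm

BACKGROUND_COLOR = "#dcdcdcff"
#: Inner glyph fraction of the cell (background rect covers this much).
INNER_FRACTION = 0.9


@dataclass
class OncoprintSpec:
    alterations: AlterationTable
    name: str = "oncoprint"
    color: ColorSpec | None = None  # category -> color
    sort: str = "memo"  # memo | input | frequency
    min_gene_count: int = 0  # drop genes altered in fewer samples
    min_sample_count: int = 0  # drop samples with fewer altered genes
    col_split: Any = None  # categorical only (dict id -> label or vector)
    top_tracks: list[Track] = field(default_factory=list)
    bottom_tracks: list[Track] = field(default_factory=list)
    left_tracks: list[Track] = field(default_factory=list)
    right_tracks: list[Track] = field(default_factory=list)
    col_gap: float = DEFAULT_GAP
    show_top_bar: bool = True
    show_right_bar: bool = True
    #: optional per-category glyph style: category -> (band fraction,
    #: vertical offset), both fractions of the inner cell height; default
    #: is equal full-width bands per present category
    band_style: dict[str, tuple[float, float]] | None = None

    def tracks_on(self, side: str) -> list[Track]:
        return getattr(self, f"{side}_tracks")


def alteration_grid(
    table: AlterationTable,
) -> tuple[list[str], list[str], dict[tuple[str, str], list[str]]]:
    """Category sets per (gene, sample) cell, axes in first-appearance order."""
    genes = table.genes
    samples = table.samples
    cells: dict[tuple[str, str], list[str]] = {}
    for rec in table.records:
        key = (rec.gene_id, rec.sample_id)
        cats = cells.setdefault(key, [])
        if rec.category not in cats:
            cats.append(rec.category)
    return genes, samples, cells


def memo_sort(
    genes: Sequence[str],
    samples: Sequence[str],
    cells: dict[tuple[str, str], list[str]],
) -> tuple[list[str], list[str]]:
    """Waterfall ordering for mutual exclusivity.

    Genes are sorted by alteration frequency descending (ties keep input
    order); samples by descending lexicographic comparison of their
    binary altered/unaltered vectors read in the sorted gene order (ties
    keep input order), so samples altered in the most frequent gene come
    first.
    """
    if not genes or not samples:
        raise SceneMapError("memo_sort needs at least one gene and one sample")
    freq = {
        g: sum(1 for s in samples if (g, s) in cells) for g in genes
    }
    gene_order = sorted(genes, key=lambda g: -freq[g])  # stable: ties in input order
    def sample_key(s: str) -> tuple[int, ...]:
        return tuple(1 if (g, s) in cells else 0 for g in gene_order)
    sample_order = sorted(samples, key=sample_key, reverse=True)
    return gene_order, sample_order


def build_oncoprint(
    spec: OncoprintSpec,
    region: Rect = DEFAULT_REGION,
    imposed_rows: list[tuple[str, list[str]]] | None = None,
    imposed_cols: list[tuple[str, list[str]]] | None = None,
    **_ignored,
) -> FigureModel:
    """Build the oncoPrint figure for ``spec`` inside ``region``."""
    genes, samples, cells = alteration_grid(spec.alterations)
    if not cells:
        raise SceneMapError("alteration table yields an empty grid")
    # inclusion filters
    genes = [
        g for g in genes
        if sum(1 for s in samples if (g, s) in cells) >= spec.min_gene_count
    ]
    samples = [
        s for s in samples
        if sum(1 for g in genes if (g, s) in cells) >= spec.min_sample_count
    ]
    if not genes or not samples:
        raise SceneMapError("no genes or samples left after filters")

    categories = [
        c for c in spec.alterations.categories
        if any(c in cells.get((g, s), []) for g in genes for s in samples)
    ]
    cspec = (spec.color or ColorSpec.categorical(title=spec.name)).resolved(categories)

    if imposed_rows is not None:
        genes = [g for _, mem in imposed_rows for g in mem]
    if imposed_cols is not None:
        col_groups = [(lab, list(mem)) for lab, mem in imposed_cols]
        samples = [s for _, mem in col_groups for s in mem]
    else:
        col_groups = None
        if spec.sort == "memo":
            if imposed_rows is None:
                genes, samples = memo_sort(genes, samples, cells)
            else:  # keep the imposed gene order; waterfall-sort samples only
                def sample_key(s: str) -> tuple[int, ...]:
                    return tuple(1 if (g, s) in cells else 0 for g in genes)
                samples = sorted(samples, key=sample_key, reverse=True)
        elif spec.sort == "frequency":
            if imposed_rows is None:
                freq = {g: sum(1 for s in samples if (g, s) in cells) for g in genes}
                genes = sorted(genes, key=lambda g: -freq[g])
        elif spec.sort != "input":
            raise SceneMapError(f"unknown sort mode {spec.sort!r}")
        if spec.col_split is not None:
            split = spec.col_split
            if isinstance(split, dict):
                missing = [s for s in samples if s not in split]
                if missing:
                    raise SceneMapError(
                        "col_split mapping is missing samples: " + ", ".join(missing)
                    )
                lab_of = {s: str(split[s]) for s in samples}
            else:
                if len(split) != len(samples):
                    raise SceneMapError("col_split vector length mismatch")
                lab_of = dict(zip(samples, map(str, split)))
            levels: list[str] = []
            for s in samples:
                if lab_of[s] not in levels:
                    levels.append(lab_of[s])
            col_groups = [
                (lev, [s for s in samples if lab_of[s] == lev]) for lev in levels
            ]
            samples = [s for _, mem in col_groups for s in mem]

    row_res = SplitResolution(groups=[("all", list(range(len(genes))))])
    if col_groups is None:
        col_res = SplitResolution(groups=[("all", list(range(len(samples))))])
    else:
        pos = {s: p for p, s in enumerate(samples)}
        col_res = SplitResolution(
            groups=[(lab, [pos[s] for s in mem]) for lab, mem in col_groups]
        )

    plot_rect = _default_plot_rect(region)
    grid = compute_grid(
        [len(genes)], col_res.sizes(), plot_rect,
        row_gap=0.0, col_gap=spec.col_gap * region.w,
    )
    col_ivals = grid.col_cell_intervals()
    row_ivals = grid.row_cell_intervals()

    scene = Scene(meta={"kind": "oncoprint", "name": spec.name, "sort": spec.sort})
    legend_requests: list[Legend] = [
        Legend.make(
            spec.name, "categorical_patches",
            [(c, {"color": (cspec.mapping or {})[c]}) for c in categories],
        )
    ]

    cat_color = dict(cspec.mapping or {})
    for di, g in enumerate(genes):
        y0, y1 = row_ivals[di]
        ch = y1 - y0
        iy0 = y0 + ch * (1 - INNER_FRACTION) / 2.0
        ih = ch * INNER_FRACTION
        for dj, s in enumerate(samples):
            x0, x1 = col_ivals[dj]
            cw = x1 - x0
            ix0 = x0 + cw * (1 - INNER_FRACTION) / 2.0
            iw = cw * INNER_FRACTION
            scene.add([
                sc.rect(ix0, iy0, iw, ih, fill=BACKGROUND_COLOR,
                        tags={"cell": "1", "row": g, "col": s})
            ])
            cats = cells.get((g, s))
            if not cats:
                continue
            present = [c for c in categories if c in cats]
            if spec.band_style:
                for c in present:
                    frac, off = spec.band_style.get(c, (1.0, 0.0))
                    scene.add([
                        sc.rect(ix0, iy0 + off * ih, iw, frac * ih,
                                fill=cat_color[c],
                                tags={"band": c, "row": g, "col": s})
                    ])
            else:
                band_h = ih / len(present)
                for k, c in enumerate(present):
                    scene.add([
                        sc.rect(ix0, iy0 + k * band_h, iw, band_h,
                                fill=cat_color[c],
                                tags={"band": c, "row": g, "col": s})
                    ])

    # frequency side-bars
    if spec.show_top_bar:
        counts = {
            c: {s: float(sum(1 for g in genes if c in cells.get((g, s), []))) for s in samples}
            for c in categories
        }
        top_bar = Track(
            kind="bar", name=f"{spec.name} counts", data=counts,
            color=ColorSpec.categorical(mapping=cat_color), extent=0.08,
        )
        rect_top = allocate_tracks(plot_rect, "top", [0.08 * region.h],
                                   pad=_cm._TRACK_PAD * region.h)[0]
        prims, legs = render_track(top_bar, samples, _track_ctx(rect_top, "top", grid))
        scene.add(prims)
    if spec.show_right_bar:
        pct = {
            g: 100.0 * sum(1 for s in samples if (g, s) in cells) / len(samples)
            for g in genes
        }
        right_bar = Track(
            kind="bar", name=f"{spec.name} freq", data={"pct": pct}, extent=0.08,
        )
        rect_right = allocate_tracks(plot_rect, "right", [0.08 * region.w],
                                     pad=_cm._TRACK_PAD * region.w)[0]
        ctx = _track_ctx(rect_right, "right", grid)
        prims, _ = render_track(right_bar, genes, ctx)
        scene.add(prims)
        for di, g in enumerate(genes):
            y0, y1 = row_ivals[di]
            scene.add([
                sc.text(rect_right.x1 + 0.005 * region.w, (y0 + y1) / 2.0,
                        f"{round(pct[g])}%", anchor="start",
                        tags={"freq_label": g})
            ])

    # extra annotation tracks (placed outside the frequency bars)
    for side in ("top", "bottom", "left", "right"):
        tracks = spec.tracks_on(side)
        if not tracks:
            continue
        scale = region.h if side in ("top", "bottom") else region.w
        lead = []
        if side == "top" and spec.show_top_bar:
            lead = [0.08 * scale]
        if side == "right" and spec.show_right_bar:
            lead = [0.12 * scale]  # bar + percentage texts
        rects = allocate_tracks(plot_rect, side, lead + [t.extent * scale for t in tracks],
                                pad=_cm._TRACK_PAD * scale)[len(lead):]
        order = samples if side in ("top", "bottom") else genes
        for track, rect in zip(tracks, rects):
            prims, legs = render_track(track, order, _track_ctx(rect, side, grid))
            scene.add(prims)
            legend_requests.extend(legs)

    scene.validate()
    return FigureModel(
        grid=grid,
        scene=scene,
        legends=build_legends(legend_requests),
        row_order=list(genes),
        col_order=list(samples),
        row_split=row_res,
        col_split=col_res,
    )
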