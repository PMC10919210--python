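"""Annotation track renderers: geometry and statistics."""

import numpy as np
import pytest

from scenemap import ColorSpec, Rect, SceneMapError, Track, box_stats, map_colors
from scenemap.tracks import TrackContext, render_track


def make_ctx(n=3, side="top", rect=Rect(0.1, 0.8, 0.6, 0.1)):
    if side in ("top", "bottom"):
        ivals = [(rect.x + rect.w * k / n, rect.x + rect.w * (k + 1) / n) for k in range(n)]
    else:
        ivals = [
            (rect.y1 - rect.h * (k + 1) / n, rect.y1 - rect.h * k / n) for k in range(n)
        ]
    return TrackContext(rect=rect, intervals=ivals, side=side)


def in_rect(prim, rect, tol=1e-9):
    return all(
        rect.x - tol <= x <= rect.x1 + tol and rect.y - tol <= y <= rect.y1 + tol
        for x, y in prim.coordinates()
    )


class TestSimpleTrack:
    def test_blocks_get_one_text_each_at_block_center(self):
        track = Track(kind="simple", name="g", add_text=True,
                      data={"a": "A", "b": "A", "c": "B"})
        ctx = make_ctx(3)
        prims, legends = render_track(track, ["a", "b", "c"], ctx)
        rects = [p for p in prims if p.kind == "rect"]
        texts = [p for p in prims if p.kind == "text"]
        assert len(rects) == 3
        assert [t.text for t in texts] == ["A", "B"]
        # block AA spans cells 0-1 of [0.1, 0.7]: center 0.3; B: 0.6
        assert texts[0].x == pytest.approx(0.3)
        assert texts[1].x == pytest.approx(0.6)

    def test_continuous_fills_follow_color_map(self):
        vals = {"a": 0.0, "b": 0.5, "c": 1.0}
        spec = ColorSpec.continuous(vmin=0, vmax=1)
        track = Track(kind="simple", name="v", data=vals, color=spec)
        prims, _ = render_track(track, ["a", "b", "c"], make_ctx(3))
        fills = [p.fill for p in prims if p.kind == "rect"]
        assert fills == map_colors([0.0, 0.5, 1.0], spec)

    def test_single_position(self):
        track = Track(kind="simple", name="g", add_text=True, data={"a": "X"})
        prims, _ = render_track(track, ["a"], make_ctx(1))
        assert len([p for p in prims if p.kind == "rect"]) == 1
        assert len([p for p in prims if p.kind == "text"]) == 1

    def test_missing_annotation_id_is_named(self):
        track = Track(kind="simple", name="g", data={"a": "A"})
        with pytest.raises(SceneMapError, match="zzz"):
            render_track(track, ["zzz"], make_ctx(1))

    def test_primitives_stay_inside_track_rect(self):
        track = Track(kind="simple", name="g", data={"a": "A", "b": "B", "c": "A"})
        ctx = make_ctx(3)
        prims, _ = render_track(track, ["a", "b", "c"], ctx)
        assert all(in_rect(p, ctx.rect) for p in prims)


class TestBarTrack:
    def test_single_vector_scales_to_max(self):
        rect = Rect(0.0, 0.0, 0.6, 0.2)
        ctx = make_ctx(3, rect=rect)
        track = Track(kind="bar", name="b", data={"v": {"a": 1.0, "b": 2.0, "c": 4.0}})
        prims, _ = render_track(track, ["a", "b", "c"], ctx)
        heights = [p.h for p in prims if p.kind == "rect"]
        assert heights == [pytest.approx(0.05), pytest.approx(0.1), pytest.approx(0.2)]

    def test_stacked_segments_conserve_total_and_ratio(self):
        ctx = make_ctx(1, rect=Rect(0.0, 0.0, 0.2, 0.3))
        track = Track(kind="bar", name="b",
                      data={"u": {"a": 1.0}, "v": {"a": 3.0}})
        prims, _ = render_track(track, ["a"], ctx)
        segs = [p for p in prims if p.kind == "rect"]
        assert len(segs) == 2
        total = sum(p.h for p in segs)
        assert total == pytest.approx(0.3, abs=1e-9)
        assert segs[1].h / segs[0].h == pytest.approx(3.0)

    def test_vector_count_switches_simple_vs_stacked(self):
        ctx = make_ctx(2)
        one, _ = render_track(
            Track(kind="bar", name="b", data={"v": {"a": 1.0, "b": 2.0}}),
            ["a", "b"], ctx,
        )
        two, legends = render_track(
            Track(kind="bar", name="b",
                  data={"u": {"a": 1.0, "b": 2.0}, "v": {"a": 1.0, "b": 0.5}}),
            ["a", "b"], ctx,
        )
        assert all("segment" not in p.tags for p in one)
        assert all("segment" in p.tags for p in two if p.kind == "rect")
        assert legends  # stacked bars document their segment colors

    def test_negative_value_in_stacked_mode_is_located(self):
        track = Track(kind="bar", name="b",
                      data={"u": {"a": 1.0}, "v": {"a": -0.5}})
        with pytest.raises(SceneMapError, match="'a'.*'v'"):
            render_track(track, ["a"], make_ctx(1))

    def test_stacked_conservation_across_positions(self):
        rng = np.random.default_rng(4)
        n = 8
        ids = [f"s{i}" for i in range(n)]
        data = {
            name: dict(zip(ids, rng.uniform(0, 5, n))) for name in ("x", "y", "z")
        }
        rect = Rect(0.0, 0.5, 0.8, 0.25)
        ctx = make_ctx(n, rect=rect)
        prims, _ = render_track(Track(kind="bar", name="b", data=data), ids, ctx)
        totals = [sum(v[i] for v in data.values()) for i in ids]
        scale = rect.h / max(totals)
        for pos, i in enumerate(ids):
            segs = [p for p in prims if p.tags.get("id") == i]
            assert sum(p.h for p in segs) == pytest.approx(totals[pos] * scale, abs=1e-9)


class TestBoxStats:
    def test_hand_computed_five_number_summary(self):
        q1, med, q3, wlo, whi, out = box_stats([1, 2, 3, 4, 5])
        assert (q1, med, q3) == (2.0, 3.0, 4.0)
        assert (wlo, whi) == (1.0, 5.0)
        assert out == []

    def test_constant_samples_zero_height_box(self):
        q1, med, q3, wlo, whi, out = box_stats([7.0] * 5)
        assert q1 == med == q3 == wlo == whi == 7.0
        assert out == []

    def test_extreme_value_is_outlier(self):
        *_, whi, out = box_stats([1, 2, 3, 4, 100])
        assert out == [100.0]
        assert whi == 4.0

    def test_geometry_ordering_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            q1, med, q3, wlo, whi, _ = box_stats(rng.standard_normal(rng.integers(1, 40)))
            assert wlo <= q1 <= med <= q3 <= whi

    def test_empty_input_rejected(self):
        with pytest.raises(SceneMapError):
            box_stats([])


class TestBoxAndScatterTracks:
    def test_scatter_endpoints_reach_track_edges(self):
        rect = Rect(0.0, 0.7, 0.4, 0.2)
        ctx = make_ctx(2, rect=rect)
        track = Track(kind="scatter", name="s", data={"a": 0.0, "b": 5.0})
        prims, _ = render_track(track, ["a", "b"], ctx)
        ys = sorted(p.y for p in prims)
        assert ys[0] == pytest.approx(rect.y)  # inner edge (top side)
        assert ys[1] == pytest.approx(rect.y1)  # outer edge

    def test_constant_box_keeps_visible_median_line(self):
        ctx = make_ctx(1)
        prims, _ = render_track(
            Track(kind="box", name="bx", data={"a": [2.0, 2.0, 2.0]}), ["a"], ctx
        )
        lines = [p for p in prims if p.kind == "line"]
        assert len(lines) == 1
        (x0, _), (x1, _) = lines[0].points
        assert x1 - x0 > 0

    def test_order_permutation_permutes_geometry(self):
        ids = ["a", "b", "c"]
        data = {"a": 1.0, "b": 2.0, "c": 3.0}
        ctx = make_ctx(3)
        fwd, _ = render_track(Track(kind="scatter", name="s", data=data), ids, ctx)
        rev, _ = render_track(Track(kind="scatter", name="s", data=data), ids[::-1], ctx)
        by_id_f = {p.tags["id"]: p.y for p in fwd}
        by_id_r = {p.tags["id"]: p.y for p in rev}
        assert by_id_f == by_id_r  # value axis identical; only x changes

    def test_box_track_stays_in_rect(self):
        rng = np.random.default_rng(2)
        ids = [f"i{k}" for k in range(4)]
        data = {i: list(rng.standard_normal(20)) for i in ids}
        ctx = make_ctx(4, side="left", rect=Rect(0.02, 0.1, 0.08, 0.7))
        prims, _ = render_track(Track(kind="box", name="bx", data=data), ids, ctx)
        assert all(in_rect(p, ctx.rect, tol=1e-6) for p in prims)


class TestLabelTrack:
    def test_merged_runs_rotated_slots(self):
        ctx = make_ctx(5, rect=Rect(0.0, 0.8, 1.0, 0.1))
        track = Track(kind="label", name="lab", merge=True, extend=True, rotation=90,
                      data={"a": "A", "b": "A", "c": "B", "d": "B", "e": "B"})
        prims, _ = render_track(track, list("abcde"), ctx)
        texts = [p for p in prims if p.kind == "text"]
        leaders = [p for p in prims if p.kind == "polyline"]
        assert len(texts) == 2 and len(leaders) == 2
        assert [t.x for t in texts] == [pytest.approx(0.25), pytest.approx(0.75)]
        assert all(t.rotation == 90 for t in texts)

    def test_single_selected_feature_among_many(self):
        n = 50
        ids = [f"r{k}" for k in range(n)]
        data = {i: None for i in ids}
        data["r30"] = "hit"
        ctx = make_ctx(n, rect=Rect(0.0, 0.8, 1.0, 0.1))
        prims, _ = render_track(
            Track(kind="label", name="lab", merge=True, data=data), ids, ctx
        )
        texts = [p for p in prims if p.kind == "text"]
        assert len(texts) == 1
        assert texts[0].x == pytest.approx(0.5)  # single slot is centered

    def test_no_labels_is_empty_not_an_error(self):
        ctx = make_ctx(3)
        prims, legends = render_track(
            Track(kind="label", name="lab", data={"a": None, "b": None, "c": None}),
            ["a", "b", "c"], ctx,
        )
        assert prims == [] and legends == []

    def test_vertical_side_places_labels_along_y(self):
        ctx = make_ctx(4, side="right", rect=Rect(0.85, 0.1, 0.1, 0.8))
        track = Track(kind="label", name="lab", merge=True,
                      data={"a": "u", "b": "u", "c": "w", "d": "w"})
        prims, _ = render_track(track, list("abcd"), ctx)
        texts = [p for p in prims if p.kind == "text"]
        assert len(texts) == 2
        assert all(t.x == pytest.approx(ctx.rect.x1) for t in texts)
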