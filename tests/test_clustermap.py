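"""The full annotated cluster-heatmap assembly."""

import numpy as np
import pytest

from scenemap import (
    ClustermapSpec,
    ColorSpec,
    LabeledMatrix,
    SceneMapError,
    Track,
    annotation_only,
    build_clustermap,
    serialize_scene,
    standardize,
)


def tiny_matrix(values, rows=None, cols=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"r{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return LabeledMatrix(values, rows, cols)


class TestStandardize:
    def test_none_is_identity(self):
        m = tiny_matrix([[1, 2], [3, 4]])
        out, flagged = standardize(m, "none")
        np.testing.assert_array_equal(out.values, m.values)
        assert flagged == []

    def test_row_zscore(self):
        m = tiny_matrix([[1, 2, 3]])
        out, _ = standardize(m, "rows")
        np.testing.assert_allclose(
            out.values[0], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_row_flagged_and_zeroed(self):
        m = tiny_matrix([[5, 5, 5], [1, 2, 3]])
        out, flagged = standardize(m, "rows")
        assert flagged == ["r0"]
        np.testing.assert_array_equal(out.values[0], [0, 0, 0])

    def test_col_mode_and_missing_values(self):
        m = tiny_matrix([[1, np.nan], [3, 4], [5, 6]])
        out, _ = standardize(m, "cols")
        col0 = out.values[:, 0]
        assert col0.mean() == pytest.approx(0.0)
        assert np.isnan(out.values[0, 1])


class TestBuildClustermap:
    def test_bare_two_by_two(self):
        spec = ClustermapSpec(
            matrix=tiny_matrix([[1, 2], [3, 4]]),
            cluster_rows=False, cluster_cols=False,
        )
        model = build_clustermap(spec)
        assert len(model.scene.tagged(cell="1")) == 4
        assert len(model.legends) == 1
        assert model.legends[0].kind == "colorbar"
        assert model.row_order == ["r0", "r1"]
        assert model.col_order == ["c0", "c1"]

    def test_integer_row_split_panel_heights(self):
        # rows are 1-D points 0, 1, 5: tree cut at k=2 gives groups (2, 1)
        spec = ClustermapSpec(
            matrix=tiny_matrix([[0.0], [1.0], [5.0]]),
            row_split=2, cluster_cols=False, method="single",
        )
        model = build_clustermap(spec)
        assert model.row_split.sizes() == [2, 1]
        h0 = model.grid.panels[(0, 0)].h
        h1 = model.grid.panels[(1, 0)].h
        assert h0 / h1 == pytest.approx(2.0)
        assert model.row_order == ["r0", "r1", "r2"]

    def test_categorical_col_split_with_add_text_track(self):
        m = tiny_matrix(np.arange(6.0).reshape(2, 3))
        groups = {"c0": "A", "c1": "A", "c2": "B"}
        spec = ClustermapSpec(
            matrix=m,
            col_split=groups,
            cluster_rows=False, cluster_cols=False,
            top_tracks=[Track(kind="simple", name="grp", data=groups, add_text=True)],
        )
        model = build_clustermap(spec)
        texts = [p for p in model.scene.by_kind("text") if p.tags.get("track") == "grp"]
        assert [t.text for t in texts] == ["A", "B"]
        w_a = model.grid.panels[(0, 0)].w
        w_b = model.grid.panels[(0, 1)].w
        assert w_a / w_b == pytest.approx(2.0)
        # texts centered over their panels
        pa = model.grid.panels[(0, 0)]
        pb = model.grid.panels[(0, 1)]
        assert texts[0].x == pytest.approx(pa.x + pa.w / 2)
        assert texts[1].x == pytest.approx(pb.x + pb.w / 2)

    def test_cell_count_conserved_with_missing_values(self):
        vals = np.arange(20.0).reshape(4, 5)
        vals[1, 2] = np.nan
        spec = ClustermapSpec(matrix=tiny_matrix(vals))
        model = build_clustermap(spec)
        cells = model.scene.tagged(cell="1")
        assert len(cells) == 20
        missing = [c for c in cells if c.tags["row"] == "r1" and c.tags["col"] == "c2"]
        assert missing[0].fill == ColorSpec.continuous().missing_color

    def test_scene_order_matches_col_order(self):
        rng = np.random.default_rng(5)
        spec = ClustermapSpec(matrix=tiny_matrix(rng.standard_normal((5, 6))))
        model = build_clustermap(spec)
        for row_id in model.row_order:
            row_cells = [p for p in model.scene.tagged(cell="1") if p.tags["row"] == row_id]
            row_cells.sort(key=lambda p: p.x)
            assert [p.tags["col"] for p in row_cells] == model.col_order

    def test_build_is_deterministic(self):
        rng = np.random.default_rng(8)
        m = tiny_matrix(rng.standard_normal((6, 4)))
        spec = ClustermapSpec(matrix=m, row_split=2, standardize="rows")
        s1 = serialize_scene(build_clustermap(spec).scene)
        s2 = serialize_scene(build_clustermap(spec).scene)
        assert s1 == s2

    def test_clustering_off_keeps_input_order(self):
        rng = np.random.default_rng(13)
        m = tiny_matrix(rng.standard_normal((5, 4)))
        model = build_clustermap(
            ClustermapSpec(matrix=m, cluster_rows=False, cluster_cols=False)
        )
        assert model.row_order == m.row_ids
        assert model.col_order == m.col_ids

    def test_unknown_annotation_id_is_named(self):
        m = tiny_matrix([[1, 2], [3, 4]])
        spec = ClustermapSpec(
            matrix=m, cluster_rows=False, cluster_cols=False,
            top_tracks=[Track(kind="simple", name="g", data={"c0": "A"})],
        )
        with pytest.raises(SceneMapError, match="c1"):
            build_clustermap(spec)

    def test_dendrograms_drawn_when_clustering(self):
        rng = np.random.default_rng(21)
        m = tiny_matrix(rng.standard_normal((5, 4)))
        model = build_clustermap(ClustermapSpec(matrix=m))
        rows = [p for p in model.scene.primitives if p.tags.get("dendrogram") == "left"]
        cols = [p for p in model.scene.primitives if p.tags.get("dendrogram") == "top"]
        assert len(rows) == 4  # n-1 brackets
        assert len(cols) == 3

    def test_categorical_split_draws_per_group_trees(self):
        rng = np.random.default_rng(22)
        m = tiny_matrix(rng.standard_normal((6, 4)))
        model = build_clustermap(
            ClustermapSpec(matrix=m, row_split=["A", "A", "A", "B", "B", "B"])
        )
        rows = [p for p in model.scene.primitives if p.tags.get("dendrogram") == "left"]
        assert len(rows) == 4  # two 3-leaf trees, 2 brackets each

    def test_track_legend_collected_once_per_spec(self):
        m = tiny_matrix([[1, 2, 3], [4, 5, 6]])
        groups = {"c0": "A", "c1": "B", "c2": "A"}
        shared = ColorSpec.categorical({"A": "#ff0000ff", "B": "#00ff00ff"})
        spec = ClustermapSpec(
            matrix=m, cluster_rows=False, cluster_cols=False,
            top_tracks=[
                Track(kind="simple", name="grp", data=groups, color=shared),
                Track(kind="simple", name="grp", data=groups, color=shared),
            ],
        )
        model = build_clustermap(spec)
        assert sum(1 for l in model.legends if l.title == "grp") == 1


class TestAnnotationOnly:
    def test_simple_track_rects_and_legend(self):
        tracks = [Track(kind="simple", name="g", data={"a": "A", "b": "B", "c": "A"})]
        model = annotation_only(tracks, axis=1, order=["a", "b", "c"])
        assert len(model.scene.by_kind("rect")) == 3
        assert len(model.legends) == 1

    def test_two_tracks_do_not_overlap(self):
        tracks = [
            Track(kind="simple", name="g", data={"a": "A", "b": "B"}),
            Track(kind="bar", name="v", data={"x": {"a": 1.0, "b": 2.0}}),
        ]
        model = annotation_only(tracks, axis=1, order=["a", "b"])
        simple = [p for p in model.scene.by_kind("rect") if p.tags.get("track") == "g"]
        bars = [p for p in model.scene.by_kind("rect") if p.tags.get("track") == "v"]
        top_of_simple = max(p.y + p.h for p in simple)
        bottom_of_bars = min(p.y for p in bars)
        assert bottom_of_bars >= top_of_simple

    def test_label_only_track_emits_no_rects(self):
        tracks = [Track(kind="label", name="lab", merge=True,
                        data={"a": "X", "b": "X", "c": None})]
        model = annotation_only(tracks, axis=1, order=["a", "b", "c"])
        assert model.scene.by_kind("rect") == []
        assert len(model.scene.by_kind("text")) == 1
        assert len(model.scene.by_kind("polyline")) == 1

    def test_empty_track_list_rejected(self):
        with pytest.raises(SceneMapError):
            annotation_only([], axis=1, order=["a"])

    def test_row_axis_mode(self):
        tracks = [Track(kind="simple", name="g", data={"a": "A", "b": "B"})]
        model = annotation_only(tracks, axis=0, order=["a", "b"])
        rects = model.scene.by_kind("rect")
        assert len(rects) == 2
        assert rects[0].y != rects[1].y  # lanes run along y
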