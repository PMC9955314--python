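import numpy as np
import pytest

import tabraster as tr
from tabraster.layout import build_layout, convert_rows


def coverage_map(layout):
    """How many cells claim each pixel (partition => all ones)."""
    cov = np.zeros((layout.height, layout.width), dtype=int)
    for x0, y0, x1, y1 in layout.cells:
        cov[y0:y1, x0:x1] += 1
    return cov


class TestBuildLayout:
    def test_single_feature_full_canvas(self):
        lay = build_layout([0], width=50, height=30)
        assert lay.cells == [(0, 0, 50, 30)]

    def test_two_equal_masses_halves(self):
        lay = build_layout([0, 1], masses=[1.0, 1.0], width=120, height=120)
        assert lay.cells[0] == (0, 0, 60, 120)
        assert lay.cells[1] == (60, 0, 120, 120)
        assert list(lay.areas()) == [7200, 7200]

    def test_eight_features_partition_and_largest(self):
        lay = build_layout(np.arange(8), "rank-based", 120, 120)
        assert np.all(coverage_map(lay) == 1)
        areas = lay.areas()
        assert areas.sum() == 14400
        assert areas[lay.ranking[0]] > areas[lay.ranking[1:]].max()

    @pytest.mark.parametrize("p", range(1, 17))
    def test_partition_order_asymmetry_determinism(self, p):
        """Exhaustive invariants on the 120x120 canvas for p = 1..16."""
        ranking = np.roll(np.arange(p), 1)  # non-trivial permutation
        lay = build_layout(ranking, "rank-based", 120, 120)
        # partition: every pixel covered exactly once
        assert np.all(coverage_map(lay) == 1)
        # area non-increasing along the ranking, up to rounding slack
        areas = lay.areas()[lay.ranking]
        assert np.all(areas[:-1] + 120 >= areas[1:])
        # asymmetric under the horizontal mirror for p >= 2 (the reflection
        # augmentation axis); under both mirrors for p >= 3 — a lone cut
        # spans the canvas, so one mirror axis is unavoidable at p = 2
        cells = set(lay.cells)
        if p >= 2:
            assert lay.mirrored("horizontal") != cells
        if p >= 3:
            assert lay.mirrored("vertical") != cells
        # deterministic
        again = build_layout(ranking, "rank-based", 120, 120)
        assert again.cells == lay.cells

    @pytest.mark.parametrize("seed", range(30))
    def test_area_proportionality_slack(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 17))
        masses = rng.uniform(0.2, 5.0, p)
        w, h = int(rng.integers(p, 130)), int(rng.integers(p, 130))
        lay = build_layout(np.arange(p), masses, w, h)
        exact = w * h * masses / masses.sum()
        assert np.max(np.abs(lay.areas()[lay.ranking] - exact)) <= max(w, h)
        assert np.all(coverage_map(lay) == 1)

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="permutation"):
            build_layout([0, 0, 1])
        with pytest.raises(ValueError, match="positive"):
            build_layout([0, 1], masses=[1.0, 0.0])
        with pytest.raises(ValueError, match="too small"):
            build_layout(np.arange(10), width=5, height=120)

    def test_json_roundtrip(self):
        lay = build_layout(np.arange(5), "rank-based", 60, 40)
        back = tr.CellLayout.from_json(lay.to_json())
        assert back.cells == lay.cells
        assert back.layout_hash() == lay.layout_hash()


class TestRasterize:
    def test_extreme_rows(self):
        lay = build_layout(np.arange(4), "rank-based", 20, 20)
        assert np.all(tr.rasterize(np.ones(4), lay).pixels == 255)
        assert np.all(tr.rasterize(np.zeros(4), lay).pixels == 0)

    def test_half_rounds_up_to_128(self):
        lay = build_layout([0], width=8, height=8)
        img = tr.rasterize([0.5], lay)  # round_half_up(127.5) = 128
        assert np.all(img.pixels == 128)

    def test_row_length_mismatch(self):
        lay = build_layout(np.arange(3), "rank-based", 10, 10)
        with pytest.raises(ValueError, match="cells"):
            tr.rasterize([0.1, 0.2], lay)

    def test_injective_at_one_255th(self):
        """Rows differing by >= 1/255 in a single feature differ as images."""
        lay = build_layout(np.arange(6), "rank-based", 30, 30)
        rng = np.random.default_rng(0)
        row = rng.uniform(0.1, 0.9, 6)
        for j in range(6):
            bumped = row.copy()
            bumped[j] += 1.0 / 255.0
            assert not np.array_equal(
                tr.rasterize(row, lay).pixels, tr.rasterize(bumped, lay).pixels
            )

    def test_cells_are_constant_intensity(self, small_table):
        norm = tr.minmax_normalize(small_table)
        lay = build_layout(np.arange(8), "rank-based", 40, 40)
        img = tr.rasterize(norm.values[5], lay)
        for x0, y0, x1, y1 in lay.cells:
            assert np.unique(img.pixels[y0:y1, x0:x1]).size == 1


class TestConvertDataset:
    def test_counts_manifest_and_determinism(self, small_table, tmp_path):
        norm = tr.minmax_normalize(small_table)
        lay = build_layout(np.arange(8), "rank-based", 40, 40)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        m1 = tr.convert_dataset(norm, lay, out1)
        m2 = tr.convert_dataset(norm, lay, out2)
        assert len(m1) == small_table.n_samples
        assert [e["row_index"] for e in m1] == list(range(len(m1)))
        assert [e["label"] for e in m1] == list(small_table.labels)
        assert all(e["layout_hash"] == lay.layout_hash() for e in m1)
        # byte-identical re-run
        for e1, e2 in zip(m1, m2):
            assert (out1 / e1["file"]).read_bytes() == (
                out2 / e2["file"]
            ).read_bytes()

    def test_single_row_table(self, tmp_path):
        table = tr.FeatureTable(
            np.array([[0.2], [0.8]]), ("f",), [0, 1], bounds={"f": (0.0, 1.0)}
        )
        norm = tr.minmax_normalize(table)
        lay = build_layout([0], width=10, height=10)
        imgs = convert_rows(norm, lay)
        assert len(imgs) == 2
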