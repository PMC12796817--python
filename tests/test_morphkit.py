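"""Connected-region analysis and the six morphometric metrics."""

import numpy as np
import pytest

from segrefine import morphkit, synthkit
from segrefine.morphkit import CellRecord


def _square_records(sides, spacing=20):
    """Synthetic records for identical squares placed on a line."""
    return [
        CellRecord(i + 1, s * s, 4 * s, (i * spacing, 0.0))
        for i, s in enumerate(sides)
    ]


class TestExtractCellRecords:
    def test_five_by_five_square(self):
        mask = np.zeros((9, 9), dtype=np.int32)
        mask[2:7, 2:7] = 1
        (rec,) = morphkit.extract_cell_records(mask)
        assert rec.area_px2 == 25
        assert rec.perimeter_px == 20  # 4s with s=5
        assert rec.centroid == (4.0, 4.0)

    def test_single_pixel_cell(self):
        mask = np.zeros((3, 3), dtype=np.int32)
        mask[1, 1] = 1
        (rec,) = morphkit.extract_cell_records(mask)
        assert (rec.area_px2, rec.perimeter_px) == (1, 4)

    def test_cell_touching_border_counts_border_edges(self):
        mask = np.ones((2, 2), dtype=np.int32)
        (rec,) = morphkit.extract_cell_records(mask)
        assert rec.perimeter_px == 8

    def test_areas_sum_to_foreground(self):
        rng = np.random.default_rng(5)
        mask = rng.integers(0, 6, (64, 64), dtype=np.int32)
        records = morphkit.extract_cell_records(mask)
        assert sum(r.area_px2 for r in records) == (mask > 0).sum()

    def test_empty_mask(self):
        assert morphkit.extract_cell_records(np.zeros((8, 8), int)) == []


class TestSpatialMetrics:
    def test_mean_distance_345_triangle(self):
        # pairwise distances 5, 5, 10 → every nearest neighbour at 5
        recs = [
            CellRecord(1, 10, 10, (0.0, 0.0)),
            CellRecord(2, 10, 10, (3.0, 4.0)),
            CellRecord(3, 10, 10, (6.0, 8.0)),
        ]
        mean_d, compact, density, distrib, flags = morphkit.spatial_metrics(recs, 10000)
        assert mean_d == pytest.approx(5.0)
        assert compact == pytest.approx(25 / 10)
        assert density == pytest.approx(3e-4)
        assert distrib is None and "distribution" in flags

    def test_density_direct(self):
        recs = [CellRecord(i, 4, 8, (float(i * 30), 0.0)) for i in (1, 2, 3)]
        *_, density, _, _ = morphkit.spatial_metrics(recs, 100 * 100)
        assert density == 3 / 10000

    def test_four_corner_symmetry_gives_zero_distribution(self):
        recs = [CellRecord(i + 1, 5, 10, c) for i, c in enumerate(
            [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0)]
        )]
        *_, distrib, flags = morphkit.spatial_metrics(recs, 400)
        assert distrib == pytest.approx(0.0, abs=1e-12)

    def test_minimum_counts_flagged(self):
        one = [CellRecord(1, 5, 10, (2.0, 2.0))]
        mean_d, compact, density, distrib, flags = morphkit.spatial_metrics(one, 100)
        assert mean_d is None and compact is None and distrib is None
        assert density == pytest.approx(0.01)
        assert "mean_distance" in flags and "distribution" in flags

    def test_planted_grid_mean_distance_equals_spacing(self):
        spacing = 12.0
        recs = [
            CellRecord(1 + i * 6 + j, 9, 12, (j * spacing, i * spacing))
            for i in range(6) for j in range(6)
        ]
        mean_d, *_ = morphkit.spatial_metrics(recs, 72 * 72)
        assert mean_d == pytest.approx(spacing, abs=1e-9)


class TestShapeComplexity:
    @pytest.mark.parametrize("sides", [[5, 5, 5], [1], [2, 4]])
    def test_squares_give_sixteen(self, sides):
        # mean(P²)/mean(A) = 16 Σs²·.../Σs² for any mix of squares
        value, flags = morphkit.shape_complexity(_square_records(sides))
        assert value == pytest.approx(16.0)
        assert not flags

    def test_ratio_of_means_not_mean_of_ratios(self):
        # rectangle 1×4 (P=10, A=4) + square 4×4: mean(P²)/mean(A) differs
        recs = [
            CellRecord(1, 4, 10, (0.0, 0.0)),
            CellRecord(2, 16, 16, (20.0, 0.0)),
        ]
        value, _ = morphkit.shape_complexity(recs)
        per_cell_mean = np.mean([10**2 / 4, 16**2 / 16])
        assert value == pytest.approx((100 + 256) / 2 / ((4 + 16) / 2))
        assert value != pytest.approx(per_cell_mean)

    def test_empty(self):
        value, flags = morphkit.shape_complexity([])
        assert value is None and "shape_complexity" in flags


def _brute_force_sobel(image):
    """Oracle: explicit 3×3 Sobel correlation with mirror padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    padded = np.pad(image.astype(float), 1, mode="reflect")
    h, w = image.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + 3, c : c + 3]
            gx[r, c] = (win * kx).sum()
            gy[r, c] = (win * ky).sum()
    return np.hypot(gx, gy)


class TestEdgeContrast:
    def test_uniform_image_undefined(self):
        image = np.full((16, 16), 50, dtype=np.uint8)
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[4:8, 4:8] = 1
        value, flags = morphkit.edge_contrast(image, mask)
        assert value is None and "edge_contrast" in flags

    def test_sharp_cell_on_noisy_background_matches_oracle(self):
        rng = np.random.default_rng(9)
        image = rng.normal(40, 5, (16, 16))
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[5:11, 5:11] = 1
        image[mask == 1] += 120
        value, flags = morphkit.edge_contrast(image, mask)
        assert not flags and value > 1

        grad = _brute_force_sobel(image)
        edge = np.zeros_like(mask, dtype=bool)
        for r in range(16):
            for c in range(16):
                if mask[r, c]:
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 16 and 0 <= cc < 16 and mask[rr, cc] != mask[r, c]:
                            edge[r, c] = True
        from scipy.ndimage import distance_transform_cdt

        bg = (mask == 0) & (distance_transform_cdt(mask == 0, metric="taxicab") > 2)
        assert value == pytest.approx(grad[edge].mean() / grad[bg].mean(), rel=1e-12)

    def test_intensity_scaling_invariance(self):
        rng = np.random.default_rng(10)
        image = rng.normal(60, 8, (24, 24))
        mask = np.zeros((24, 24), dtype=np.int32)
        mask[6:12, 8:14] = 1
        image[mask == 1] += 80
        v1, _ = morphkit.edge_contrast(image, mask)
        v2, _ = morphkit.edge_contrast(image * 3.5, mask)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestMorphoReport:
    def test_single_cell_flags(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        mask[10:15, 10:15] = 1
        report = morphkit.morpho_report(None, mask)
        assert report.n_cells == 1
        assert report.density == pytest.approx(1 / 64**2)
        assert report.shape_complexity == pytest.approx(16.0)
        assert report.mean_distance is None and "mean_distance" in report.flags

    def test_determinism(self, sparse_fixture):
        _, image, mask, _ = sparse_fixture
        one = morphkit.morpho_report(image, mask)
        two = morphkit.morpho_report(image, mask)
        assert one == two

    def test_translation_invariance_for_interior_content(self):
        base = np.zeros((96, 96), dtype=np.int32)
        rng = np.random.default_rng(12)
        image = rng.normal(40, 6, (96, 96))
        for i, (r, c) in enumerate([(20, 20), (20, 50), (50, 20), (50, 55)], start=1):
            base[r : r + 6, c : c + 6] = i
        image[base > 0] += 90
        shifted_mask = np.roll(base, (5, 7), axis=(0, 1))
        shifted_image = np.roll(image, (5, 7), axis=(0, 1))
        a = morphkit.morpho_report(image, base)
        b = morphkit.morpho_report(shifted_image, shifted_mask)
        for attr in ("n_cells", "mean_distance", "compactness", "density",
                     "distribution", "shape_complexity"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-9)

    def test_canvas_doubling_scales_density_only(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        for i, (r, c) in enumerate([(10, 10), (10, 40), (40, 10), (40, 40)], start=1):
            mask[r : r + 5, c : c + 5] = i
        big = np.zeros((128, 128), dtype=np.int32)
        big[:64, :64] = mask
        small_rep = morphkit.morpho_report(None, mask)
        big_rep = morphkit.morpho_report(None, big)
        assert big_rep.density == pytest.approx(small_rep.density / 4)
        assert big_rep.shape_complexity == pytest.approx(small_rep.shape_complexity)
        assert big_rep.mean_distance == pytest.approx(small_rep.mean_distance)

    def test_regime_ordering(self):
        dense = synthkit.regime_params("dense_lowcontrast", n_cells=60, seed=21)
        sparse = synthkit.regime_params("sparse_highcontrast", n_cells=60, seed=21)
        d = morphkit.morpho_report(*synthkit.generate_tissue(dense)[:2])
        s = morphkit.morpho_report(*synthkit.generate_tissue(sparse)[:2])
        assert d.mean_distance < s.mean_distance
        assert d.density > s.density
        assert d.edge_contrast < s.edge_contrast
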