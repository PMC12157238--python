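"""Fruit segmentation stages against brute-force oracles."""

import numpy as np
import pytest

from wolfvision import (
    CameraIntrinsics,
    SceneSpec,
    area_filter,
    binarize,
    compute_histogram,
    fruit_centroids,
    generate_scene,
    morphological_open,
    pixel_to_3d,
    segment_fruits,
    valley_threshold,
)
from wolfvision.fruit_pipeline import GrayHistogram


def hist_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return GrayHistogram(counts=counts, total=int(counts.sum()))


class TestHistogram:
    def test_constant_image(self):
        hist = compute_histogram(np.full((10, 10), 128, dtype=np.uint8))
        assert hist.counts[128] == 100
        assert hist.counts.sum() == 100

    def test_two_level_image(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:5] = 255
        hist = compute_histogram(img)
        assert hist.counts[0] == hist.counts[255] == 50

    def test_conservation(self, rng):
        img = rng.integers(0, 256, size=(37, 53), dtype=np.uint8)
        hist = compute_histogram(img)
        assert hist.counts.sum() == img.size == hist.total


class TestValleyThreshold:
    @staticmethod
    def _bimodal(c1=60, c2=180, valley_bin=None):
        bins = np.arange(256)
        counts = (
            1000 * np.exp(-0.5 * ((bins - c1) / 12.0) ** 2)
            + 600 * np.exp(-0.5 * ((bins - c2) / 12.0) ** 2)
        ).astype(np.int64) + 1
        if valley_bin is not None:
            counts[valley_bin] = 0
        return hist_from_counts(counts)

    def test_unique_zero_valley(self):
        # brute-force scan: the unique zero bin between the modes wins
        result = valley_threshold(self._bimodal(valley_bin=120))
        assert result.method == "valley"
        assert result.threshold == 120

    def test_zero_plateau_midpoint(self):
        counts = np.zeros(256, dtype=np.int64)
        bins = np.arange(256)
        counts += (800 * np.exp(-0.5 * ((bins - 50) / 8.0) ** 2)).astype(np.int64)
        counts += (700 * np.exp(-0.5 * ((bins - 200) / 8.0) ** 2)).astype(np.int64)
        result = valley_threshold(hist_from_counts(counts))
        assert result.method == "valley"
        # exhaustive scan of the raw counts between the two modes
        between = counts[51:200]
        min_bins = np.flatnonzero(between == between.min()) + 51
        assert result.threshold == round((min_bins[0] + min_bins[-1]) / 2)

    def test_unimodal_falls_back(self):
        bins = np.arange(256)
        counts = (1000 * np.exp(-0.5 * ((bins - 128) / 20.0) ** 2)).astype(np.int64)
        result = valley_threshold(hist_from_counts(counts))
        assert result.method == "otsu_fallback"
        assert 0 <= result.threshold <= 255

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            valley_threshold(hist_from_counts(np.zeros(256, dtype=np.int64)))


class TestBinarize:
    def test_constant_image_polarity(self):
        img = np.full((5, 5), 100, dtype=np.uint8)
        assert binarize(img, 99).all()
        assert not binarize(img, 100).any()
        assert not binarize(img, 200).any()

    def test_two_level_split(self):
        img = np.zeros((6, 6), dtype=np.uint8)
        img[:, 3:] = 200
        mask = binarize(img, 100)
        np.testing.assert_array_equal(mask, img == 200)

    def test_dark_foreground_polarity(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[0, 0] = 250
        mask = binarize(img, 100, bright_foreground=False)
        assert mask.sum() == 15 and not mask[0, 0]


class TestMorphologicalOpen:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not morphological_open(mask, 3).any()

    def test_solid_rectangle_preserved(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 4:16] = True
        np.testing.assert_array_equal(morphological_open(mask, 3), mask)

    def test_idempotence(self, rng):
        mask = rng.random((40, 40)) > 0.5
        once = morphological_open(mask, 3)
        np.testing.assert_array_equal(morphological_open(once, 3), once)


class TestAreaFilter:
    @staticmethod
    def _mask_with_blocks(*sizes):
        """Horizontal 2-row blocks of the given pixel areas, well separated."""
        mask = np.zeros((len(sizes) * 10, 200), dtype=bool)
        for i, size in enumerate(sizes):
            cols = size // 2
            mask[i * 10 : i * 10 + 2, 0:cols] = True
        return mask

    def test_small_component_removed(self):
        mask = self._mask_with_blocks(50, 150)
        out = area_filter(mask, min_area=100)
        assert out.sum() == 150

    def test_exact_boundary_survives(self):
        # "fewer than 100 pixels" are removed: exactly 100 stays, 99 goes
        mask = self._mask_with_blocks(100)
        assert area_filter(mask, min_area=100).sum() == 100
        mask99 = np.zeros((10, 200), dtype=bool)
        mask99[0:1, 0:99] = True
        assert area_filter(mask99, min_area=100).sum() == 0

    def test_empty_mask(self):
        mask = np.zeros((5, 5), dtype=bool)
        assert not area_filter(mask).any()

    def test_pipeline_monotonicity(self, rng):
        """Foreground never grows across opening and area filtering."""
        mask = rng.random((60, 60)) > 0.4
        opened = morphological_open(mask, 3)
        filtered = area_filter(opened, min_area=20)
        assert opened.sum() <= mask.sum()
        assert filtered.sum() <= opened.sum()


class TestFruitCentroids:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 2] = True
        (det,) = fruit_centroids(mask)
        assert (det.centroid_x, det.centroid_y) == (2.0, 1.0)

    def test_square_symmetry(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:10, 0:10] = True
        (det,) = fruit_centroids(mask)
        assert (det.centroid_x, det.centroid_y) == (4.5, 4.5)
        assert det.area == 100

    def test_disk_against_brute_force_moment(self):
        yy, xx = np.mgrid[:60, :60]
        mask = (yy - 30) ** 2 + (xx - 20) ** 2 <= 49
        (det,) = fruit_centroids(mask)
        # independent double-loop first moment
        sx = sy = n = 0
        for y in range(60):
            for x in range(60):
                if mask[y, x]:
                    sx += x
                    sy += y
                    n += 1
        assert abs(det.centroid_x - sx / n) < 1e-9
        assert abs(det.centroid_y - sy / n) < 1e-9
        assert abs(det.centroid_x - 20) < 0.1 and abs(det.centroid_y - 30) < 0.1

    def test_centroid_inside_bbox(self, rng):
        mask = rng.random((50, 50)) > 0.6
        for det in fruit_centroids(mask):
            x0, y0, x1, y1 = det.bbox
            assert x0 <= det.centroid_x <= x1
            assert y0 <= det.centroid_y <= y1


class TestPixelTo3d:
    INTR = CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0, cy=240.0, depth_scale=0.001)

    def test_principal_ray(self):
        p = pixel_to_3d(320, 240, 500, self.INTR)
        assert p.valid and (p.X, p.Y) == (0.0, 0.0) and p.Z == 0.5

    def test_zero_depth_flagged_invalid(self):
        assert not pixel_to_3d(100, 100, 0, self.INTR).valid

    def test_unit_tangent(self):
        p = pixel_to_3d(320 + 600, 240, 1000, self.INTR)
        np.testing.assert_allclose((p.X, p.Y, p.Z), (1.0, 0.0, 1.0), atol=1e-12)


class TestSegmentFruits:
    def test_recovers_synthetic_fruits(self, fruit_scene):
        result = segment_fruits(fruit_scene.rgb)
        truth = fruit_scene.truth.fruit_centroids
        assert len(result.detections) == len(truth)
        for tx, ty in truth:
            best = min(
                np.hypot(d.centroid_x - tx, d.centroid_y - ty)
                for d in result.detections
            )
            assert best <= 2.0

    def test_zero_fruit_scene_empty(self):
        scene = generate_scene(SceneSpec(width=64, height=64, n_fruits=0))
        assert segment_fruits(scene.rgb).detections == []

    def test_small_fruit_filtered_out(self):
        spec = SceneSpec(width=96, height=96, n_fruits=1, fruit_radius_range=(4.0, 4.0))
        scene = generate_scene(spec)
        assert scene.truth.fruit_masks[0].sum() < 100
        assert segment_fruits(scene.rgb).detections == []

    def test_3d_attached_when_depth_given(self, fruit_scene):
        intr = CameraIntrinsics(fx=460.0, fy=460.0, cx=160.0, cy=120.0)
        result = segment_fruits(fruit_scene.rgb, fruit_scene.depth, intr)
        for det in result.detections:
            assert det.point3d is not None and det.point3d.valid
            # fruits sit at the 200-300 mm working distance
            assert 0.18 <= det.point3d.Z <= 0.32

    def test_intermediates_retrievable(self, fruit_scene):
        result = segment_fruits(fruit_scene.rgb)
        for key in ("a_channel", "i_channel", "feature", "histogram",
                    "mask_raw", "mask_open", "mask_final"):
            assert key in result.intermediates
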