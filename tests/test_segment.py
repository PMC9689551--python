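"""Segmentation: contour extraction, minimum-area rotated boxes against a
rotation-sweep oracle, upright crop extraction."""

import numpy as np
import pytest

from ricedom.preprocess import PreprocessConfig
from ricedom.segment import (Contour, GrainCrop, OrientedBox, extract_grain,
                             find_grain_contours, min_area_box, segment_image)


def sweep_box_area(points, step_deg=0.1):
    """Brute-force oracle: minimum bounding-rectangle area over a dense
    grid of rotation angles."""
    pts = np.asarray(points, float)
    angles = np.radians(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(angles), np.sin(angles)
    x = pts[:, 0][None, :] * c[:, None] + pts[:, 1][None, :] * s[:, None]
    y = -pts[:, 0][None, :] * s[:, None] + pts[:, 1][None, :] * c[:, None]
    areas = (x.max(1) - x.min(1)) * (y.max(1) - y.min(1))
    return float(areas.min())


class TestFindGrainContours:
    def test_empty_mask_gives_empty_list(self):
        assert find_grain_contours(np.zeros((30, 30), np.uint8)) == []

    def test_one_contour_per_synthetic_grain(self, small_scan, preprocess_cfg):
        from ricedom.preprocess import preprocess_scan

        spec, img, truths = small_scan
        mask = preprocess_scan(img, preprocess_cfg)
        contours = find_grain_contours(mask, min_area_px=200)
        assert len(contours) == len(truths)

    def test_min_area_filters_debris(self):
        mask = np.zeros((60, 60), np.uint8)
        mask[10:30, 10:25] = 1  # grain, 300 px
        mask[50, 50:52] = 1  # 2-px speck
        contours = find_grain_contours(mask, min_area_px=50)
        assert len(contours) == 1
        assert contours[0].area_px == 300

    def test_contour_needs_three_points(self):
        with pytest.raises(ValueError):
            Contour(np.array([[0.0, 0.0], [1.0, 1.0]]), 2)


class TestMinAreaBox:
    def test_axis_aligned_rectangle(self):
        ys, xs = np.mgrid[0:10, 0:20]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        box = min_area_box(pts)
        assert box.long_side == pytest.approx(19.0, abs=1e-6)
        assert box.short_side == pytest.approx(9.0, abs=1e-6)
        assert box.angle_deg % 90.0 == pytest.approx(0.0, abs=1e-6)

    def test_rotated_rectangle_recovers_sides_and_angle(self):
        base = np.array([[x, y] for x in np.linspace(-10, 10, 41)
                         for y in np.linspace(-5, 5, 21)])
        theta = np.radians(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        pts = base @ R.T
        box = min_area_box(pts)
        assert box.long_side == pytest.approx(20.0, abs=1.0)
        assert box.short_side == pytest.approx(10.0, abs=1.0)
        assert (-box.angle_deg) % 90.0 == pytest.approx(30.0, abs=1.0) or \
               (-box.angle_deg) % 90.0 == pytest.approx(60.0, abs=1.0)

    def test_thin_diagonal_line_of_pixels(self):
        pts = np.array([[i + dx, i + dy] for i in range(30)
                        for dx in (0, 1) for dy in (0, 1)], float)
        box = min_area_box(pts)
        assert box.long_side == pytest.approx(30 * np.sqrt(2), rel=0.05)

    def test_collinear_points_rejected(self):
        pts = np.array([[i, 2 * i] for i in range(10)], float)
        with pytest.raises(ValueError):
            min_area_box(pts)

    def test_vertices_form_rectangle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(30, 2)) * 10
            box = min_area_box(pts)
            v = box.vertices
            d = [np.linalg.norm(v[(i + 1) % 4] - v[i]) for i in range(4)]
            assert d[0] == pytest.approx(d[2], abs=0.5)
            assert d[1] == pytest.approx(d[3], abs=0.5)
            e1, e2 = v[1] - v[0], v[2] - v[1]
            cosang = abs(e1 @ e2) / (np.linalg.norm(e1) * np.linalg.norm(e2))
            assert cosang < np.sin(np.radians(0.5))
            assert -90.0 < box.angle_deg <= 0.0

    def test_matches_rotation_sweep_oracle_on_random_point_sets(self, rng):
        """Calipers area within 1% of a 0.1-degree rotation sweep."""
        for _ in range(100):
            pts = rng.normal(size=(int(rng.integers(5, 40)), 2)) * 20
            box = min_area_box(pts)
            oracle = sweep_box_area(pts)
            assert box.area <= oracle * 1.01 + 1e-9
            assert box.area >= oracle * 0.99 - 1e-9

    def test_encloses_every_input_point(self, rng):
        pts = rng.normal(size=(50, 2)) * 15
        poly = min_area_box(pts).as_polygon().buffer(1e-6)
        from shapely.geometry import Point

        assert all(poly.contains(Point(*p)) for p in pts)


class TestExtractGrain:
    def _image_with_box(self, w=200, h=150):
        img = np.zeros((h, w, 3), np.uint8)
        return img

    def test_margin_adds_to_both_sides(self):
        img = np.full((150, 200, 3), 7, np.uint8)
        v = np.array([[90.0, 65.0], [110.0, 65.0], [110.0, 85.0], [90.0, 85.0]])
        box = OrientedBox(v, 0.0, 20.0, 20.0)
        crop = extract_grain(img, box, margin=5)
        assert crop.image.shape[:2] == (30, 30)

    def test_upright_box_dims(self):
        img = np.full((150, 200, 3), 7, np.uint8)
        # axis-aligned 10 wide x 20 tall box at the center
        v = np.array([[95.0, 65.0], [105.0, 65.0], [105.0, 85.0], [95.0, 85.0]])
        box = OrientedBox(v, 0.0, 20.0, 10.0)
        crop = extract_grain(img, box, margin=5)
        assert crop.image.shape[:2] == (30, 20)

    def test_margin_zero_recovers_box_contents(self):
        img = np.zeros((100, 100, 3), np.uint8)
        img[40:60, 45:55] = 200  # 10 wide x 20 tall block
        v = np.array([[45.0, 40.0], [54.0, 40.0], [54.0, 59.0], [45.0, 59.0]])
        box = OrientedBox(v, 0.0, 19.0, 9.0)
        crop = extract_grain(img, box, margin=0)
        assert crop.image.shape[:2] == (19, 9)
        assert (crop.image > 100).all()

    def test_corner_box_clamps_without_error(self):
        img = np.full((100, 100, 3), 7, np.uint8)
        v = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 20.0], [0.0, 20.0]])
        box = OrientedBox(v, 0.0, 20.0, 10.0)
        crop = extract_grain(img, box, margin=5)
        h, w = crop.image.shape[:2]
        assert h <= 30 and w <= 20  # clamped at the image border
        assert h >= 20 and w >= 10

    def test_far_outside_box_rejected(self):
        img = np.zeros((50, 50, 3), np.uint8)
        v = np.array([[500.0, 500.0], [520.0, 500.0], [520.0, 510.0], [500.0, 510.0]])
        box = OrientedBox(v, 0.0, 20.0, 10.0)
        with pytest.raises(ValueError):
            extract_grain(img, box, margin=5)


class TestSegmentImage:
    def test_recovers_grain_count_and_boxes(self, small_scan, preprocess_cfg):
        spec, img, truths = small_scan
        crops = segment_image(img, preprocess_cfg)
        assert len(crops) == len(truths)
        for crop in crops:
            assert max(t.box.iou(crop.box) for t in truths) >= 0.8

    def test_uprightness(self, small_scan, preprocess_cfg):
        _, img, _ = small_scan
        for crop in segment_image(img, preprocess_cfg):
            h, w = crop.image.shape[:2]
            assert h >= w

    def test_crop_centers_map_into_truth_masks(self, small_scan, preprocess_cfg):
        _, img, truths = small_scan
        for crop in segment_image(img, preprocess_cfg):
            cx, cy = crop.box.center
            hit = any(
                t.full_mask(img.shape[:2])[int(round(cy)), int(round(cx))]
                for t in truths
            )
            assert hit

    def test_canny_path_recovers_grain_count(self, small_scan, preprocess_cfg):
        """The optional hysteresis-edge foreground path finds the same
        grains as the default thresholded-mask path."""
        spec, img, truths = small_scan
        crops = segment_image(img, preprocess_cfg, edge_method="canny")
        assert len(crops) == len(truths)
        with pytest.raises(ValueError):
            segment_image(img, preprocess_cfg, edge_method="sobel")

    def test_empty_scan_gives_empty_list(self, preprocess_cfg):
        img = np.full((120, 120, 3), 10, np.uint8)
        assert segment_image(img, preprocess_cfg) == []

    def test_row_major_order(self, small_scan, preprocess_cfg):
        _, img, _ = small_scan
        centers = [tuple(c.box.center) for c in segment_image(img, preprocess_cfg)]
        keys = [(round(cy), round(cx)) for cx, cy in centers]
        assert keys == sorted(keys)
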