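"""Geometry core: box centers, robust 3x3 depth sampling, FOV conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pineloc import (
    BoundingBox,
    CameraModel,
    DepthFrame,
    PixelPoint,
    box_center,
    localize,
    metric_to_pixel,
    pixel_to_metric,
    rescale_box,
    robust_depth,
)


class TestBoxCenter:
    @pytest.mark.parametrize(
        "box, expected",
        [
            ((0, 0, 10, 10), (5, 5)),
            ((7, 3, 0, 0), (7, 3)),  # degenerate box is its own corner
            ((1200, 150, 196, 102), (1298, 201)),
            ((10, 10, 5, 3), (12.5, 11.5)),  # odd extents stay fractional
        ],
    )
    def test_center_arithmetic(self, box, expected):
        c = box_center(BoundingBox(*box))
        assert (c.x, c.y) == expected

    def test_negative_extent_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 0, -1, 5)

    def test_clamping_to_frame(self):
        b = BoundingBox(-10, -5, 30, 20).clamped(100, 50)
        assert (b.x_a, b.y_a, b.w, b.h) == (0, 0, 20, 15)


class TestRobustDepth:
    def _frame_with_block(self, values):
        grid = np.zeros((9, 9))
        grid[3:6, 3:6] = np.asarray(values, dtype=float).reshape(3, 3)
        return DepthFrame(grid)

    def test_uniform_neighborhood(self):
        frame = self._frame_with_block([[255] * 3] * 3)
        assert robust_depth(frame, PixelPoint(4, 4)) == 255.0

    def test_invalid_cells_excluded(self):
        frame = self._frame_with_block([[300, 0, 300], [0, 300, 0], [300, 0, 300]])
        assert robust_depth(frame, PixelPoint(4, 4)) == 300.0

    def test_mean_of_mixed_values(self):
        frame = self._frame_with_block([[250, 250, 250], [250, 260, 250], [250, 250, 250]])
        assert robust_depth(frame, PixelPoint(4, 4)) == pytest.approx((250 * 8 + 260) / 9)

    def test_all_dropout_is_invalid_not_error(self):
        frame = self._frame_with_block([[0] * 3] * 3)
        assert robust_depth(frame, PixelPoint(4, 4)) is None

    def test_threshold_is_strictly_greater_than_one(self):
        frame = self._frame_with_block([[1, 1, 1], [1, 1.5, 1], [1, 1, 1]])
        assert robust_depth(frame, PixelPoint(4, 4)) == 1.5

    def test_point_outside_frame_raises(self):
        frame = DepthFrame.constant(10, 10, 100)
        with pytest.raises(ValueError):
            robust_depth(frame, PixelPoint(20, 5))

    def test_border_cells_treated_as_invalid(self):
        # corner pixel: only the 2x2 in-frame cells can contribute
        grid = np.zeros((5, 5))
        grid[0, 0] = 100.0
        grid[0, 1] = 200.0
        assert robust_depth(DepthFrame(grid), PixelPoint(0, 0)) == 150.0

    def test_fractional_center_rounds_to_nearest(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = 400.0
        frame = DepthFrame(grid)
        # 1.5 rounds away from zero to 2, so the 3x3 around (2, 2) applies
        assert robust_depth(frame, PixelPoint(1.5, 1.5)) == 400.0

    @given(
        st.lists(st.booleans(), min_size=9, max_size=9).filter(any),
        st.integers(min_value=2, max_value=10000),
    )
    def test_constant_plane_exact_under_any_dropout(self, keep, depth):
        """Mean of identical survivors equals the plane depth exactly
        (depth cameras report integer millimetres)."""
        depth = float(depth)
        cells = np.where(np.asarray(keep).reshape(3, 3), depth, 0.0)
        grid = np.zeros((5, 5))
        grid[1:4, 1:4] = cells
        assert robust_depth(DepthFrame(grid), PixelPoint(2, 2)) == depth


class TestPixelToMetric:
    def test_reference_point_maps_to_origin(self, cam):
        p = pixel_to_metric(cam.frame_center, cam.frame_center, 421.0, cam)
        assert p.dx == 0.0 and p.dy == 0.0 and p.dz == 421.0

    def test_bias_correction_is_subtraction(self, cam):
        p = pixel_to_metric(PixelPoint(100, 100), cam.frame_center, 500.0, cam)
        assert p.dz_corrected == 494.0

    def test_invalid_depth_rejected(self, cam):
        with pytest.raises(ValueError):
            pixel_to_metric(PixelPoint(0, 0), cam.frame_center, 1.0, cam)

    @pytest.mark.parametrize("sx, sy", [(1, -1), (-1, 1), (1, 1), (-1, -1)])
    def test_quadrant_sign_convention(self, cam, sx, sy):
        """Right of center dx > 0; above center dy < 0 (image rows grow down)."""
        p = pixel_to_metric(
            PixelPoint(960 + 100 * sx, 540 + 100 * sy), cam.frame_center, 500.0, cam
        )
        assert math.copysign(1, p.dx) == sx
        assert math.copysign(1, p.dy) == sy

    @given(
        st.floats(min_value=-400, max_value=400),
        st.floats(min_value=-300, max_value=300),
        st.floats(min_value=200, max_value=10000),
    )
    def test_round_trip_through_inverse_projection(self, dx, dy, dz):
        """Inverse projection then forward conversion recovers metric offsets."""
        cam = CameraModel()
        pix = metric_to_pixel(dx, dy, dz, cam)
        p = pixel_to_metric(pix, cam.frame_center, dz, cam)
        assert abs(p.dx - dx) < 1e-9
        assert abs(p.dy - dy) < 1e-9

    @given(
        st.floats(min_value=-900, max_value=900),
        st.floats(min_value=200, max_value=4000),
    )
    def test_linearity_in_offset_and_depth(self, off, dz):
        cam = CameraModel()
        ref = cam.frame_center
        p1 = pixel_to_metric(PixelPoint(ref.x + off, ref.y + off / 2), ref, dz, cam)
        p2 = pixel_to_metric(PixelPoint(ref.x + off, ref.y + off / 2), ref, 2 * dz, cam)
        assert p2.dx == pytest.approx(2 * p1.dx, abs=1e-9)
        assert p2.dy == pytest.approx(2 * p1.dy, abs=1e-9)


class TestLocalize:
    def test_composition_on_uniform_plane(self, cam):
        frame = DepthFrame.constant(1920, 1080, 255)
        res = localize(BoundingBox(1200, 150, 196, 102), frame, cam)
        assert res.ok and res.num_valid == 9
        assert res.point.dx == pytest.approx(56.10, abs=0.02)
        assert res.point.dy == pytest.approx(-59.85, abs=0.02)
        assert res.point.dz == 255.0

    def test_frame_center_box(self, cam):
        frame = DepthFrame.constant(1920, 1080, 700)
        res = localize(BoundingBox(960 - 40, 540 - 40, 80, 80), frame, cam)
        assert res.point.dx == 0.0 and res.point.dy == 0.0 and res.point.dz == 700.0

    def test_dropout_region_fails_gracefully(self, cam):
        grid = np.full((1080, 1920), 500.0)
        grid[500:580, 900:1020] = 0.0
        res = localize(BoundingBox(940, 520, 40, 40), DepthFrame(grid), cam)
        assert not res.ok and res.point is None
        assert (res.center.x, res.center.y) == (960, 540)


class TestRescaleBox:
    def test_network_to_depth_resolution(self):
        b = rescale_box(BoundingBox(112, 112, 224, 224), (448, 448), (1920, 1080))
        assert (b.x_a, b.y_a) == (480, 270)
        assert (b.w, b.h) == (960, 540)

    @given(
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=0, max_value=148),
        st.floats(min_value=0, max_value=148),
    )
    def test_rescale_round_trip(self, xa, ya, w, h):
        b = BoundingBox(xa, ya, w, h)
        back = rescale_box(rescale_box(b, (448, 448), (1920, 1080)), (1920, 1080), (448, 448))
        assert back.x_a == pytest.approx(b.x_a, abs=1e-9)
        assert back.w == pytest.approx(b.w, abs=1e-9)
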