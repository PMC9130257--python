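"""Pinhole-free FOV camera geometry: bounding-box centers, robust depth
sampling, and pixel-to-metric conversion.

The depth camera is modelled purely by its horizontal/vertical field of
view and pixel resolution; no focal length or lens-distortion terms are
used.  A detection's metric offset from a reference pixel (normally the
frame center) is

    D_x = tan(H/2) * D_z * 2 / m * (x_b - x_1)
    D_y = tan(V/2) * D_z * 2 / n * (y_b - y_1)

where ``(x_b, y_b)`` is the bounding-box center, ``(x_1, y_1)`` the
reference pixel, ``m``/``n`` the frame width/height in pixels and ``D_z``
the range along the optical axis in millimetres.  Signs follow image
coordinates: D_x > 0 right of the reference, D_y > 0 below it (so the
upper-right image corner has D_x > 0, D_y < 0).

Range values come from a depth frame in millimetres where any value of
at most 1 mm marks a failed measurement (dropout under strong lighting).
The depth at a point is the mean of the *valid* values in the 3x3
neighborhood around it; when no neighbor is valid the point cannot be
localized.  Depth cameras of this type run a few millimetres long versus
a laser rangefinder, so a constant bias (default 6 mm) is subtracted to
form a corrected range alongside the raw one; the raw range is what
enters the D_x/D_y conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CameraModel",
    "BoundingBox",
    "PixelPoint",
    "DepthFrame",
    "Point3D",
    "LocalizationResult",
    "INVALID_DEPTH_MM",
    "box_center",
    "robust_depth",
    "pixel_to_metric",
    "metric_to_pixel",
    "localize",
    "rescale_box",
]

#: depth values less than or equal to this many millimetres are invalid
INVALID_DEPTH_MM = 1.0


@dataclass(frozen=True)
class CameraModel:
    """FOV/resolution description of the RGB-D camera.

    Defaults match an Intel RealSense D435i-class device: 64 degree
    horizontal and 41 degree vertical field of view at 1920x1080, with a
    6 mm systematic range bias relative to a laser rangefinder.
    """

    fov_h_deg: float = 64.0
    fov_v_deg: float = 41.0
    width_px: int = 1920
    height_px: int = 1080
    z_bias_mm: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fov_h_deg < 180.0):
            raise ValueError(f"fov_h_deg must be in (0, 180), got {self.fov_h_deg}")
        if not (0.0 < self.fov_v_deg < 180.0):
            raise ValueError(f"fov_v_deg must be in (0, 180), got {self.fov_v_deg}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("resolution must be positive")
        if not math.isfinite(self.z_bias_mm):
            raise ValueError("z_bias_mm must be finite")

    @property
    def frame_center(self) -> "PixelPoint":
        """Default reference pixel (m/2, n/2)."""
        return PixelPoint(self.width_px / 2.0, self.height_px / 2.0)

    # mm of lateral extent per pixel per mm of range, along each axis
    @property
    def x_scale(self) -> float:
        return math.tan(math.radians(self.fov_h_deg) / 2.0) * 2.0 / self.width_px

    @property
    def y_scale(self) -> float:
        return math.tan(math.radians(self.fov_v_deg) / 2.0) * 2.0 / self.height_px


@dataclass(frozen=True)
class PixelPoint:
    """A (column, row) image location; fractional values are allowed."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"pixel coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detection rectangle anchored at its upper-left corner."""

    x_a: float
    y_a: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError(f"box extents must be nonnegative, got w={self.w}, h={self.h}")

    @property
    def center(self) -> PixelPoint:
        return box_center(self)

    def clamped(self, width: int, height: int) -> "BoundingBox":
        """Intersect the box with a ``width`` x ``height`` frame."""
        x0 = min(max(self.x_a, 0.0), float(width))
        y0 = min(max(self.y_a, 0.0), float(height))
        x1 = min(max(self.x_a + self.w, 0.0), float(width))
        y1 = min(max(self.y_a + self.h, 0.0), float(height))
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)


class DepthFrame:
    """Per-pixel range image in millimetres.

    Values <= 1 mm (conventionally 0) mark failed measurements.
    """

    def __init__(self, depth_mm: np.ndarray):
        arr = np.asarray(depth_mm, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"depth grid must be 2-D, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("depth values must be nonnegative")
        self.depth_mm = arr

    @property
    def height(self) -> int:
        return self.depth_mm.shape[0]

    @property
    def width(self) -> int:
        return self.depth_mm.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.depth_mm > INVALID_DEPTH_MM

    @classmethod
    def constant(cls, width: int, height: int, depth_mm: float) -> "DepthFrame":
        return cls(np.full((height, width), float(depth_mm)))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DepthFrame) and np.array_equal(self.depth_mm, other.depth_mm)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DepthFrame({self.width}x{self.height})"


@dataclass(frozen=True)
class Point3D:
    """Metric camera-frame offsets in millimetres.

    ``dx`` is positive to the right of the reference pixel, ``dy``
    positive below it, ``dz`` the raw range along the optical axis and
    ``dz_corrected`` the bias-subtracted range.
    """

    dx: float
    dy: float
    dz: float
    dz_corrected: float


@dataclass(frozen=True)
class LocalizationResult:
    """Outcome of localizing a bounding box against a depth frame.

    ``point`` is ``None`` when every pixel of the sampling neighborhood
    was invalid (total depth dropout); ``center`` always carries the
    pixel center that was sampled.
    """

    center: PixelPoint
    point: Optional[Point3D]
    num_valid: int = 0

    @property
    def ok(self) -> bool:
        return self.point is not None


def box_center(box: BoundingBox) -> PixelPoint:
    """Center (x_a + w/2, y_a + h/2) of a detection box.

    Fractional centers (odd extents) are preserved, not rounded.
    """
    return PixelPoint(box.x_a + box.w / 2.0, box.y_a + box.h / 2.0)


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else int(math.ceil(v - 0.5))


def robust_depth(frame: DepthFrame, p: PixelPoint) -> Optional[float]:
    """Mean of the valid (> 1 mm) depths in the 3x3 block around ``p``.

    ``p`` is rounded to the nearest pixel (ties away from zero) first.
    Neighborhood cells falling outside the frame are treated as invalid
    and excluded, like dropout pixels.  Returns ``None`` when no cell in
    the neighborhood holds a valid measurement.

    Raises ``ValueError`` if ``p`` itself lies outside the frame.
    """
    col = _round_half_away(p.x)
    row = _round_half_away(p.y)
    if not (0 <= col < frame.width and 0 <= row < frame.height):
        raise ValueError(
            f"point ({p.x}, {p.y}) outside {frame.width}x{frame.height} frame"
        )
    r0, r1 = max(row - 1, 0), min(row + 2, frame.height)
    c0, c1 = max(col - 1, 0), min(col + 2, frame.width)
    block = frame.depth_mm[r0:r1, c0:c1]
    valid = block[block > INVALID_DEPTH_MM]
    if valid.size == 0:
        return None
    return float(valid.mean())


def pixel_to_metric(
    p: PixelPoint,
    ref: PixelPoint,
    dz: float,
    cam: CameraModel,
) -> Point3D:
    """Convert a pixel offset from ``ref`` at range ``dz`` into millimetres.

    ``dz`` must be a valid range (> 1 mm).  The raw range drives the
    lateral conversion; ``dz_corrected = dz - z_bias_mm`` is reported
    alongside.
    """
    if not (dz > INVALID_DEPTH_MM):
        raise ValueError(f"dz must exceed {INVALID_DEPTH_MM} mm, got {dz}")
    dx = cam.x_scale * dz * (p.x - ref.x)
    dy = cam.y_scale * dz * (p.y - ref.y)
    return Point3D(dx=dx, dy=dy, dz=float(dz), dz_corrected=float(dz) - cam.z_bias_mm)


def metric_to_pixel(dx: float, dy: float, dz: float, cam: CameraModel,
                    ref: Optional[PixelPoint] = None) -> PixelPoint:
    """Inverse of :func:`pixel_to_metric`: metric offsets back to a pixel.

    Used as the projection oracle for synthetic scenes:
    ``x_b = x_1 + dx * m / (2 * dz * tan(H/2))`` and the vertical analog.
    """
    if not (dz > INVALID_DEPTH_MM):
        raise ValueError(f"dz must exceed {INVALID_DEPTH_MM} mm, got {dz}")
    if ref is None:
        ref = cam.frame_center
    return PixelPoint(ref.x + dx / (cam.x_scale * dz), ref.y + dy / (cam.y_scale * dz))


def localize(
    box: BoundingBox,
    frame: DepthFrame,
    cam: Optional[CameraModel] = None,
    ref: Optional[PixelPoint] = None,
) -> LocalizationResult:
    """Full pipeline: box center -> robust depth -> metric conversion.

    ``ref`` defaults to the frame center (m/2, n/2).  When the sampling
    neighborhood holds no valid depth, the result carries the pixel
    center with ``point=None`` rather than raising.
    """
    if cam is None:
        cam = CameraModel()
    if ref is None:
        ref = cam.frame_center
    center = box_center(box)
    dz = robust_depth(frame, center)
    if dz is None:
        return LocalizationResult(center=center, point=None, num_valid=0)
    col = _round_half_away(center.x)
    row = _round_half_away(center.y)
    r0, r1 = max(row - 1, 0), min(row + 2, frame.height)
    c0, c1 = max(col - 1, 0), min(col + 2, frame.width)
    num = int(np.count_nonzero(frame.depth_mm[r0:r1, c0:c1] > INVALID_DEPTH_MM))
    return LocalizationResult(center=center, point=pixel_to_metric(center, ref, dz, cam),
                              num_valid=num)


def rescale_box(
    box: BoundingBox,
    source_resolution: tuple[int, int],
    target_resolution: tuple[int, int],
) -> BoundingBox:
    """Map a box between resolutions by independent x/y linear factors.

    Detections are typically produced at the network input size
    (448x448) while depth frames are 1920x1080; this is the single place
    where the two coordinate systems are reconciled.
    """
    sw, sh = source_resolution
    tw, th = target_resolution
    if sw <= 0 or sh <= 0 or tw <= 0 or th <= 0:
        raise ValueError("resolutions must be positive")
    fx, fy = tw / sw, th / sh
    return BoundingBox(box.x_a * fx, box.y_a * fy, box.w * fx, box.h * fy)
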