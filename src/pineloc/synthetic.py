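"""Synthetic scenes with exact ground truth.

No public image database exists for this pipeline, so everything is
exercised on generated data:

* checkerboard range targets -- a flat board of known cell size (21 mm
  in the reference protocol) at a known distance, with every cell
  intersection's pixel position computed by the *inverse* projection, so
  the intersections form an exact oracle for the forward conversion;
* depth-noise injection emulating the camera's stated failure modes:
  dropout (measurement failure under strong lighting, value 0), a small
  positive systematic range bias, and optional zero-mean jitter;
* fruit mock-ups -- class-colored ellipses on a soil background with
  tight ground-truth boxes, deliberately parametric rather than
  photorealistic: they test the pipeline, not a CNN.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .camera import (
    CameraModel,
    DepthFrame,
    BoundingBox,
    PixelPoint,
    Point3D,
    metric_to_pixel,
)
from .detection import CLASS_ANCHOR_COLORS, CLASS_LABELS

__all__ = [
    "CheckerboardSpec",
    "CheckerboardScene",
    "NoiseSpec",
    "FruitSpec",
    "FruitSceneSpec",
    "FruitScene",
    "make_checkerboard_scene",
    "apply_depth_noise",
    "make_fruit_scene",
    "random_fruit_scene_spec",
    "BACKGROUND_COLOR",
]

#: soil-brown background, far from every class anchor color
BACKGROUND_COLOR = (110, 85, 60)


@dataclass(frozen=True)
class CheckerboardSpec:
    """A flat checkerboard facing the camera at a known distance.

    ``board_cells`` counts (columns, rows) of cells; intersections are
    the interior corners plus the outer ones, indexed from the board
    center.  ``center_pixel`` pins the board-center intersection; it
    defaults to the frame center.
    """

    distance_mm: float
    cell_mm: float = 21.0
    board_cells: tuple[int, int] = (8, 8)
    center_pixel: Optional[PixelPoint] = None

    def __post_init__(self) -> None:
        if self.cell_mm <= 0:
            raise ValueError("cell_mm must be positive")
        # camera working range: 20 cm to 10 m
        if not (200.0 <= self.distance_mm <= 10000.0):
            raise ValueError(
                f"distance_mm {self.distance_mm} outside the 200-10000 mm working range"
            )
        if self.board_cells[0] <= 0 or self.board_cells[1] <= 0:
            raise ValueError("board_cells must be positive")


@dataclass(frozen=True)
class Intersection:
    """Ground-truth pairing of a board intersection's pixel and metric
    coordinates."""

    pixel: PixelPoint
    point: Point3D
    cell_index: tuple[int, int]


@dataclass(frozen=True)
class CheckerboardScene:
    depth: DepthFrame
    image: np.ndarray  # HxW uint8 intensity
    intersections: tuple[Intersection, ...]
    spec: CheckerboardSpec
    reference: PixelPoint


def make_checkerboard_scene(
    spec: CheckerboardSpec, cam: Optional[CameraModel] = None
) -> CheckerboardScene:
    """Render a constant-depth plane plus checkerboard intensity image.

    Intersection pixel coordinates come from the closed-form inverse
    projection, so ``localize`` / ``pixel_to_metric`` at any listed
    intersection must reproduce its stored metric point (up to the
    half-pixel quantization of the depth sampling).
    """
    if cam is None:
        cam = CameraModel()
    ref = spec.center_pixel if spec.center_pixel is not None else cam.frame_center
    dz = spec.distance_mm
    ncx, ncy = spec.board_cells
    half_x = ncx / 2.0 * spec.cell_mm
    half_y = ncy / 2.0 * spec.cell_mm
    for corner_dx, corner_dy in ((half_x, half_y), (-half_x, -half_y)):
        p = metric_to_pixel(corner_dx, corner_dy, dz, cam, ref)
        if not (0 <= p.x < cam.width_px and 0 <= p.y < cam.height_px):
            raise ValueError(
                f"board ({ncx}x{ncy} cells of {spec.cell_mm} mm) does not fit in the "
                f"frame at {dz} mm"
            )

    depth = DepthFrame.constant(cam.width_px, cam.height_px, dz)

    # intensity image: alternate cells in metric board coordinates
    cols = np.arange(cam.width_px) + 0.5
    rows = np.arange(cam.height_px) + 0.5
    mm_x = (cols - ref.x) * cam.x_scale * dz
    mm_y = (rows - ref.y) * cam.y_scale * dz
    cell_i = np.floor(mm_x[None, :] / spec.cell_mm)
    cell_j = np.floor(mm_y[:, None] / spec.cell_mm)
    checker = ((cell_i + cell_j) % 2 == 0)
    on_board = (
        (np.abs(mm_x[None, :]) <= half_x) & (np.abs(mm_y[:, None]) <= half_y)
    )
    image = np.where(on_board & checker, 255, np.where(on_board, 0, 128)).astype(np.uint8)

    intersections = []
    for j in range(-(ncy // 2), ncy // 2 + 1):
        for i in range(-(ncx // 2), ncx // 2 + 1):
            dx = i * spec.cell_mm
            dy = j * spec.cell_mm
            pixel = metric_to_pixel(dx, dy, dz, cam, ref)
            if not (1 <= pixel.x < cam.width_px - 1 and 1 <= pixel.y < cam.height_px - 1):
                continue
            intersections.append(
                Intersection(
                    pixel=pixel,
                    point=Point3D(dx, dy, dz, dz - cam.z_bias_mm),
                    cell_index=(i, j),
                )
            )
    return CheckerboardScene(
        depth=depth,
        image=image,
        intersections=tuple(intersections),
        spec=spec,
        reference=ref,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Depth-camera failure modes to inject.

    ``dropout_fraction`` is the probability a pixel fails (set to 0);
    ``z_bias_mm`` is added to every surviving pixel, emulating the
    systematic overestimate versus a laser rangefinder; ``jitter_sd_mm``
    adds zero-mean Gaussian noise.
    """

    dropout_fraction: float = 0.0
    jitter_sd_mm: float = 0.0
    z_bias_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ValueError("dropout_fraction must be in [0, 1]")
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter_sd_mm must be nonnegative")


def apply_depth_noise(frame: DepthFrame, spec: NoiseSpec) -> DepthFrame:
    """Seeded, reproducible noise injection; the input frame is untouched."""
    rng = np.random.default_rng(spec.seed)
    depth = frame.depth_mm.copy()
    valid = frame.valid_mask
    depth[valid] += spec.z_bias_mm
    if spec.jitter_sd_mm > 0:
        depth[valid] += rng.normal(0.0, spec.jitter_sd_mm, size=int(valid.sum()))
    if spec.dropout_fraction > 0:
        drop = rng.random(depth.shape) < spec.dropout_fraction
        depth[drop] = 0.0
    return DepthFrame(np.clip(depth, 0.0, None))


@dataclass(frozen=True)
class FruitSpec:
    """One fruit: class label, ellipse center (px), ellipse radii (px),
    and its range from the camera."""

    cls: str
    center: tuple[float, float]
    radii: tuple[float, float] = (60.0, 80.0)
    distance_mm: float = 500.0

    def __post_init__(self) -> None:
        if self.cls not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.cls!r}")
        if min(self.radii) <= 0:
            raise ValueError("radii must be positive")


@dataclass(frozen=True)
class FruitSceneSpec:
    """At most two fruit per frame (the acquisition constraint of the
    reference system: a single station never images more)."""

    fruits: tuple[FruitSpec, ...]
    width: int = 448
    height: int = 448
    background_mm: float = 1500.0
    color_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fruits) > 2:
            raise ValueError("no more than two fruit per frame")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame size must be positive")


@dataclass(frozen=True)
class FruitScene:
    image: np.ndarray  # HxWx3 uint8
    depth: DepthFrame
    boxes: tuple[BoundingBox, ...]
    classes: tuple[str, ...]
    spec: FruitSceneSpec


def _fruit_color_field(cls: str, mask: np.ndarray) -> np.ndarray:
    """Per-pixel RGB for one fruit mask.

    Ripening fruit grades from yellow at the bottom to green at the top
    (yellowing proceeds bottom-up); the other classes are uniform.
    """
    h, w = mask.shape
    out = np.zeros((h, w, 3), dtype=float)
    anchors = CLASS_ANCHOR_COLORS[cls]
    if cls == "ripening":
        rows = np.nonzero(mask.any(axis=1))[0]
        top, bottom = rows.min(), rows.max()
        span = max(bottom - top, 1)
        yellow = np.asarray(anchors[0], dtype=float)
        green = np.asarray(anchors[-1], dtype=float)
        t = (np.arange(h) - top) / span  # 0 at top (green) .. 1 at bottom (yellow)
        t = np.clip(t, 0.0, 1.0)
        grad = green[None, :] * (1 - t[:, None]) + yellow[None, :] * t[:, None]
        out[:] = grad[:, None, :]
    else:
        out[:] = np.asarray(anchors[0], dtype=float)
    return out


def make_fruit_scene(spec: FruitSceneSpec) -> FruitScene:
    """Render class-colored elliptical fruit over a soil background.

    Each fruit gets a tight bounding box around its rendered pixels;
    fruit pixels carry the fruit's range and the background a farther
    constant plane.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = np.empty((h, w, 3), dtype=float)
    image[:] = BACKGROUND_COLOR
    depth = np.full((h, w), float(spec.background_mm))
    yy, xx = np.mgrid[0:h, 0:w]

    boxes: list[BoundingBox] = []
    classes: list[str] = []
    for fruit in spec.fruits:
        cx, cy = fruit.center
        rx, ry = fruit.radii
        mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        if not mask.any():
            raise ValueError(f"fruit at {fruit.center} renders no pixels")
        image[mask] = _fruit_color_field(fruit.cls, mask)[mask]
        depth[mask] = fruit.distance_mm
        rows = np.nonzero(mask.any(axis=1))[0]
        cols = np.nonzero(mask.any(axis=0))[0]
        boxes.append(
            BoundingBox(
                float(cols.min()),
                float(rows.min()),
                float(cols.max() - cols.min() + 1),
                float(rows.max() - rows.min() + 1),
            )
        )
        classes.append(fruit.cls)

    if spec.color_noise_sd > 0:
        image += rng.normal(0.0, spec.color_noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return FruitScene(
        image=image,
        depth=DepthFrame(depth),
        boxes=tuple(boxes),
        classes=tuple(classes),
        spec=spec,
    )


def random_fruit_scene_spec(
    seed: int,
    width: int = 448,
    height: int = 448,
) -> FruitSceneSpec:
    """A randomized one- or two-fruit scene spec, pure in ``seed``."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 3))
    fruits = []
    # split the frame into left/right halves so two fruit never overlap
    for k in range(n):
        lo = k * width / 2.0 if n == 2 else 0.0
        hi = (k + 1) * width / 2.0 if n == 2 else float(width)
        rx = float(rng.uniform(25, min(45, (hi - lo) / 2 - 10)))
        ry = float(rng.uniform(30, 60))
        cx = float(rng.uniform(lo + rx + 5, hi - rx - 5))
        cy = float(rng.uniform(ry + 5, height - ry - 5))
        cls = str(rng.choice(CLASS_LABELS))
        dist = float(rng.integers(300, 801))  # integer mm, 16-bit codec friendly
        fruits.append(FruitSpec(cls=cls, center=(cx, cy), radii=(rx, ry), distance_mm=dist))
    return FruitSceneSpec(fruits=tuple(fruits), width=width, height=height, seed=seed)
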