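"""Fruit maturity taxonomy and the detector contract.

The production detector slot is a single-shot CNN (YOLO-style) trained
on a private field database; that network is *not* part of this package.
What lives here instead is:

* the four-class maturity taxonomy (bag / ripe / ripening / unripe) with
  BBCH growth-stage annotations and the harvestability rule,
* :class:`DetectorConfig`, interoperability metadata echoing the
  production network settings (input size, anchor boxes, object cap),
* :func:`detect_baseline`, a color-blob detector good enough to exercise
  the downstream pipeline on synthetic scenes,
* :func:`load_detections` / :func:`save_detections` for the normalized
  ``class cx cy w h [conf]`` text dialect that external detectors emit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .camera import BoundingBox, rescale_box

__all__ = [
    "MaturityClass",
    "BAG",
    "RIPE",
    "RIPENING",
    "UNRIPE",
    "CLASS_LABELS",
    "CLASSES",
    "CLASS_INDEX",
    "Detection",
    "DetectorConfig",
    "Harvestability",
    "detect_baseline",
    "classify_harvestability",
    "load_detections",
    "save_detections",
    "CLASS_ANCHOR_COLORS",
]


@dataclass(frozen=True)
class MaturityClass:
    """One maturity label with its BBCH growth-stage annotation.

    ``harvestable`` is ``True`` for pickable fruit (ripe, ripening),
    ``False`` for unripe, and ``None`` for bagged fruit, whose maturity
    cannot be judged from the image.

    The BBCH annotation is free text: the source mapping between codes
    and labels is internally inconsistent (stage 709 is described both
    as final fruit development and listed against the unripe row), so
    both readings are recorded without adjudication.
    """

    label: str
    bbch: str
    harvestable: Optional[bool]


BAG = MaturityClass("bag", "not in BBCH fruit scale; bagged against sun exposure", None)
RIPE = MaturityClass("ripe", "stage 8 (ripe; also annotated 'still green' / 709 in source table)", True)
RIPENING = MaturityClass("ripening", "stages 801-809, gradually yellowing bottom to top", True)
UNRIPE = MaturityClass("unripe", "immature; source table lists stage 709 here as well", False)

CLASSES: tuple[MaturityClass, ...] = (BAG, RIPE, RIPENING, UNRIPE)
CLASS_LABELS: tuple[str, ...] = tuple(c.label for c in CLASSES)
#: index order of the text dialect: 0=bag, 1=ripe, 2=ripening, 3=unripe
CLASS_INDEX: dict[str, int] = {c.label: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class Detection:
    """One detector output: a box, a maturity class and a confidence."""

    box: BoundingBox
    cls: MaturityClass
    confidence: float
    source_resolution: tuple[int, int] = (448, 448)

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        w, h = self.source_resolution
        b = self.box
        if b.x_a < -1e-9 or b.y_a < -1e-9 or b.x_a + b.w > w + 1e-9 or b.y_a + b.h > h + 1e-9:
            raise ValueError(f"box {b} exceeds source resolution {self.source_resolution}")


@dataclass(frozen=True)
class DetectorConfig:
    """Production-network metadata kept for interoperability.

    Stored verbatim; nothing here is executed.  ``max_objects`` reflects
    the acquisition constraint that no frame ever holds more than two
    fruit.
    """

    input_size: tuple[int, int, int] = (448, 448, 3)
    anchor_boxes: tuple[tuple[int, int], ...] = ((344, 338), (108, 115), (223, 290), (238, 167))
    max_objects: int = 2


# Anchor colors of the synthetic palette, RGB 0-255.  The baseline
# detector votes each pixel to its nearest anchor; ripening gets three
# anchors because its rendering grades from yellow (bottom) to green
# (top).
CLASS_ANCHOR_COLORS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "bag": ((205, 185, 150),),
    "ripe": ((175, 220, 150),),
    "ripening": ((225, 205, 40), (140, 170, 40), (60, 140, 40)),
    "unripe": ((20, 90, 30),),
}
#: a pixel farther than this (RGB Euclidean) from every anchor is background
_ANCHOR_RADIUS = 60.0


def _pixel_votes(image: np.ndarray) -> np.ndarray:
    """Per-pixel class vote: index into CLASSES, or -1 for background."""
    flat = image.reshape(-1, 3).astype(float)
    anchors = []
    owner = []
    for lbl, colors in CLASS_ANCHOR_COLORS.items():
        for c in colors:
            anchors.append(c)
            owner.append(CLASS_INDEX[lbl])
    anchors_arr = np.asarray(anchors, dtype=float)  # (A, 3)
    d2 = ((flat[:, None, :] - anchors_arr[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    votes = np.asarray(owner)[best]
    votes[np.sqrt(d2[np.arange(len(flat)), best]) > _ANCHOR_RADIUS] = -1
    return votes.reshape(image.shape[:2])


def detect_baseline(
    image: np.ndarray,
    min_area_px: int = 200,
    max_objects: int = 2,
) -> list[Detection]:
    """Color-blob stand-in detector for synthetic scenes.

    Pixels are voted to the nearest class anchor color, connected
    non-background components are extracted, components below
    ``min_area_px`` are dropped, and the largest ``max_objects``
    components are returned with tight boxes.  The class is the majority
    pixel vote within the component and the confidence is the fraction
    of component pixels agreeing with it.

    An image with no fruit-colored blob yields an empty list.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected an HxWx3 color image, got shape {img.shape}")
    img = img[:, :, :3]
    votes = _pixel_votes(img)
    labeled = cc_label(votes >= 0, connectivity=2)
    regions = sorted(regionprops(labeled), key=lambda r: r.area, reverse=True)
    h, w = votes.shape
    out: list[Detection] = []
    for region in regions:
        if region.area < min_area_px or len(out) >= max_objects:
            break
        r0, c0, r1, c1 = region.bbox
        component_votes = votes[labeled == region.label]
        counts = np.bincount(component_votes, minlength=len(CLASSES))
        cls_idx = int(counts.argmax())
        out.append(
            Detection(
                box=BoundingBox(float(c0), float(r0), float(c1 - c0), float(r1 - r0)),
                cls=CLASSES[cls_idx],
                confidence=float(counts[cls_idx] / counts.sum()),
                source_resolution=(w, h),
            )
        )
    return out


@dataclass(frozen=True)
class Harvestability:
    harvestable: Optional[bool]
    cls: MaturityClass

    @property
    def indeterminate(self) -> bool:
        return self.harvestable is None


def classify_harvestability(d: Detection) -> Harvestability:
    """Ripe/ripening fruit is pickable, unripe is not, bagged fruit is
    indeterminate (the bag hides the maturity)."""
    return Harvestability(harvestable=d.cls.harvestable, cls=d.cls)


def load_detections(
    path: str | Path,
    source_resolution: tuple[int, int] = (448, 448),
    target_frame: Optional[tuple[int, int]] = None,
) -> list[Detection]:
    """Parse normalized ``class cx cy w h [conf]`` lines.

    Coordinates are fractions of ``source_resolution``; boxes are
    denormalized to that resolution and, when ``target_frame`` is given,
    rescaled to it by independent x/y factors.
    """
    sw, sh = source_resolution
    out: list[Detection] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            idx = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed number ({exc})") from None
        if not (0 <= idx < len(CLASSES)):
            raise ValueError(f"{path}:{lineno}: class index {idx} outside 0-{len(CLASSES) - 1}")
        box = BoundingBox((cx - w / 2.0) * sw, (cy - h / 2.0) * sh, w * sw, h * sh)
        res = source_resolution
        if target_frame is not None:
            box = rescale_box(box, source_resolution, target_frame)
            res = target_frame
        out.append(Detection(box=box, cls=CLASSES[idx], confidence=conf, source_resolution=res))
    return out


def save_detections(path: str | Path, detections: Sequence[Detection]) -> None:
    """Write detections in the normalized text dialect (inverse of
    :func:`load_detections` at the same source resolution)."""
    lines = []
    for d in detections:
        sw, sh = d.source_resolution
        cx = (d.box.x_a + d.box.w / 2.0) / sw
        cy = (d.box.y_a + d.box.h / 2.0) / sh
        lines.append(
            f"{CLASS_INDEX[d.cls.label]} {cx:.9f} {cy:.9f} "
            f"{d.box.w / sw:.9f} {d.box.h / sh:.9f} {d.confidence:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
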