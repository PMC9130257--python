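"""Format codecs and configuration shared by all stages.

Depth frames travel as 16-bit grayscale PNG or PGM (1 unit = 1 mm,
invalid pixels encoded as 0) or as a plain CSV grid of millimetre
values.  Camera settings come from a small JSON file.  The reference
measurement tables used by the evaluation protocol ship with the
package as CSV.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .camera import CameraModel, DepthFrame
from .evaluation import RangeMeasurement, DetectionRecord

__all__ = [
    "read_depth",
    "write_depth",
    "read_camera_config",
    "write_camera_config",
    "read_range_measurements",
    "read_detection_records",
    "load_indoor_table",
    "load_outdoor_table",
    "indoor_range_measurements",
    "outdoor_range_measurements",
]

_IMAGE_SUFFIXES = {".png", ".pgm"}


def write_depth(path: str | Path, frame: DepthFrame) -> None:
    """Write a depth frame; format chosen by suffix (.png/.pgm/.csv).

    Image codecs store uint16 millimetres and therefore require integer
    values in [0, 65535]; the CSV codec is lossless for any float grid.
    """
    path = Path(path)
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        depth = frame.depth_mm
        rounded = np.rint(depth)
        if np.any(np.abs(depth - rounded) > 1e-9) or np.any(rounded > 65535):
            raise ValueError(
                "16-bit image codec requires integer depths in [0, 65535]; "
                "use the CSV codec for fractional values"
            )
        iio.imwrite(path, rounded.astype(np.uint16))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, frame.depth_mm, delimiter=",", fmt="%.6g")
    else:
        raise ValueError(f"unsupported depth format {path.suffix!r} (use .png, .pgm or .csv)")


def read_depth(path: str | Path) -> DepthFrame:
    """Read a depth frame written by :func:`write_depth`.

    An 8-bit image is rejected outright: silently scaling it would
    corrupt the millimetre encoding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        arr = iio.imread(path)
        # some readers promote 16-bit PGM to a wider integer type; 8-bit
        # sources are rejected outright rather than silently rescaled
        if arr.dtype == np.uint8 or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(
                f"{path}: expected a 16-bit grayscale depth image, got dtype {arr.dtype}"
            )
        if arr.size and arr.max() > 65535:
            raise ValueError(f"{path}: depth values exceed the 16-bit range")
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
        return DepthFrame(arr.astype(float))
    if path.suffix.lower() == ".csv":
        return DepthFrame(np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float)))
    raise ValueError(f"unsupported depth format {path.suffix!r} (use .png, .pgm or .csv)")


_CAMERA_KEYS = {"fov_h", "fov_v", "width", "height", "z_bias"}


def read_camera_config(path: str | Path) -> CameraModel:
    """Load camera settings from JSON; keys fov_h, fov_v, width, height,
    z_bias, all optional (defaults are the reference device's values).
    Unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = json.loads(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: camera config must be a JSON object")
    unknown = set(raw) - _CAMERA_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown camera config keys {sorted(unknown)}")
    defaults = CameraModel()
    return CameraModel(
        fov_h_deg=float(raw.get("fov_h", defaults.fov_h_deg)),
        fov_v_deg=float(raw.get("fov_v", defaults.fov_v_deg)),
        width_px=int(raw.get("width", defaults.width_px)),
        height_px=int(raw.get("height", defaults.height_px)),
        z_bias_mm=float(raw.get("z_bias", defaults.z_bias_mm)),
    )


def write_camera_config(path: str | Path, cam: CameraModel) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "fov_h": cam.fov_h_deg,
                "fov_v": cam.fov_v_deg,
                "width": cam.width_px,
                "height": cam.height_px,
                "z_bias": cam.z_bias_mm,
            },
            indent=2,
        )
        + "\n"
    )


def read_range_measurements(path: str | Path) -> list[RangeMeasurement]:
    """CSV with columns label, reference_mm, measured_mm."""
    df = pd.read_csv(path)
    missing = {"reference_mm", "measured_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    labels = df["label"].astype(str) if "label" in df.columns else df.index.astype(str)
    return [
        RangeMeasurement(reference_mm=float(r), measured_mm=float(m), label=str(l))
        for l, r, m in zip(labels, df["reference_mm"], df["measured_mm"])
    ]


def read_detection_records(path: str | Path) -> list[DetectionRecord]:
    """CSV or JSON with fields true_class, box_correct, predicted_class
    (empty/null when the box was wrong)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    out = []
    for row in rows:
        pred = row.get("predicted_class")
        if pred is None or (isinstance(pred, float) and np.isnan(pred)) or pred == "":
            pred = None
        out.append(
            DetectionRecord(
                true_class=str(row["true_class"]),
                box_correct=bool(row["box_correct"]),
                predicted_class=pred,
            )
        )
    return out


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("pineloc.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_indoor_table() -> pd.DataFrame:
    """Reference indoor checkerboard protocol: 12 rows of ruler / laser /
    depth readings with per-row reference and sampling pixels and the
    published metric offsets and error rates.

    Note: row 5's raw depth error-rate cell is internally inconsistent
    with its own difference and reference (it repeats row 4's value);
    consumers should recompute error rates from the raw readings.
    """
    return _packaged_csv("indoor_checkerboard.csv")


def load_outdoor_table() -> pd.DataFrame:
    """Reference outdoor protocol: 9 (laser, depth) pairs with published
    differences and error rates."""
    return _packaged_csv("outdoor_range.csv")


def indoor_range_measurements() -> list[RangeMeasurement]:
    """The indoor table as range measurements (laser standard vs depth)."""
    df = load_indoor_table()
    return [
        RangeMeasurement(
            reference_mm=float(r.laser_mm), measured_mm=float(r.depth_mm), label=str(r.row)
        )
        for r in df.itertuples()
    ]


def outdoor_range_measurements() -> list[RangeMeasurement]:
    """The outdoor table as range measurements."""
    df = load_outdoor_table()
    return [
        RangeMeasurement(
            reference_mm=float(r.laser_mm), measured_mm=float(r.depth_mm), label=str(r.row)
        )
        for r in df.itertuples()
    ]
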