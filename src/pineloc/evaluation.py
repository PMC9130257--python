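"""Accuracy protocols: range-error evaluation against a laser-rangefinder
standard, and detection metrics (box selection accuracy / classification
accuracy) with confusion counts.

Range protocol: the laser rangefinder reading is the standard answer; the
difference ``measured - reference`` is the calculation error and the
error rate is the absolute difference divided by the standard distance,
in percent.  A fixed systematic bias (default 6 mm) can be subtracted
from the difference to form a corrected error.

Detection protocol:

* BA (box selection accuracy): fraction of annotated images in which the
  fruit was correctly framed, over all records.
* CA (classification accuracy): fraction of correctly classified images
  among the *correctly boxed* ones -- a misframed fruit has no class
  prediction to score.

Percentages are carried at full precision; rendering rounds half away
from zero to two decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .detection import CLASS_LABELS

__all__ = [
    "RangeMeasurement",
    "ErrorReport",
    "RangeSummary",
    "DetectionRecord",
    "MetricsReport",
    "error_rate",
    "summarize_range_errors",
    "detection_metrics",
    "render_report",
    "round2",
]


def round2(v: float) -> float:
    """Round to 2 decimals, ties away from zero (display convention)."""
    if not math.isfinite(v):
        return v
    s = -1.0 if v < 0 else 1.0
    return s * math.floor(abs(v) * 100.0 + 0.5) / 100.0


@dataclass(frozen=True)
class RangeMeasurement:
    """One (standard, depth-camera) range pair in millimetres."""

    reference_mm: float
    measured_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reference_mm > 0:
            raise ValueError(f"reference_mm must be positive, got {self.reference_mm}")


@dataclass(frozen=True)
class ErrorReport:
    """Signed difference and percent error for one measurement, raw and
    after bias correction."""

    label: str
    reference_mm: float
    measured_mm: float
    difference_mm: float
    error_rate_pct: float
    corrected_difference_mm: float
    corrected_error_rate_pct: float


@dataclass(frozen=True)
class RangeSummary:
    reports: tuple[ErrorReport, ...]
    band: Optional[tuple[float, float]]
    max_error_rate_pct: float
    max_corrected_error_rate_pct: float
    mean_error_rate_pct: float
    mean_corrected_error_rate_pct: float
    n_in_band: int


def error_rate(m: RangeMeasurement, z_bias: float = 0.0) -> ErrorReport:
    """Difference, percent error and bias-corrected variants for one pair.

    The difference keeps its sign; error rates use the absolute value
    over the reference distance.
    """
    diff = m.measured_mm - m.reference_mm
    corr = diff - z_bias
    return ErrorReport(
        label=m.label,
        reference_mm=m.reference_mm,
        measured_mm=m.measured_mm,
        difference_mm=diff,
        error_rate_pct=abs(diff) / m.reference_mm * 100.0,
        corrected_difference_mm=corr,
        corrected_error_rate_pct=abs(corr) / m.reference_mm * 100.0,
    )


def summarize_range_errors(
    measurements: Sequence[RangeMeasurement],
    z_bias: float = 0.0,
    band: Optional[tuple[float, float]] = None,
) -> RangeSummary:
    """Per-row error reports plus max/mean rates over a reference band.

    ``band`` is an inclusive (low, high) interval on the reference
    distance; rows outside it still get reports but do not enter the
    aggregates.
    """
    if not measurements:
        raise ValueError("at least one measurement is required")
    reports = tuple(error_rate(m, z_bias) for m in measurements)
    if band is None:
        in_band = reports
    else:
        lo, hi = band
        in_band = tuple(r for r in reports if lo <= r.reference_mm <= hi)
    if not in_band:
        raise ValueError(f"no measurement falls in band {band}")
    raw = [r.error_rate_pct for r in in_band]
    cor = [r.corrected_error_rate_pct for r in in_band]
    return RangeSummary(
        reports=reports,
        band=band,
        max_error_rate_pct=max(raw),
        max_corrected_error_rate_pct=max(cor),
        mean_error_rate_pct=sum(raw) / len(raw),
        mean_corrected_error_rate_pct=sum(cor) / len(cor),
        n_in_band=len(in_band),
    )


@dataclass(frozen=True)
class DetectionRecord:
    """Ground truth vs. outcome for one annotated image.

    ``predicted_class`` must be present exactly when the box was correct:
    a misframed fruit has no class to score.
    """

    true_class: str
    box_correct: bool
    predicted_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.true_class not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.box_correct and self.predicted_class is None:
            raise ValueError("boxed record must carry a predicted class")
        if not self.box_correct and self.predicted_class is not None:
            raise ValueError("unboxed record cannot carry a predicted class")
        if self.predicted_class is not None and self.predicted_class not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.predicted_class!r}")


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and overall BA/CA percentages plus confusion counts.

    ``ca`` values are ``None`` where no record of the class was boxed
    (the metric is undefined, not zero).  ``confusion`` is a true-class x
    predicted-class count table over boxed records only.
    """

    n_records: int
    ba_overall: float
    ca_overall: Optional[float]
    ba_per_class: dict[str, Optional[float]]
    ca_per_class: dict[str, Optional[float]]
    confusion: pd.DataFrame


def detection_metrics(records: Sequence[DetectionRecord]) -> MetricsReport:
    """Aggregate BA/CA and a confusion matrix from per-image records."""
    if not records:
        raise ValueError("at least one record is required")
    classes = list(CLASS_LABELS)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    n_boxed = 0
    n_correct = 0
    per_n: dict[str, int] = {c: 0 for c in classes}
    per_boxed: dict[str, int] = {c: 0 for c in classes}
    per_correct: dict[str, int] = {c: 0 for c in classes}
    for r in records:
        per_n[r.true_class] += 1
        if r.box_correct:
            n_boxed += 1
            per_boxed[r.true_class] += 1
            confusion.loc[r.true_class, r.predicted_class] += 1
            if r.predicted_class == r.true_class:
                n_correct += 1
                per_correct[r.true_class] += 1

    def pct(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den * 100.0

    return MetricsReport(
        n_records=len(records),
        ba_overall=n_boxed / len(records) * 100.0,
        ca_overall=pct(n_correct, n_boxed),
        ba_per_class={c: pct(per_boxed[c], per_n[c]) for c in classes},
        ca_per_class={c: pct(per_correct[c], per_boxed[c]) for c in classes},
        confusion=confusion,
    )


def _fmt(v: Optional[float]) -> str:
    return "n/a" if v is None else f"{round2(v):.2f}"


def render_report(report: MetricsReport | RangeSummary) -> tuple[str, dict]:
    """Render a report as table text plus a JSON-serializable record.

    Column order is deterministic; percentages print to two decimals.
    """
    if isinstance(report, MetricsReport):
        lines = [f"{'class':<10} {'n':>6} {'BA %':>8} {'CA %':>8}"]
        for c in CLASS_LABELS:
            n = int(report.confusion.loc[c].sum())
            lines.append(
                f"{c:<10} {n:>6} {_fmt(report.ba_per_class[c]):>8} "
                f"{_fmt(report.ca_per_class[c]):>8}"
            )
        lines.append(
            f"{'overall':<10} {report.n_records:>6} "
            f"{_fmt(report.ba_overall):>8} {_fmt(report.ca_overall):>8}"
        )
        lines.append("")
        lines.append("confusion (true x predicted, boxed records):")
        lines.append(report.confusion.to_string())
        record = {
            "schema_version": 1,
            "kind": "detection_metrics",
            "n_records": report.n_records,
            "ba_overall_pct": round2(report.ba_overall),
            "ca_overall_pct": None if report.ca_overall is None else round2(report.ca_overall),
            "ba_per_class_pct": {
                c: (None if v is None else round2(v)) for c, v in report.ba_per_class.items()
            },
            "ca_per_class_pct": {
                c: (None if v is None else round2(v)) for c, v in report.ca_per_class.items()
            },
            "confusion": {
                t: {p: int(report.confusion.loc[t, p]) for p in CLASS_LABELS}
                for t in CLASS_LABELS
            },
        }
        return "\n".join(lines), record

    if isinstance(report, RangeSummary):
        header = (
            f"{'label':<8} {'ref mm':>8} {'meas mm':>8} {'diff mm':>8} "
            f"{'err %':>7} {'corr mm':>8} {'corr %':>7}"
        )
        lines = [header]
        for r in report.reports:
            lines.append(
                f"{r.label:<8} {r.reference_mm:>8.0f} {r.measured_mm:>8.0f} "
                f"{r.difference_mm:>+8.0f} {round2(r.error_rate_pct):>7.2f} "
                f"{r.corrected_difference_mm:>+8.0f} "
                f"{round2(r.corrected_error_rate_pct):>7.2f}"
            )
        band_txt = "all" if report.band is None else f"{report.band[0]:g}..{report.band[1]:g} mm"
        lines.append(
            f"max over {band_txt} (n={report.n_in_band}): "
            f"raw {round2(report.max_error_rate_pct):.2f}% "
            f"corrected {round2(report.max_corrected_error_rate_pct):.2f}%"
        )
        record = {
            "schema_version": 1,
            "kind": "range_summary",
            "band_mm": list(report.band) if report.band else None,
            "n_in_band": report.n_in_band,
            "max_error_rate_pct": round2(report.max_error_rate_pct),
            "max_corrected_error_rate_pct": round2(report.max_corrected_error_rate_pct),
            "mean_error_rate_pct": round2(report.mean_error_rate_pct),
            "mean_corrected_error_rate_pct": round2(report.mean_corrected_error_rate_pct),
            "rows": [
                {
                    "label": r.label,
                    "reference_mm": r.reference_mm,
                    "measured_mm": r.measured_mm,
                    "difference_mm": r.difference_mm,
                    "error_rate_pct": round2(r.error_rate_pct),
                    "corrected_difference_mm": r.corrected_difference_mm,
                    "corrected_error_rate_pct": round2(r.corrected_error_rate_pct),
                }
                for r in report.reports
            ],
        }
        return "\n".join(lines), record

    raise TypeError(f"cannot render {type(report).__name__}")
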