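"""Pixel-level segmentation evaluation.

Confusion counts against a manual ground-truth mask and the four standard
ratios:

    sensitivity = TP / (TP + FN)        (vessel recall)
    specificity = TN / (TN + FP)        (background recall)
    accuracy    = (TP + TN) / total
    precision   = TP / (TP + FP)

Counts are taken inside the field-of-view mask by default (the usual
convention for the public fundus benchmarks); whole-frame evaluation is
available by passing ``fov=None``.  A metric whose denominator is zero is
reported as NaN (an explicit undefined marker), never silently as 0 or 1,
and is skipped — with bookkeeping — when averaging.

The package also ships two reference per-image metric tables for the
DRIVE (20 images) and CHASE_DB1 (14 images) test sets, obtained with the
baseline curvelet + mean-C method; they exercise the aggregation exactly
as published result tables do.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ConsistencyError, DegenerateInputError
from .preprocess import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "EvaluationReport",
    "confusion_counts",
    "metrics",
    "aggregate",
    "dice",
    "load_reference_metrics",
    "write_report_csv",
]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision")


@dataclass
class ConfusionCounts:
    """Pixel confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsRow:
    """One evaluation row; NaN marks an undefined metric."""

    image_id: str
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class EvaluationReport:
    """Per-image rows plus unweighted column means."""

    rows: List[MetricsRow]
    means: MetricsRow
    skipped: Dict[str, int] = field(default_factory=dict)


def confusion_counts(
    pred: BinaryMask, truth: BinaryMask, fov: Optional[BinaryMask] = None
) -> ConfusionCounts:
    """Count TP/FP/TN/FN over the FOV (all pixels when ``fov`` is None)."""
    if pred.shape != truth.shape:
        raise ConsistencyError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}"
        )
    p = pred.astype_bool()
    t = truth.astype_bool()
    if fov is not None:
        if fov.shape != pred.shape:
            raise ConsistencyError("fov dimensions do not match masks")
        sel = fov.astype_bool()
        p = p[sel]
        t = t[sel]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts, image_id: str = "") -> MetricsRow:
    """The four classification ratios for one image."""
    if c.total == 0:
        raise DegenerateInputError("all confusion counts are zero")
    return MetricsRow(
        image_id=image_id,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
    )


def aggregate(rows: Sequence[MetricsRow]) -> EvaluationReport:
    """Unweighted column means, skipping undefined (NaN) entries.

    The number of skipped entries per column is recorded so an average
    over a reduced denominator is never silent.
    """
    if not rows:
        raise DegenerateInputError("cannot aggregate an empty row list")
    means = {}
    skipped = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in rows]
        ok = [v for v in vals if not math.isnan(v)]
        skipped[name] = len(vals) - len(ok)
        means[name] = sum(ok) / len(ok) if ok else math.nan
    mean_row = MetricsRow(image_id="mean", **means)
    return EvaluationReport(rows=list(rows), means=mean_row, skipped=skipped)


def dice(pred: BinaryMask, truth: BinaryMask, fov: Optional[BinaryMask] = None) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); used in phantom recovery tests."""
    c = confusion_counts(pred, truth, fov)
    den = 2 * c.tp + c.fp + c.fn
    return 2.0 * c.tp / den if den > 0 else math.nan


_REFERENCE_FILES = {
    "drive": "drive_reference_metrics.csv",
    "chase_db1": "chase_reference_metrics.csv",
    "chase": "chase_reference_metrics.csv",
}


def load_reference_metrics(dataset: str) -> List[MetricsRow]:
    """Load the bundled reference per-image metric table.

    ``dataset`` is ``"drive"`` or ``"chase_db1"``.
    """
    key = dataset.lower()
    if key not in _REFERENCE_FILES:
        raise ValueError(f"unknown dataset {dataset!r}; use 'drive' or 'chase_db1'")
    ref = resources.files("vesselx.data").joinpath(_REFERENCE_FILES[key])
    rows: List[MetricsRow] = []
    with ref.open("r", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                MetricsRow(
                    image_id=rec["image_id"],
                    sensitivity=float(rec["sensitivity"]),
                    specificity=float(rec["specificity"]),
                    accuracy=float(rec["accuracy"]),
                    precision=float(rec["precision"]),
                )
            )
    return rows


def write_report_csv(report: EvaluationReport, path) -> None:
    """Write rows plus a final ``mean`` row as CSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", *METRIC_NAMES])
        for row in [*report.rows, report.means]:
            writer.writerow(
                [row.image_id] + [f"{getattr(row, n):.6f}" for n in METRIC_NAMES]
            )
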