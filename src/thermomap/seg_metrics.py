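"""Confusion-matrix segmentation metrics: per-class IoU, MIoU, MPA, centroid offset.

With ``p_ij`` the number of pixels of true class i predicted as class j,

    IoU_i = p_ii / (sum_j p_ij + sum_j p_ji - p_ii)
    PA_i  = p_ii / sum_j p_ij          (per-class recall)

MIoU and MPA are the means over classes present in truth or prediction;
classes absent from both are excluded (0/0 undefined) and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyEvaluationError,
    EmptyMaskError,
    InvalidInputError,
    LabelError,
    ShapeError,
)

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_from_masks",
    "metric_report",
    "binary_iou",
    "centroid_offset",
]


@dataclass
class ConfusionMatrix:
    """k x k pixel-count matrix; counts[i, j] = true class i, predicted class j."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ShapeError("confusion matrix must be square")
        if c.shape[0] < 2:
            raise InvalidInputError("need at least 2 classes")
        if (c < 0).any():
            raise InvalidInputError("counts must be non-negative")
        self.counts = c.astype(np.int64)
        if not self.class_names:
            self.class_names = [str(i) for i in range(c.shape[0])]
        if len(self.class_names) != c.shape[0]:
            raise InvalidInputError("class_names length must match k")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        """Pool two confusion matrices (global, image-pooled evaluation)."""
        if other.k != self.k:
            raise ShapeError("cannot pool confusion matrices of different k")
        return ConfusionMatrix(self.counts + other.counts, list(self.class_names))


@dataclass
class MetricReport:
    """Per-class IoU/accuracy with their means over present classes."""

    per_class_iou: dict[str, float]
    per_class_accuracy: dict[str, float]
    miou: float
    mpa: float
    excluded_classes: list[str]

    def to_dict(self) -> dict:
        return {
            "per_class_iou": self.per_class_iou,
            "per_class_accuracy": self.per_class_accuracy,
            "miou": self.miou,
            "mpa": self.mpa,
            "excluded_classes": self.excluded_classes,
        }


def confusion_from_masks(truth, pred, k: int, class_names=None) -> ConfusionMatrix:
    """Tally a k-class confusion matrix from two integer label grids."""
    t = np.asarray(getattr(truth, "grid", truth))
    p = np.asarray(getattr(pred, "grid", pred))
    if t.shape != p.shape:
        raise ShapeError(f"mask shapes differ: {t.shape} vs {p.shape}")
    if t.min() < 0 or p.min() < 0 or t.max() >= k or p.max() >= k:
        raise LabelError(f"label codes outside [0, {k})")
    counts = np.bincount(
        (t.astype(np.int64).ravel() * k + p.astype(np.int64).ravel()), minlength=k * k
    ).reshape(k, k)
    return ConfusionMatrix(counts, list(class_names) if class_names else [])


def metric_report(cm: ConfusionMatrix, *, restrict_to=None) -> MetricReport:
    """IoU/MIoU/MPA from a confusion matrix.

    ``restrict_to`` optionally limits the means to the given class indices
    (e.g. the four head regions, excluding background); per-class values are
    still reported for all present classes.
    """
    c = cm.counts
    if c.sum() == 0:
        raise EmptyEvaluationError("confusion matrix contains no pixels")
    row = c.sum(axis=1)  # truth totals
    col = c.sum(axis=0)  # prediction totals
    diag = np.diag(c)
    present = (row + col) > 0
    if restrict_to is not None:
        sel = np.zeros(cm.k, dtype=bool)
        sel[list(restrict_to)] = True
        present = present & sel
    if not present.any():
        raise EmptyEvaluationError("no classes present under the requested restriction")
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = diag / (row + col - diag)
        pa = diag / row
    names = cm.class_names
    per_iou = {names[i]: float(iou[i]) for i in range(cm.k) if present[i]}
    # per-class accuracy is undefined for classes never in truth; report on
    # truth-present classes; the means run over the same class set
    pa_present = present & (row > 0)
    per_pa = {names[i]: float(pa[i]) for i in range(cm.k) if pa_present[i]}
    miou = float(np.mean(iou[present]))
    mpa = float(np.mean(pa[pa_present])) if pa_present.any() else 0.0
    excluded = [names[i] for i in range(cm.k) if not present[i]]
    return MetricReport(per_iou, per_pa, miou, mpa, excluded)


def binary_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def mask_centroid(a: np.ndarray) -> np.ndarray:
    """Unweighted pixel-center centroid of a binary mask, (u, v)."""
    a = np.asarray(a, dtype=bool)
    if not a.any():
        raise EmptyMaskError("cannot take the centroid of an empty mask")
    vs, us = np.nonzero(a)
    return np.array([us.mean(), vs.mean()])


def centroid_offset(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in pixels between the centroids of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(mask_centroid(a) - mask_centroid(b)))
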