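"""Pluggable segmentation contract, reference segmenter, and mask losses.

The measurement pipeline needs two segmentation stages (background removal,
head-region labelling) but is agnostic to the model behind them: anything
satisfying :class:`SegmenterContract` can be wired in.  For synthetic scenes
a :class:`ReferenceSegmenter` inverts the scene's color table exactly, so the
full pipeline runs without trained network weights.

The losses used to train such segmenters are provided for completeness:
focal loss FL(p_t) = -alpha * (1 - p_t)^gamma * log(p_t) (mean-reduced,
natural log), dice loss, binary cross-entropy, and their combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import InvalidInputError, ShapeError, UnmappedColorError
from .roi_mapping import LabelMask, RegionLabel

__all__ = [
    "DEFAULT_COLOR_TABLE",
    "FocalLossParams",
    "SegmenterContract",
    "ReferenceSegmenter",
    "focal_loss",
    "dice_loss",
    "bce_loss",
    "combined_mask_loss",
    "pt_from_prediction",
]

#: Fixed RGB color code per region used by the synthetic scene renderer.
DEFAULT_COLOR_TABLE: dict[RegionLabel, tuple[int, int, int]] = {
    RegionLabel.BACKGROUND: (40, 40, 40),
    RegionLabel.COMB: (220, 40, 40),
    RegionLabel.EYE: (30, 30, 220),
    RegionLabel.BEAK: (230, 190, 40),
    RegionLabel.WATTLE: (200, 60, 160),
}

_PT_FLOOR = 1e-7


@dataclass(frozen=True)
class FocalLossParams:
    """Class-balance factor alpha in (0, 1] and focusing exponent gamma >= 0.

    Defaults follow the originating focal-loss convention (alpha=0.25,
    gamma=2); at gamma=0, alpha=1 the loss reduces to cross-entropy.
    """

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise InvalidInputError("alpha must lie in (0, 1]")
        if self.gamma < 0:
            raise InvalidInputError("gamma must be >= 0")


def focal_loss(pt, params: FocalLossParams = FocalLossParams()) -> float:
    """Mean over pixels of -alpha * (1 - pt)^gamma * ln(pt).

    ``pt`` is the predicted probability of the true class per pixel, in
    [0, 1]; values are floored at 1e-7 before the log so a confidently wrong
    pixel yields a large finite loss.
    """
    pt = np.asarray(pt, dtype=float)
    if pt.size == 0:
        raise InvalidInputError("focal_loss needs at least one probability")
    if not np.isfinite(pt).all() or pt.min() < 0 or pt.max() > 1:
        raise InvalidInputError("probabilities must lie in [0, 1]")
    ptc = np.clip(pt, _PT_FLOOR, 1.0)
    return float(np.mean(-params.alpha * (1.0 - ptc) ** params.gamma * np.log(ptc)))


def bce_loss(pred, truth) -> float:
    """Mean binary cross-entropy between a soft mask and a binary mask."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ShapeError(f"shapes differ: {pred.shape} vs {truth.shape}")
    p = np.clip(pred, _PT_FLOOR, 1.0 - _PT_FLOOR)
    return float(np.mean(-(truth * np.log(p) + (1.0 - truth) * np.log1p(-p))))


def dice_loss(pred, truth, *, eps: float = 1.0) -> float:
    """1 - (2 |pred * truth| + eps) / (|pred| + |truth| + eps), in [0, 1]."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ShapeError(f"shapes differ: {pred.shape} vs {truth.shape}")
    inter = float((pred * truth).sum())
    total = float(pred.sum() + truth.sum())
    return 1.0 - (2.0 * inter + eps) / (total + eps)


def pt_from_prediction(pred, truth) -> np.ndarray:
    """Per-pixel probability of the true class from a soft foreground mask."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ShapeError(f"shapes differ: {pred.shape} vs {truth.shape}")
    return np.where(truth, pred, 1.0 - pred)


def combined_mask_loss(
    pred,
    truth,
    params: FocalLossParams = FocalLossParams(),
    *,
    dice_weight: float = 1.0,
    focal_weight: float = 1.0,
) -> float:
    """Weighted focal + dice mask loss (equal weights by default)."""
    return focal_weight * focal_loss(pt_from_prediction(pred, truth), params) + (
        dice_weight * dice_loss(pred, truth)
    )


@runtime_checkable
class SegmenterContract(Protocol):
    """Callable surface every segmentation stage must satisfy."""

    #: label code -> semantic name, declaring the output class table
    class_table: dict[int, str]

    def __call__(self, image: np.ndarray) -> LabelMask: ...


class ReferenceSegmenter:
    """Color-table inversion segmenter for synthetic scenes.

    In strict mode any pixel color outside the declared table raises
    :class:`UnmappedColorError` listing the offending values; with
    ``strict=False`` each pixel is assigned the nearest table color
    (Euclidean in RGB), which tolerates additive image noise.
    """

    def __init__(
        self,
        color_table: dict[RegionLabel, tuple[int, int, int]] | None = None,
        *,
        strict: bool = True,
    ):
        self.color_table = dict(color_table or DEFAULT_COLOR_TABLE)
        self.strict = strict
        self.class_table = {int(r): r.name.lower() for r in self.color_table}
        self._labels = np.array([int(r) for r in self.color_table], dtype=np.uint8)
        self._colors = np.array(
            [c for c in self.color_table.values()], dtype=float
        )

    def __call__(self, image: np.ndarray) -> LabelMask:
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ShapeError("expected an (H, W, 3) color image")
        if self.strict:
            # exact color-table inversion on packed 24-bit codes
            packed = (
                img[..., 0].astype(np.uint32) << 16
                | img[..., 1].astype(np.uint32) << 8
                | img[..., 2].astype(np.uint32)
            ).ravel()
            table = {
                (int(c[0]) << 16 | int(c[1]) << 8 | int(c[2])): lab
                for c, lab in zip(self._colors.astype(int), self._labels)
            }
            uniq, inv = np.unique(packed, return_inverse=True)
            unknown = [u for u in uniq.tolist() if u not in table]
            if unknown:
                raise UnmappedColorError(
                    [(u >> 16 & 255, u >> 8 & 255, u & 255) for u in unknown[:10]]
                )
            lut = np.array([table[u] for u in uniq.tolist()], dtype=np.uint8)
            grid = lut[inv].reshape(img.shape[:2])
            return LabelMask(grid, frame="rgb")
        flat = img.reshape(-1, 3).astype(float)
        out = np.empty(len(flat), dtype=np.uint8)
        chunk = 1 << 19  # bound peak memory on full-resolution frames
        for lo in range(0, len(flat), chunk):
            part = flat[lo : lo + chunk]
            d2 = ((part[:, None, :] - self._colors[None, :, :]) ** 2).sum(axis=2)
            out[lo : lo + chunk] = self._labels[np.argmin(d2, axis=1)]
        grid = out.reshape(img.shape[:2])
        return LabelMask(grid, frame="rgb")
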