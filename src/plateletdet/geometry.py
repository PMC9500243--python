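"""Axis-aligned boxes and pairwise similarity measures (IOU, CIOU, match).

Coordinate convention: continuous, 0-based, half-open
``[x_min, x_max) x [y_min, y_max)``; ``area = width * height``.  VOC's 1-based
inclusive pixel indices are converted at I/O time (:mod:`plateletdet.voc_data`),
so everything here is convention-free.

The *match parameter* is the sum CIOU + IOU: unlike plain IOU it stays
informative (non-flat gradient) when the two boxes do not overlap, because the
CIOU term carries a normalized center-distance penalty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Kind = Literal["iou", "ciou", "match"]

__all__ = [
    "Box",
    "SimilarityValue",
    "iou",
    "ciou",
    "match_parameter",
    "pairwise_matrix",
    "boxes_to_array",
    "shape_iou_matrix",
]


class SimilarityValue(float):
    """A float tagged with the similarity kind that produced it.

    ``kind="iou"`` values lie in [0, 1]; ``kind="ciou"`` values are <= 1;
    ``kind="match"`` (= ciou + iou) values are <= 2.
    """

    __slots__ = ("kind",)

    def __new__(cls, value: float, kind: Kind):
        obj = super().__new__(cls, value)
        obj.kind = kind
        return obj


@dataclass
class Box:
    """Axis-aligned rectangle with a class label."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "platelet"

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return max(self.width, 0.0) * max(self.height, 0.0)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def is_degenerate(self) -> bool:
        return self.width <= 0 or self.height <= 0

    def shifted(self, dx: float, dy: float) -> "Box":
        return replace(self, x_min=self.x_min + dx, y_min=self.y_min + dy,
                       x_max=self.x_max + dx, y_max=self.y_max + dy)

    def scaled(self, s: float) -> "Box":
        return replace(self, x_min=self.x_min * s, y_min=self.y_min * s,
                       x_max=self.x_max * s, y_max=self.y_max * s)


def boxes_to_array(boxes: Sequence[Box]) -> np.ndarray:
    """Stack boxes into an (N, 4) float array of (x_min, y_min, x_max, y_max)."""
    if not boxes:
        return np.zeros((0, 4), dtype=float)
    return np.array([[b.x_min, b.y_min, b.x_max, b.y_max] for b in boxes],
                    dtype=float)


def iou(a: Box, b: Box) -> SimilarityValue:
    """Intersection over union of two boxes.

    Degenerate (zero-area) boxes yield 0 rather than raising, so a corrupt
    annotation cannot crash a batch evaluation.
    """
    if a.is_degenerate or b.is_degenerate:
        logger.debug("iou: degenerate box, returning 0")
        return SimilarityValue(0.0, "iou")
    return SimilarityValue(_iou_scalar(a, b), "iou")


def _iou_scalar(a: Box, b: Box) -> float:
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def ciou(pred: Box, gt: Box) -> SimilarityValue:
    """Complete-IOU similarity: IOU - rho^2/c^2 - alpha*nu.

    ``rho^2`` is the squared distance between box centers, ``c`` the diagonal
    of the smallest enclosing box, ``nu`` the aspect-ratio consistency term
    ``(4/pi^2) * (arctan(w_gt/h_gt) - arctan(w/h))^2`` and
    ``alpha = nu / ((1 - IOU) + nu)`` (0 when that denominator vanishes).
    A degenerate box contributes IOU 0 but still incurs the distance penalty.
    """
    overlap = 0.0 if (pred.is_degenerate or gt.is_degenerate) else _iou_scalar(pred, gt)
    cx_p, cy_p = pred.center
    cx_g, cy_g = gt.center
    rho2 = (cx_p - cx_g) ** 2 + (cy_p - cy_g) ** 2
    ex = max(pred.x_max, gt.x_max) - min(pred.x_min, gt.x_min)
    ey = max(pred.y_max, gt.y_max) - min(pred.y_min, gt.y_min)
    c2 = ex * ex + ey * ey
    dist = rho2 / c2 if c2 > 0 else 0.0  # coincident points: no penalty
    # arctan2 handles zero heights of degenerate boxes gracefully
    nu = (4.0 / math.pi ** 2) * (
        math.atan2(gt.width, gt.height) - math.atan2(pred.width, pred.height)
    ) ** 2
    denom = (1.0 - overlap) + nu
    alpha = nu / denom if denom > 0 else 0.0
    return SimilarityValue(overlap - dist - alpha * nu, "ciou")


def match_parameter(pred: Box, gt: Box) -> SimilarityValue:
    """Assignment score CIOU + IOU; equals 2 iff the boxes are identical."""
    return SimilarityValue(float(ciou(pred, gt)) + float(iou(pred, gt)), "match")


# ---------------------------------------------------------------------------
# vectorized pairwise forms (bit-agree with the scalar ops to 1e-9)
# ---------------------------------------------------------------------------

def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IOU of (N,4) vs (M,4) corner-form arrays -> (N, M)."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0.0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0.0)
    inter = iw * ih
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])).clip(min=0.0)
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])).clip(min=0.0)
    union = area_a[:, None] + area_b[None, :] - inter
    degenerate = (area_a[:, None] <= 0) | (area_b[None, :] <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    out[degenerate] = 0.0
    return out


def ciou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise CIOU of (N,4) vs (M,4) corner-form arrays -> (N, M)."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    overlap = iou_matrix(a, b)
    acx = 0.5 * (a[:, 0] + a[:, 2])
    acy = 0.5 * (a[:, 1] + a[:, 3])
    bcx = 0.5 * (b[:, 0] + b[:, 2])
    bcy = 0.5 * (b[:, 1] + b[:, 3])
    rho2 = (acx[:, None] - bcx[None, :]) ** 2 + (acy[:, None] - bcy[None, :]) ** 2
    ex = np.maximum(a[:, None, 2], b[None, :, 2]) - np.minimum(a[:, None, 0], b[None, :, 0])
    ey = np.maximum(a[:, None, 3], b[None, :, 3]) - np.minimum(a[:, None, 1], b[None, :, 1])
    c2 = ex * ex + ey * ey
    dist = np.where(c2 > 0, rho2 / np.where(c2 > 0, c2, 1.0), 0.0)
    ang_a = np.arctan2(a[:, 2] - a[:, 0], a[:, 3] - a[:, 1])
    ang_b = np.arctan2(b[:, 2] - b[:, 0], b[:, 3] - b[:, 1])
    nu = (4.0 / math.pi ** 2) * (ang_b[None, :] - ang_a[:, None]) ** 2
    denom = (1.0 - overlap) + nu
    alpha = np.where(denom > 0, nu / np.where(denom > 0, denom, 1.0), 0.0)
    return overlap - dist - alpha * nu


_MATRIX_FNS = {
    "iou": iou_matrix,
    "ciou": ciou_matrix,
    "match": lambda a, b: iou_matrix(a, b) + ciou_matrix(a, b),
}


def pairwise_matrix(boxes_a: Sequence[Box], boxes_b: Sequence[Box],
                    kind: Kind = "iou") -> np.ndarray:
    """Matrix of similarity values; entry (i, j) = op(boxes_a[i], boxes_b[j])."""
    if kind not in _MATRIX_FNS:
        raise ValueError(f"unknown similarity kind {kind!r}")
    a = boxes_to_array(boxes_a)
    b = boxes_to_array(boxes_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]), dtype=float)
    return _MATRIX_FNS[kind](a, b)


def shape_iou_matrix(wh_a: np.ndarray, wh_b: np.ndarray) -> np.ndarray:
    """IOU of center-aligned shapes: (N,2) widths/heights vs (M,2) -> (N,M).

    Center-aligning makes intersection = min(w)*min(h); this is the distance
    kernel used for anchor clustering and anchor->target shape matching.
    """
    wh_a = np.asarray(wh_a, dtype=float).reshape(-1, 2)
    wh_b = np.asarray(wh_b, dtype=float).reshape(-1, 2)
    inter = (np.minimum(wh_a[:, None, 0], wh_b[None, :, 0])
             * np.minimum(wh_a[:, None, 1], wh_b[None, :, 1]))
    union = (wh_a[:, 0] * wh_a[:, 1])[:, None] + (wh_b[:, 0] * wh_b[:, 1])[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
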