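"""Decode raw grids to detections, threshold, and suppress duplicates.

Decode convention: center = (cell + sigmoid(t_xy)) * stride, size =
anchor * exp(t_wh); confidence = sigmoid(objectness) * sigmoid(class score).
NMS is greedy by descending confidence at IOU threshold 0.45; the confidence
threshold defaults to 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from . import autodiff as ad
from .anchors import AnchorSet
from .geometry import Box, boxes_to_array, iou_matrix
from .model import Detector
from .voc_data import letterbox

__all__ = ["Detection", "decode", "nms", "detect"]


@dataclass
class Detection:
    box: Box
    confidence: float
    class_name: str = "platelet"

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe on both tails
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(raw: Sequence[np.ndarray], anchors: AnchorSet, input_size: int,
           num_classes: int = 1, conf_threshold: float = 0.0,
           class_names: Sequence[str] = ("platelet",)) -> list[Detection]:
    """Decode one image's raw per-scale grids into detections.

    ``raw`` holds arrays of shape (A*(5+C), S, S) ordered coarsest-first
    (a leading batch dim of 1 is squeezed).  Detections are in network
    (letterboxed) coordinates, ordered scale-major then cell-major, which
    fixes the deterministic NMS tie-break order.
    """
    n_scales = len(raw)
    a_per = anchors.anchors_per_scale
    detections: list[Detection] = []
    for s_idx, grid in enumerate(raw):
        grid = np.asarray(grid.data if isinstance(grid, ad.Tensor) else grid)
        if grid.ndim == 4:
            if grid.shape[0] != 1:
                raise ValueError("decode expects a single image; pass per-image slices")
            grid = grid[0]
        ch, s, _ = grid.shape
        expected = a_per * (5 + num_classes)
        if ch != expected:
            raise ValueError(
                f"scale {s_idx}: {ch} channels do not match "
                f"{a_per} anchors x (5 + {num_classes})")
        stride = input_size // s
        group = anchors.group_shapes(n_scales - 1 - s_idx)
        g = grid.reshape(a_per, 5 + num_classes, s, s)
        gx = np.arange(s, dtype=float)
        px = (gx[None, None, :] + _sigmoid(g[:, 0])) * stride
        py = (gx[None, :, None] + _sigmoid(g[:, 1])) * stride
        pw = group[:, 0, None, None] * np.exp(np.clip(g[:, 2], -20.0, 20.0))
        ph = group[:, 1, None, None] * np.exp(np.clip(g[:, 3], -20.0, 20.0))
        obj = _sigmoid(g[:, 4])
        cls_prob = _sigmoid(g[:, 5:])                      # (A, C, S, S)
        best_cls = cls_prob.argmax(axis=1)                 # (A, S, S)
        conf = obj * np.take_along_axis(
            cls_prob, best_cls[:, None], axis=1)[:, 0]
        # strict comparison: confidence is mathematically < 1, so a threshold
        # of 1.0 always yields no detections even when sigmoid saturates
        keep = np.nonzero(conf > conf_threshold) if conf_threshold > 0 else \
            np.nonzero(np.ones_like(conf, dtype=bool))
        for a_i, r_i, c_i in zip(*keep):
            w, h = pw[a_i, r_i, c_i], ph[a_i, r_i, c_i]
            cx, cy = px[a_i, r_i, c_i], py[a_i, r_i, c_i]
            cls_i = int(best_cls[a_i, r_i, c_i])
            detections.append(Detection(
                box=Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2,
                        label=class_names[cls_i] if cls_i < len(class_names)
                        else f"class{cls_i}"),
                confidence=float(conf[a_i, r_i, c_i]),
                class_name=class_names[cls_i] if cls_i < len(class_names)
                else f"class{cls_i}"))
    return detections


def nms(dets: Sequence[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy same-class non-maximum suppression.

    Detections are visited in descending confidence (ties keep input order);
    any candidate with IOU > threshold against an already-kept detection of
    the same class is dropped.  Output is sorted by confidence.
    """
    if not dets:
        return []
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    boxes = boxes_to_array([d.box for d in dets])
    classes = [d.class_name for d in dets]
    kept: list[int] = []
    kept_by_class: dict[str, list[int]] = {}
    for i in order:
        same = kept_by_class.get(classes[i], [])
        if same:
            ious = iou_matrix(boxes[i:i + 1], boxes[same])[0]
            if (ious > iou_threshold).any():
                continue
        kept.append(i)
        kept_by_class.setdefault(classes[i], []).append(i)
    return [dets[i] for i in kept]


def detect(model: Detector, image, conf_threshold: float = 0.25,
           iou_threshold: float = 0.45,
           class_names: Sequence[str] = ("platelet",),
           pre_nms_topk: int = 1000) -> list[Detection]:
    """Full single-image pipeline: letterbox -> forward -> decode -> filter ->
    NMS -> inverse letterbox; boxes come back in original image coordinates,
    clipped to the image bounds.

    ``pre_nms_topk`` caps the candidates entering NMS (highest confidence
    first) — it only matters at very low confidence thresholds where an
    untrained model floods the grid.
    """
    if isinstance(image, (str, Path)):
        path = Path(image)
        if not path.exists():
            raise FileNotFoundError(f"image not found: {path}")
        image = np.asarray(Image.open(path).convert("RGB"))
    image = np.asarray(image)
    h, w = image.shape[:2]
    cfg = model.config
    canvas, _, lmap = letterbox(image, None, target_size=cfg.input_size)
    batch = np.ascontiguousarray(
        canvas.transpose(2, 0, 1), dtype=np.float32)[None] / 255.0
    model.eval()
    with ad.no_grad():
        raw = model.forward(batch)
    dets = decode([r.data[0] for r in raw], cfg.anchors, cfg.input_size,
                  num_classes=cfg.num_classes, conf_threshold=conf_threshold,
                  class_names=class_names)
    if len(dets) > pre_nms_topk:
        dets = sorted(dets, key=lambda d: -d.confidence)[:pre_nms_topk]
    dets = nms(dets, iou_threshold)
    out: list[Detection] = []
    for d in dets:
        b = lmap.invert_box(d.box)
        b = Box(max(b.x_min, 0.0), max(b.y_min, 0.0),
                min(b.x_max, float(w)), min(b.y_max, float(h)), label=b.label)
        if not b.is_degenerate:
            out.append(Detection(box=b, confidence=d.confidence,
                                 class_name=d.class_name))
    return out
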