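"""Detection metrics: confusion counts, precision/recall/F1, average
precision, threshold sweeps, and comparison reports.

AP is the raw Riemann sum ``sum_k P(k) * delta_r(k)`` over confidence-ranked
detections — no 11-point or all-point interpolation.  The evaluation IOU
threshold defaults to 0.5 (the VOC convention); 0.45 is the NMS threshold
only, not the evaluation threshold.

TN is undefined for detection and reported as "-".  F1 follows the harmonic
form 2PR/(P+R) = 2TP/(2TP+FP+FN); note that published comparison tables
occasionally print F1 values inconsistent with their own P/R columns (e.g. a
P=100%, R=15% row listed as F1=1% where the harmonic mean gives ~26%) — this
module always computes the harmonic form.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import Box, boxes_to_array, iou_matrix
from .infer import Detection
from .voc_data import ImageRecord

logger = logging.getLogger(__name__)

__all__ = ["EvalCounts", "PRCurve", "match_detections", "precision", "recall",
           "f1", "pr_curve", "average_precision", "threshold_sweep",
           "comparison_report", "evaluate_model", "EvalResult"]


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


def match_detections(dets: Sequence[Detection], gts: Sequence[Box],
                     eval_iou: float = 0.5) -> tuple[list[bool], EvalCounts]:
    """Greedy confidence-ranked matching of detections to ground truths.

    A detection is a TP if its best IOU against a not-yet-matched ground
    truth reaches ``eval_iou`` (ties in rank keep input order); every other
    detection is an FP and every unmatched ground truth an FN.  Returns the
    per-detection TP flags in ranked order plus the counts.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    gt_arr = boxes_to_array(gts)
    matched = np.zeros(len(gts), dtype=bool)
    flags: list[bool] = []
    for i in order:
        d = dets[i]
        hit = False
        if len(gts):
            ious = iou_matrix(boxes_to_array([d.box]), gt_arr)[0]
            ious[matched] = -1.0
            j = int(ious.argmax())
            if ious[j] >= eval_iou:
                matched[j] = True
                hit = True
        flags.append(hit)
    tp = sum(flags)
    return flags, EvalCounts(tp=tp, fp=len(flags) - tp,
                             fn=len(gts) - tp)


def precision(counts: EvalCounts) -> float:
    """TP / (TP + FP); 0 by convention when there are no detections."""
    denom = counts.tp + counts.fp
    if denom == 0:
        logger.debug("precision: no detections, defined as 0")
        return 0.0
    return counts.tp / denom


def recall(counts: EvalCounts) -> float:
    """TP / (TP + FN); 0 by convention when there are no ground truths."""
    denom = counts.tp + counts.fn
    if denom == 0:
        logger.debug("recall: no ground truths, defined as 0")
        return 0.0
    return counts.tp / denom


def f1(arg, r: float | None = None) -> float:
    """Harmonic mean of precision and recall.

    Accepts either an :class:`EvalCounts` (uses 2TP/(2TP+FP+FN)) or a
    (precision, recall) pair; both forms agree exactly.
    """
    if isinstance(arg, EvalCounts):
        denom = 2 * arg.tp + arg.fp + arg.fn
        return 2 * arg.tp / denom if denom else 0.0
    p = float(arg)
    r = float(r)
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class PRCurve:
    """Ranked precision/recall arrays P(k), r(k) and increments delta_r(k)."""

    precisions: np.ndarray
    recalls: np.ndarray
    delta_r: np.ndarray

    def __post_init__(self):
        self.precisions = np.asarray(self.precisions, dtype=float)
        self.recalls = np.asarray(self.recalls, dtype=float)
        self.delta_r = np.asarray(self.delta_r, dtype=float)


def pr_curve(flags: Sequence[bool], n_gt: int) -> PRCurve:
    """Build the ranked P/R curve from ordered TP flags and the GT count."""
    flags = np.asarray(flags, dtype=bool)
    tp_cum = np.cumsum(flags)
    k = np.arange(1, flags.size + 1)
    precisions = tp_cum / k
    recalls = tp_cum / n_gt if n_gt > 0 else np.zeros_like(precisions)
    delta_r = np.diff(recalls, prepend=0.0)
    return PRCurve(precisions=precisions, recalls=recalls, delta_r=delta_r)


def average_precision(curve: PRCurve) -> float:
    """AP = sum_k P(k) * delta_r(k): area under the stepwise P-R path."""
    if curve.precisions.size == 0:
        return 0.0
    return float(np.sum(curve.precisions * curve.delta_r))


def ap_from_flags(flags: Sequence[bool], n_gt: int) -> float:
    if n_gt == 0:
        logger.warning("average precision with zero ground truths, defined 0")
        return 0.0
    return average_precision(pr_curve(flags, n_gt))


def threshold_sweep(dets: Sequence[Detection], gts: Sequence[Box],
                    thresholds: np.ndarray | None = None,
                    eval_iou: float = 0.5) -> dict:
    """Recompute P/R/F1 at each confidence cutoff.

    Returns arrays per threshold plus the argmax-F1 threshold and the
    P-R curve data; recall is non-increasing in the threshold.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0 + 1e-9, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    ps, rs, f1s = [], [], []
    for t in thresholds:
        kept = [d for d in dets if d.confidence >= t]
        _, counts = match_detections(kept, gts, eval_iou=eval_iou)
        ps.append(precision(counts))
        rs.append(recall(counts))
        f1s.append(f1(counts))
    ps, rs, f1s = map(np.asarray, (ps, rs, f1s))
    flags, _ = match_detections(list(dets), gts, eval_iou=eval_iou)
    return {
        "thresholds": thresholds,
        "precision": ps,
        "recall": rs,
        "f1": f1s,
        "best_f1_threshold": float(thresholds[int(np.argmax(f1s))]),
        "pr_curve": pr_curve(flags, len(gts)),
    }


def threshold_sweep_images(per_image, thresholds: np.ndarray | None = None,
                           eval_iou: float = 0.5) -> dict:
    """Image-aware threshold sweep over ``EvalResult.per_image`` pairs.

    Counts are pooled across images at each confidence cutoff (detections are
    only ever matched against ground truths of their own image).
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0 + 1e-9, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    ps, rs, f1s = [], [], []
    for t in thresholds:
        pooled = EvalCounts()
        for dets, gts in per_image:
            kept = [d for d in dets if d.confidence >= t]
            _, counts = match_detections(kept, gts, eval_iou=eval_iou)
            pooled = pooled + counts
        ps.append(precision(pooled))
        rs.append(recall(pooled))
        f1s.append(f1(pooled))
    ps, rs, f1s = map(np.asarray, (ps, rs, f1s))
    return {"thresholds": thresholds, "precision": ps, "recall": rs,
            "f1": f1s,
            "best_f1_threshold": float(thresholds[int(np.argmax(f1s))])}


def sweep_to_csv(sweep: dict) -> str:
    lines = ["threshold,precision,recall,f1"]
    for t, p, r, f in zip(sweep["thresholds"], sweep["precision"],
                          sweep["recall"], sweep["f1"]):
        lines.append(f"{t:.2f},{p:.6f},{r:.6f},{f:.6f}")
    return "\n".join(lines) + "\n"


def comparison_report(runs: Mapping[str, Mapping[str, float]],
                      sep: str = "\t") -> str:
    """Emit a delimited method-comparison table (AP/F1/P/R/time per row)."""
    if not runs:
        raise ValueError("comparison_report needs at least one run")
    cols = ("ap", "f1", "precision", "recall", "seconds")
    lines = [sep.join(("method",) + cols)]
    for name, metrics in runs.items():
        vals = [f"{float(metrics.get(c, float('nan'))):.4f}" for c in cols]
        lines.append(sep.join([name] + vals))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# model-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    ap: float
    counts: EvalCounts
    precision: float
    recall: float
    f1: float
    seconds: float
    per_image: list = field(default_factory=list)

    def as_run(self) -> dict:
        return {"ap": self.ap, "f1": self.f1, "precision": self.precision,
                "recall": self.recall, "seconds": self.seconds}


def evaluate_model(model, records: Sequence[ImageRecord],
                   conf_threshold: float = 0.25, nms_iou: float = 0.45,
                   eval_iou: float = 0.5, max_dets_per_image: int = 300) -> EvalResult:
    """Run detection over ``records`` and score it.

    AP ranks all detections across images by confidence globally (each is
    matched within its own image); P/R/F1 are computed from the pooled
    counts at the given confidence threshold.
    """
    from .infer import detect  # local import avoids a cycle at import time

    t0 = time.time()
    ranked: list[tuple[float, int, Detection]] = []
    gts_per_image: list[list[Box]] = []
    dets_per_image: list[list[Detection]] = []
    for idx, rec in enumerate(records):
        dets = detect(model, rec.image_path, conf_threshold=conf_threshold,
                      iou_threshold=nms_iou)
        dets = sorted(dets, key=lambda d: -d.confidence)[:max_dets_per_image]
        dets_per_image.append(dets)
        gts_per_image.append(list(rec.boxes))
        for d in dets:
            ranked.append((d.confidence, idx, d))

    # global ranking, per-image matching
    ranked.sort(key=lambda t: -t[0])
    matched = [np.zeros(len(g), dtype=bool) for g in gts_per_image]
    flags: list[bool] = []
    for conf, idx, d in ranked:
        gts = gts_per_image[idx]
        hit = False
        if gts:
            ious = iou_matrix(boxes_to_array([d.box]), boxes_to_array(gts))[0]
            ious[matched[idx]] = -1.0
            j = int(ious.argmax())
            if ious[j] >= eval_iou:
                matched[idx][j] = True
                hit = True
        flags.append(hit)
    n_gt = sum(len(g) for g in gts_per_image)
    ap = ap_from_flags(flags, n_gt)
    tp = sum(flags)
    counts = EvalCounts(tp=tp, fp=len(flags) - tp, fn=n_gt - tp)
    return EvalResult(ap=ap, counts=counts, precision=precision(counts),
                      recall=recall(counts), f1=f1(counts),
                      seconds=time.time() - t0,
                      per_image=list(zip(dets_per_image, gts_per_image)))
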