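"""Anchor priors: k-means clustering of ground-truth box shapes.

Clustering uses the YOLO-family convention d(box, centroid) = 1 - IOU of the
center-aligned shapes by default (plain Euclidean on (w, h) is available
behind ``metric="euclidean"``).  Centroid update is the arithmetic mean of
member shapes; initialization samples k distinct shapes with the given seed;
ties on equal distance break to the lowest cluster index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Box, shape_iou_matrix

logger = logging.getLogger(__name__)

__all__ = ["AnchorSet", "DEFAULT_ANCHORS", "kmeans_anchors", "mean_best_iou",
           "assign_scales"]


@dataclass
class AnchorSet:
    """An ordered list of (w, h) priors plus a partition into scale groups.

    ``scale_groups`` holds index groups ordered from smallest to largest mean
    area; the smallest-area group is bound to the finest detection grid.
    """

    anchors: list[tuple[float, float]]
    scale_groups: list[list[int]] | None = None

    def __post_init__(self):
        for w, h in self.anchors:
            if w <= 0 or h <= 0:
                raise ValueError(f"anchor ({w}, {h}) must have positive extent")
        if self.scale_groups is not None:
            flat = sorted(i for g in self.scale_groups for i in g)
            if flat != list(range(len(self.anchors))):
                raise ValueError("scale_groups must partition the anchor indices")
            areas = [np.mean([self.anchors[i][0] * self.anchors[i][1] for i in g])
                     for g in self.scale_groups]
            if areas != sorted(areas):
                raise ValueError("scale_groups must be ordered by ascending mean area")

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def anchors_per_scale(self) -> int:
        if not self.scale_groups:
            raise ValueError("anchor set has no scale groups assigned")
        return len(self.scale_groups[0])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.anchors, dtype=float)

    def group_shapes(self, group: int) -> np.ndarray:
        """(w, h) array of the anchors in scale group ``group`` (0 = finest)."""
        return np.asarray([self.anchors[i] for i in self.scale_groups[group]],
                          dtype=float)

    def to_lines(self) -> str:
        """Serialize as comma-separated "w,h" lines (model-config dialect)."""
        return "\n".join(f"{w:g},{h:g}" for w, h in self.anchors) + "\n"

    @classmethod
    def from_lines(cls, text: str, n_scales: int = 3) -> "AnchorSet":
        anchors = []
        for line in text.strip().splitlines():
            w, h = (float(v) for v in line.split(","))
            anchors.append((w, h))
        s = cls(anchors)
        return assign_scales(s, n_scales) if len(anchors) % n_scales == 0 else s


def _grouped_by_area(anchors: list[tuple[float, float]],
                     n_scales: int) -> list[list[int]]:
    order = sorted(range(len(anchors)), key=lambda i: anchors[i][0] * anchors[i][1])
    per = len(anchors) // n_scales
    return [list(order[g * per:(g + 1) * per]) for g in range(n_scales)]


def assign_scales(anchors: AnchorSet, n_scales: int = 3) -> AnchorSet:
    """Partition anchors into ``n_scales`` contiguous area-sorted groups."""
    if len(anchors) % n_scales != 0:
        raise ValueError(
            f"{len(anchors)} anchors cannot be split into {n_scales} equal scale groups")
    return AnchorSet(list(anchors.anchors),
                     _grouped_by_area(anchors.anchors, n_scales))


#: Reference nine-anchor prior set for platelet-scale data, kept in its
#: published order (not area-sorted; scale groups are formed by area).
DEFAULT_ANCHORS = AnchorSet(
    anchors=[(3, 6), (16, 18), (13, 19), (29, 29), (13, 25),
             (24, 30), (24, 39), (39, 42), (45, 60)],
    scale_groups=_grouped_by_area(
        [(3, 6), (16, 18), (13, 19), (29, 29), (13, 25),
         (24, 30), (24, 39), (39, 42), (45, 60)], 3),
)


def _valid_shapes(boxes: Sequence[Box]) -> np.ndarray:
    shapes = []
    n_bad = 0
    for b in boxes:
        if b.is_degenerate:
            n_bad += 1
            continue
        shapes.append((b.width, b.height))
    if n_bad:
        logger.warning("excluded %d degenerate boxes from clustering", n_bad)
    return np.asarray(shapes, dtype=float).reshape(-1, 2)


def _distances(shapes: np.ndarray, centroids: np.ndarray,
               metric: str) -> np.ndarray:
    if metric == "iou":
        return 1.0 - shape_iou_matrix(shapes, centroids)
    if metric == "euclidean":
        return np.linalg.norm(shapes[:, None, :] - centroids[None, :, :], axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def kmeans_anchors(boxes: Sequence[Box], k: int = 9, seed: int = 0,
                   max_iter: int = 300, metric: str = "iou",
                   with_history: bool = False):
    """Cluster box shapes into k anchor priors.

    Returns an :class:`AnchorSet` with centroids sorted ascending by area
    (scale groups set when k divides by 3).  With ``with_history=True`` also
    returns the per-iteration mean-distance objective, which is non-increasing.
    The result is deterministic given ``seed`` and invariant to the input box
    ordering (shapes are canonicalized by lexicographic sort before seeding).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shapes = _valid_shapes(boxes)
    n = shapes.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} valid boxes, got {n}")
    # canonical order -> seeding is independent of caller's box ordering
    shapes = shapes[np.lexsort((shapes[:, 1], shapes[:, 0]))]
    rng = np.random.default_rng(seed)
    uniq = np.unique(shapes, axis=0)
    if uniq.shape[0] >= k:
        centroids = uniq[rng.choice(uniq.shape[0], size=k, replace=False)]
    else:  # fewer distinct shapes than clusters: duplicates are unavoidable
        centroids = shapes[rng.choice(n, size=k, replace=False)]
    assign = np.full(n, -1, dtype=int)
    history: list[float] = []
    prev_centroids = centroids.copy()
    for _ in range(max_iter):
        d = _distances(shapes, centroids, metric)
        new_assign = np.argmin(d, axis=1)  # argmin takes lowest index on ties
        obj = float(d[np.arange(n), new_assign].mean())
        if history and obj > history[-1]:
            # mean update under IOU distance is a heuristic; stop (and revert)
            # the moment it stops improving so the objective is monotone
            centroids = prev_centroids
            break
        history.append(obj)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        prev_centroids = centroids.copy()
        for j in range(k):
            members = shapes[assign == j]
            if members.shape[0]:
                centroids[j] = members.mean(axis=0)
    order = np.argsort(centroids[:, 0] * centroids[:, 1], kind="stable")
    centroids = centroids[order]
    result = AnchorSet([(float(w), float(h)) for w, h in centroids])
    if k % 3 == 0:
        result = assign_scales(result, 3)
    return (result, history) if with_history else result


def mean_best_iou(boxes: Sequence[Box], anchors: AnchorSet) -> float:
    """Average over boxes of the best center-aligned IOU against any anchor."""
    shapes = _valid_shapes(boxes)
    if shapes.shape[0] == 0:
        raise ValueError("mean_best_iou needs at least one valid box")
    best = shape_iou_matrix(shapes, anchors.as_array()).max(axis=1)
    return float(best.mean())
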