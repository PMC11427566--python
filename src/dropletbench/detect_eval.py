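"""Detection-box primitives and evaluation.

Boxes are center-format ``(cx, cy, w, h)`` in continuous pixel coordinates,
each carrying a class label and a confidence in ``[0, 1]``.  On top of them
the module provides intersection-over-union, class-wise greedy non-maximum
suppression, confidence-ordered matching against ground truth,
precision/recall curves with all-point-interpolated average precision
(and mAP over the 0.50:0.95 IoU ladder), and detection confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetBox",
    "MatchOutcome",
    "PRCurve",
    "iou",
    "nms",
    "match",
    "average_precision",
    "mean_average_precision",
    "confusion_matrix",
]

IOU_LADDER = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class DetBox:
    """Center-format bounding box with class label and confidence."""

    cx: float
    cy: float
    w: float
    h: float
    cls: str = "droplet"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width and height must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) corner representation; exact inverse of from_corners."""
        return (self.cx - self.w / 2, self.cy - self.h / 2, self.cx + self.w / 2, self.cy + self.h / 2)

    @classmethod
    def from_corners(
        cls, x1: float, y1: float, x2: float, y2: float, label: str = "droplet", confidence: float = 1.0
    ) -> "DetBox":
        return cls(cx=(x1 + x2) / 2, cy=(y1 + y2) / 2, w=x2 - x1, h=y2 - y1, cls=label, confidence=confidence)


@dataclass
class MatchOutcome:
    """Per-class TP/FP/FN tallies plus the matched (pred, gt, iou) pairs."""

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def totals(self) -> tuple[int, int, int]:
        return sum(self.tp.values()), sum(self.fp.values()), sum(self.fn.values())


@dataclass
class PRCurve:
    """Precision/recall swept over descending confidence thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    ap: float


def iou(a: DetBox, b: DetBox) -> float:
    """Intersection-over-union of two boxes in continuous coordinates."""
    ax1, ay1, ax2, ay2 = a.to_corners()
    bx1, by1, bx2, by2 = b.to_corners()
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def _conf_order(boxes: list[DetBox]) -> list[int]:
    # descending confidence, stable in input order on ties
    return sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))


def nms(boxes: list[DetBox], iou_threshold: float = 0.45) -> list[DetBox]:
    """Class-wise greedy non-maximum suppression.

    Boxes are visited in descending confidence; a box is kept iff its IoU
    with every already-kept box of the same class is ``<= iou_threshold``.
    Output preserves the kept (confidence) order.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in [0, 1]")
    kept: list[DetBox] = []
    for i in _conf_order(boxes):
        b = boxes[i]
        if all(iou(b, k) <= iou_threshold for k in kept if k.cls == b.cls):
            kept.append(b)
    return kept


def match(preds: list[DetBox], gts: list[DetBox], iou_threshold: float = 0.5) -> MatchOutcome:
    """Greedy one-to-one matching of predictions to ground truth on one image.

    Predictions are visited in descending confidence; each takes the
    still-unmatched same-class ground truth of highest IoU ``>= threshold``
    (ties broken by lower ground-truth index).
    """
    classes = sorted({b.cls for b in preds} | {b.cls for b in gts})
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    gt_taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    for pi in _conf_order(preds):
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if gt_taken[j] or g.cls != p.cls:
                continue
            v = iou(p, g)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            tp[p.cls] += 1
            pairs.append((pi, best_j, best_iou))
        else:
            fp[p.cls] += 1
    for j, g in enumerate(gts):
        if not gt_taken[j]:
            fn[g.cls] += 1
    return MatchOutcome(tp=tp, fp=fp, fn=fn, pairs=pairs)


def _ap_from_flags(flags: np.ndarray, n_gt: int, n_points: int | None) -> tuple[np.ndarray, np.ndarray, float]:
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (non-increasing from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if n_points is None:
        # all-point interpolation: area under the envelope vs recall
        r = np.concatenate(([0.0], recall))
        ap = float(np.sum((r[1:] - r[:-1]) * env))
    else:
        levels = np.linspace(0.0, 1.0, n_points)
        interp = np.array([env[recall >= lv].max() if np.any(recall >= lv) else 0.0 for lv in levels])
        ap = float(interp.mean())
    return precision, recall, ap


def average_precision(
    image_boxes: list[tuple[list[DetBox], list[DetBox]]],
    cls: str,
    iou_threshold: float = 0.5,
    n_points: int | None = None,
) -> PRCurve:
    """Average precision for one class over a set of images.

    ``image_boxes`` is a list of ``(predictions, ground_truths)`` per image.
    Predictions are matched greedily in global descending-confidence order,
    one-to-one within each image.  AP is the area under the precision
    envelope versus recall (all-point interpolation); pass ``n_points=101``
    for the COCO-style fixed-grid variant.
    """
    n_gt = sum(sum(1 for g in gts if g.cls == cls) for _, gts in image_boxes)
    if n_gt == 0:
        raise ValueError(f"class {cls!r} absent from ground truth; AP undefined")
    records: list[tuple[float, int, int]] = []  # (confidence, image index, pred index)
    for ii, (preds, _) in enumerate(image_boxes):
        for pi, p in enumerate(preds):
            if p.cls == cls:
                records.append((p.confidence, ii, pi))
    if not records:
        return PRCurve(np.array([]), np.array([]), np.array([]), 0.0)
    records.sort(key=lambda r: (-r[0], r[1], r[2]))
    taken = [[False] * len(gts) for _, gts in image_boxes]
    flags = np.zeros(len(records), dtype=bool)
    for k, (_, ii, pi) in enumerate(records):
        preds, gts = image_boxes[ii]
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[ii][j] or g.cls != cls:
                continue
            v = iou(p, g)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[ii][best_j] = True
            flags[k] = True
    precision, recall, ap = _ap_from_flags(flags, n_gt, n_points)
    return PRCurve(
        thresholds=np.array([r[0] for r in records]),
        precision=precision,
        recall=recall,
        ap=ap,
    )


def mean_average_precision(
    image_boxes: list[tuple[list[DetBox], list[DetBox]]],
    classes: list[str] | None = None,
    iou_thresholds: tuple[float, ...] = IOU_LADDER,
    n_points: int | None = None,
) -> float:
    """mAP: AP averaged over classes and the given IoU thresholds (default 0.50:0.95)."""
    if classes is None:
        classes = sorted({g.cls for _, gts in image_boxes for g in gts})
    if not classes:
        raise ValueError("no ground-truth classes to evaluate")
    aps = [
        average_precision(image_boxes, c, t, n_points=n_points).ap for c in classes for t in iou_thresholds
    ]
    return float(np.mean(aps))


def confusion_matrix(
    preds: list[DetBox],
    gts: list[DetBox],
    classes: list[str] | None = None,
    iou_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Detection confusion matrix at a fixed IoU threshold.

    Boxes are matched greedily by confidence on IoU alone (class-agnostic)
    so that class confusions land off-diagonal; unmatched predictions count
    against the ``background`` column, unmatched ground truths against the
    ``background`` row.  Returns the matrix (rows = predicted class, columns
    = true class) and per-class precision/recall percentages.
    """
    if classes is None:
        classes = sorted({b.cls for b in preds} | {b.cls for b in gts})
    labels = list(classes) + ["background"]
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    gt_taken = [False] * len(gts)
    for pi in _conf_order(preds):
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if gt_taken[j]:
                continue
            v = iou(p, g)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            table.loc[p.cls, gts[best_j].cls] += 1
        else:
            table.loc[p.cls, "background"] += 1
    for j, g in enumerate(gts):
        if not gt_taken[j]:
            table.loc["background", g.cls] += 1
    metrics: dict[str, dict[str, float]] = {}
    for c in classes:
        tp = int(table.loc[c, c])
        fp = int(table.loc[c].sum()) - tp
        fn = int(table[c].sum()) - tp
        precision = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
        recall = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        metrics[c] = {"precision": precision, "recall": recall}
    return table, metrics
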