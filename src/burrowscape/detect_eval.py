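"""Object-detection evaluation for mound detectors, plus a classical baseline.

Matching follows the usual detection-benchmark rules: predictions are
taken in descending score order and greedily matched to the unmatched
ground-truth box of highest overlap, with a true positive requiring
IoU strictly greater than the threshold (default 0.5; an overlap of
exactly 0.5 counts as a false positive). A second detection of an
already-matched truth is a false positive ("detected more than once");
unmatched truths are false negatives. Precision, recall and F1 come
from pooled counts; F1 = 2TP/(2TP+FP+FN) is identically the harmonic
mean of precision and recall. Average precision is the all-point
interpolated area under the precision-recall curve (precision envelope,
PASCAL-VOC-2010 style) at a single IoU threshold.

The baseline detector is a thresholded connected-component blob finder
with a physical size prior (mound diameter 0.15-0.50 m), standing in
for a trained network so the pipeline runs end to end on synthetic
imagery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "DetectionBox",
    "DetectionMetrics",
    "MatchResult",
    "iou",
    "match_detections",
    "evaluate",
    "evaluate_tiles",
    "average_precision",
    "baseline_blob_detector",
]


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned box in pixel coordinates, half-open [xmin, xmax) x [ymin, ymax).

    Origin is the image top-left; ``score`` is a confidence in [0, 1]
    for predictions and ``None`` for ground truth.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate box {self}")
        if self.score is not None and not 0 <= self.score <= 1:
            raise ValueError("score must be in [0, 1]")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    # index pairs (pred_idx, truth_idx) of matches, pred indices in input order
    assignment: list[tuple[int, int]]
    # per-prediction TP flags in descending-score order, for AP sweeping
    pred_order: list[int]
    pred_is_tp: list[bool]


def match_detections(
    preds: Sequence[DetectionBox],
    truths: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy score-ordered matching of predictions to ground truth.

    Ties in score are broken by xmin then ymin so that matching is
    deterministic. A prediction whose best unmatched truth has IoU
    <= ``iou_threshold`` — or whose candidates are all matched already —
    is a false positive.
    """
    order = sorted(
        range(len(preds)),
        key=lambda i: (-(preds[i].score if preds[i].score is not None else 1.0),
                       preds[i].xmin, preds[i].ymin),
    )
    matched_truth = [False] * len(truths)
    assignment: list[tuple[int, int]] = []
    pred_is_tp: list[bool] = []
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j, t in enumerate(truths):
            if matched_truth[j]:
                continue
            v = iou(preds[i], t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_truth[best_j] = True
            assignment.append((i, best_j))
            pred_is_tp.append(True)
        else:
            pred_is_tp.append(False)
    tp = len(assignment)
    return MatchResult(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(truths) - tp,
        assignment=assignment,
        pred_order=order,
        pred_is_tp=pred_is_tp,
    )


@dataclass
class DetectionMetrics:
    """Pooled detection metrics at one IoU threshold.

    Ratios are NaN ("undefined"), not zero, when their denominator is
    empty — e.g. precision with no predictions.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    average_precision: float
    iou_threshold: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "average_precision": self.average_precision,
            "iou_threshold": self.iou_threshold,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def average_precision(scores: np.ndarray, is_tp: np.ndarray, n_truth: int) -> float:
    """All-point interpolated AP from per-prediction scores and TP flags.

    Predictions are swept in descending score order; precision is
    replaced by its running maximum from the right (the envelope) and
    integrated over recall. Invariant to strictly monotone score
    transformations, since only the order enters.
    """
    if n_truth == 0:
        return float("nan")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    tp_cum = np.cumsum(np.asarray(is_tp, dtype=float)[order])
    fp_cum = np.cumsum(1.0 - np.asarray(is_tp, dtype=float)[order])
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def evaluate(
    preds: Sequence[DetectionBox],
    truths: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
) -> DetectionMetrics:
    """Evaluate predictions against truth on a single image."""
    return evaluate_tiles([(preds, truths)], iou_threshold)


def evaluate_tiles(
    tiles: Sequence[tuple[Sequence[DetectionBox], Sequence[DetectionBox]]],
    iou_threshold: float = 0.5,
) -> DetectionMetrics:
    """Match per tile, pool counts, and compute pooled metrics and AP."""
    tp = fp = fn = 0
    all_scores: list[float] = []
    all_flags: list[bool] = []
    n_truth = 0
    for preds, truths in tiles:
        m = match_detections(preds, truths, iou_threshold)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        n_truth += len(truths)
        for rank, i in enumerate(m.pred_order):
            s = preds[i].score
            all_scores.append(s if s is not None else 1.0)
            all_flags.append(m.pred_is_tp[rank])
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    ap = average_precision(np.array(all_scores), np.array(all_flags), n_truth)
    m = DetectionMetrics(tp, fp, fn, precision, recall, f1, ap, iou_threshold)
    # harmonic-mean identity, asserted on every evaluation
    if not (math.isnan(m.precision) or math.isnan(m.recall)) and m.precision + m.recall > 0:
        hm = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert abs(m.f1 - hm) < 1e-12, "F1 != harmonic mean of precision and recall"
    return m


def baseline_blob_detector(
    image: np.ndarray,
    gsd: float,
    diameter_range: tuple[float, float] = (0.15, 0.50),
    contrast_threshold: float = 0.1,
    background_quantile: float = 0.99,
    size_tolerance: float = 0.5,
) -> list[DetectionBox]:
    """Classical bright-blob detector with a physical size prior.

    The image is thresholded at a robust estimate of the
    ``background_quantile`` background quantile (median plus the
    matching normal deviate times the MAD-based sigma, so bright
    objects cannot drag the estimate up) plus ``contrast_threshold``
    (image units); connected components
    whose equivalent diameter falls within ``diameter_range`` (metres,
    converted through ``gsd`` and widened by ``size_tolerance`` as a
    relative margin to absorb rasterisation) become detections. The
    score is the component's mean brightness excess over the threshold,
    normalised to [0, 1] across components.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-band image")
    if img.size == 0 or not np.any(img > img.min()):
        return []
    from scipy import stats as _stats

    med = float(np.median(img))
    sigma = 1.4826 * float(np.median(np.abs(img - med)))
    thr = med + float(_stats.norm.ppf(background_quantile)) * sigma + contrast_threshold
    mask = img > thr
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    lo = diameter_range[0] / gsd * (1 - size_tolerance)
    hi = diameter_range[1] / gsd * (1 + size_tolerance)
    boxes = []
    raw_scores = []
    for rp in measure.regionprops(labels, intensity_image=img):
        if not lo <= rp.equivalent_diameter_area <= hi:
            continue
        r0, c0, r1, c1 = rp.bbox  # already half-open
        boxes.append((c0, r0, c1, r1))
        raw_scores.append(rp.intensity_mean - thr)
    if not boxes:
        return []
    s = np.asarray(raw_scores)
    smax = s.max()
    scores = s / smax if smax > 0 else np.full_like(s, 0.5)
    return [
        DetectionBox(float(x0), float(y0), float(x1), float(y1), score=float(sc))
        for (x0, y0, x1, y1), sc in zip(boxes, np.clip(scores, 0.0, 1.0))
    ]
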