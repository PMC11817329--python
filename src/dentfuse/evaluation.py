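"""Detection metrics: matching, precision/recall/F1, PR curves, AP, mAP@0.5.

A prediction counts as a true positive when it overlaps an unclaimed
ground-truth box of the same class with IoU >= 0.5 (inclusive).  Matching is
greedy in descending confidence with one-to-one ground-truth assignment — the
standard PASCAL/COCO discipline.  AP is the area under the precision envelope
of the PR sweep (all-point interpolation); an 11-point variant is available
for comparison.  mAP@0.5 is the unweighted mean of per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import Detection, GroundTruthBox, iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "EvalReport",
    "match_detections",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "map50",
    "operating_point",
    "evaluate",
]


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN counts for one matching pass, with the matched pairs."""

    tp: int
    fp: int
    fn: int
    matched_pairs: tuple[tuple[Detection, GroundTruthBox, float], ...]

    def __post_init__(self) -> None:
        assert self.tp == len(self.matched_pairs)


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall pairs swept over descending confidence cutoffs.

    ``points[i]`` is the ``(recall, precision)`` obtained by keeping every
    prediction with confidence >= ``thresholds[i]``; recall is non-decreasing
    along the list.
    """

    points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]


@dataclass(frozen=True)
class EvalReport:
    """Per-class AP, their mean (mAP@0.5), and operating-point P/R/F1."""

    per_class_ap: Mapping[int, float]
    map50: float
    precision: float
    recall: float
    f1: float
    operating_threshold: float


def match_detections(
    preds: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of one image's predictions to ground truth.

    Predictions are visited in descending confidence; each claims the not-yet
    -matched same-class ground truth with the highest IoU, provided that IoU
    meets ``iou_threshold``.  Unmatched predictions are FP, unmatched ground
    truths FN.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    claimed = [False] * len(gts)
    pairs: list[tuple[Detection, GroundTruthBox, float]] = []
    for i in order:
        pred = preds[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if claimed[j] or gt.label != pred.label:
                continue
            overlap = iou(pred.box, gt.box)
            if overlap > best_iou:
                best_iou, best_j = overlap, j
        if best_j >= 0 and best_iou >= iou_threshold:
            claimed[best_j] = True
            pairs.append((pred, gts[best_j], best_iou))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, matched_pairs=tuple(pairs)
    )


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), with the zero-count
    conventions P=0, R=0, F1=0 where the denominators vanish."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _flags_per_prediction(
    preds_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[GroundTruthBox]],
    iou_threshold: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Global confidence-ordered TP flags for the PR sweep.

    Matching is greedy per image in global confidence order, so the ranked TP
    flags at any cutoff agree with matching only the predictions above it.
    Returns (confidences desc, tp flags, number of ground truths).
    """
    n_gt = sum(len(v) for v in gts_by_image.values())
    ranked: list[tuple[float, str, int]] = []  # (conf, image, idx in image)
    for iid, preds in preds_by_image.items():
        for k, det in enumerate(preds):
            ranked.append((det.confidence, iid, k))
    ranked.sort(key=lambda t: -t[0])

    claimed = {iid: [False] * len(gts) for iid, gts in gts_by_image.items()}
    confs = np.empty(len(ranked))
    flags = np.zeros(len(ranked), dtype=bool)
    for i, (conf, iid, k) in enumerate(ranked):
        confs[i] = conf
        pred = preds_by_image[iid][k]
        gts = gts_by_image.get(iid, ())
        taken = claimed.get(iid, [])
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if taken[j] or gt.label != pred.label:
                continue
            overlap = iou(pred.box, gt.box)
            if overlap > best_iou:
                best_iou, best_j = overlap, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            flags[i] = True
    return confs, flags, n_gt


def pr_curve(
    preds_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[GroundTruthBox]],
    iou_threshold: float = 0.5,
) -> PRCurve:
    """Sweep the confidence cutoff over all distinct prediction confidences,
    computing cumulative precision and recall against fixed ground truth."""
    confs, flags, n_gt = _flags_per_prediction(
        preds_by_image, gts_by_image, iou_threshold
    )
    if n_gt == 0:
        raise ValueError("no ground-truth boxes: recall is undefined")
    if len(confs) == 0:
        return PRCurve(points=(), thresholds=())
    cum_tp = np.cumsum(flags)
    cum_fp = np.cumsum(~flags)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # duplicate confidences collapse onto their last (most inclusive) entry
    keep = np.ones(len(confs), dtype=bool)
    keep[:-1] = confs[:-1] != confs[1:]
    points = tuple(zip(recall[keep].tolist(), precision[keep].tolist()))
    return PRCurve(points=points, thresholds=tuple(confs[keep].tolist()))


def average_precision(curve: PRCurve, *, eleven_point: bool = False) -> float:
    """Area under the precision envelope of the PR curve.

    All-point interpolation: replace precision by its running maximum over
    recalls to the right, then integrate over recall.  ``eleven_point``
    switches to the historical mean over recalls {0, 0.1, ..., 1.0}.
    """
    if not curve.points:
        return 0.0
    recall = np.array([r for r, _ in curve.points])
    precision = np.array([p for _, p in curve.points])
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([0.0], precision, [0.0]))
    # precision envelope: max over r' >= r
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    if eleven_point:
        grid = np.linspace(0.0, 1.0, 11)
        vals = [p[np.searchsorted(r, g, side="left")] if g <= r[-1] else 0.0 for g in grid]
        return float(np.mean(vals))
    steps = np.flatnonzero(r[1:] != r[:-1]) + 1
    return float(np.sum((r[steps] - r[steps - 1]) * p[steps]))


def map50(per_class_ap: Mapping[int, float]) -> float:
    """Unweighted mean of per-class AP values."""
    if not per_class_ap:
        raise ValueError("no classes to average")
    return float(np.mean(list(per_class_ap.values())))


def operating_point(
    curve: PRCurve,
    mode: str = "max_f1",
    threshold: float | None = None,
) -> tuple[float, float, float, float]:
    """Pick the single (precision, recall, f1, threshold) reported alongside
    the curve: the max-F1 sweep point (ties -> higher recall), or the sweep
    point at a fixed confidence cutoff."""
    if not curve.points:
        raise ValueError("empty PR curve")
    if mode == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold mode needs a threshold")
        best = None
        for (r, p), t in zip(curve.points, curve.thresholds):
            if t >= threshold:
                best = (p, r, t)
        if best is None:  # cutoff above every confidence: nothing kept
            return 0.0, 0.0, 0.0, threshold
        p, r, t = best
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f1, threshold
    if mode != "max_f1":
        raise ValueError(f"unknown operating-point mode {mode!r}")
    best_f1, best = -1.0, None
    for (r, p), t in zip(curve.points, curve.thresholds):
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1 or (f1 == best_f1 and best is not None and r > best[1]):
            best_f1, best = f1, (p, r, t)
    p, r, t = best
    return p, r, best_f1, t


def evaluate(
    preds_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[GroundTruthBox]],
    iou_threshold: float = 0.5,
    *,
    operating_mode: str = "max_f1",
    operating_threshold: float | None = None,
    eleven_point: bool = False,
) -> EvalReport:
    """Full evaluation: per-class AP, mAP@0.5 and operating-point P/R/F1.

    AP is computed per class from the class-restricted PR sweep; the
    operating point is taken from the class-pooled sweep so the P/R/F1 triple
    describes one detector operating threshold, as detection frameworks
    report it.
    """
    labels = sorted(
        {g.label for gts in gts_by_image.values() for g in gts}
    )
    per_class: dict[int, float] = {}
    for label in labels:
        p_sub = {
            iid: [d for d in preds if d.label == label]
            for iid, preds in preds_by_image.items()
        }
        g_sub = {
            iid: [g for g in gts if g.label == label]
            for iid, gts in gts_by_image.items()
        }
        curve = pr_curve(p_sub, g_sub, iou_threshold)
        per_class[label] = average_precision(curve, eleven_point=eleven_point)
    pooled = pr_curve(preds_by_image, gts_by_image, iou_threshold)
    if pooled.points:
        p, r, f1, thr = operating_point(
            pooled, mode=operating_mode, threshold=operating_threshold
        )
    else:
        p = r = f1 = 0.0
        thr = float("nan")
    return EvalReport(
        per_class_ap=per_class,
        map50=map50(per_class),
        precision=p,
        recall=r,
        f1=f1,
        operating_threshold=thr,
    )
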