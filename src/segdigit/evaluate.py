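"""Detection evaluation: IoU, greedy matching, precision/recall curves,
average precision (all-point interpolation) and mean FPS.

A detection is correct when its box overlaps a same-class ground-truth box
with IoU at or above a fixed threshold (default 0.5).  Detections are
matched greedily in order of descending confidence, one-to-one per frame;
the precision-recall curve is swept over the unique detection scores, and
AP integrates the monotone precision envelope over recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import BBox, Detection, GroundTruthBox

__all__ = [
    "MatchConfig",
    "MatchCounts",
    "PRCurve",
    "APResult",
    "MAPResult",
    "iou",
    "match_detections",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "mean_fps",
    "evaluate_detections",
]


@dataclass(frozen=True)
class MatchConfig:
    """IoU threshold deciding correctness; the PR sweep runs over scores."""

    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError(f"IoU threshold must be in (0, 1]: {self.iou_threshold}")


@dataclass
class MatchCounts:
    """TP/FP/FN/TN tallies for one class at one score threshold.

    TN is carried for completeness but is undefined for detection and
    unused by precision/recall.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class PRCurve:
    """(recall, precision) points in order of descending score threshold."""

    thresholds: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class APResult:
    label: int
    ap: float


@dataclass(frozen=True)
class MAPResult:
    map: float
    per_class: tuple[APResult, ...]


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two half-open boxes; 1 for identical
    boxes, 0 for disjoint boxes, symmetric."""
    ix = max(0, min(a.x + a.width, b.x + b.width) - max(a.x, b.x))
    iy = max(0, min(a.y + a.height, b.y + b.height) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    if union == 0:
        return 1.0 if inter == 0 and a.area == b.area == 0 else 0.0
    return inter / union


def _sorted_dets(dets: list[Detection]) -> list[Detection]:
    # descending score; ties broken by box (x, y) for determinism
    return sorted(dets, key=lambda d: (-d.score, d.bbox.x, d.bbox.y))


def _greedy_match(
    dets: list[Detection], gts: list[GroundTruthBox], tau: float
) -> list[bool]:
    """One-to-one greedy matching of score-sorted same-class detections to
    ground truths; returns a TP flag per sorted detection."""
    used = [False] * len(gts)
    flags: list[bool] = []
    for det in dets:
        best, best_iou = -1, tau
        for gi, gt in enumerate(gts):
            if used[gi] or gt.label != det.label:
                continue
            ov = iou(det.bbox, gt.bbox)
            if ov >= best_iou:
                best, best_iou = gi, ov
        if best >= 0:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def match_detections(
    dets: list[Detection],
    gts: list[GroundTruthBox],
    cfg: MatchConfig = MatchConfig(),
    score_min: float = 0.0,
) -> dict[int, MatchCounts]:
    """Per-class TP/FP/FN counts at a single score threshold."""
    labels = sorted({d.label for d in dets} | {g.label for g in gts})
    out: dict[int, MatchCounts] = {}
    for label in labels:
        cls_dets = _sorted_dets([d for d in dets if d.label == label and d.score >= score_min])
        cls_gts = [g for g in gts if g.label == label]
        flags = _greedy_match(cls_dets, cls_gts, cfg.iou_threshold)
        tp = sum(flags)
        out[label] = MatchCounts(tp=tp, fp=len(flags) - tp, fn=len(cls_gts) - tp)
    return out


def precision_recall(c: MatchCounts) -> tuple[float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN); 0/0 is defined as
    precision 1 (no wrong predictions made) and recall 0."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 1.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return precision, recall


def _pr_from_frames(
    per_frame: list[tuple[list[Detection], list[GroundTruthBox]]],
    cfg: MatchConfig,
    label: int | None = None,
) -> tuple[PRCurve, int]:
    """PR curve over a set of frames (detections only match ground truths
    of their own frame).  Returns the curve and the total GT count."""
    scored: list[tuple[float, bool, BBox]] = []
    n_gt = 0
    for dets, gts in per_frame:
        if label is not None:
            dets = [d for d in dets if d.label == label]
            gts = [g for g in gts if g.label == label]
        n_gt += len(gts)
        sdets = _sorted_dets(dets)
        flags = _greedy_match(sdets, gts, cfg.iou_threshold)
        scored.extend((d.score, f, d.bbox) for d, f in zip(sdets, flags))

    scored.sort(key=lambda t: (-t[0], t[2].x, t[2].y))
    curve = PRCurve()
    tp = fp = 0
    i = 0
    while i < len(scored):
        thr = scored[i][0]
        while i < len(scored) and scored[i][0] == thr:
            if scored[i][1]:
                tp += 1
            else:
                fp += 1
            i += 1
        curve.thresholds.append(thr)
        curve.precision.append(tp / (tp + fp))
        curve.recall.append(tp / n_gt if n_gt else 0.0)
    return curve, n_gt


def pr_curve(
    dets: list[Detection],
    gts: list[GroundTruthBox],
    cfg: MatchConfig = MatchConfig(),
    label: int | None = None,
) -> PRCurve:
    """Precision-recall curve for one frame's detections, swept over the
    sorted unique detection scores at a fixed IoU threshold."""
    curve, _ = _pr_from_frames([(dets, gts)], cfg, label)
    return curve


def average_precision(curve: PRCurve, label: int = 0) -> APResult:
    """Area under the PR curve with the monotone precision envelope
    (all-point interpolation): AP = sum over recall increments of
    increment x envelope precision."""
    if not curve.recall:
        return APResult(label=label, ap=0.0)
    mrec = np.concatenate([[0.0], np.asarray(curve.recall)])
    mpre = np.concatenate([[1.0], np.asarray(curve.precision)])
    # envelope: precision at recall r is the max precision at any r' >= r
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    ap = float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))
    return APResult(label=label, ap=ap)


def mean_average_precision(aps: list[APResult]) -> MAPResult:
    """Arithmetic mean of per-class APs."""
    if not aps:
        raise ValueError("mean over an empty AP list is undefined")
    return MAPResult(map=float(np.mean([a.ap for a in aps])), per_class=tuple(aps))


def mean_fps(samples: list[float]) -> float:
    """Mean of per-frame FPS samples."""
    if len(samples) == 0:
        raise ValueError("mFPS of an empty sample list is undefined")
    return float(np.mean(samples))


def evaluate_detections(
    per_frame: list[tuple[list[Detection], list[GroundTruthBox]]],
    cfg: MatchConfig = MatchConfig(),
) -> MAPResult:
    """mAP over all digit classes present in the ground truth of a stream
    of (detections, ground truths) frame pairs."""
    labels = sorted({g.label for _, gts in per_frame for g in gts})
    if not labels:
        raise ValueError("no ground-truth boxes to evaluate against")
    aps = []
    for label in labels:
        curve, _ = _pr_from_frames(per_frame, cfg, label)
        aps.append(average_precision(curve, label=label))
    return mean_average_precision(aps)
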