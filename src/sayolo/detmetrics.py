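"""Object-detection evaluation: greedy matching, P/R/F1, AP and mAP.

Detections are matched to ground truth greedily within each
(image, class) group: detections are visited in order of descending
confidence and claim the unmatched ground-truth box of highest IoU at
or above the IoU threshold (ties broken toward the lowest ground-truth
index).  From the resulting TP/FP flags the module computes precision,
recall, F1, the 101-point interpolated average precision (the COCO
convention) and its means over classes and IoU thresholds (mAP0.5 and
mAP0.5-0.95).

Degenerate-count conventions: precision with ``TP+FP = 0``, recall with
``TP+FN = 0`` and F1 with ``P+R = 0`` are all defined as 0 so that
metrics never propagate NaN.  AP for a class with no ground truth is
*undefined* and reported as absent rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

from .boxgeom import Box, BoxPair, iou

__all__ = [
    "DetectionRecord",
    "GroundTruthRecord",
    "PRPoint",
    "MatchResult",
    "match",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "COCO_THRESHOLDS",
    "read_detections",
    "read_ground_truths",
    "write_detections",
    "write_ground_truths",
]

COCO_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))


@dataclass(frozen=True)
class DetectionRecord:
    """A scored predicted box for one image and class."""

    image_id: Hashable
    class_id: Hashable
    score: float
    box: Box

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class GroundTruthRecord:
    """A reference box for one image and class."""

    image_id: Hashable
    class_id: Hashable
    box: Box


@dataclass(frozen=True)
class PRPoint:
    precision: float
    recall: float
    threshold: float


@dataclass(frozen=True)
class MatchResult:
    """Per-detection TP/FP flags plus per-ground-truth matched flags.

    ``det_order`` gives the indices of the input detections in the
    deterministic evaluation order (descending score, input order as
    tie-break); ``tp``/``fp`` align with that order.
    """

    det_order: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    gt_matched: np.ndarray

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int(self.fp.sum())

    @property
    def n_fn(self) -> int:
        return int((~self.gt_matched).sum())


def _det_sort_order(dets: Sequence[DetectionRecord]) -> np.ndarray:
    scores = np.array([d.score for d in dets], dtype=float)
    # stable sort on -score keeps input order among equal scores
    return np.argsort(-scores, kind="stable")


def match(
    dets: Sequence[DetectionRecord],
    gts: Sequence[GroundTruthRecord],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy score-ordered matching of detections to ground truth.

    Only records sharing image and class can match; each ground-truth
    box is claimed at most once.
    """
    order = _det_sort_order(dets)
    tp = np.zeros(len(dets), dtype=bool)
    gt_matched = np.zeros(len(gts), dtype=bool)

    gt_index: dict[tuple[Hashable, Hashable], list[int]] = {}
    for j, g in enumerate(gts):
        gt_index.setdefault((g.image_id, g.class_id), []).append(j)

    for rank, i in enumerate(order):
        d = dets[i]
        best_j, best_iou = -1, -1.0
        for j in gt_index.get((d.image_id, d.class_id), ()):
            if gt_matched[j]:
                continue
            ov = iou(BoxPair(pred=d.box, gt=gts[j].box))
            if ov < iou_threshold:
                continue
            # strict > keeps the lowest-index ground truth on ties
            if ov > best_iou:
                best_j, best_iou = j, ov
        if best_j >= 0:
            gt_matched[best_j] = True
            tp[rank] = True
    return MatchResult(det_order=order, tp=tp, fp=~tp, gt_matched=gt_matched)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def pr_curve(
    dets: Sequence[DetectionRecord],
    gts: Sequence[GroundTruthRecord],
    iou_threshold: float = 0.5,
) -> list[PRPoint]:
    """Precision/recall points swept over the detection scores.

    One point per rank of the score-ordered detection list, i.e. the
    curve obtained by lowering the confidence cut through every
    detection score.
    """
    res = match(dets, gts, iou_threshold)
    n_gt = len(gts)
    points: list[PRPoint] = []
    tp_cum = fp_cum = 0
    for rank, i in enumerate(res.det_order):
        tp_cum += int(res.tp[rank])
        fp_cum += int(res.fp[rank])
        p = tp_cum / (tp_cum + fp_cum)
        r = tp_cum / n_gt if n_gt else 0.0
        points.append(PRPoint(precision=p, recall=r, threshold=dets[i].score))
    return points


def _ap_from_curve(precisions: np.ndarray, recalls: np.ndarray) -> float:
    """101-point interpolated AP from a PR curve (COCO convention)."""
    if len(precisions) == 0:
        return 0.0
    # precision envelope: best precision at recall >= each sample point
    order = np.argsort(recalls, kind="stable")
    rec = recalls[order]
    prec = precisions[order]
    env = np.maximum.accumulate(prec[::-1])[::-1]
    sample_recalls = np.linspace(0.0, 1.0, 101)
    # for each sampled recall, the envelope at the first curve point
    # with recall >= sample (0 beyond the curve's maximum recall)
    idx = np.searchsorted(rec, sample_recalls, side="left")
    sampled = np.where(idx < len(rec), env[np.minimum(idx, len(rec) - 1)], 0.0)
    return float(sampled.mean())


def average_precision(
    dets: Sequence[DetectionRecord],
    gts: Sequence[GroundTruthRecord],
    iou_threshold: float = 0.5,
) -> float | None:
    """101-point interpolated AP; ``None`` when there is no ground truth."""
    if not gts:
        return None
    points = pr_curve(dets, gts, iou_threshold)
    return _ap_from_curve(
        np.array([p.precision for p in points]),
        np.array([p.recall for p in points]),
    )


def mean_ap(
    dets: Sequence[DetectionRecord],
    gts: Sequence[GroundTruthRecord],
    thresholds: Iterable[float] = (0.5,),
) -> tuple[float, dict[Hashable, float]]:
    """Mean AP over the classes present in the ground truth.

    Returns ``(mAP, per_class)`` where ``per_class`` maps each class to
    its AP averaged over the requested IoU thresholds.  ``thresholds=
    COCO_THRESHOLDS`` yields mAP0.5-0.95.
    """
    thresholds = tuple(thresholds)
    classes = sorted({g.class_id for g in gts}, key=str)
    if not classes:
        raise ValueError("ground-truth set must contain at least one class")
    per_class: dict[Hashable, float] = {}
    for cls in classes:
        cls_dets = [d for d in dets if d.class_id == cls]
        cls_gts = [g for g in gts if g.class_id == cls]
        aps = [average_precision(cls_dets, cls_gts, t) for t in thresholds]
        per_class[cls] = float(np.mean([a for a in aps]))
    return float(np.mean(list(per_class.values()))), per_class


# ---------------------------------------------------------------------------
# plain-text record I/O
# ---------------------------------------------------------------------------
# detections:    image_id class_id score cx cy w h
# ground truths: image_id class_id cx cy w h

def read_detections(path) -> list[DetectionRecord]:
    records: list[DetectionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 'image_id class_id score cx cy w h'"
                )
            img, cls, score, cx, cy, w, h = parts
            records.append(
                DetectionRecord(
                    image_id=img,
                    class_id=cls,
                    score=float(score),
                    box=Box(float(cx), float(cy), float(w), float(h)),
                )
            )
    return records


def read_ground_truths(path) -> list[GroundTruthRecord]:
    records: list[GroundTruthRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 'image_id class_id cx cy w h'"
                )
            img, cls, cx, cy, w, h = parts
            records.append(
                GroundTruthRecord(
                    image_id=img,
                    class_id=cls,
                    box=Box(float(cx), float(cy), float(w), float(h)),
                )
            )
    return records


def write_detections(path, dets: Iterable[DetectionRecord]) -> None:
    with open(path, "w") as fh:
        for d in dets:
            b = d.box
            fh.write(
                f"{d.image_id} {d.class_id} {d.score:.6f} "
                f"{b.cx:.6g} {b.cy:.6g} {b.w:.6g} {b.h:.6g}\n"
            )


def write_ground_truths(path, gts: Iterable[GroundTruthRecord]) -> None:
    with open(path, "w") as fh:
        for g in gts:
            b = g.box
            fh.write(
                f"{g.image_id} {g.class_id} {b.cx:.6g} {b.cy:.6g} {b.w:.6g} {b.h:.6g}\n"
            )
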