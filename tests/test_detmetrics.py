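import numpy as np
import pytest

from sayolo.boxgeom import Box
from sayolo.detmetrics import (
    COCO_THRESHOLDS,
    DetectionRecord,
    GroundTruthRecord,
    average_precision,
    match,
    mean_ap,
    precision_recall_f1,
    read_detections,
    read_ground_truths,
    write_detections,
    write_ground_truths,
)

# ---------------------------------------------------------------------------
# independent oracle: corner-arithmetic IoU, loop-based greedy matching and
# exhaustive threshold-enumeration 101-point AP
# ---------------------------------------------------------------------------


def oracle_iou(a: Box, b: Box) -> float:
    iw = min(a.right, b.right) - max(a.left, b.left)
    ih = min(a.bottom, b.bottom) - max(a.top, b.top)
    inter = max(iw, 0.0) * max(ih, 0.0)
    return inter / (a.area + b.area - inter)


def oracle_match_counts(dets, gts, thr):
    taken = [False] * len(gts)
    tp = 0
    for d in sorted(dets, key=lambda d: -d.score):
        best, best_iou = None, -1.0
        for j, g in enumerate(gts):
            if taken[j] or g.image_id != d.image_id or g.class_id != d.class_id:
                continue
            ov = oracle_iou(d.box, g.box)
            if ov >= thr and ov > best_iou:
                best, best_iou = j, ov
        if best is not None:
            taken[best] = True
            tp += 1
    return tp


def oracle_ap(dets, gts, thr):
    """Re-match from scratch at every distinct score cut, then sample the
    precision envelope at 101 recall points."""
    points = []
    for cut in sorted({d.score for d in dets}, reverse=True):
        sub = [d for d in dets if d.score >= cut]
        tp = oracle_match_counts(sub, gts, thr)
        points.append((tp / len(gts), tp / len(sub)))
    total = 0.0
    for r_s in np.linspace(0, 1, 101):
        total += max((p for r, p in points if r >= r_s - 1e-12), default=0.0)
    return total / 101


def random_records(rng, n_gt=4, n_det=6):
    images = ["a", "b"]
    classes = ["c0", "c1"]
    gts = [
        GroundTruthRecord(
            image_id=str(rng.choice(images)),
            class_id=str(rng.choice(classes)),
            box=Box(*rng.uniform(5, 45, 2), *rng.uniform(3, 15, 2)),
        )
        for _ in range(n_gt)
    ]
    dets = []
    scores = rng.permutation(np.linspace(0.1, 0.9, n_det))  # distinct scores
    for s in scores:
        if rng.uniform() < 0.7 and gts:
            base = gts[int(rng.integers(len(gts)))]
            jitter = rng.normal(0, 3, 4)
            box = Box(
                base.box.cx + jitter[0],
                base.box.cy + jitter[1],
                max(base.box.w + jitter[2], 1),
                max(base.box.h + jitter[3], 1),
            )
            dets.append(
                DetectionRecord(base.image_id, base.class_id, float(s), box)
            )
        else:
            dets.append(
                DetectionRecord(
                    str(rng.choice(images)),
                    str(rng.choice(classes)),
                    float(s),
                    Box(*rng.uniform(5, 45, 2), *rng.uniform(3, 15, 2)),
                )
            )
    return dets, gts


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

GT = GroundTruthRecord("img", "cls", Box(10, 10, 6, 6))


class TestMatch:
    def test_single_exact_detection_is_tp(self):
        dets = [DetectionRecord("img", "cls", 0.9, Box(10, 10, 6, 6))]
        res = match(dets, [GT], 0.5)
        assert (res.n_tp, res.n_fp, res.n_fn) == (1, 0, 0)

    def test_duplicate_detection_is_fp(self):
        dets = [
            DetectionRecord("img", "cls", 0.9, Box(10, 10, 6, 6)),
            DetectionRecord("img", "cls", 0.7, Box(10.5, 10, 6, 6)),
        ]
        res = match(dets, [GT], 0.5)
        assert (res.n_tp, res.n_fp, res.n_fn) == (1, 1, 0)
        # the higher-scored detection claims the box
        assert res.tp[0] and not res.tp[1]

    def test_missed_gt_is_fn(self):
        res = match([], [GT], 0.5)
        assert (res.n_tp, res.n_fp, res.n_fn) == (0, 0, 1)

    def test_class_and_image_must_agree(self):
        dets = [
            DetectionRecord("img", "other", 0.9, Box(10, 10, 6, 6)),
            DetectionRecord("img2", "cls", 0.9, Box(10, 10, 6, 6)),
        ]
        res = match(dets, [GT], 0.5)
        assert res.n_tp == 0 and res.n_fp == 2

    def test_order_permutation_invariant(self, rng):
        dets, gts = random_records(rng, n_gt=5, n_det=8)
        base = match(dets, gts, 0.5)
        perm = [dets[i] for i in rng.permutation(len(dets))]
        shuffled = match(perm, gts, 0.5)
        assert base.n_tp == shuffled.n_tp
        assert base.n_fp == shuffled.n_fp
        assert sorted(base.gt_matched) == sorted(shuffled.gt_matched)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (8, 2, 2, (0.8, 0.8, 0.8)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
            (1, 1, 0, (0.5, 1.0, 2 / 3)),
        ],
    )
    def test_examples(self, tp, fp, fn, expected):
        assert precision_recall_f1(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = [
            GroundTruthRecord("img", "cls", Box(10, 10, 6, 6)),
            GroundTruthRecord("img", "cls", Box(30, 30, 8, 8)),
        ]
        dets = [
            DetectionRecord("img", "cls", 0.9, Box(10, 10, 6, 6)),
            DetectionRecord("img", "cls", 0.8, Box(30, 30, 8, 8)),
        ]
        assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)

    def test_zero_tp_detector(self):
        dets = [DetectionRecord("img", "cls", 0.9, Box(40, 40, 2, 2))]
        assert average_precision(dets, [GT], 0.5) == pytest.approx(0.0)

    def test_empty_gt_reported_absent(self):
        dets = [DetectionRecord("img", "cls", 0.9, Box(10, 10, 6, 6))]
        assert average_precision(dets, [], 0.5) is None

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(100):
            dets, gts = random_records(
                rng, n_gt=int(rng.integers(1, 5)), n_det=int(rng.integers(1, 8))
            )
            got = average_precision(dets, gts, 0.5)
            assert got == pytest.approx(oracle_ap(dets, gts, 0.5), abs=1e-9)

    def test_duplicating_a_detection_never_raises_ap(self, rng):
        for _ in range(20):
            dets, gts = random_records(rng)
            base = average_precision(dets, gts, 0.5)
            dup = dets[int(rng.integers(len(dets)))]
            lowered = DetectionRecord(
                dup.image_id, dup.class_id, dup.score * 0.5, dup.box
            )
            assert average_precision(dets + [lowered], gts, 0.5) <= base + 1e-12


class TestMeanAP:
    def test_mean_over_classes(self, rng):
        dets, gts = random_records(rng, n_gt=6, n_det=9)
        m, per_class = mean_ap(dets, gts, thresholds=[0.5])
        assert m == pytest.approx(np.mean(list(per_class.values())))
        for cls, ap in per_class.items():
            cls_dets = [d for d in dets if d.class_id == cls]
            cls_gts = [g for g in gts if g.class_id == cls]
            assert ap == pytest.approx(average_precision(cls_dets, cls_gts, 0.5))

    def test_two_class_arithmetic_mean(self):
        gts = [
            GroundTruthRecord("img", "a", Box(10, 10, 6, 6)),
            GroundTruthRecord("img", "b", Box(30, 30, 6, 6)),
        ]
        dets = [
            DetectionRecord("img", "a", 0.9, Box(10, 10, 6, 6)),  # AP(a) = 1
            DetectionRecord("img", "b", 0.9, Box(50, 50, 2, 2)),  # AP(b) = 0
        ]
        m, per_class = mean_ap(dets, gts, thresholds=[0.5])
        assert per_class == {"a": pytest.approx(1.0), "b": pytest.approx(0.0)}
        assert m == pytest.approx(0.5)

    def test_strict_thresholds_never_help(self, rng):
        dets, gts = random_records(rng, n_gt=6, n_det=9)
        m50, _ = mean_ap(dets, gts, thresholds=[0.5])
        m5095, _ = mean_ap(dets, gts, thresholds=COCO_THRESHOLDS)
        assert m5095 <= m50 + 1e-12

    def test_all_metrics_in_unit_interval(self, rng):
        dets, gts = random_records(rng)
        m, per_class = mean_ap(dets, gts, thresholds=COCO_THRESHOLDS)
        assert 0.0 <= m <= 1.0
        assert all(0.0 <= ap <= 1.0 for ap in per_class.values())

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            mean_ap([], [], thresholds=[0.5])


class TestRecordIO:
    def test_round_trip(self, tmp_path, rng):
        dets, gts = random_records(rng)
        dpath, gpath = tmp_path / "dets.txt", tmp_path / "gts.txt"
        write_detections(dpath, dets)
        write_ground_truths(gpath, gts)
        dets2 = read_detections(dpath)
        gts2 = read_ground_truths(gpath)
        assert len(dets2) == len(dets) and len(gts2) == len(gts)
        for a, b in zip(dets, dets2):
            assert (a.image_id, a.class_id) == (b.image_id, b.class_id)
            assert b.score == pytest.approx(a.score, abs=1e-6)
            assert b.box.as_array() == pytest.approx(a.box.as_array(), rel=1e-5)

    def test_malformed_line_reported_with_location(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("img cls 0.5 1 2 3\n")
        with pytest.raises(ValueError, match="bad.txt:1"):
            read_detections(path)
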