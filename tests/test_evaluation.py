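"""Detection metrics: matching, P/R/F1, AP, sweeps, reports."""

import numpy as np
import pytest

from plateletdet.evaluation import (EvalCounts, ap_from_flags,
                                    comparison_report, f1, match_detections,
                                    pr_curve, precision, recall,
                                    threshold_sweep)
from plateletdet.geometry import Box, iou
from plateletdet.infer import Detection


def det(x0, y0, x1, y1, conf):
    return Detection(box=Box(x0, y0, x1, y1), confidence=conf)


def reference_match(dets, gts, thr):
    """Independent greedy matcher written as explicit loops."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    used = set()
    flags = []
    for i in order:
        best_j, best_iou = None, -1.0
        for j, g in enumerate(gts):
            if j in used:
                continue
            v = float(iou(dets[i].box, g))
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None and best_iou >= thr:
            used.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags


def reference_ap(flags, n_gt):
    """Prefix-enumeration oracle for the Riemann-sum AP."""
    total = 0.0
    tp = 0
    prev_recall = 0.0
    for k, flag in enumerate(flags, start=1):
        tp += int(flag)
        p_k = tp / k
        r_k = tp / n_gt
        total += p_k * (r_k - prev_recall)
        prev_recall = r_k
    return total


class TestMatchDetections:
    def test_exact_hit(self):
        flags, c = match_detections([det(0, 0, 10, 10, 0.9)],
                                    [Box(0, 0, 10, 10)])
        assert flags == [True]
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_double_detection_one_tp_one_fp(self):
        dets = [det(0, 0, 10, 10, 0.9), det(0, 0, 10, 10, 0.8)]
        _, c = match_detections(dets, [Box(0, 0, 10, 10)])
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_miss_is_fn(self):
        _, c = match_detections([], [Box(0, 0, 5, 5)])
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_count_identities(self, rng):
        for _ in range(30):
            n_d, n_g = rng.integers(0, 15, 2)
            dets = [det(x, y, x + 8, y + 8, float(rng.uniform()))
                    for x, y in rng.uniform(0, 60, (n_d, 2))]
            gts = [Box(x, y, x + 8, y + 8)
                   for x, y in rng.uniform(0, 60, (n_g, 2))]
            _, c = match_detections(dets, gts)
            assert c.tp + c.fn == len(gts)
            assert c.tp + c.fp == len(dets)

    def test_matches_reference_on_random_scenes(self, rng):
        for _ in range(200):
            n_d, n_g = int(rng.integers(0, 12)), int(rng.integers(0, 8))
            dets = [det(x, y, x + rng.uniform(4, 14), y + rng.uniform(4, 14),
                        float(rng.uniform()))
                    for x, y in rng.uniform(0, 50, (n_d, 2))]
            gts = [Box(x, y, x + rng.uniform(4, 14), y + rng.uniform(4, 14))
                   for x, y in rng.uniform(0, 50, (n_g, 2))]
            thr = float(rng.uniform(0.3, 0.7))
            got_flags, got_counts = match_detections(dets, gts, eval_iou=thr)
            want_flags = reference_match(dets, gts, thr)
            assert got_flags == want_flags
            assert got_counts.tp == sum(want_flags)


class TestPrf:
    def test_yolo_row_f1(self):
        # printed precision/recall imply 86% to the nearest whole percent
        assert round(100 * f1(0.8531, 0.8686)) == 86

    def test_faster_rcnn_row_f1(self):
        assert round(100 * f1(0.2708, 0.7417)) == 40

    def test_ssd_row_f1(self):
        assert round(100 * f1(0.8551, 0.0722)) == 13

    def test_counts_and_pair_forms_agree(self, rng):
        for _ in range(50):
            tp, fp, fn = (int(v) for v in rng.integers(0, 30, 3))
            c = EvalCounts(tp=tp, fp=fp, fn=fn)
            via_counts = f1(c)
            via_pair = f1(precision(c), recall(c))
            if tp > 0:
                assert via_counts == pytest.approx(via_pair, abs=1e-12)

    def test_balanced_half(self):
        c = EvalCounts(tp=5, fp=5, fn=5)
        assert precision(c) == recall(c) == f1(c) == 0.5

    def test_zero_denominators(self):
        c = EvalCounts()
        assert precision(c) == recall(c) == f1(c) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvalCounts(tp=-1)


class TestAveragePrecision:
    def test_single_correct_detection(self):
        assert ap_from_flags([True], 1) == pytest.approx(1.0)

    def test_tp_then_fp_still_one(self):
        assert ap_from_flags([True, False], 1) == pytest.approx(1.0)

    def test_fp_then_tp(self):
        # recall gained at precision 1/2
        assert ap_from_flags([False, True], 1) == pytest.approx(0.5)

    def test_zero_gt_defined_zero(self):
        assert ap_from_flags([True, False], 0) == 0.0

    def test_matches_prefix_oracle(self, rng):
        for _ in range(500):
            m = int(rng.integers(1, 40))
            flags = list(rng.random(m) < 0.4)
            n_gt = max(int(rng.integers(1, 20)), sum(flags))
            assert ap_from_flags(flags, n_gt) == pytest.approx(
                reference_ap(flags, n_gt), abs=1e-12)

    def test_bounds_and_perfection(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 20))
            flags = list(rng.random(m) < 0.5)
            n_gt = max(sum(flags), 1)
            v = ap_from_flags(flags, n_gt)
            assert 0.0 <= v <= 1.0 + 1e-12
        # all GTs recalled before any FP -> AP = 1
        assert ap_from_flags([True, True, False], 2) == pytest.approx(1.0)

    def test_curve_invariants(self, rng):
        flags = list(rng.random(25) < 0.5)
        n_gt = max(sum(flags), 1)
        curve = pr_curve(flags, n_gt)
        assert (np.diff(curve.recalls) >= 0).all()
        assert ((0 <= curve.precisions) & (curve.precisions <= 1)).all()
        assert curve.delta_r.sum() == pytest.approx(curve.recalls[-1])


class TestThresholdSweep:
    def _scene(self, rng, n=20):
        gts = [Box(x, y, x + 10, y + 10)
               for x, y in rng.uniform(0, 80, (6, 2))]
        dets = []
        for g in gts[:4]:  # 4 good detections
            dets.append(det(g.x_min + 1, g.y_min + 1, g.x_max + 1, g.y_max + 1,
                            float(rng.uniform(0.5, 1.0))))
        for _ in range(n - 4):  # noise
            x, y = rng.uniform(0, 80, 2)
            dets.append(det(x, y, x + 10, y + 10, float(rng.uniform(0, 0.6))))
        return dets, gts

    def test_threshold_above_max_conf_zero_recall(self, rng):
        dets, gts = self._scene(rng)
        sweep = threshold_sweep(dets, gts, thresholds=np.array([1.1]))
        assert sweep["recall"][0] == 0.0

    def test_recall_non_increasing(self, rng):
        dets, gts = self._scene(rng)
        sweep = threshold_sweep(dets, gts)
        assert (np.diff(sweep["recall"]) <= 1e-12).all()

    def test_f1_matches_recomputation(self, rng):
        from plateletdet.evaluation import match_detections as md
        dets, gts = self._scene(rng)
        sweep = threshold_sweep(dets, gts, thresholds=np.arange(0, 1.01, 0.1))
        for t, f in zip(sweep["thresholds"], sweep["f1"]):
            kept = [d for d in dets if d.confidence >= t]
            _, counts = md(kept, gts)
            assert f == pytest.approx(f1(counts), abs=1e-12)

    def test_precision_rises_on_monotone_fixture(self):
        # constructed so every high-confidence detection is correct
        gts = [Box(i * 20, 0, i * 20 + 10, 10) for i in range(5)]
        dets = [det(g.x_min, g.y_min, g.x_max, g.y_max, 0.9 - 0.02 * i)
                for i, g in enumerate(gts)]
        dets += [det(200 + i * 20, 50, 210 + i * 20, 60, 0.3 - 0.02 * i)
                 for i in range(5)]
        sweep = threshold_sweep(dets, gts, thresholds=np.array([0.1, 0.5]))
        assert sweep["precision"][1] >= sweep["precision"][0]


class TestComparisonReport:
    def test_single_run_single_row(self):
        text = comparison_report({"improved": {"ap": 0.8731, "f1": 0.88,
                                               "precision": 0.8906,
                                               "recall": 0.8731, "seconds": 4.07}})
        lines = text.strip().splitlines()
        assert len(lines) == 2
        assert lines[0].startswith("method")

    def test_values_roundtrip(self):
        run = {"ap": 0.1234, "f1": 0.5678, "precision": 0.9, "recall": 0.25,
               "seconds": 1.5}
        text = comparison_report({"m": run})
        fields = text.strip().splitlines()[1].split("\t")
        assert fields[1:] == ["0.1234", "0.5678", "0.9000", "0.2500", "1.5000"]

    def test_f1_column_consistent_with_pr(self, rng):
        runs = {}
        for i in range(5):
            tp, fp, fn = (int(v) + 1 for v in rng.integers(0, 40, 3))
            c = EvalCounts(tp=tp, fp=fp, fn=fn)
            runs[f"run{i}"] = {"ap": 0.5, "f1": f1(c), "precision": precision(c),
                               "recall": recall(c), "seconds": 0.0}
        text = comparison_report(runs)
        for line in text.strip().splitlines()[1:]:
            _, ap, f1_v, p, r, _ = line.split("\t")
            assert float(f1_v) == pytest.approx(f1(float(p), float(r)), abs=2e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            comparison_report({})


class TestImageAwareSweep:
    def test_pooled_counts_and_csv(self, rng):
        from plateletdet.evaluation import (sweep_to_csv,
                                            threshold_sweep_images)
        per_image = []
        for _ in range(3):
            gts = [Box(x, y, x + 10, y + 10)
                   for x, y in rng.uniform(0, 70, (4, 2))]
            dets = [det(g.x_min, g.y_min, g.x_max, g.y_max,
                        float(rng.uniform(0.4, 1.0))) for g in gts[:2]]
            per_image.append((dets, gts))
        sweep = threshold_sweep_images(per_image,
                                       thresholds=np.arange(0, 1.01, 0.25))
        assert (np.diff(sweep["recall"]) <= 1e-12).all()
        csv = sweep_to_csv(sweep)
        assert csv.splitlines()[0] == "threshold,precision,recall,f1"
        assert len(csv.splitlines()) == len(sweep["thresholds"]) + 1
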