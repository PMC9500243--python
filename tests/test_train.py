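"""Target assignment, loss, LR schedule, and training-loop smoke tests."""

import numpy as np
import pytest

from plateletdet import autodiff as ad
from plateletdet.anchors import AnchorSet, DEFAULT_ANCHORS, assign_scales
from plateletdet.geometry import Box, match_parameter
from plateletdet.model import DetectorConfig, build_detector
from plateletdet.train import (TrainConfig, assign_targets, compute_loss,
                               lr_at, train)

from conftest import random_boxes

GRIDS_160 = [(16, 10), (8, 20), (4, 40)]  # improved variant at input 160


class TestLrSchedule:
    def test_epoch_one_is_base(self):
        assert lr_at(1, TrainConfig()) == pytest.approx(1e-3)

    def test_epoch_two_decayed_once(self):
        assert lr_at(2, TrainConfig()) == pytest.approx(1e-3 * 0.92)

    def test_after_drop(self):
        assert lr_at(51, TrainConfig()) == pytest.approx(1e-4 * 0.92 ** 50)

    def test_non_increasing(self):
        cfg = TrainConfig()
        values = [lr_at(e, cfg) for e in range(1, 101)]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lr_at(0, TrainConfig())
        with pytest.raises(ValueError):
            lr_at(101, TrainConfig())

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_decay=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=10)  # default drop epoch 50 >= epochs


class TestAssignTargets:
    def test_exact_anchor_shape_selected(self):
        # GT shaped exactly like anchor (16, 18) -> that anchor's triple
        gt = [Box(50, 50, 66, 68)]
        targets = assign_targets(gt, DEFAULT_ANCHORS, GRIDS_160)
        total = sum(int(o.sum()) for o in targets.obj)
        assert total == 1
        # (16,18) sits in the middle area group -> middle model scale
        g = DEFAULT_ANCHORS.scale_groups
        anchor_idx = DEFAULT_ANCHORS.anchors.index((16, 18))
        group_idx = next(i for i, grp in enumerate(g) if anchor_idx in grp)
        model_scale = len(g) - 1 - group_idx
        assert targets.obj[model_scale].sum() == 1

    def test_two_gts_two_disjoint_positives(self):
        gt = [Box(10, 10, 20, 22), Box(100, 100, 112, 110)]
        targets = assign_targets(gt, DEFAULT_ANCHORS, GRIDS_160)
        assert sum(int(o.sum()) for o in targets.obj) == 2

    def test_positive_count_equals_gt_count(self, rng):
        for _ in range(10):
            gt = random_boxes(rng, 12, hi=150, integer=False)
            targets = assign_targets(gt, DEFAULT_ANCHORS, GRIDS_160)
            assert sum(int(o.sum()) for o in targets.obj) == len(gt)

    def test_matches_brute_force_argmax(self, rng):
        """Best anchor equals an explicit loop over all 9 match parameters."""
        anchors = DEFAULT_ANCHORS
        for _ in range(20):
            g = random_boxes(rng, 1, hi=150, integer=False)[0]
            targets = assign_targets([g], anchors, GRIDS_160)
            scores = []
            for w, h in anchors.anchors:
                a_box = Box(-w / 2, -h / 2, w / 2, h / 2)
                g_box = Box(-g.width / 2, -g.height / 2, g.width / 2, g.height / 2)
                scores.append(float(match_parameter(g_box, a_box)))
            best_global = int(np.argmax(scores))
            group_idx = next(i for i, grp in enumerate(anchors.scale_groups)
                             if best_global in grp)
            slot = anchors.scale_groups[group_idx].index(best_global)
            model_scale = 3 - 1 - group_idx
            stride, s = GRIDS_160[model_scale]
            cx, cy = g.center
            ci, ri = int(cx // stride), int(cy // stride)
            assert targets.obj[model_scale][slot, min(ri, s - 1), min(ci, s - 1)] == 1

    def test_center_outside_image_clipped(self, caplog):
        gt = [Box(170, 170, 190, 190)]  # outside a 160px image
        targets = assign_targets(gt, DEFAULT_ANCHORS, GRIDS_160)
        assert sum(int(o.sum()) for o in targets.obj) == 1


def _toy_setup(dtype=np.float64, n_gt=2, seed=0):
    """A tiny 2-cell-per-scale raw prediction + targets for loss tests."""
    anchors = assign_scales(AnchorSet(
        anchors=[(4, 4), (6, 8), (8, 6), (10, 10), (12, 16), (16, 12),
                 (20, 20), (24, 30), (30, 24)]), 3)
    grids = [(16, 2), (8, 4), (4, 8)]  # input 32
    strides = [16, 8, 4]
    rng = np.random.default_rng(seed)
    raw = [ad.Tensor(rng.standard_normal((1, 18, s, s)).astype(dtype) * 0.5,
                     requires_grad=True) for _, s in grids]
    gt = [Box(4, 4, 12, 12), Box(18, 16, 30, 28)][:n_gt]
    targets = assign_targets(gt, anchors, grids)
    return raw, targets, anchors, strides


class TestComputeLoss:
    def test_empty_gt_zero_box_and_cls(self):
        raw, _, anchors, strides = _toy_setup()
        empty = assign_targets([], anchors, [(16, 2), (8, 4), (4, 8)])
        total, comps = compute_loss(raw, [empty], anchors, strides)
        assert comps["box"] == 0.0 and comps["cls"] == 0.0
        assert comps["obj"] > 0.0

    def test_components_non_negative(self):
        raw, targets, anchors, strides = _toy_setup()
        _, comps = compute_loss(raw, [targets], anchors, strides)
        assert min(comps["box"], comps["obj"], comps["cls"]) >= 0.0

    def test_perfect_predictions_near_zero_loss(self):
        raw, targets, anchors, strides = _toy_setup()
        # overwrite raw data so decoded boxes hit targets and logits saturate
        for s_idx, t in enumerate(raw):
            data = np.full_like(t.data, -20.0)  # objectness/class strongly off
            n, ch, s, _ = data.shape
            data = data.reshape(1, 3, 6, s, s)
            stride = strides[s_idx]
            group = anchors.group_shapes(3 - 1 - s_idx)
            pos = np.nonzero(targets.obj[s_idx] == 1)
            for a_i, r_i, c_i in zip(*pos):
                box = targets.tbox[s_idx][a_i, r_i, c_i]
                cx, cy = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
                w, h = box[2] - box[0], box[3] - box[1]
                sig_x = cx / stride - c_i
                sig_y = cy / stride - r_i
                logit = lambda p: np.log(p / (1 - p))
                data[0, a_i, 0, r_i, c_i] = logit(np.clip(sig_x, 1e-9, 1 - 1e-9))
                data[0, a_i, 1, r_i, c_i] = logit(np.clip(sig_y, 1e-9, 1 - 1e-9))
                data[0, a_i, 2, r_i, c_i] = np.log(w / group[a_i, 0])
                data[0, a_i, 3, r_i, c_i] = np.log(h / group[a_i, 1])
                data[0, a_i, 4, r_i, c_i] = 20.0
                data[0, a_i, 5, r_i, c_i] = 20.0
            t.data = data.reshape(1, 18, s, s)
        total, comps = compute_loss(raw, [targets], anchors, strides)
        assert comps["total"] < 1e-3

    def test_finite_difference_gradients(self):
        """Loss gradient vs central differences to 1e-4 on the toy grid."""
        raw, targets, anchors, strides = _toy_setup(dtype=np.float64)

        def loss_value():
            clean = [ad.Tensor(t.data.copy(), requires_grad=True) for t in raw]
            total, _ = compute_loss(clean, [targets], anchors, strides)
            return float(total.data)

        total, _ = compute_loss(raw, [targets], anchors, strides)
        total.backward()
        rng = np.random.default_rng(7)
        eps = 1e-6
        for t in raw:
            flat = t.data.reshape(-1)
            gflat = t.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=25, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_value()
                flat[idx] = orig - eps
                lo = loss_value()
                flat[idx] = orig
                num = (hi - lo) / (2 * eps)
                assert abs(num - gflat[idx]) < 1e-4, \
                    f"grad mismatch at {idx}: {num} vs {gflat[idx]}"

    def test_shape_mismatch_error(self):
        raw, targets, anchors, strides = _toy_setup()
        bad = [ad.Tensor(np.zeros((1, 17, s.shape[2], s.shape[3]))) for s in raw]
        with pytest.raises(ValueError, match="channels"):
            compute_loss(bad, [targets], anchors, strides)

    def test_batch_size_mismatch_error(self):
        raw, targets, anchors, strides = _toy_setup()
        with pytest.raises(ValueError, match="batch"):
            compute_loss(raw, [targets, targets], anchors, strides)


class TestTrainLoop:
    def test_smoke_two_epochs_and_checkpoint(self, tiny_dataset, tmp_path):
        from plateletdet.voc_data import DatasetSplit
        _, split, _ = tiny_dataset
        cfg = DetectorConfig(variant="improved", input_size=128,
                             width_mult=0.125)
        model = build_detector(cfg, seed=0)
        tc = TrainConfig(epochs=2, lr_drop_epoch=1, batch_size=4, seed=0)
        history, best = train(model, split, tc, out_dir=tmp_path / "run")
        assert len(history) == 2
        assert (tmp_path / "run" / "best.npz").exists()
        assert (tmp_path / "run" / "train_log.json").exists()

    def test_empty_split_error(self):
        from plateletdet.voc_data import DatasetSplit
        model = build_detector(DetectorConfig(variant="improved",
                                              input_size=64, width_mult=0.125))
        with pytest.raises(ValueError, match="empty"):
            train(model, DatasetSplit([], [], []),
                  TrainConfig(epochs=2, lr_drop_epoch=1))

    def test_seed_determinism_first_epoch(self, tiny_dataset):
        _, split, _ = tiny_dataset
        losses = []
        for _ in range(2):
            cfg = DetectorConfig(variant="improved", input_size=128,
                                 width_mult=0.125)
            model = build_detector(cfg, seed=3)
            tc = TrainConfig(epochs=2, lr_drop_epoch=1, batch_size=4, seed=3)
            history, _ = train(model, split, tc, eval_every=10)
            losses.append(history[0]["total"])
        assert losses[0] == losses[1]
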