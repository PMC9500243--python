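# plateletdet

Small-object detection of platelets in stained blood-smear images with a
YOLO-style single-stage detector, implemented in pure numpy (a compact
reverse-mode autodiff engine ships with the package — no deep-learning
framework required).

Key ingredients:

* **Improved multiscale head** — alongside the classic heads at strides
  32/16/8 (13×13 / 26×26 / 52×52 grids at input 416), the `improved` variant
  adds a shallow 104×104 head (stride 4) and drops the 13×13 head, trading
  coarse semantic context for the fine detail small platelets need.
* **Anchor clustering** — k-means over ground-truth box shapes with
  1 − IOU distance (center-aligned shapes), plus a nine-anchor default
  constant for platelet-scale data.
* **CIOU + IOU match parameter** — target assignment scores anchors by the
  sum of CIOU and IOU, which stays informative even for non-overlapping
  boxes; the localization loss is 1 − CIOU.
* **Evaluation suite** — greedy detection matching, precision / recall / F1,
  raw Riemann-sum average precision, confidence-threshold sweeps, and
  method-comparison reports.
* **Synthetic smear generator** — deterministic stained-smear-like images
  (pale background, large unlabeled erythrocyte distractors, small dark
  platelet blobs) with Pascal VOC XML annotations, so the entire pipeline is
  testable offline.

## CLI

One entry point with subcommands mirroring the workflow
generate → cluster-anchors → train → detect → evaluate:

```bash
plateletdet generate --out data --n 412 --seed 0        # synthetic dataset (296/33/83 split)
plateletdet cluster-anchors --annotations data/Annotations --k 9 --seed 0 --out anchors.txt
plateletdet train --data data --out run --variant improved --epochs 100 --seed 0
plateletdet detect --checkpoint run/best.npz --image data/JPEGImages/smear_0000.png --conf 0.25
plateletdet evaluate --checkpoint run/best.npz --data data --split test --eval-iou 0.5
plateletdet demo --out demo_run --seed 7                # full pipeline at reduced scale
```

Defaults follow the reference configuration: input 416, 9 anchors
(3 per scale), 100 epochs, LR 0.001 → 0.0001 after epoch 50 with a ×0.92
per-epoch decay, batch size 4, NMS IOU 0.45, confidence 0.25. Note the
published LR description is self-contradictory (a fixed drop *and* a
per-epoch decay); both are composed here — see `plateletdet/train.py`.

## Library sketch

| module | what it does |
| --- | --- |
| `geometry` | `Box`, IOU / CIOU / match-parameter scalars + vectorized pairwise matrices |
| `anchors` | IOU-distance k-means, `mean_best_iou`, scale-group assignment, default anchor constant |
| `voc_data` | Pascal VOC XML read/write, seeded dataset splitting, letterboxing with invertible affine |
| `synthetic_smear` | deterministic smear image + annotation generator |
| `model` | Darknet-53-style backbone + baseline/improved necks and heads (`width_mult` for desk-scale models) |
| `train` | match-parameter target assignment, composite loss, LR schedule, training loop |
| `infer` | grid decoding, greedy NMS, single-image `detect` pipeline |
| `evaluation` | confusion counts, P/R/F1, AP, threshold sweeps, comparison reports |
| `autodiff` | numpy reverse-mode engine: conv2d (im2col), batchnorm, Adam, gradient-checked ops |
| `cli` | click command group tying it all together |
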