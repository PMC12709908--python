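# panicle3d

3D sorghum panicle phenotyping from canopy point clouds: a procedural
generator of labelled synthetic canopies, the SegVoteNet multi-task
segmentation + detection network, and the evaluation/morphometrics layer
that turns detections into breeding-relevant panicle size metrics.

## Who this is for

Plant-phenotyping groups that reconstruct field plots as 3D point clouds
(UAV photogrammetry or radiance-field exports) and want per-plot panicle
counts, positions and size distributions without manual annotation.  The
clouds carry coordinates only — no colour, no normals — and panicles sit
densely packed in the upper canopy, so the package trains entirely on
synthetic plots and treats detection as a geometry problem.

## What is inside

- **`panicle3d.flight`** — capture-plan arithmetic for video-based UAV
  acquisition: motion blur = speed x shutter (2.5 m/s at 1/8000 s → 0.3 mm),
  whole frames = floor(duration x fps) (20 s at 30 fps → 600), and GSD
  under a documented pinhole convention.
- **`panicle3d.synth`** — procedural single-row plots: four panicle
  morphology templates (emerging → open), internode-cylinder stems whose
  top radius matches the peduncle, drooping leaf ribbons, overlap-free
  placement at 5–15 cm spacing with gap injection, area-weighted labelled
  sampling, and finalization (upper-canopy crop, FPS to 100,000 points,
  one oriented box + size class per panicle instance).
- **`panicle3d.augment`** — label-preserving training augmentation:
  xy-rotation, bounded rescale (0.85–1.15), class-aware jitter
  (leaf > panicle = stem, with a no-merge guard around panicles), dropout
  (p in 0.2–0.5), shuffle.
- **`panicle3d.model`** — SegVoteNet as a scikit-learn-style estimator.
  A shared 4-layer set-abstraction encoder (2560/1024/512/256 points,
  multi-scale grouping at panicle-scale radii) feeds a feature-propagation
  segmentation decoder (class-weighted cross-entropy 0.3/0.6/0.1) and a
  detection branch that seeds deep-Hough voting *only from
  panicle-predicted points*, groups features with full-height cylinder
  queries (radii 0.075/0.1 m), casts two votes per seed, and decodes
  proposals as size class + residual and heading bin + residual.  Training
  is AdamW at 0.002 with 10x decay at epochs 24 and 32.  The network runs
  on a small numpy reverse-mode autodiff engine (`panicle3d.nn`) — no GPU
  or deep-learning framework required.
- **`panicle3d.evaluate`** — AP/AR at IoU 0.25/0.5 with exact rotated-box
  IoU, all-class and panicle-only segmentation accuracy, and per-detection
  morphometrics (height, length, width, radius = (length+width)/4).

## Worked example

Generate a short synthetic row, overfit the reduced-width model profile on
it, and score its own detections (about a minute on one CPU core):

```python
import numpy as np
from panicle3d.synth import PlotSpec, place_plants, sample_scene_rng, finalize_cloud
from panicle3d.model import SegVoteNet, TrainConfig
from panicle3d.evaluate import average_precision, segmentation_accuracy

scene = place_plants(PlotSpec(row_length=0.5, gap_probability=0.0),
                     np.random.default_rng(5))
cloud = finalize_cloud(sample_scene_rng(scene, 6000, np.random.default_rng(6)), 2000)
model = SegVoteNet(profile="small", seed=0,
                   train=TrainConfig(batch_size=1, n_epochs=400,
                                     decay_epochs=(250, 350), input_points=None,
                                     val_interval=10_000, weight_decay=0.0))
model.fit([cloud])
res = model.infer(cloud.coords)
ap25, _ = average_precision(res["boxes"], res["scores"], cloud.boxes, 0.25)
print(f"plants: {len(scene.plants)}  panicle boxes: {len(cloud.boxes)}")
print(f"detections: {len(res['boxes'])}")
print(f"AP@0.25 on the training scene: {ap25:.3f}")
print(f"segmentation accuracy: {segmentation_accuracy(res['labels'], cloud.semantic):.3f}")
```

prints

```
plants: 5  panicle boxes: 4
detections: 6
AP@0.25 on the training scene: 0.900
segmentation accuracy: 0.989
```

Five plants were placed, four panicles were large enough to receive ground
truth boxes, and after 400 training steps the model re-detects them on the
scene it was trained on with AP 0.900 at IoU 0.25 while labelling 98.9 % of
points correctly (class-balanced) — a capacity check of the architecture,
not a field-generalisation claim.

## Command line

```bash
panicle3d plan --config capture.yaml               # blur / frames / GSD
panicle3d generate --n-scenes 10 --seed 0 --out ds/  # synthetic dataset
panicle3d train --data ds/ --out run/              # train SegVoteNet
panicle3d infer --checkpoint run/checkpoint.npz --cloud plot.ply --out det.json
panicle3d eval --pred det/ --gt ds/                # mAP/mAR + morphometrics
```

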