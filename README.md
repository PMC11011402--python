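# greenfruit

Detecting **unripe (green) fruit against same-color foliage** is one of the
hard cases of orchard phenotyping: the targets share hue with the canopy,
are partly hidden by leaves, and field datasets are small (a few hundred
images) because acquisition across weather and lighting conditions is
expensive. `greenfruit` is a complete, CPU-trainable implementation of an
attention-augmented single-stage detector for this regime, together with
the data-side machinery that makes small datasets workable:

* a **Conv-AT block** — an attention-integration block built from channel
  attention (CA), spatial attention (SA) and ReLU convolution stacks (CBR),
  combined by channel concatenation:

  ```
  P(X) = concat[ F_CA(X) ; F_CBR(X) ]
  H(X) = concat[ F_CBR(P(X)) ; F_SA(X) ]
  W(X) = concat[ F_CBR(H(X)) ; F_CBR(X) ]
  Y(X) = BN( F_CBR(W(X)) )
  ```

  with `F_CA(X) = X · σ(MLP(avgpool X) + MLP(maxpool X))` (per-channel
  gates) and `F_SA(X) = X · σ(mix[avgpool_c X ; maxpool_c X])` (per-pixel
  gates), σ the sigmoid;
* a **v5-family detector** around it: CBS/C3/SPPF backbone, FPN+PAN neck,
  three-scale anchor head (strides 8/16/32), CIoU + BCE loss, k-means
  adaptive anchors, NMS;
* the **three-way augmentation schedule** for small datasets: mask-guided
  **Copy-Paste** (p = 1.0; 4 fruit + 15 leaf instances pasted per image),
  **Mosaic** (p = 0.8) and **Mixup** (p = 0.3, `x = λ·xi + (1−λ)·xj` with
  λ ~ Beta(α, α) and labels concatenated unweighted);
* the **IoU-0.5 evaluation protocol**: greedy matching (TP iff IoU > 0.5),
  precision, recall, F1 = 2PR/(P+R), all-point-interpolated AP and mAP;
* a **synthetic orchard scene generator** producing green-on-green scenes
  with ground-truth boxes and per-instance masks, standing in for the
  segmentation provider so the whole stack runs at desk scale.

The network layer runs on a small NumPy reverse-mode autodiff engine
(`greenfruit.nn`) — no GPU framework required; everything trains on one CPU
core at miniature scale.

## Worked example

```python
import numpy as np
from greenfruit.synth import SceneConfig, generate_scene
from greenfruit.augment import AugmentConfig
from greenfruit.model import build_detector
from greenfruit.train import train_loop, evaluate_model

cfg = SceneConfig.desk_scale(seed=7)          # 160x160 green-on-green scenes
rng = np.random.default_rng(7)
train = [generate_scene(cfg, rng) for _ in range(64)]
held_out = [generate_scene(cfg, rng) for _ in range(16)]

model = build_detector({"width_base": 8, "depths": (1, 1, 1, 1)}, seed=7)
model, history = train_loop(train, model, AugmentConfig(preset_size=160, seed=7),
                            epochs=60, seed=7, val_images=held_out, eval_every=5)
report = evaluate_model(model, held_out, 160)
print(report.as_percent_table())
```

On this run the evaluation table prints (values are percentages at IoU 0.5;
your machine reproduces them exactly for the same seed):

```
| category | P | R | F1 | AP |
|---|---|---|---|---|
| 0 | 76.5 | 50.0 | 60.5 | 61.2 |
| **mAP** | | | | **61.2** |
```

i.e. after 60 epochs (~6 minutes on one CPU core) the miniature detector
recovers half of the held-out green fruits at 76% precision (mAP@0.5 61%) —
the point of the exercise being that the full pipeline (attention blocks,
augmentation, anchors, loss, evaluation) is exercised end to end, not that
a 160-px miniature reaches field-scale accuracy. Held-out mAP varies by
roughly ±10 points across data seeds at this tiny evaluation size (16
scenes).

The same pipeline is scriptable from the shell:

```bash
greenfruit synth --out data/orchard --n-images 80 --seed 7
greenfruit train --data data/orchard --out model.npz --epochs 60 --seed 7
greenfruit evaluate --checkpoint model.npz --data data/orchard --out report.json
```

## Layout

| module | contents |
|---|---|
| `greenfruit.boxes` / `labels` | box records, YOLO-txt label I/O, 7:3 splitting |
| `greenfruit.synth` | synthetic orchard scenes + instance-mask provider |
| `greenfruit.augment` | copy-paste, mosaic, mixup, letterbox, scheduler |
| `greenfruit.nn` | NumPy autodiff engine and layers |
| `greenfruit.blocks` | CBS/CBR, CA, SA, Conv-AT, C3, SPPF |
| `greenfruit.model` | detector assembly, decode, NMS, autoanchor, checkpoints |
| `greenfruit.loss` / `train` | CIoU loss, target assignment, SGD training loop |
| `greenfruit.metrics` | IoU-0.5 matching, P/R/F1/AP/mAP |
| `greenfruit.cli` / `config` | `greenfruit` command, YAML run configs |

See `docs/methods.md` for the modeling choices, parameter meanings and
known limitations.
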