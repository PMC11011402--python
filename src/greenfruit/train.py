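"""Training loop: SGD with momentum, warmup + cosine schedule, per-epoch eval.

Desk-scale defaults (small inputs, small batches) are tuned for CPU runs on
synthetic scenes; every constant is exposed through the ``hyp`` dict so
full-scale settings can be supplied unchanged.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .augment import AugmentConfig, apply_train_pipeline, letterbox
from .labels import LabeledImage
from .loss import HYP_DEFAULTS, assign_targets, compute_loss
from .metrics import EvalReport, evaluate_detections
from .model import Detector, autoanchor, detect, save_checkpoint

__all__ = ["SGD", "TrainHistory", "train_loop", "evaluate_model", "HYP_TRAIN_DEFAULTS"]

HYP_TRAIN_DEFAULTS = dict(
    HYP_DEFAULTS,
    lr0=0.02,
    lrf=0.1,  # final lr = lr0 * lrf after cosine decay
    momentum=0.937,
    weight_decay=5e-4,
    warmup_epochs=2.0,
    batch_size=8,
    conf_threshold_eval=0.001,
    nms_iou=0.45,
)


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if p.data.ndim >= 2:  # decay conv/linear weights, not BN/bias terms
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainHistory:
    """Per-epoch record of loss terms and validation metrics."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.epochs.append(kwargs)

    def to_csv(self, path: str | Path) -> None:
        if not self.epochs:
            return
        keys = list(dict.fromkeys(k for e in self.epochs for k in e))
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys, restval="")
            writer.writeheader()
            writer.writerows(self.epochs)

    @property
    def best_map(self) -> float:
        vals = [e.get("val_map50", 0.0) for e in self.epochs]
        return max(vals) if vals else 0.0


def _lr_at(step: int, steps_per_epoch: int, epochs: int, hyp: dict) -> float:
    """Linear warmup to lr0, then cosine decay to lr0 * lrf."""
    warmup_steps = max(1, int(hyp["warmup_epochs"] * steps_per_epoch))
    total = max(1, epochs * steps_per_epoch)
    if step < warmup_steps:
        return hyp["lr0"] * (step + 1) / warmup_steps
    frac = (step - warmup_steps) / max(1, total - warmup_steps)
    return hyp["lr0"] * (hyp["lrf"] + (1 - hyp["lrf"]) * 0.5 * (1 + math.cos(math.pi * frac)))


def _batch_arrays(samples: Sequence[LabeledImage]):
    """Stack letterboxed samples into (x, targets) training arrays."""
    pixels = np.stack([s.pixels for s in samples]).astype(np.float32) / 255.0
    x = pixels.transpose(0, 3, 1, 2)
    rows = []
    for i, s in enumerate(samples):
        for b in s.boxes:
            rows.append((i, b.category_id, b.cx, b.cy, b.w, b.h))
    targets = np.array(rows, dtype=float).reshape(-1, 6)
    return x, targets


def evaluate_model(model: Detector, images: Sequence[LabeledImage], input_size: int,
                   conf_threshold: float = 0.001, nms_iou: float = 0.45,
                   iou_threshold: float = 0.5) -> EvalReport:
    """Letterbox, run inference and score a labeled image set at IoU 0.5."""
    boxed = [letterbox(img, input_size)[0] for img in images]
    batch = np.stack([b.pixels for b in boxed])
    dets = detect(model, batch, conf_threshold=conf_threshold, nms_iou=nms_iou)
    gts = [b.boxes for b in boxed]
    sizes = [(input_size, input_size)] * len(boxed)
    return evaluate_detections(dets, gts, sizes, iou_threshold=iou_threshold)


def train_loop(
    train_images: Sequence[LabeledImage],
    model: Detector,
    aug_config: AugmentConfig,
    epochs: int = 30,
    hyp: dict | None = None,
    seed: int = 0,
    val_images: Sequence[LabeledImage] | None = None,
    checkpoint_path: str | Path | None = None,
    eval_every: int = 5,
    verbose: bool = False,
    refit_anchors: bool = True,
) -> tuple[Detector, TrainHistory]:
    """Fit the detector on (augmented) labeled images.

    SGD with momentum under a warmup + cosine schedule; the validation set
    is scored every ``eval_every`` epochs and the best-mAP weights are
    retained (and written to ``checkpoint_path`` if given).  Anchors are
    re-estimated from the training boxes before the first step unless
    ``refit_anchors`` is false.  Fully deterministic for a fixed seed.
    Raises ``RuntimeError`` with diagnostics if the loss goes non-finite.
    """
    if not train_images:
        raise ValueError("training set is empty")
    hyp = dict(HYP_TRAIN_DEFAULTS, **(hyp or {}))
    rng = np.random.default_rng(seed)
    size = aug_config.preset_size

    if refit_anchors:
        wh = np.array(
            [(b.w * size, b.h * size) for img in train_images for b in img.boxes]
        ).reshape(-1, 2)
        model.anchors = autoanchor(wh, seed=seed)

    batch = int(hyp["batch_size"])
    steps_per_epoch = max(1, len(train_images) // batch)
    opt = SGD(model.parameters(), lr=hyp["lr0"], momentum=hyp["momentum"],
              weight_decay=hyp["weight_decay"])
    stream = apply_train_pipeline(train_images, aug_config, rng, n_samples=None)
    history = TrainHistory()
    best_state = None
    best_map = -1.0
    step = 0
    for epoch in range(epochs):
        model.train()
        epoch_loss = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}
        for _ in range(steps_per_epoch):
            samples = [next(stream).image for _ in range(batch)]
            x, targets = _batch_arrays(samples)
            from .nn import Tensor

            raw = model(Tensor(x))
            grids = [(m.shape[2], m.shape[3]) for m in raw]
            asn = assign_targets(targets, model.anchors, grids,
                                 ratio_limit=hyp["anchor_ratio_limit"])
            terms = compute_loss(raw, asn, model.n_classes, hyp)
            if not math.isfinite(terms.total_value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss terms box={terms.box} obj={terms.obj} cls={terms.cls}"
                )
            opt.zero_grad()
            terms.total.backward()
            opt.lr = _lr_at(step, steps_per_epoch, epochs, hyp)
            opt.step()
            step += 1
            epoch_loss["box"] += terms.box
            epoch_loss["obj"] += terms.obj
            epoch_loss["cls"] += terms.cls
            epoch_loss["total"] += terms.total_value
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            **{k: v / steps_per_epoch for k, v in epoch_loss.items()},
        }
        if val_images and ((epoch + 1) % eval_every == 0 or epoch == epochs - 1):
            report = evaluate_model(model, val_images, size,
                                    conf_threshold=hyp["conf_threshold_eval"],
                                    nms_iou=hyp["nms_iou"])
            record["val_map50"] = report.map50
            if report.map50 > best_map:
                best_map = report.map50
                best_state = model.state_dict()
        history.append(**record)
        if verbose:
            printable = {k: (f"{v:.4f}" if isinstance(v, float) else v)
                         for k, v in record.items()}
            print(f"epoch {printable}")
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path,
                        extra={"best_map50": best_map, "epochs": epochs, "seed": seed})
    return model, history
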