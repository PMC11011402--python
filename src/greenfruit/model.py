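"""Detector assembly: backbone, FPN+PAN neck, three-scale anchor head.

The backbone stacks CBS / Conv-AT / C3 blocks and closes with SPPF; the
attention block sits at the stride-2 downsampling positions between stages
(configurable placement mask).  The neck runs the conventional top-down
semantic path (FPN) followed by the bottom-up localization path (PAN).  The
head emits, at strides 8/16/32, a ``3 * (5 + n_classes)`` vector per grid
cell: box offsets, objectness and class logits for three anchors.

Decoding follows the v5-family convention::

    center = (2 * sigmoid(t_xy) - 0.5 + grid) * stride
    size   = (2 * sigmoid(t_wh))**2 * anchor
    conf   = sigmoid(obj) * sigmoid(cls)

so an all-zero prediction lands at the cell center with the anchor's size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .boxes import DetectionBox, box_iou
from .blocks import C3, SPPF, ConvAT, ConvBnAct
from .nn import Conv2d, Module, Parameter, Tensor, concat, no_grad, upsample_nearest2x

__all__ = [
    "AnchorSet",
    "DEFAULT_ANCHORS",
    "Detector",
    "build_detector",
    "decode_predictions",
    "nms",
    "autoanchor",
    "save_checkpoint",
    "load_checkpoint",
]

STRIDES = (8, 16, 32)

# the standard 640-scale nine anchors, small to large
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)


@dataclass(frozen=True)
class AnchorSet:
    """Nine prior box sizes in input pixels, three per detection scale."""

    anchors: tuple  # 3 scales x 3 anchors x (w, h)
    strides: tuple = STRIDES

    def __post_init__(self) -> None:
        arr = np.asarray(self.anchors, dtype=float)
        if arr.shape != (3, 3, 2):
            raise ValueError(f"anchors must be 3x3x(w,h), got shape {arr.shape}")
        if (arr <= 0).any():
            raise ValueError("anchors must be positive")
        areas = arr[..., 0] * arr[..., 1]
        if not (np.diff(areas, axis=1) >= 0).all():
            raise ValueError("anchors must be sorted by area within each scale")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.anchors, dtype=np.float32)

    @classmethod
    def default(cls) -> "AnchorSet":
        return cls(DEFAULT_ANCHORS)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "AnchorSet":
        arr = np.asarray(arr, dtype=float).reshape(3, 3, 2)
        # sort by area within each scale to satisfy the invariant
        order = np.argsort(arr[..., 0] * arr[..., 1], axis=1)
        arr = np.take_along_axis(arr, order[..., None], axis=1)
        return cls(tuple(tuple(tuple(a) for a in scale) for scale in arr))


DEFAULT_ARCH = {
    "width_base": 8,  # channels double each stage: w, 2w, 4w, 8w, 16w
    "depths": (1, 2, 2, 1),  # C3 bottleneck counts per stage
    "conv_at": (True, True, True, True),  # attention block at each downsample
    "reduction": 16,
}


class Detector(Module):
    """Backbone + neck + head; forward returns the three raw head maps."""

    def __init__(self, arch: dict | None = None, n_classes: int = 1,
                 anchors: AnchorSet | None = None, seed: int = 0):
        super().__init__()
        self.arch = dict(DEFAULT_ARCH, **(arch or {}))
        self.n_classes = int(n_classes)
        self.anchors = anchors or AnchorSet.default()
        rng = np.random.default_rng(seed)
        w = self.arch["width_base"]
        d = self.arch["depths"]
        at = self.arch["conv_at"]
        red = self.arch["reduction"]

        def down(c_in, c_out, use_at):
            if use_at:
                return ConvAT(c_in, c_out, stride=2, reduction=red, rng=rng)
            return ConvBnAct(c_in, c_out, 3, stride=2, rng=rng)

        # backbone
        self.stem = ConvBnAct(3, w, 3, stride=2, rng=rng)  # /2
        self.down1 = down(w, 2 * w, at[0])
        self.c3_1 = C3(2 * w, 2 * w, d[0], rng=rng)  # /4
        self.down2 = down(2 * w, 4 * w, at[1])
        self.c3_2 = C3(4 * w, 4 * w, d[1], rng=rng)  # /8 -> P3
        self.down3 = down(4 * w, 8 * w, at[2])
        self.c3_3 = C3(8 * w, 8 * w, d[2], rng=rng)  # /16 -> P4
        self.down4 = down(8 * w, 16 * w, at[3])
        self.c3_4 = C3(16 * w, 16 * w, d[3], rng=rng)
        self.sppf = SPPF(16 * w, 16 * w, rng=rng)  # /32 -> P5
        # neck: FPN (top-down) then PAN (bottom-up)
        self.lat5 = ConvBnAct(16 * w, 8 * w, 1, rng=rng)
        self.fpn4 = C3(16 * w, 8 * w, 1, shortcut=False, rng=rng)
        self.lat4 = ConvBnAct(8 * w, 4 * w, 1, rng=rng)
        self.fpn3 = C3(8 * w, 4 * w, 1, shortcut=False, rng=rng)
        self.pan_down3 = ConvBnAct(4 * w, 4 * w, 3, stride=2, rng=rng)
        self.pan4 = C3(8 * w, 8 * w, 1, shortcut=False, rng=rng)
        self.pan_down4 = ConvBnAct(8 * w, 8 * w, 3, stride=2, rng=rng)
        self.pan5 = C3(16 * w, 16 * w, 1, shortcut=False, rng=rng)
        # head: one 1x1 conv per scale
        n_out = 3 * (5 + self.n_classes)
        self.head3 = Conv2d(4 * w, n_out, 1, bias=True, rng=rng)
        self.head4 = Conv2d(8 * w, n_out, 1, bias=True, rng=rng)
        self.head5 = Conv2d(16 * w, n_out, 1, bias=True, rng=rng)
        for head in (self.head3, self.head4, self.head5):
            b = head.bias.data.reshape(3, 5 + self.n_classes)
            b[:, 4] = -4.5  # objectness prior ~ 1%: rare-object initialization
            head.bias.data = b.reshape(-1)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stem(x)
        x = self.c3_1(self.down1(x))
        p3 = self.c3_2(self.down2(x))
        p4 = self.c3_3(self.down3(p3))
        p5 = self.sppf(self.c3_4(self.down4(p4)))
        # top-down
        l5 = self.lat5(p5)
        m4 = self.fpn4(concat([upsample_nearest2x(l5), p4], axis=1))
        l4 = self.lat4(m4)
        o3 = self.fpn3(concat([upsample_nearest2x(l4), p3], axis=1))
        # bottom-up
        o4 = self.pan4(concat([self.pan_down3(o3), l4], axis=1))
        o5 = self.pan5(concat([self.pan_down4(o4), l5], axis=1))
        return self.head3(o3), self.head4(o4), self.head5(o5)


def build_detector(arch: dict | None = None, n_classes: int = 1,
                   anchors: AnchorSet | None = None, seed: int = 0) -> Detector:
    """Construct a detector and sanity-check its channel plan."""
    model = Detector(arch, n_classes, anchors, seed)
    w = model.arch["width_base"]
    if w < 2 or (2 * w) % 2:
        raise ValueError(f"width_base {w} yields an invalid channel plan")
    return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def _reshape_head(raw: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, 3*(5+nc), H, W) -> (N, 3, H, W, 5+nc)."""
    n, _, h, w = raw.shape
    return raw.reshape(n, 3, 5 + n_classes, h, w).transpose(0, 1, 3, 4, 2)


def decode_predictions(
    raw_maps,
    anchors: AnchorSet,
    conf_threshold: float = 0.001,
    n_classes: int = 1,
    image_size: tuple[int, int] | None = None,
) -> list[list[DetectionBox]]:
    """Decode the three raw head maps into per-image detection lists.

    Boxes below ``conf_threshold`` are dropped; survivors are clipped to the
    image bounds (inferred from grid size times stride when not given).
    """
    arrs = [m.data if isinstance(m, Tensor) else np.asarray(m) for m in raw_maps]
    if len(arrs) != 3:
        raise ValueError(f"expected 3 head maps, got {len(arrs)}")
    anchor_arr = anchors.as_array()
    n_batch = arrs[0].shape[0]
    out: list[list[DetectionBox]] = [[] for _ in range(n_batch)]
    if image_size is None:
        image_size = (arrs[0].shape[3] * anchors.strides[0],
                      arrs[0].shape[2] * anchors.strides[0])
    w_img, h_img = image_size
    for scale, (raw, stride) in enumerate(zip(arrs, anchors.strides)):
        pred = _reshape_head(raw, n_classes)
        n, _, h, w, _ = pred.shape
        sig = _sigmoid(pred)
        gx, gy = np.meshgrid(np.arange(w), np.arange(h))
        cx = (2.0 * sig[..., 0] - 0.5 + gx) * stride
        cy = (2.0 * sig[..., 1] - 0.5 + gy) * stride
        bw = (2.0 * sig[..., 2]) ** 2 * anchor_arr[scale, :, 0].reshape(1, 3, 1, 1)
        bh = (2.0 * sig[..., 3]) ** 2 * anchor_arr[scale, :, 1].reshape(1, 3, 1, 1)
        obj = sig[..., 4]
        cls = sig[..., 5:]
        conf = obj[..., None] * cls  # (N, 3, H, W, nc)
        best_cls = conf.argmax(axis=-1)
        best_conf = conf.max(axis=-1)
        keep = best_conf >= conf_threshold
        for b in range(n):
            idx = np.nonzero(keep[b])
            for a, i, j in zip(*idx):
                x1 = np.clip(cx[b, a, i, j] - bw[b, a, i, j] / 2, 0, w_img)
                x2 = np.clip(cx[b, a, i, j] + bw[b, a, i, j] / 2, 0, w_img)
                y1 = np.clip(cy[b, a, i, j] - bh[b, a, i, j] / 2, 0, h_img)
                y2 = np.clip(cy[b, a, i, j] + bh[b, a, i, j] / 2, 0, h_img)
                if x2 <= x1 or y2 <= y1:
                    continue
                out[b].append(
                    DetectionBox(int(best_cls[b, a, i, j]), float(best_conf[b, a, i, j]),
                                 float(x1), float(y1), float(x2), float(y2))
                )
    return out


def nms(boxes: list[DetectionBox], iou_threshold: float = 0.45) -> list[DetectionBox]:
    """Greedy per-category non-maximum suppression by descending confidence."""
    kept: list[DetectionBox] = []
    by_cat: dict[int, list[DetectionBox]] = {}
    for b in boxes:
        by_cat.setdefault(b.category_id, []).append(b)
    for cat_boxes in by_cat.values():
        cat_boxes.sort(key=lambda b: -b.confidence)
        cat_kept: list[DetectionBox] = []
        for b in cat_boxes:
            if all(box_iou(b.corners, k.corners) <= iou_threshold for k in cat_kept):
                cat_kept.append(b)
        kept.extend(cat_kept)
    kept.sort(key=lambda b: -b.confidence)
    return kept


def detect(model: Detector, images: np.ndarray, conf_threshold: float = 0.25,
           nms_iou: float = 0.45) -> list[list[DetectionBox]]:
    """Run eval-mode inference on a (N, H, W, 3) uint8 batch: decode + NMS."""
    was_training = model.training
    model.eval()
    x = Tensor(images.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
    with no_grad():
        raw = model(x)
    if was_training:
        model.train()
    decoded = decode_predictions(raw, model.anchors, conf_threshold, model.n_classes,
                                 image_size=(images.shape[2], images.shape[1]))
    return [nms(dets, nms_iou) for dets in decoded]


# -- adaptive anchors ----------------------------------------------------------

def _wh_iou(wh: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """IoU between co-centered boxes given only (w, h); shapes (N,2), (K,2) -> (N,K)."""
    inter = np.minimum(wh[:, None, 0], centroids[None, :, 0]) * np.minimum(
        wh[:, None, 1], centroids[None, :, 1]
    )
    union = (wh[:, 0] * wh[:, 1])[:, None] + (centroids[:, 0] * centroids[:, 1])[None, :] - inter
    return inter / union


def best_possible_recall(wh: np.ndarray, anchors: np.ndarray, ratio_limit: float = 4.0) -> float:
    """Fraction of boxes whose best anchor stays within the assigner's ratio bound."""
    r = wh[:, None, :] / anchors[None, :, :]
    worst = np.maximum(r, 1.0 / r).max(axis=2)  # (N, K)
    return float((worst.min(axis=1) < ratio_limit).mean())


def autoanchor(wh: np.ndarray, k: int = 9, iterations: int = 30,
               mutations: int = 300, seed: int = 0,
               track: list | None = None) -> AnchorSet:
    """Cluster training-box sizes into k anchors (1-IoU k-means + mutation).

    ``wh`` is an (N, 2) array of box sizes in input pixels.  Lloyd iterations
    assign each box to its highest-IoU centroid and move centroids to the
    member-wise median; an update that would increase the mean ``1 - IoU``
    objective is rejected, so the objective is non-increasing.  A random
    mutation phase then perturbs the centroids, keeping changes that improve
    best-possible recall (then mean IoU).  Falls back to the default anchors
    with a warning when fewer than ``k`` boxes are available.
    """
    wh = np.asarray(wh, dtype=float).reshape(-1, 2)
    if len(wh) < k:
        warnings.warn(f"autoanchor: only {len(wh)} boxes (< {k}); using default anchors")
        return AnchorSet.default()
    rng = np.random.default_rng(seed)
    centroids = wh[rng.choice(len(wh), size=k, replace=False)].copy()

    def objective(c: np.ndarray) -> float:
        return float((1.0 - _wh_iou(wh, c).max(axis=1)).mean())

    obj = objective(centroids)
    if track is not None:
        track.append(obj)
    for _ in range(iterations):
        assign = _wh_iou(wh, centroids).argmax(axis=1)
        new = centroids.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                new[j] = np.median(members, axis=0)
        new_obj = objective(new)
        if new_obj > obj + 1e-12:  # safeguard: reject a worsening update
            break
        converged = abs(new_obj - obj) < 1e-12
        centroids, obj = new, new_obj
        if track is not None:
            track.append(obj)
        if converged:
            break

    fitness = (best_possible_recall(wh, centroids), float(_wh_iou(wh, centroids).max(axis=1).mean()))
    for _ in range(mutations):
        factor = np.where(rng.uniform(size=centroids.shape) < 0.3,
                          rng.normal(1.0, 0.1, size=centroids.shape), 1.0)
        cand = np.clip(centroids * factor, 2.0, None)
        cand_fit = (best_possible_recall(wh, cand), float(_wh_iou(wh, cand).max(axis=1).mean()))
        if cand_fit > fitness:
            centroids, fitness = cand, cand_fit
    return AnchorSet.from_array(centroids[np.argsort(centroids.prod(axis=1))])


# -- checkpoints ---------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Detector, path: str | Path,
                    class_names: tuple[str, ...] = ("fruit",),
                    extra: dict | None = None) -> None:
    """Write architecture config, weights, anchors and class names to one file."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "arch": {k: list(v) if isinstance(v, tuple) else v for k, v in model.arch.items()},
        "n_classes": model.n_classes,
        "anchors": np.asarray(model.anchors.anchors).tolist(),
        "strides": list(model.anchors.strides),
        "class_names": list(class_names),
        "extra": extra or {},
    }
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[Detector, dict]:
    """Rebuild a detector from a checkpoint; returns (model, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        state = {key[len("param/"):]: data[key] for key in data.files if key.startswith("param/")}
    arch = {k: tuple(v) if isinstance(v, list) else v for k, v in meta["arch"].items()}
    anchors = AnchorSet(tuple(tuple(tuple(a) for a in s) for s in meta["anchors"]),
                        tuple(meta["strides"]))
    model = Detector(arch, meta["n_classes"], anchors)
    model.load_state_dict(state)
    model.eval()
    return model, meta
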