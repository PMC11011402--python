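"""Input-side augmentations for small-dataset detector training.

Three methods expand the training distribution, each applied per sample with
its own probability:

* **mask-guided Copy-Paste** (p = 1.0 by default): instances cut out along
  their segmentation masks — here 4 fruits and 15 leaves per image — are
  geometrically transformed (flip / rotation / scale, nearest-neighbor so
  pixel values are preserved exactly) and composited into the target scene.
  Pasted fruits contribute new boxes; pasted leaves only occlude.
* **Mosaic** (p = 0.8): four images are each resized to the preset size and
  tiled around a random center on a double-size canvas, which is then
  cropped and resized back to the preset size.
* **Mixup** (p = 0.3): a convex pixel blend ``lam * a + (1 - lam) * b`` with
  ``lam ~ Beta(alpha, alpha)``; the label sets of both images are
  concatenated unweighted.

Letterboxing (aspect-preserving resize + symmetric gray padding) always runs
last so every sample reaches the network at the preset square size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

from .boxes import BBox, bbox_to_corners, box_iou, corners_to_bbox
from .labels import LabeledImage
from .synth import InstanceMask

__all__ = [
    "AugmentConfig",
    "TransformRecord",
    "PasteRecord",
    "PastePool",
    "copy_paste",
    "mosaic",
    "sample_mixup_lambda",
    "mixup",
    "letterbox",
    "apply_train_pipeline",
    "transform_instance",
]

_PAD_FILL = 114  # conventional gray fill for detector letterboxing


@dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and knobs of the training-time augmentation schedule."""

    p_copy_paste: float = 1.0
    n_fruit_paste: int = 4
    n_leaf_paste: int = 15
    p_mosaic: float = 0.8
    p_mixup: float = 0.3
    mixup_alpha: float = 8.0
    preset_size: int = 640
    flip_prob: float = 0.5
    rotation_range: float = 10.0  # degrees, applied to pasted instances
    paste_scale: tuple[float, float] = (0.5, 1.5)
    crop_scale: tuple[float, float] = (0.6, 1.0)  # mosaic crop window / canvas
    hsv_jitter: tuple[float, float, float] = (0.015, 0.3, 0.2)
    max_paste_cover: float = 0.9  # drop an original box if pastes cover more
    paste_iou_limit: float = 0.3
    min_visibility: float = 0.1  # mosaic: drop boxes clipped below this area frac
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_copy_paste", "p_mosaic", "p_mixup", "flip_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be positive")
        if self.preset_size <= 0:
            raise ValueError("preset_size must be positive")


@dataclass(frozen=True)
class TransformRecord:
    """Audit record of a geometric image transform: applying it to source
    boxes must reproduce the output boxes exactly."""

    scale: tuple[float, float]  # (sx, sy)
    pad: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)  # l, t, r, b
    flipped: bool = False
    note: str = ""

    def apply_point(self, x: float, y: float, src_size: tuple[int, int]) -> tuple[float, float]:
        sx, sy = self.scale
        if self.flipped:
            x = src_size[0] - x
        return x * sx + self.pad[0], y * sy + self.pad[1]

    def invert_point(self, x: float, y: float, src_size: tuple[int, int]) -> tuple[float, float]:
        sx, sy = self.scale
        x = (x - self.pad[0]) / sx
        y = (y - self.pad[1]) / sy
        if self.flipped:
            x = src_size[0] - x
        return x, y


@dataclass(frozen=True)
class PasteRecord:
    """One pasted instance: its source, transform parameters and placement."""

    pool_index: int
    category: str
    flip: bool
    angle_deg: float
    scale: float
    position: tuple[int, int]  # top-left of the pasted patch on the target
    patch_shape: tuple[int, int]  # (h, w) after transform


class PastePool:
    """Instance library for copy-paste: masks plus their source pixels.

    Built from scenes that carry instance masks (the segmentation-provider
    contract); sampling is with replacement, so a single donor scene
    suffices.
    """

    def __init__(self, images: Sequence[LabeledImage]):
        self.entries: list[tuple[InstanceMask, np.ndarray]] = []
        from .synth import get_instances

        for img in images:
            for inst in get_instances(img):
                self.entries.append((inst, img.pixels))
        self.fruit_idx = [i for i, (m, _) in enumerate(self.entries) if m.category == "fruit"]
        self.leaf_idx = [i for i, (m, _) in enumerate(self.entries) if m.category == "leaf"]

    def __len__(self) -> int:
        return len(self.entries)


def _crop_instance(inst: InstanceMask, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cut the tight patch (pixels, mask) of an instance out of its source."""
    ys, xs = np.nonzero(inst.mask)
    y1, y2 = ys.min(), ys.max() + 1
    x1, x2 = xs.min(), xs.max() + 1
    return pixels[y1:y2, x1:x2].copy(), inst.mask[y1:y2, x1:x2].copy()


def transform_instance(
    patch: np.ndarray, mask: np.ndarray, flip: bool, angle_deg: float, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the recorded flip/rotation/scale to an instance patch.

    Nearest-neighbor resampling throughout, so every output pixel is an
    exact copy of some source pixel and the binary mask stays binary; the
    same record always reproduces the same output.
    """
    from scipy import ndimage

    if flip:
        patch, mask = patch[:, ::-1], mask[:, ::-1]
    if angle_deg != 0.0:
        patch = ndimage.rotate(patch, angle_deg, order=0, reshape=True, mode="constant")
        mask = ndimage.rotate(mask, angle_deg, order=0, reshape=True, mode="constant")
    if scale != 1.0:
        patch = ndimage.zoom(patch, (scale, scale, 1.0), order=0)
        mask = ndimage.zoom(mask, (scale, scale), order=0)
    mask = mask.astype(bool)
    return patch, mask


def copy_paste(
    target: LabeledImage,
    pool: PastePool,
    n_fruit: int = 4,
    n_leaf: int = 15,
    rng: np.random.Generator | None = None,
    config: AugmentConfig | None = None,
) -> tuple[LabeledImage, list[PasteRecord]]:
    """Paste ``n_fruit`` fruit and ``n_leaf`` leaf instances into ``target``.

    Each pasted fruit appends the tight box of its transformed mask; leaves
    add occlusion only.  Placement is uniform with IoU <= ``paste_iou_limit``
    against existing fruit boxes (20 retries, then the instance is skipped
    with a warning).  A pre-existing box is dropped only when pasted pixels
    cover more than ``max_paste_cover`` of its area.
    """
    rng = np.random.default_rng() if rng is None else rng
    cfg = config or AugmentConfig()
    if n_fruit > 0 and not pool.fruit_idx:
        raise ValueError("paste pool contains no fruit instances")
    if n_leaf > 0 and not pool.leaf_idx:
        raise ValueError("paste pool contains no leaf instances")

    out = target.pixels.copy()
    h_t, w_t = out.shape[:2]
    new_boxes: list[BBox] = []
    records: list[PasteRecord] = []
    cover = np.zeros((h_t, w_t), dtype=bool)

    plan = [("fruit", int(rng.choice(pool.fruit_idx))) for _ in range(n_fruit)] + [
        ("leaf", int(rng.choice(pool.leaf_idx))) for _ in range(n_leaf)
    ]
    existing_corners = [bbox_to_corners(b, target.size) for b in target.boxes]
    for category, idx in plan:
        inst, src_pixels = pool.entries[idx]
        patch, mask = _crop_instance(inst, src_pixels)
        flip = bool(rng.uniform() < cfg.flip_prob)
        angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
        scale = float(rng.uniform(*cfg.paste_scale))
        patch, mask = transform_instance(patch, mask, flip, angle, scale)
        ph, pw = mask.shape
        if ph >= h_t or pw >= w_t or not mask.any():
            warnings.warn(f"pasted instance {idx} does not fit target; skipped")
            continue
        placed = None
        for _ in range(20):
            x0 = int(rng.integers(0, w_t - pw + 1))
            y0 = int(rng.integers(0, h_t - ph + 1))
            if category == "leaf":
                placed = (x0, y0)
                break
            cand = (x0, y0, x0 + pw, y0 + ph)
            if all(box_iou(cand, c) <= cfg.paste_iou_limit for c in existing_corners):
                placed = (x0, y0)
                break
        if placed is None:
            warnings.warn(f"no placement found for instance {idx}; skipped")
            continue
        x0, y0 = placed
        region = out[y0 : y0 + ph, x0 : x0 + pw]
        region[mask] = patch[mask]
        cover[y0 : y0 + ph, x0 : x0 + pw] |= mask
        records.append(
            PasteRecord(idx, category, flip, angle, scale, (x0, y0), (ph, pw))
        )
        if category == "fruit":
            ys, xs = np.nonzero(mask)
            corners = (x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1, y0 + ys.max() + 1)
            new_boxes.append(corners_to_bbox(corners, target.size, inst_category_id(inst)))
            existing_corners.append(tuple(float(c) for c in corners))

    kept: list[BBox] = []
    for b in target.boxes:
        x1, y1, x2, y2 = (int(round(v)) for v in bbox_to_corners(b, target.size))
        area = max((x2 - x1) * (y2 - y1), 1)
        covered = int(cover[y1:y2, x1:x2].sum())
        if covered / area <= cfg.max_paste_cover:
            kept.append(b)
    return (
        LabeledImage(pixels=out, boxes=kept + new_boxes, image_id=target.image_id + "+cp"),
        records,
    )


def inst_category_id(inst: InstanceMask) -> int:
    """Pasted fruits keep the single-category id 0 by default."""
    return 0


def _resize(pixels: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (W, H)."""
    return np.asarray(Image.fromarray(pixels).resize(size, Image.BILINEAR))


def mosaic(
    images: Sequence[LabeledImage],
    preset_size: int,
    rng: np.random.Generator | None = None,
    center: tuple[float, float] | None = None,
    crop_frac: float | None = None,
    min_visibility: float = 0.1,
) -> tuple[LabeledImage, list[TransformRecord]]:
    """Tile four images around a center point and cut a training canvas.

    Each image is resized to ``preset_size`` square, placed in one quadrant
    of a double-size canvas around ``center`` (random in [0.5s, 1.5s]^2),
    and the canvas is cropped to a centered window of ``crop_frac * 2s``
    (random in the configured range, 1.0 = whole canvas) then resized to
    ``preset_size``.  Boxes are clipped to the crop; boxes whose clipped area
    falls below ``min_visibility`` of the original, or with any side under
    2 px, are dropped.  Returns the composed image and one
    :class:`TransformRecord` per quadrant mapping source pixels to output
    pixels.
    """
    if len(images) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(images)}")
    rng = np.random.default_rng() if rng is None else rng
    s = preset_size
    if center is None:
        center = (float(rng.uniform(0.5 * s, 1.5 * s)), float(rng.uniform(0.5 * s, 1.5 * s)))
    if crop_frac is None:
        crop_frac = float(rng.uniform(0.6, 1.0))
    xc, yc = center
    canvas = np.full((2 * s, 2 * s, 3), _PAD_FILL, dtype=np.uint8)

    # crop window: centered on the canvas, side crop_frac * 2s
    side = crop_frac * 2 * s
    cx0, cy0 = s - side / 2.0, s - side / 2.0
    out_scale = s / side

    placements = [  # (x1, y1) = top-left of each resized image on the canvas
        (xc - s, yc - s),
        (xc, yc - s),
        (xc - s, yc),
        (xc, yc),
    ]
    records: list[TransformRecord] = []
    out_boxes: list[BBox] = []
    for img, (px, py) in zip(images, placements):
        resized = _resize(img.pixels, (s, s))
        sx = s / img.size[0]
        sy = s / img.size[1]
        # paste with clipping at canvas bounds
        x1, y1 = int(round(px)), int(round(py))
        src_x1, src_y1 = max(0, -x1), max(0, -y1)
        dst_x1, dst_y1 = max(0, x1), max(0, y1)
        dst_x2, dst_y2 = min(2 * s, x1 + s), min(2 * s, y1 + s)
        if dst_x2 > dst_x1 and dst_y2 > dst_y1:
            canvas[dst_y1:dst_y2, dst_x1:dst_x2] = resized[
                src_y1 : src_y1 + (dst_y2 - dst_y1), src_x1 : src_x1 + (dst_x2 - dst_x1)
            ]
        # full source->output transform: resize, place, crop, final resize
        rec = TransformRecord(
            scale=(sx * out_scale, sy * out_scale),
            pad=(
                (x1 - cx0) * out_scale,
                (y1 - cy0) * out_scale,
                0.0,
                0.0,
            ),
            note="mosaic-quadrant",
        )
        records.append(rec)
        for b in img.boxes:
            bx1, by1, bx2, by2 = bbox_to_corners(b, img.size)
            ox1, oy1 = rec.apply_point(bx1, by1, img.size)
            ox2, oy2 = rec.apply_point(bx2, by2, img.size)
            cx1_, cy1_ = np.clip(ox1, 0, s), np.clip(oy1, 0, s)
            cx2_, cy2_ = np.clip(ox2, 0, s), np.clip(oy2, 0, s)
            if cx2_ - cx1_ < 2 or cy2_ - cy1_ < 2:
                continue
            area_full = (ox2 - ox1) * (oy2 - oy1)
            area_clip = (cx2_ - cx1_) * (cy2_ - cy1_)
            if area_clip < min_visibility * area_full:
                continue
            out_boxes.append(corners_to_bbox((cx1_, cy1_, cx2_, cy2_), (s, s), b.category_id))

    ix0, iy0 = int(round(cx0)), int(round(cy0))
    iside = int(round(side))
    cropped = canvas[iy0 : iy0 + iside, ix0 : ix0 + iside]
    out = _resize(cropped, (s, s))
    return LabeledImage(pixels=out, boxes=out_boxes, image_id="mosaic"), records


def sample_mixup_lambda(alpha: float, rng: np.random.Generator | None = None) -> float:
    """Draw the mixup coefficient ``lam ~ Beta(alpha, alpha)``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    rng = np.random.default_rng() if rng is None else rng
    return float(rng.beta(alpha, alpha))


def mixup(a: LabeledImage, b: LabeledImage, lam: float) -> LabeledImage:
    """Blend two same-size images: ``lam * a + (1 - lam) * b``; concatenate labels.

    The blend is computed in real arithmetic and rounded once to 8-bit.
    Both label sets are kept at full weight — no lambda weighting and no
    deduplication of overlapping boxes.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"size mismatch: {a.pixels.shape} vs {b.pixels.shape}")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    blend = lam * a.pixels.astype(np.float64) + (1.0 - lam) * b.pixels.astype(np.float64)
    pixels = np.clip(np.rint(blend), 0, 255).astype(np.uint8)
    return LabeledImage(
        pixels=pixels, boxes=list(a.boxes) + list(b.boxes), image_id=f"{a.image_id}*{b.image_id}"
    )


def letterbox(image: LabeledImage, target: int) -> tuple[LabeledImage, TransformRecord]:
    """Aspect-preserving resize + symmetric gray padding to ``target`` square."""
    w, h = image.size
    r = min(target / w, target / h)
    nw, nh = max(1, int(round(w * r))), max(1, int(round(h * r)))
    resized = _resize(image.pixels, (nw, nh))
    pad_l = (target - nw) // 2
    pad_t = (target - nh) // 2
    canvas = np.full((target, target, 3), _PAD_FILL, dtype=np.uint8)
    canvas[pad_t : pad_t + nh, pad_l : pad_l + nw] = resized
    rec = TransformRecord(
        scale=(nw / w, nh / h),
        pad=(pad_l, pad_t, target - nw - pad_l, target - nh - pad_t),
        note="letterbox",
    )
    boxes = []
    for b in image.boxes:
        x1, y1, x2, y2 = bbox_to_corners(b, image.size)
        x1, y1 = rec.apply_point(x1, y1, image.size)
        x2, y2 = rec.apply_point(x2, y2, image.size)
        boxes.append(corners_to_bbox((x1, y1, x2, y2), (target, target), b.category_id))
    return (
        LabeledImage(pixels=canvas, boxes=boxes, image_id=image.image_id),
        rec,
    )


def _hsv_jitter(image: LabeledImage, gains: tuple[float, float, float],
                rng: np.random.Generator) -> LabeledImage:
    gh, gs, gv = (rng.uniform(-1, 1) * g for g in gains)
    hsv = rgb_to_hsv(image.pixels / 255.0)
    hsv[..., 0] = (hsv[..., 0] + gh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + gs), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + gv), 0, 1)
    pixels = np.clip(np.rint(hsv_to_rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return replace(image, pixels=pixels)


@dataclass
class AugmentedSample:
    image: LabeledImage
    applied: dict[str, bool] = field(default_factory=dict)


def draw_schedule(config: AugmentConfig, rng: np.random.Generator,
                  allow_mixup: bool = True) -> dict[str, bool]:
    """Draw the per-sample Bernoulli decisions of the augmentation schedule."""
    return {
        "copy_paste": bool(rng.uniform() < config.p_copy_paste),
        "mosaic": bool(rng.uniform() < config.p_mosaic),
        "mixup": bool(allow_mixup and rng.uniform() < config.p_mixup),
    }


def apply_train_pipeline(
    dataset: Sequence[LabeledImage],
    config: AugmentConfig,
    rng: np.random.Generator | None = None,
    pool: PastePool | None = None,
    n_samples: int | None = None,
    jitter: bool = True,
) -> Iterator[AugmentedSample]:
    """Stream augmented training samples from a dataset of labeled images.

    Per sample: copy-paste with ``p_copy_paste``, mosaic with ``p_mosaic``
    (drawing three extra images), mixup with ``p_mixup`` against a second
    independently augmented sample, then letterboxing to ``preset_size``.
    Runs forever unless ``n_samples`` is given.  Fully deterministic under a
    seeded generator.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if pool is None and any(img.masks for img in dataset):
        pool = PastePool([img for img in dataset if img.masks])

    def one(allow_mixup: bool) -> tuple[LabeledImage, dict[str, bool]]:
        img = dataset[int(rng.integers(len(dataset)))]
        sched = draw_schedule(config, rng, allow_mixup)
        applied = {"copy_paste": False, "mosaic": False, "mixup": False}
        if pool is not None and sched["copy_paste"]:
            img, _ = copy_paste(
                img, pool, config.n_fruit_paste, config.n_leaf_paste, rng, config
            )
            applied["copy_paste"] = True
        if jitter and any(g > 0 for g in config.hsv_jitter):
            img = _hsv_jitter(img, config.hsv_jitter, rng)
        if sched["mosaic"]:
            extra = [dataset[int(rng.integers(len(dataset)))] for _ in range(3)]
            img, _ = mosaic(
                [img] + extra, config.preset_size, rng,
                crop_frac=float(rng.uniform(*config.crop_scale)),
                min_visibility=config.min_visibility,
            )
            applied["mosaic"] = True
        if sched["mixup"]:
            other, _ = one(allow_mixup=False)
            if other.pixels.shape != img.pixels.shape:
                other, _ = letterbox_to_match(other, img)
            lam = sample_mixup_lambda(config.mixup_alpha, rng)
            img = mixup(img, other, lam)
            applied["mixup"] = True
        return img, applied

    produced = 0
    while n_samples is None or produced < n_samples:
        img, applied = one(allow_mixup=True)
        img, _ = letterbox(img, config.preset_size)
        if rng.uniform() < config.flip_prob:
            img = hflip(img)
        yield AugmentedSample(image=img, applied=applied)
        produced += 1


def hflip(image: LabeledImage) -> LabeledImage:
    boxes = [replace(b, cx=1.0 - b.cx) for b in image.boxes]
    return LabeledImage(
        pixels=image.pixels[:, ::-1].copy(), boxes=boxes, image_id=image.image_id
    )


def letterbox_to_match(img: LabeledImage, ref: LabeledImage) -> tuple[LabeledImage, TransformRecord]:
    """Letterbox ``img`` to the (square) size of ``ref`` for mixup."""
    return letterbox(img, ref.pixels.shape[0])
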