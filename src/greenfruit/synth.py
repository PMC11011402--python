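"""Synthetic green-on-green orchard scenes with boxes and instance masks.

The generator emulates the hard regime of field imagery of unripe fruit: the
targets share hue with the foliage behind them, are partly hidden by leaves,
and exposure varies shot to shot.  Each scene carries per-instance binary
masks, so the generator doubles as the segmentation provider required by the
mask-guided copy-paste augmentation (the masks play the role a general
segmentation model would play on real photographs).

Fruits are shaded ellipses with a specular highlight; leaf occluders are
elongated rotated ellipses.  Both are laid down in HSV and converted to RGB.
Boxes are amodal: a fruit's box covers its full rendered extent even where a
leaf is composited above it, matching common field-annotation practice.
Masks stored on :class:`~greenfruit.labels.LabeledImage` are likewise the
full pre-occlusion instance masks.
"""

from __future__ import annotations

import csv
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .boxes import BBox, bbox_to_corners, box_iou
from .labels import LabeledImage, split_dataset, write_dataset_yaml, write_labels

__all__ = ["SceneConfig", "InstanceMask", "generate_scene", "get_instances", "render_dataset"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic orchard scene distribution.

    Hues are degrees on the color wheel; ``hue_delta`` is the (small) offset
    of fruit hue from the foliage hue — the similar-color premise of the
    whole problem.  ``exposure_jitter`` multiplies the value channel to mimic
    sunny/cloudy/overcast acquisition conditions.
    """

    image_size: tuple[int, int] = (640, 640)  # (W, H)
    n_fruit: tuple[int, int] = (1, 8)
    fruit_radius: tuple[int, int] = (12, 60)
    fruit_eccentricity: tuple[float, float] = (0.75, 1.0)
    hue_base: float = 110.0
    hue_delta: float = 12.0
    n_leaf_occluders: tuple[int, int] = (5, 20)
    occlusion_prob: float = 0.3
    exposure_jitter: tuple[float, float] = (0.75, 1.25)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        for name in ("n_fruit", "fruit_radius", "fruit_eccentricity", "n_leaf_occluders",
                     "exposure_jitter"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range is empty: {(lo, hi)}")
        if 2 * self.fruit_radius[1] > min(w, h):
            raise ValueError(
                f"fruit_radius {self.fruit_radius} incompatible with image size {self.image_size}"
            )
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise ValueError("occlusion_prob must be in [0, 1]")
        if not (0.0 <= self.hue_delta <= 60.0):
            raise ValueError("hue_delta must stay small (<= 60 degrees) for the similar-color premise")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "SceneConfig":
        """A 160x160 miniature of the default scene for CPU-budget training."""
        return cls(
            image_size=(160, 160),
            n_fruit=(1, 4),
            fruit_radius=(10, 28),
            n_leaf_occluders=(3, 8),
            seed=seed,
        )


@dataclass
class InstanceMask:
    """A binary instance mask with its category and originating image."""

    mask: np.ndarray  # H x W bool
    category: str  # "fruit" | "leaf"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("instance mask is empty")
        if self.category not in ("fruit", "leaf"):
            raise ValueError(f"unknown category {self.category!r}")


def _ellipse_field(w: int, h: int, cx: float, cy: float, rx: float, ry: float,
                   angle: float) -> np.ndarray:
    """Normalized squared radius of each pixel under a rotated ellipse (<=1 inside)."""
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    dx, dy = xx - cx, yy - cy
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    return u * u + v * v


def _mask_bbox(mask: np.ndarray, image_size: tuple[int, int], category_id: int = 0) -> BBox:
    """Tight normalized center-format box of a binary mask (half-open pixels)."""
    ys, xs = np.nonzero(mask)
    w, h = image_size
    x1, x2 = int(xs.min()), int(xs.max()) + 1
    y1, y2 = int(ys.min()), int(ys.max()) + 1
    return BBox(category_id, (x1 + x2) / 2 / w, (y1 + y2) / 2 / h, (x2 - x1) / w, (y2 - y1) / h)


def _render_background(w: int, h: int, hue_base: float, rng: np.random.Generator) -> np.ndarray:
    """Foliage-like HSV canvas: low-frequency blotches + pixel-level texture."""
    coarse = rng.uniform(0.0, 1.0, size=(h // 16 + 1, w // 16 + 1))
    blotch = np.kron(coarse, np.ones((16, 16)))[:h, :w]
    hsv = np.empty((h, w, 3))
    hsv[..., 0] = ((hue_base + rng.normal(0, 4, size=(h, w))) % 360.0) / 360.0
    hsv[..., 1] = np.clip(0.55 + 0.2 * (blotch - 0.5) + rng.normal(0, 0.05, (h, w)), 0.2, 1.0)
    hsv[..., 2] = np.clip(0.35 + 0.25 * blotch + rng.normal(0, 0.04, (h, w)), 0.05, 0.9)
    return hsv


def _sample_fruit_geometry(cfg: SceneConfig, w: int, h: int, rng: np.random.Generator):
    """Sample one fruit's placement: (cx, cy, rx, ry, angle)."""
    r = rng.uniform(*cfg.fruit_radius)
    ecc = rng.uniform(*cfg.fruit_eccentricity)
    rx, ry = r, r * ecc
    angle = rng.uniform(0, np.pi)
    margin = max(rx, ry)
    cx = rng.uniform(margin, w - margin)
    cy = rng.uniform(margin, h - margin)
    return cx, cy, rx, ry, angle


def _paint_fruit(hsv: np.ndarray, cfg: SceneConfig, geom, field_sq: np.ndarray,
                 mask: np.ndarray, rng: np.random.Generator) -> None:
    """Shade one fruit ellipse in place given its sampled geometry and mask."""
    h, w = hsv.shape[:2]
    cx, cy, rx, ry, _angle = geom
    # hue offset stays within the configured similar-color band
    hue = (cfg.hue_base + rng.uniform(0.5, 1.0) * cfg.hue_delta * rng.choice([-1.0, 1.0])) % 360.0
    rad = np.sqrt(np.clip(field_sq, 0.0, 1.0))
    shade = 0.75 - 0.35 * rad**2  # center bright, limb dark
    # specular highlight offset toward the upper-left
    hx, hy = cx - 0.35 * rx, cy - 0.35 * ry
    spec = np.exp(-(((np.arange(w) - hx) ** 2)[None, :] / (0.18 * rx * rx + 1e-9)
                    + ((np.arange(h) - hy) ** 2)[:, None] / (0.18 * ry * ry + 1e-9)))
    hsv[..., 0][mask] = hue / 360.0
    hsv[..., 1][mask] = np.clip(0.65 - 0.45 * spec[mask], 0.05, 1.0)
    hsv[..., 2][mask] = np.clip(shade[mask] + 0.5 * spec[mask], 0.0, 1.0)


def _paint_leaf(hsv: np.ndarray, cfg: SceneConfig, rng: np.random.Generator,
                near: tuple[float, float] | None) -> np.ndarray:
    """Draw one elongated leaf lobe; optionally centered near a fruit to occlude it."""
    h, w = hsv.shape[:2]
    length = rng.uniform(0.6, 1.4) * np.mean(cfg.fruit_radius)
    width = length * rng.uniform(0.25, 0.45)
    angle = rng.uniform(0, np.pi)
    if near is not None:
        cx = np.clip(near[0] + rng.normal(0, length * 0.5), 0, w - 1)
        cy = np.clip(near[1] + rng.normal(0, length * 0.5), 0, h - 1)
    else:
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
    field_sq = _ellipse_field(w, h, cx, cy, length, width, angle)
    mask = field_sq <= 1.0
    if not mask.any():
        return mask
    hue = (cfg.hue_base + rng.normal(0, 5)) % 360.0
    rad = np.sqrt(np.clip(field_sq, 0.0, 1.0))
    hsv[..., 0][mask] = hue / 360.0
    hsv[..., 1][mask] = np.clip(0.6 + rng.normal(0, 0.05), 0.2, 1.0)
    hsv[..., 2][mask] = np.clip(0.3 + 0.3 * (1 - rad[mask]) + rng.normal(0, 0.03), 0.05, 0.9)
    return mask


def generate_scene(config: SceneConfig, rng: np.random.Generator | int | None = None,
                   image_id: str = "scene") -> LabeledImage:
    """Render one scene: background, fruits, leaf occluders, exposure and noise.

    Deterministic given the generator state.  Every fruit gets an amodal
    instance mask and the tight bounding box of that mask; leaves get masks
    but no boxes.  Fruit placement keeps pairwise box IoU <= 0.3 where
    possible (20 retries, then the overlapping placement is accepted).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    w, h = config.image_size
    hsv = _render_background(w, h, config.hue_base, rng)

    n_fruit = int(rng.integers(config.n_fruit[0], config.n_fruit[1] + 1))
    fruit_masks: list[np.ndarray] = []
    boxes: list[BBox] = []
    for _ in range(n_fruit):
        placed = None
        for _attempt in range(20):
            geom = _sample_fruit_geometry(config, w, h, rng)
            field_sq = _ellipse_field(w, h, *geom)
            mask = field_sq <= 1.0
            if not mask.any():
                continue
            box = _mask_bbox(mask, (w, h))
            corners = bbox_to_corners(box, (w, h))
            if all(box_iou(corners, bbox_to_corners(b, (w, h))) <= 0.3 for b in boxes):
                placed = (geom, field_sq, mask, box)
                break
            if placed is None:
                placed = (geom, field_sq, mask, box)
        if placed is not None:
            geom, field_sq, mask, box = placed
            _paint_fruit(hsv, config, geom, field_sq, mask, rng)
            fruit_masks.append(mask)
            boxes.append(box)

    n_leaf = int(rng.integers(config.n_leaf_occluders[0], config.n_leaf_occluders[1] + 1))
    leaf_masks: list[np.ndarray] = []
    fruit_centers = [((b.cx * w), (b.cy * h)) for b in boxes]
    for _ in range(n_leaf):
        occlude = bool(fruit_centers) and rng.uniform() < config.occlusion_prob
        near = fruit_centers[int(rng.integers(len(fruit_centers)))] if occlude else None
        mask = _paint_leaf(hsv, config, rng, near)
        if mask.any():
            leaf_masks.append(mask)

    rgb = hsv_to_rgb(hsv)
    rgb *= rng.uniform(*config.exposure_jitter)
    rgb = rgb * 255.0 + rng.normal(0.0, config.noise_sd, size=rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    masks = fruit_masks + leaf_masks
    categories = ["fruit"] * len(fruit_masks) + ["leaf"] * len(leaf_masks)
    return LabeledImage(pixels=pixels, boxes=boxes, masks=masks,
                        mask_categories=categories, image_id=image_id)


def get_instances(image: LabeledImage) -> list[InstanceMask]:
    """Return the per-instance masks of a scene, labeled fruit/leaf.

    This is the segmentation-provider contract: the synthetic provider simply
    returns the stored ground-truth masks.  An adapter wrapping a real
    segmentation model can satisfy the same contract on real photographs.
    Raises if the image carries no masks.
    """
    if image.masks is None:
        raise ValueError(
            f"image {image.image_id!r} carries no instance masks and no provider is configured"
        )
    return [
        InstanceMask(mask=m, category=c, source_id=image.image_id)
        for m, c in zip(image.masks, image.mask_categories)
    ]


def save_masks(image: LabeledImage, masks_dir: Path, stem: str) -> None:
    """Write the instance-mask stack (npz, amodal) and an indexed preview PNG."""
    masks_dir.mkdir(parents=True, exist_ok=True)
    stack = np.stack(image.masks) if image.masks else np.zeros((0,) + image.pixels.shape[:2], bool)
    np.savez_compressed(masks_dir / f"{stem}.npz", masks=stack,
                        categories=np.array(image.mask_categories or [], dtype="U8"))
    indexed = np.zeros(image.pixels.shape[:2], dtype=np.uint8)
    for i, m in enumerate(image.masks or [], start=1):  # draw order: later wins
        indexed[m] = i
    Image.fromarray(indexed, mode="L").save(masks_dir / f"{stem}.png")


def load_masks(masks_dir: Path, stem: str) -> tuple[list[np.ndarray], list[str]]:
    with np.load(masks_dir / f"{stem}.npz") as data:
        stack, cats = data["masks"], data["categories"]
    return [stack[i] for i in range(stack.shape[0])], [str(c) for c in cats]


def render_dataset(config: SceneConfig, n_images: int, out_dir: str | Path,
                   ratio: float = 0.7, class_names: tuple[str, ...] = ("fruit",)) -> Path:
    """Render ``n_images`` scenes into the on-disk dataset layout, split 7:3.

    Writes ``images/{train,test}``, ``labels/{train,test}``, ``masks/`` and
    ``dataset.yaml`` + ``masks.csv``.  Deterministic given ``config.seed``.
    On failure, partially written output is removed.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    try:
        rng = np.random.default_rng(config.seed)
        stems = [f"scene_{i:05d}" for i in range(n_images)]
        split = split_dataset(stems, ratio=ratio, seed=config.seed)
        which = {s: "train" for s in split.train_ids}
        which.update({s: "test" for s in split.test_ids})
        rows = []
        for stem in stems:
            scene = generate_scene(config, rng, image_id=stem)
            part = which[stem]
            img_dir = out_dir / "images" / part
            lbl_dir = out_dir / "labels" / part
            img_dir.mkdir(parents=True, exist_ok=True)
            lbl_dir.mkdir(parents=True, exist_ok=True)
            Image.fromarray(scene.pixels).save(img_dir / f"{stem}.png")
            write_labels(scene.boxes, lbl_dir / f"{stem}.txt")
            save_masks(scene, out_dir / "masks", stem)
            for i, cat in enumerate(scene.mask_categories or []):
                rows.append((stem, i, cat))
        with open(out_dir / "masks.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stem", "instance", "category"])
            writer.writerows(rows)
        write_dataset_yaml(out_dir, class_names)
    except Exception:
        if created and out_dir.exists():
            shutil.rmtree(out_dir)
        raise
    return out_dir


def load_labeled_image(root: str | Path, split: str, stem: str,
                       with_masks: bool = True) -> LabeledImage:
    """Read one image + labels (+ masks if present) back from the dataset layout."""
    root = Path(root)
    pixels = np.asarray(Image.open(root / "images" / split / f"{stem}.png").convert("RGB"))
    from .labels import read_labels

    boxes = read_labels(root / "labels" / split / f"{stem}.txt")
    masks = cats = None
    if with_masks and (root / "masks" / f"{stem}.npz").exists():
        masks, cats = load_masks(root / "masks", stem)
    return LabeledImage(pixels=pixels, boxes=list(boxes), masks=masks,
                        mask_categories=cats, image_id=stem)
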