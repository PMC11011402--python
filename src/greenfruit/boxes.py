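"""Bounding-box records and coordinate conventions.

Ground-truth labels use the YOLO dialect: one box per line, category id plus a
center-format box ``(cx, cy, w, h)`` normalized to ``[0, 1]`` by image width
and height.  Pixel coordinates are 0-based and boxes are half-open
``[x1, x2) x [y1, y2)``, so a full-image box on a WxH image maps to
``(0, 0, W, H)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BBox",
    "DetectionBox",
    "bbox_to_corners",
    "corners_to_bbox",
    "box_iou",
    "box_iou_matrix",
]


@dataclass(frozen=True)
class BBox:
    """A normalized center-format ground-truth box.

    Attributes
    ----------
    category_id : int
        Non-negative class index.
    cx, cy : float
        Box center, normalized to [0, 1] by image width / height.
    w, h : float
        Box width / height, normalized; strictly positive.
    """

    category_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.category_id < 0:
            raise ValueError(f"category_id must be >= 0, got {self.category_id}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")


@dataclass(frozen=True)
class DetectionBox:
    """A model detection: class, confidence, absolute corner box in pixels."""

    category_id: int
    confidence: float
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence={self.confidence} outside [0, 1]")
        if self.x1 >= self.x2 or self.y1 >= self.y2:
            raise ValueError(
                f"degenerate corner box ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


def bbox_to_corners(box: BBox, image_size: tuple[int, int]) -> tuple[float, float, float, float]:
    """Convert a normalized center box to absolute pixel corners ``(x1, y1, x2, y2)``.

    Raises ``ValueError`` if the box degenerates (zero extent) after scaling.
    """
    w_img, h_img = image_size
    if w_img <= 0 or h_img <= 0:
        raise ValueError(f"image size must be positive, got {image_size}")
    x1 = (box.cx - box.w / 2.0) * w_img
    x2 = (box.cx + box.w / 2.0) * w_img
    y1 = (box.cy - box.h / 2.0) * h_img
    y2 = (box.cy + box.h / 2.0) * h_img
    if x2 <= x1 or y2 <= y1:
        raise ValueError(f"box degenerates to zero extent on image {image_size}")
    return (x1, y1, x2, y2)


def corners_to_bbox(
    corners: Sequence[float], image_size: tuple[int, int], category_id: int = 0
) -> BBox:
    """Convert absolute pixel corners to a normalized center-format :class:`BBox`."""
    w_img, h_img = image_size
    if w_img <= 0 or h_img <= 0:
        raise ValueError(f"image size must be positive, got {image_size}")
    x1, y1, x2, y2 = corners
    if x2 <= x1 or y2 <= y1:
        raise ValueError(f"degenerate corner box {tuple(corners)}")
    return BBox(
        category_id=category_id,
        cx=(x1 + x2) / 2.0 / w_img,
        cy=(y1 + y2) / 2.0 / h_img,
        w=(x2 - x1) / w_img,
        h=(y2 - y1) / h_img,
    )


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two corner boxes; 0 when disjoint.

    The IoU is the overlap ratio between two boxes and underlies both
    non-maximum suppression and the true-positive matching rule.
    """
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError("degenerate box passed to box_iou")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two arrays of corner boxes, shapes (N,4) and (M,4)."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou
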