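"""YOLO-format label files, dataset layout, and train/test splitting.

Dataset layout on disk::

    root/
      images/{train,test}/<stem>.png
      labels/{train,test}/<stem>.txt
      masks/<stem>.png          # optional indexed instance masks
      masks.csv                 # instance -> category map
      dataset.yaml              # paths + class names

Each label file holds one ``<class> <cx> <cy> <w> <h>`` line per box,
normalized floats written with six decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .boxes import BBox

__all__ = [
    "LabeledImage",
    "DatasetSplit",
    "read_labels",
    "write_labels",
    "split_dataset",
    "write_dataset_yaml",
    "read_dataset_yaml",
]


@dataclass
class LabeledImage:
    """An RGB image with its ground-truth boxes and optional instance masks.

    ``masks`` aligns with fruit boxes first (one mask per box, in order),
    followed by leaf-occluder masks that carry no box.  ``mask_categories``
    labels each mask ``"fruit"`` or ``"leaf"``.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    boxes: list[BBox] = field(default_factory=list)
    masks: list[np.ndarray] | None = None  # each H x W bool
    mask_categories: list[str] | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.masks is not None:
            if self.mask_categories is None or len(self.masks) != len(self.mask_categories):
                raise ValueError("masks and mask_categories must align")

    @property
    def size(self) -> tuple[int, int]:
        """(W, H) in pixels."""
        return (self.pixels.shape[1], self.pixels.shape[0])


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
        if not (0.0 < self.ratio < 1.0):
            raise ValueError(f"ratio must be in (0, 1), got {self.ratio}")


def read_labels(path: str | Path, image_size: tuple[int, int] | None = None) -> list[BBox]:
    """Read a YOLO label file into a list of :class:`BBox`.

    ``image_size`` is accepted for interface symmetry (labels are normalized,
    so it is not needed to parse them).  Malformed lines raise ``ValueError``
    naming the offending line number; out-of-range coordinates raise through
    the :class:`BBox` validator.
    """
    path = Path(path)
    boxes: list[BBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable number: {exc}") from exc
        try:
            boxes.append(BBox(cls, *vals))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return boxes


def write_labels(boxes: Sequence[BBox], path: str | Path) -> None:
    """Write boxes to a YOLO label file, one six-decimal line per box."""
    path = Path(path)
    lines = [
        f"{b.category_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}" for b in boxes
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def split_dataset(ids: Sequence[str], ratio: float = 0.7, seed: int = 0) -> DatasetSplit:
    """Random disjoint train/test split with ``|train| = floor(ratio * N)``.

    Deterministic for a fixed seed.  Requires at least two ids so both halves
    are non-empty-capable.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if len(ids) < 2:
        raise ValueError(f"need at least 2 ids to split, got {len(ids)}")
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = math.floor(ratio * len(ids))
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return DatasetSplit(train_ids=train, test_ids=test, ratio=ratio)


def write_dataset_yaml(
    root: str | Path, class_names: Sequence[str], path_name: str = "dataset.yaml"
) -> Path:
    root = Path(root)
    doc = {
        "path": ".",  # relative to the yaml's own directory
        "train": "images/train",
        "test": "images/test",
        "names": {i: n for i, n in enumerate(class_names)},
        "nc": len(class_names),
    }
    out = root / path_name
    out.write_text(yaml.safe_dump(doc, sort_keys=False))
    return out


def read_dataset_yaml(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("path", "train", "test", "names"):
        if key not in doc:
            raise ValueError(f"dataset yaml missing key {key!r}")
    return doc


def list_split_stems(root: str | Path, split: str) -> list[str]:
    """Sorted stems of the images present under ``images/<split>``."""
    img_dir = Path(root) / "images" / split
    return sorted(p.stem for p in img_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
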