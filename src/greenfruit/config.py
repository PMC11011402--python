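"""Run configuration: YAML loading, defaults, validation, seed fan-out.

A run is described by one YAML document with optional blocks ``scene``
(synthetic generator), ``augment`` (augmentation schedule), ``arch``
(detector architecture), ``hyp`` (training hyperparameters) and scalar
fields ``seed`` / ``n_classes``.  Defaults follow the study conditions:
copy-paste probability 1.0 with 4 fruit + 15 leaf pastes, mosaic 0.8,
mixup 0.3, IoU threshold 0.5, 7:3 train/test split.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .model import DEFAULT_ARCH
from .synth import SceneConfig
from .train import HYP_TRAIN_DEFAULTS

__all__ = ["RunConfig", "load_config", "derive_seed"]

_TOP_KEYS = {"seed", "n_classes", "split_ratio", "iou_threshold",
             "scene", "augment", "arch", "hyp", "verbosity"}


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, so stages can re-run in isolation."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    n_classes: int = 1
    split_ratio: float = 0.7
    iou_threshold: float = 0.5
    verbosity: int = 1
    scene: SceneConfig = field(default_factory=SceneConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    arch: dict = field(default_factory=lambda: dict(DEFAULT_ARCH))
    hyp: dict = field(default_factory=lambda: dict(HYP_TRAIN_DEFAULTS))

    def echo(self) -> str:
        """The effective configuration as YAML (logged so runs are reproducible)."""
        doc = {
            "seed": self.seed,
            "n_classes": self.n_classes,
            "split_ratio": self.split_ratio,
            "iou_threshold": self.iou_threshold,
            "scene": _dataclass_doc(self.scene),
            "augment": _dataclass_doc(self.augment),
            "arch": {k: list(v) if isinstance(v, tuple) else v for k, v in self.arch.items()},
            "hyp": {k: list(v) if isinstance(v, tuple) else v for k, v in self.hyp.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _dataclass_doc(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _build_block(cls, block: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(
            f"unknown {name} keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in block:
            continue
        v = block[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a run config from YAML with flag overrides applied on top.

    An empty (or absent) file yields the full documented default set.
    Unknown keys raise ``ValueError`` listing the valid ones.
    """
    doc: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
            doc = loaded
    for key, value in (overrides or {}).items():
        if "." in key:  # dotted overrides address block fields, e.g. augment.p_mosaic
            block, sub = key.split(".", 1)
            doc.setdefault(block, {})[sub] = value
        else:
            doc[key] = value

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}")
    for key, expect in (("seed", int), ("n_classes", int), ("verbosity", int),
                        ("split_ratio", float), ("iou_threshold", float)):
        if key in doc and not isinstance(doc[key], (int, float)):
            raise ValueError(f"config key {key!r} must be numeric")

    cfg = RunConfig(
        seed=int(doc.get("seed", 0)),
        n_classes=int(doc.get("n_classes", 1)),
        split_ratio=float(doc.get("split_ratio", 0.7)),
        iou_threshold=float(doc.get("iou_threshold", 0.5)),
        verbosity=int(doc.get("verbosity", 1)),
        scene=_build_block(SceneConfig, doc.get("scene", {}) or {}, "scene"),
        augment=_build_block(AugmentConfig, doc.get("augment", {}) or {}, "augment"),
        arch=dict(DEFAULT_ARCH, **(doc.get("arch", {}) or {})),
        hyp=dict(HYP_TRAIN_DEFAULTS, **(doc.get("hyp", {}) or {})),
    )
    bad_arch = set(cfg.arch) - set(DEFAULT_ARCH)
    if bad_arch:
        raise ValueError(f"unknown arch keys {sorted(bad_arch)}; valid: {sorted(DEFAULT_ARCH)}")
    bad_hyp = set(cfg.hyp) - set(HYP_TRAIN_DEFAULTS)
    if bad_hyp:
        raise ValueError(f"unknown hyp keys {sorted(bad_hyp)}; valid: {sorted(HYP_TRAIN_DEFAULTS)}")
    return cfg
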