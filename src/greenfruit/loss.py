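"""Training loss: CIoU box term, objectness BCE with soft targets, class BCE.

The detector inherits the single-stage family's composite loss.  A ground
truth is assigned to an anchor when their width/height ratios stay within a
factor of 4, and to its grid cell plus the two nearest neighbor cells, which
triples the positive sample count.  The box term is ``1 - CIoU`` averaged
over matches; objectness is binary cross-entropy against CIoU-valued soft
targets at matched locations (zero elsewhere), balanced 4/1/0.4 across the
small/medium/large scales; the class term is BCE at matched locations
(skipped in the single-category case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import AnchorSet, _reshape_head
from .nn import Tensor, bce_with_logits, concat, maximum, minimum

__all__ = ["LossTerms", "HYP_DEFAULTS", "ciou_corners", "ciou_tensor", "assign_targets",
           "compute_loss"]

HYP_DEFAULTS = {
    "box_weight": 0.05,
    "obj_weight": 1.0,
    "cls_weight": 0.5,
    "obj_balance": (4.0, 1.0, 0.4),  # small / medium / large scale
    "anchor_ratio_limit": 4.0,
}


@dataclass
class LossTerms:
    """Weighted loss components; ``total`` keeps the autodiff graph."""

    box: float
    obj: float
    cls: float
    weights: dict = field(default_factory=dict)
    total: Tensor | None = None

    @property
    def total_value(self) -> float:
        return float(self.total.data) if self.total is not None else math.nan


def ciou_corners(a, b) -> float:
    """Complete IoU of two corner boxes (plain floats, for tests and eval).

    ``IoU - d^2 / c^2 - alpha * v``: overlap minus normalized center
    distance minus an aspect-consistency penalty; 1.0 for identical boxes,
    negative for far-apart ones.
    """
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError("degenerate box passed to ciou")
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    wa, ha = ax2 - ax1, ay2 - ay1
    wb, hb = bx2 - bx1, by2 - by1
    union = wa * ha + wb * hb - inter
    iou = inter / union
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw * cw + ch * ch
    d2 = ((ax1 + ax2 - bx1 - bx2) ** 2 + (ay1 + ay2 - by1 - by2) ** 2) / 4.0
    v = (4.0 / math.pi**2) * (math.atan(wa / ha) - math.atan(wb / hb)) ** 2
    alpha = v / (1.0 - iou + v + 1e-12)
    return iou - d2 / c2 - alpha * v


def ciou_tensor(pred_xywh: Tensor, target_xywh: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Differentiable CIoU between predicted and target center-format boxes.

    ``pred_xywh`` is (M, 4) ``(cx, cy, w, h)``; targets are constants.
    The trade-off coefficient alpha is treated as a constant (no gradient),
    as is conventional.
    """
    t = np.asarray(target_xywh, dtype=pred_xywh.data.dtype)
    px1 = pred_xywh[:, 0] - pred_xywh[:, 2] * 0.5
    px2 = pred_xywh[:, 0] + pred_xywh[:, 2] * 0.5
    py1 = pred_xywh[:, 1] - pred_xywh[:, 3] * 0.5
    py2 = pred_xywh[:, 1] + pred_xywh[:, 3] * 0.5
    tx1, tx2 = t[:, 0] - t[:, 2] * 0.5, t[:, 0] + t[:, 2] * 0.5
    ty1, ty2 = t[:, 1] - t[:, 3] * 0.5, t[:, 1] + t[:, 3] * 0.5

    iw = maximum(minimum(px2, tx2) - maximum(px1, tx1), 0.0)
    ih = maximum(minimum(py2, ty2) - maximum(py1, ty1), 0.0)
    inter = iw * ih
    union = pred_xywh[:, 2] * pred_xywh[:, 3] + t[:, 2] * t[:, 3] - inter + eps
    iou = inter / union

    cw = maximum(px2, tx2) - minimum(px1, tx1)
    ch = maximum(py2, ty2) - minimum(py1, ty1)
    c2 = cw * cw + ch * ch + eps
    d2 = ((pred_xywh[:, 0] - t[:, 0]) ** 2.0 + (pred_xywh[:, 1] - t[:, 1]) ** 2.0)
    atan_diff = (pred_xywh[:, 2] / (pred_xywh[:, 3] + eps)).atan() - np.arctan(
        t[:, 2] / (t[:, 3] + eps)
    )
    v = (4.0 / math.pi**2) * atan_diff * atan_diff
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))  # constant
    return iou - d2 / c2 - alpha * v


@dataclass
class ScaleAssignment:
    """Matched targets for one detection scale."""

    img_idx: np.ndarray  # (M,)
    anchor_idx: np.ndarray  # (M,)
    cell_y: np.ndarray  # (M,)
    cell_x: np.ndarray  # (M,)
    t_xy: np.ndarray  # (M, 2) center offset from the cell origin, in (-0.5, 1.5)
    t_wh: np.ndarray  # (M, 2) box size in grid units
    t_cls: np.ndarray  # (M,)
    anchor_wh: np.ndarray  # (M, 2) matched anchor in grid units


def assign_targets(
    targets: np.ndarray,
    anchors: AnchorSet,
    grid_sizes,
    ratio_limit: float = 4.0,
) -> list[ScaleAssignment]:
    """Assign ground truths to anchors and cells on each scale.

    ``targets`` is (T, 6): ``(image_index, class, cx, cy, w, h)`` with the
    box normalized.  ``grid_sizes`` lists (H, W) per scale.  A gt matches an
    anchor when ``max(w/wa, wa/w, h/ha, ha/h) < ratio_limit``; it lands in
    its own cell plus the two neighbor cells its center is closest to.
    """
    targets = np.asarray(targets, dtype=float).reshape(-1, 6)
    anchor_arr = anchors.as_array()
    out: list[ScaleAssignment] = []
    for scale, ((gh, gw), stride) in enumerate(zip(grid_sizes, anchors.strides)):
        empty = lambda *shape: np.zeros(shape)
        if len(targets) == 0:
            out.append(ScaleAssignment(*(np.zeros(0, dtype=int),) * 4,
                                       empty(0, 2), empty(0, 2), np.zeros(0, dtype=int),
                                       empty(0, 2)))
            continue
        anc = anchor_arr[scale] / stride  # grid units
        g = targets.copy()
        g[:, 2] *= gw
        g[:, 4] *= gw
        g[:, 3] *= gh
        g[:, 5] *= gh
        # anchor filter: (T, A)
        r = g[:, None, 4:6] / anc[None, :, :]
        ok = np.maximum(r, 1.0 / r).max(axis=2) < ratio_limit
        t_idx, a_idx = np.nonzero(ok)
        if len(t_idx) == 0:
            out.append(ScaleAssignment(*(np.zeros(0, dtype=int),) * 4,
                                       empty(0, 2), empty(0, 2), np.zeros(0, dtype=int),
                                       empty(0, 2)))
            continue
        gxy = g[t_idx, 2:4]
        # neighbor-cell replication: the center cell plus the two nearest
        frac = gxy % 1.0
        offsets = [np.zeros_like(gxy)]
        keep = [np.ones(len(t_idx), dtype=bool)]
        for axis in (0, 1):
            lo = (frac[:, axis] < 0.5) & (gxy[:, axis] > 1.0)
            hi = (frac[:, axis] >= 0.5) & (gxy[:, axis] < (gw if axis == 0 else gh) - 1.0)
            off_lo = np.zeros_like(gxy)
            off_lo[:, axis] = -1.0
            off_hi = np.zeros_like(gxy)
            off_hi[:, axis] = 1.0
            offsets += [off_lo, off_hi]
            keep += [lo, hi]
        sel_t, sel_a, cells = [], [], []
        for off, k in zip(offsets, keep):
            sel_t.append(t_idx[k])
            sel_a.append(a_idx[k])
            cells.append(np.floor(gxy[k] + off[k]).astype(int))
        t_all = np.concatenate(sel_t)
        a_all = np.concatenate(sel_a)
        cell = np.concatenate(cells)
        cell[:, 0] = np.clip(cell[:, 0], 0, gw - 1)
        cell[:, 1] = np.clip(cell[:, 1], 0, gh - 1)
        out.append(
            ScaleAssignment(
                img_idx=g[t_all, 0].astype(int),
                anchor_idx=a_all,
                cell_y=cell[:, 1],
                cell_x=cell[:, 0],
                t_xy=g[t_all, 2:4] - cell,
                t_wh=g[t_all, 4:6],
                t_cls=g[t_all, 1].astype(int),
                anchor_wh=anc[a_all],
            )
        )
    return out


def compute_loss(
    raw_maps,
    assignments: list[ScaleAssignment],
    n_classes: int = 1,
    hyp: dict | None = None,
) -> LossTerms:
    """Composite detection loss over the three head maps.

    With no assignments the box and class terms are zero and only the
    objectness term (all-background) is computed.  The total is scaled by
    the batch size, following the family convention.
    """
    hyp = dict(HYP_DEFAULTS, **(hyp or {}))
    lbox = Tensor(np.zeros(()))
    lobj = Tensor(np.zeros(()))
    lcls = Tensor(np.zeros(()))
    n_batch = raw_maps[0].shape[0]
    for scale, (raw, asn) in enumerate(zip(raw_maps, assignments)):
        n, ch, gh, gw = raw.shape
        pred = raw.reshape(n, 3, 5 + n_classes, gh, gw).transpose(0, 1, 3, 4, 2)
        tobj = np.zeros((n, 3, gh, gw), dtype=raw.data.dtype)
        if len(asn.img_idx):
            idx = (asn.img_idx, asn.anchor_idx, asn.cell_y, asn.cell_x)
            ps = pred[idx]  # (M, 5+nc)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2.0 * asn.anchor_wh
            pbox = concat([pxy, pwh], axis=1)
            tbox = np.concatenate([asn.t_xy, asn.t_wh], axis=1)
            ciou = ciou_tensor(pbox, tbox)
            lbox = lbox + (1.0 - ciou).mean()
            tobj[idx] = np.clip(ciou.data, 0.0, None)
            if n_classes > 1:
                onehot = np.zeros((len(asn.t_cls), n_classes), dtype=raw.data.dtype)
                onehot[np.arange(len(asn.t_cls)), asn.t_cls] = 1.0
                lcls = lcls + bce_with_logits(ps[:, 5:], onehot).mean()
        obj_logits = pred[..., 4]
        lobj = lobj + bce_with_logits(obj_logits, tobj).mean() * hyp["obj_balance"][scale]
    total = (
        hyp["box_weight"] * lbox + hyp["obj_weight"] * lobj + hyp["cls_weight"] * lcls
    ) * float(n_batch)
    return LossTerms(
        box=float(lbox.data),
        obj=float(lobj.data),
        cls=float(lcls.data),
        weights={k: hyp[k] for k in ("box_weight", "obj_weight", "cls_weight")},
        total=total,
    )
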