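"""Tensor building blocks of the attention-augmented detector backbone.

All blocks operate on batched NCHW tensors (a feature map is C channels by
H by W; the batch axis is implementation plumbing).

* ``ConvBnAct`` — convolution, batch norm, activation.  The SiLU variant
  (CBS) is the general-purpose backbone convolution; the ReLU variant (CBR)
  is the internal workhorse of the Conv-AT block.
* ``ChannelAttention`` — per-channel sigmoid gates from globally pooled
  spatial statistics: ``X * sigmoid(MLP(avgpool(X)) + MLP(maxpool(X)))``
  with a shared two-layer bottleneck MLP.
* ``SpatialAttention`` — per-pixel sigmoid gates from channel-pooled maps:
  average and max across channels, concatenated to a 2-channel map, reduced
  to one channel by a learned 1x1 mix, sigmoid, broadcast onto ``X``.
* ``ConvAT`` — four concatenation stages combining channel-attended,
  spatially-attended and convolved views of the input, closed by an extra
  batch normalization.
* ``C3`` — cross-stage-partial block (bottleneck path + bypass, fused).
* ``SPPF`` — cascaded same-stride max pools concatenated to fuse
  receptive-field scales.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Linear,
    Module,
    Tensor,
    avgpool2d,
    concat,
    maxpool2d,
)

__all__ = [
    "ConvBnAct",
    "ChannelAttention",
    "SpatialAttention",
    "ConvAT",
    "Bottleneck",
    "C3",
    "SPPF",
]


class ConvBnAct(Module):
    """Convolution -> batch norm -> activation (``"silu"`` = CBS, ``"relu"`` = CBR).

    Same-padding ``k // 2``, so spatial size maps to
    ``floor((H + 2p - k) / s) + 1``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 activation: str = "silu", rng: np.random.Generator | None = None):
        super().__init__()
        if activation not in ("silu", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.conv = Conv2d(c_in, c_out, kernel, stride=stride, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.activation == "silu" else y.relu()


def _attention_hidden(c_in: int, reduction: int) -> int:
    """Bottleneck width of the attention MLP: c/r with a floor of min(8, c)."""
    return max(c_in // reduction, min(8, c_in))


class ChannelAttention(Module):
    """Per-channel gates from pooled spatial statistics (shared MLP, sigmoid).

    With all MLP weights zero the gate is sigmoid(0) = 0.5 everywhere, so the
    block reduces exactly to ``0.5 * X``.  Output shape equals input shape.
    """

    def __init__(self, c_in: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_in < 1:
            raise ValueError("channel attention needs at least one channel")
        if reduction < 1 or reduction > max(c_in, 1) * 16:
            raise ValueError(f"invalid reduction {reduction} for {c_in} channels")
        hidden = _attention_hidden(c_in, reduction)
        self.fc1 = Linear(c_in, hidden, bias=False, rng=rng)
        self.fc2 = Linear(hidden, c_in, bias=False, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))  # (N, C)
        mx = x.max(axis=(2, 3))
        gate = (self._mlp(avg) + self._mlp(mx)).sigmoid()  # (N, C)
        n, c = gate.shape
        return x * gate.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Per-pixel gates from channel-pooled maps (1x1 mix of avg|max, sigmoid).

    With the mixing weights zero the block reduces exactly to ``0.5 * X``.
    """

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        self.mix = Conv2d(2, 1, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)  # (N, 1, H, W)
        mx = x.max(axis=1, keepdims=True)
        gate = self.mix(concat([avg, mx], axis=1)).sigmoid()  # (N, 1, H, W)
        return x * gate


class ConvAT(Module):
    """Attention-integration block: concatenation of attended and convolved views.

    Stages (channel-axis concatenation throughout)::

        P = concat(CA(X),       CBR1(X))      # c_in + c_out/2 channels
        H = concat(CBR2(P),     SA(X))        # c_out/2 + c_in
        W = concat(CBR3(H),     CBR4(X))      # c_out/2 + c_out/2
        Y = BN(CBR5(W))                       # c_out

    Downsampling by ``stride`` happens in CBR1/CBR4; the CA and SA paths are
    stride-matched by average pooling so the concatenations align spatially.
    The closing BN is applied on top of CBR5's own BN — both are kept, the
    extra normalization guarding the concatenation-heavy topology.
    """

    def __init__(self, c_in: int, c_out: int, stride: int = 2, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_out % 2:
            raise ValueError(f"ConvAT needs even c_out, got {c_out}")
        c_half = c_out // 2
        self.stride = stride
        self.ca = ChannelAttention(c_in, reduction, rng=rng)
        self.sa = SpatialAttention(rng=rng)
        self.cbr1 = ConvBnAct(c_in, c_half, 3, stride=stride, activation="relu", rng=rng)
        self.cbr2 = ConvBnAct(c_in + c_half, c_half, 3, activation="relu", rng=rng)
        self.cbr3 = ConvBnAct(c_in + c_half, c_half, 3, activation="relu", rng=rng)
        self.cbr4 = ConvBnAct(c_in, c_half, 3, stride=stride, activation="relu", rng=rng)
        self.cbr5 = ConvBnAct(c_out, c_out, 3, activation="relu", rng=rng)
        self.bn_out = BatchNorm2d(c_out)

    def _downsample(self, x: Tensor) -> Tensor:
        return avgpool2d(x, self.stride) if self.stride > 1 else x

    def forward(self, x: Tensor) -> Tensor:
        p = concat([self._downsample(self.ca(x)), self.cbr1(x)], axis=1)
        h = concat([self.cbr2(p), self._downsample(self.sa(x))], axis=1)
        w = concat([self.cbr3(h), self.cbr4(x)], axis=1)
        return self.bn_out(self.cbr5(w))


class Bottleneck(Module):
    """1x1 -> 3x3 convolution pair with optional residual connection."""

    def __init__(self, c: int, shortcut: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.cv1 = ConvBnAct(c, c, 1, rng=rng)
        self.cv2 = ConvBnAct(c, c, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C3(Module):
    """Cross-stage-partial block: bottleneck path and bypass, concatenated.

    The input is projected to two ``c_out / 2`` halves; one passes through
    ``n`` bottlenecks, the other bypasses; a 1x1 fusion restores ``c_out``.
    """

    def __init__(self, c_in: int, c_out: int, n: int = 1, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_out % 2:
            raise ValueError(f"C3 needs even c_out, got {c_out}")
        c_half = c_out // 2
        self.cv1 = ConvBnAct(c_in, c_half, 1, rng=rng)
        self.cv2 = ConvBnAct(c_in, c_half, 1, rng=rng)
        self.bottlenecks = [Bottleneck(c_half, shortcut, rng=rng) for _ in range(n)]
        self.cv3 = ConvBnAct(c_out, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        main = self.cv1(x)
        for b in self.bottlenecks:
            main = b(main)
        return self.cv3(concat([main, self.cv2(x)], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three cascaded k x k stride-1 max pools.

    Cascading a k=5 pool three times matches single pools with receptive
    fields 5, 9 and 13; the four maps are concatenated and fused 1x1.
    Spatial size is preserved.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c_half = c_in // 2
        self.kernel = kernel
        self.cv1 = ConvBnAct(c_in, c_half, 1, rng=rng)
        self.cv2 = ConvBnAct(c_half * 4, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y0 = self.cv1(x)
        y1 = maxpool2d(y0, self.kernel)
        y2 = maxpool2d(y1, self.kernel)
        y3 = maxpool2d(y2, self.kernel)
        return self.cv2(concat([y0, y1, y2, y3], axis=1))
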