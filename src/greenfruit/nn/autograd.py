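"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

Just enough tensor calculus to train a small convolutional detector on a
CPU: elementwise arithmetic with broadcasting, matmul, reductions, shape
ops, the activations used by the detector family (sigmoid / ReLU / SiLU),
and fused primitives for the expensive layers (im2col convolution, batch
norm, pooling, nearest upsampling, binary cross-entropy with logits).

Gradients flow through a taped graph of closures; ``Tensor.backward()``
runs the tape in reverse topological order.  A ``no_grad`` context disables
taping for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = ["Tensor", "no_grad", "concat", "maximum", "minimum", "conv2d", "batch_norm",
           "maxpool2d", "avgpool2d", "upsample_nearest2x", "bce_with_logits", "stack"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_accumulate")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if not isinstance(data, np.ndarray) else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None] | None) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = ()
        out._backward = None
        out.requires_grad = _grad_enabled and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient only valid for scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._accumulate = grads  # type: ignore[attr-defined]
                node._backward(g)
            else:
                node.grad = g if node.grad is None else node.grad + g
        # tear the tape down: closures capture large intermediates (im2col
        # buffers, masks) inside reference cycles, so freeing them must not
        # wait for the cyclic garbage collector
        for node in topo:
            if node._backward is not None:
                node._backward = None
                node._parents = ()
                if hasattr(node, "_accumulate"):
                    del node._accumulate
                node.requires_grad = node.grad is not None

    def _send(self, parent: "Tensor", grad: np.ndarray) -> None:
        """Route a gradient contribution to a parent during backward."""
        if not parent.requires_grad:
            return
        if parent._backward is None:  # leaf
            parent.grad = grad.copy() if parent.grad is None else parent.grad + grad
        else:
            store = self._accumulate  # type: ignore[attr-defined]
            key = id(parent)
            store[key] = grad if key not in store else store[key] + grad

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g, self=self, other=other):
            out._send(self, _unbroadcast(g, self.data.shape))
            out._send(other, _unbroadcast(g, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g, self=self):
            out._send(self, -g)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g, self=self, other=other):
            out._send(self, _unbroadcast(g * other.data, self.data.shape))
            out._send(other, _unbroadcast(g * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g, self=self, other=other):
            out._send(self, _unbroadcast(g / other.data, self.data.shape))
            out._send(other, _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g, self=self):
            out._send(self, g * exponent * self.data ** (exponent - 1))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g, self=self, other=other):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            out._send(self, _unbroadcast(ga, self.data.shape))
            out._send(other, _unbroadcast(gb, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, self=self):
            out._send(self, g * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward(g, self=self):
            out._send(self, g / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, self=self):
            out._send(self, g * 0.5 / out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def atan(self):
        def backward(g, self=self):
            out._send(self, g / (1.0 + self.data**2))

        out = Tensor._make(np.arctan(self.data), (self,), backward)
        return out

    def sigmoid(self):
        out_data = expit(self.data)

        def backward(g, self=self):
            out._send(self, g * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward(g, self=self):
            out._send(self, g * mask)

        out = Tensor._make(self.data * mask, (self,), backward)
        return out

    def silu(self):
        sig = expit(self.data)
        out_data = self.data * sig

        def backward(g, self=self):
            out._send(self, g * (sig * (1.0 + self.data * (1.0 - sig))))

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, self=self):
            g_arr = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g_arr = np.expand_dims(g_arr, axes)
            out._send(self, np.broadcast_to(g_arr, self.data.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g, self=self):
            expanded = out_data if keepdims or axis is None else np.expand_dims(
                out_data, axis if isinstance(axis, tuple) else (axis,)
            )
            mask = self.data == expanded
            # split ties evenly so the gradient check stays symmetric
            counts = mask.sum(axis=axis, keepdims=True)
            g_arr = np.asarray(g)
            if axis is not None and not keepdims:
                g_arr = np.expand_dims(g_arr, axis if isinstance(axis, tuple) else (axis,))
            out._send(self, mask * (g_arr / counts))

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, self=self):
            out._send(self, g.reshape(old))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, self=self):
            out._send(self, g.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, self=self):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            out._send(self, gx)

        out = Tensor._make(out_data, (self,), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            out._send(t, g[tuple(sl)])

    out = Tensor._make(out_data, tensors, backward)
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            out._send(t, np.take(g, i, axis=axis))

    out = Tensor._make(out_data, tensors, backward)
    return out


def maximum(a: Tensor, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    out_data = np.maximum(a.data, b.data)
    a_wins = a.data >= b.data

    def backward(g):
        out._send(a, _unbroadcast(g * a_wins, a.data.shape))
        out._send(b, _unbroadcast(g * (~a_wins), b.data.shape))

    out = Tensor._make(out_data, (a, b), backward)
    return out


def minimum(a: Tensor, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    out_data = np.minimum(a.data, b.data)
    a_wins = a.data <= b.data

    def backward(g):
        out._send(a, _unbroadcast(g * a_wins, a.data.shape))
        out._send(b, _unbroadcast(g * (~a_wins), b.data.shape))

    out = Tensor._make(out_data, (a, b), backward)
    return out


# -- fused layer primitives ----------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution via im2col + matmul; NCHW layout, square kernel."""
    n, c, h, w = x.data.shape
    c_out, c_in, k, _ = weight.data.shape
    if c != c_in:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {c_in}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    h_out = (h + 2 * padding - k) // stride + 1
    w_out = (w + 2 * padding - k) // stride + 1
    windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, k, k) -> (N, Ho*Wo, C*k*k)
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, h_out * w_out, c_in * k * k
    )
    w_mat = weight.data.reshape(c_out, -1)
    out_data = (cols @ w_mat.T).transpose(0, 2, 1).reshape(n, c_out, h_out, w_out)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)

    def backward(g):
        g2 = g.reshape(n, c_out, h_out * w_out).transpose(0, 2, 1)  # (N, L, Cout)
        if weight.requires_grad:
            gw = (g2.reshape(-1, c_out).T @ cols.reshape(-1, c_in * k * k)).reshape(weight.data.shape)
            out._send(weight, gw)
        if bias is not None and bias.requires_grad:
            out._send(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (g2 @ w_mat).reshape(n, h_out, w_out, c_in, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki : ki + stride * h_out : stride,
                        kj : kj + stride * w_out : stride] += dcols[:, :, :, :, ki, kj]
            out._send(x, dxp[:, :, padding : padding + h, padding : padding + w]
                      if padding else dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(out_data, parents, backward)
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalization over an NCHW tensor.

    In training mode the batch statistics are used and the running buffers
    updated in place; in eval mode the running buffers are used.
    """
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for the buffer
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            out._send(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            out._send(beta, g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(1, -1, 1, 1)
            if training:
                mean_g = gxhat.mean(axis=axes, keepdims=True)
                mean_gx = (gxhat * xhat).mean(axis=axes, keepdims=True)
                dx = (gxhat - mean_g - xhat * mean_gx) * inv_std.reshape(1, -1, 1, 1)
            else:
                dx = gxhat * inv_std.reshape(1, -1, 1, 1)
            out._send(x, dx)

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int = 1, padding: int | None = None) -> Tensor:
    """Max pooling; default same-padding with stride 1 preserves spatial size."""
    if padding is None:
        padding = kernel // 2
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    h_out = (h + 2 * padding - kernel) // stride + 1
    w_out = (w + 2 * padding - kernel) // stride + 1
    windows = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = windows.reshape(n, c, h_out, w_out, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        ki, kj = np.divmod(arg, kernel)
        ii = np.arange(h_out).reshape(1, 1, -1, 1) * stride + ki
        jj = np.arange(w_out).reshape(1, 1, 1, -1) * stride + kj
        nn_idx = np.arange(n).reshape(-1, 1, 1, 1)
        cc_idx = np.arange(c).reshape(1, -1, 1, 1)
        dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        np.add.at(dxp, (np.broadcast_to(nn_idx, arg.shape), np.broadcast_to(cc_idx, arg.shape),
                        ii, jj), g)
        out._send(x, dxp[:, :, padding : padding + h, padding : padding + w]
                  if padding else dxp)

    out = Tensor._make(out_data, (x,), backward)
    return out


def avgpool2d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping average pooling (kernel == stride); H, W must divide."""
    n, c, h, w = x.data.shape
    if h % kernel or w % kernel:
        raise ValueError(f"avgpool2d: spatial size {(h, w)} not divisible by {kernel}")
    r = x.data.reshape(n, c, h // kernel, kernel, w // kernel, kernel)
    out_data = r.mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3) / (kernel * kernel)
        out._send(x, gx)

    out = Tensor._make(out_data, (x,), backward)
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        out._send(x, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out = Tensor._make(out_data, (x,), backward)
    return out


def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Elementwise binary cross-entropy on logits, numerically stable."""
    t = targets.data if isinstance(targets, Tensor) else np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    out_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(g):
        out._send(logits, g * (expit(z) - t))

    out = Tensor._make(out_data, (logits,), backward)
    return out
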