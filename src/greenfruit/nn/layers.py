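"""Layer/module abstractions over the autodiff engine.

Mirrors the conventional deep-learning layer API at the scale this package
needs: ``Module`` with parameter discovery, train/eval modes and state
dicts; ``Conv2d``, ``BatchNorm2d``, ``Linear`` and a ``Sequential``
container.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, batch_norm, conv2d

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d", "Linear", "Sequential", "Identity"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ------------------------------------------------------------
    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):  # buffers registered by name
            yield prefix + name, getattr(self, name)
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.named_children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (obj, name.rsplit(".", 1)) for name, obj in self.named_buffers()}
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.astype(np.float32).copy()
            elif key in buffers:
                buffers[key][0][...] = value
            else:
                raise KeyError(f"unexpected state key {key}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing state keys: {sorted(missing)[:5]}")


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU-family nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean, self.running_var,
                          training=self.training, momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
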