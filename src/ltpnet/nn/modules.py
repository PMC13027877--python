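"""Layer abstractions over the autodiff primitives.

Mirrors the familiar torch-style ``Module`` API at the small scale this
package needs: parameter registration by attribute assignment, recursive
``named_parameters``, train/eval modes (batch norm), and flat state dicts
of numpy arrays for checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import ops
from .tensor import Tensor

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the parameter-initialisation RNG (module construction order
    then fully determines all initial weights)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _init_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    """A tensor flagged as learnable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing -------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, buf in self._buffers.items():
            out[prefix + name] = np.asarray(buf).copy()
        for name, mod in self._modules.items():
            out.update(mod.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in checkpoint")
            if state[key].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key!r}")
            p.data = np.asarray(state[key], dtype=np.float64).copy()
        for name in self._buffers:
            key = prefix + name
            if key in state:
                buf = np.asarray(state[key]).copy()
                self._buffers[name] = buf
                object.__setattr__(self, name, buf)
        for name, mod in self._modules.items():
            mod.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._order = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._order.append(m)

    def __len__(self) -> int:
        return len(self._order)

    def __getitem__(self, i: int) -> Module:
        return self._order[i]

    def forward(self, x):
        for m in self._order:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """3x3/1x1/... convolution with Kaiming init and zero bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = in_channels // groups * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            _init_rng().normal(0.0, std, (out_channels, in_channels // groups,
                                          kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        return ops.conv2d(x, self.weight, self.bias, stride=self.stride,
                          padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        std = np.sqrt(1.0 / in_features)
        self.weight = Parameter(_init_rng().uniform(-std, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return ops.linear(x, self.weight, self.bias)


class GroupNorm(Module):
    """Group normalisation with identity-affine init; the group count is
    clamped down to the channel count when necessary."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        num_groups = min(num_groups, num_channels)
        while num_channels % num_groups:
            num_groups -= 1
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))

    def forward(self, x):
        return ops.group_norm(x, self.num_groups, self.weight, self.bias, self.eps)


class BatchNorm2d(Module):
    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = num_channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))
        self.register_buffer("running_mean", np.zeros(num_channels))
        self.register_buffer("running_var", np.ones(num_channels))

    def forward(self, x):
        C = self.num_channels
        if self.training:
            mu = ops.mean(x, axis=(0, 2, 3), keepdims=True)
            centred = ops.sub(x, mu)
            var = ops.mean(ops.mul(centred, centred), axis=(0, 2, 3), keepdims=True)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mu.data.reshape(C) - rm)
            rv += self.momentum * (var.data.reshape(C) - rv)
            norm = ops.div(centred, ops.sqrt(ops.add(var, self.eps)))
        else:
            rm = self._buffers["running_mean"].reshape(1, C, 1, 1)
            rv = self._buffers["running_var"].reshape(1, C, 1, 1)
            norm = ops.div(ops.sub(x, Tensor(rm)), Tensor(np.sqrt(rv + self.eps)))
        return ops.add(
            ops.mul(norm, ops.reshape(self.weight, (1, C, 1, 1))),
            ops.reshape(self.bias, (1, C, 1, 1)),
        )
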