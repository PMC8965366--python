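"""Layer modules over the autodiff tape: parameter registry, state dicts,
train/eval modes, and the handful of layers the three networks need."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor
from .conv import conv3d, conv_transpose3d

__all__ = [
    "Module",
    "Sequential",
    "Conv3d",
    "ConvTranspose3d",
    "Linear",
    "BatchNorm3d",
    "Dropout",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "freeze",
    "unfreeze",
    "state_bytes_equal",
]


class Module:
    """Base class: children/parameters are discovered from instance attributes
    (lists of modules are supported); buffers are non-trained state such as
    batch-norm running statistics."""

    def __init__(self):
        self.training = True

    # -- registry ---------------------------------------------------------

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _own_params(self) -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield name, value

    def _own_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield name, getattr(self, name)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- modes ------------------------------------------------------------

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- state ------------------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self._own_params():
            state[prefix + name] = p.data.copy()
        for name, buf in self._own_buffers():
            state[prefix + name] = np.array(buf, copy=True)
        for cname, child in self._children():
            state.update(child.state_dict(prefix + cname + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._own_params():
            key = prefix + name
            src = np.asarray(state[key], dtype=np.float64)
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}: {src.shape} vs {p.data.shape}")
            p.data = src.copy()
        for name, _ in self._own_buffers():
            key = prefix + name
            setattr(self, name, np.array(state[key], dtype=np.float64, copy=True))
        for cname, child in self._children():
            child.load_state_dict(state, prefix + cname + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def freeze(module: Module) -> Module:
    """Stop gradient accumulation on every parameter (inputs still get grads)."""
    for p in module.parameters():
        p.requires_grad = False
    return module


def unfreeze(module: Module) -> Module:
    for p in module.parameters():
        p.requires_grad = True
    return module


def state_bytes_equal(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> bool:
    """Bitwise comparison of two state dicts (keys and array bytes)."""
    if set(a) != set(b):
        return False
    return all(
        a[k].shape == b[k].shape and a[k].tobytes() == b[k].tobytes() for k in a
    )


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel**3
        self.stride, self.pad = stride, pad
        self.weight = Tensor(
            _kaiming(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        output_padding: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel**3
        self.stride, self.pad, self.output_padding = stride, pad, output_padding
        self.weight = Tensor(
            _kaiming(rng, (in_channels, out_channels, kernel, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(
            x, self.weight, self.bias, self.stride, self.pad, self.output_padding
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(
            _kaiming(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm3d(Module):
    """Per-channel normalisation over batch and spatial axes.

    Training mode uses batch statistics and updates running estimates;
    eval mode uses the running estimates, so a frozen network is a pure
    function of its state dict.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = (x - mu).square().mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    """Inverted dropout with a module-owned random stream (reproducible
    given the build seed); identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
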