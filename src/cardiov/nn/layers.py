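"""Neural-network modules built on the autodiff core.

Modules hold parameters as `Tensor`s with `requires_grad=True` and expose
`__call__` for the forward pass. A module tree is walked with
:meth:`Module.parameters`; train/eval mode (dropout, batch-norm statistics)
is toggled with :meth:`Module.train` / :meth:`Module.eval`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, batch_norm_train, conv1d, max_pool1d, relu,
                       sigmoid, swish)

__all__ = [
    "Module",
    "Conv1d",
    "Dense",
    "BatchNorm1d",
    "Dropout",
    "MaxPool1d",
    "SqueezeExcite",
]


class Module:
    """Base class: parameter discovery, mode switching, state (de)serialization."""

    def __init__(self):
        self.training = True

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for name, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                yield f"{prefix}{name}", v
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True):
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v.copy() for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].data[...] = value
            elif kind == "buffer":
                bufs[name][...] = value
            else:
                raise KeyError(f"unrecognized state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int,
             dtype=np.float64) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(dtype),
                  requires_grad=True)


class Conv1d(Module):
    """Grouped 1D convolution with explicit asymmetric padding, no bias
    (every convolution in the network is preceded by batch norm)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: tuple[int, int] = (0, 0), groups: int = 1,
                 dtype=np.float64):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) must be divisible "
                f"by groups ({groups})")
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size
        self.weight = _kaiming(
            rng, (out_channels, in_channels // groups, kernel_size), fan_in,
            dtype)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, stride=self.stride,
                      pad_left=self.padding[0], pad_right=self.padding[1],
                      groups=self.groups)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.weight = _kaiming(rng, (in_features, out_features), in_features,
                               dtype)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over (batch, time) for (N, C, L) activations.

    Training mode normalizes with batch statistics and updates running
    estimates (momentum 0.1); eval mode uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu
            self.running_var *= 1 - m
            self.running_var += m * var
            return out
        c_shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        mu = self.running_mean.reshape(c_shape)
        sd = np.sqrt(self.running_var.reshape(c_shape) + self.eps)
        xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(c_shape) + self.beta.reshape(c_shape)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Needs an RNG per forward call
    for reproducible batch order — pass one at construction."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype)
        return x * (mask * (1.0 / keep))


class MaxPool1d(Module):
    def __init__(self, kernel: int = 2, stride: int = 2):
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return max_pool1d(x, self.kernel, self.stride)


class SqueezeExcite(Module):
    """Channel attention: squeeze by temporal mean, two dense layers
    (ReLU inside, sigmoid gate), multiply channel-wise."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(channels, hidden, rng, dtype)
        self.fc2 = Dense(hidden, channels, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=2)                      # (N, C)
        gate = sigmoid(self.fc2(relu(self.fc1(s))))
        n, c = gate.shape
        return x * gate.reshape(n, c, 1)
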