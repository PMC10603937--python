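"""Neural-network building blocks over the autodiff core.

Module/parameter bookkeeping, 2-D convolution layers, batch normalisation
with small-batch-safe defaults, and the Adam optimizer.  Initialisation is
always driven by an explicit ``numpy.random.Generator`` so that model
construction is reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, conv2d

DTYPE = np.float32


class Parameter(Tensor):
    """A tensor that is always part of the gradient graph."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Minimal container: tracks sub-modules and parameters by attribute name."""

    def __init__(self):
        self._training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m._training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown parameter/buffer {name!r}")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """2-D convolution (cross-correlation), He-normal initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels,
                                       kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W).

    Uses batch statistics in training mode (safe down to a single sample
    because spatial positions contribute to the statistics) and running
    exponential-average statistics at evaluation time.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, channels, 1, 1), dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self._training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean *= (1.0 - self.momentum)
            self.running_mean += self.momentum * mu.data.astype(DTYPE)
            self.running_var *= (1.0 - self.momentum)
            self.running_var += self.momentum * var.data.astype(DTYPE)
            xhat = xc / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta


class ConvNormAct(Module):
    """Conv -> BatchNorm -> ReLU, the repeated unit of encoder/decoder blocks."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel_size: int = 3,
                 stride: int = 1):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng,
                           stride=stride, padding=kernel_size // 2, bias=False)
        self.norm = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class Adam:
    """Adam optimizer (Kingma & Ba) with optional global-norm gradient
    clipping (stabilises small-batch training from scratch)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _clip(self) -> None:
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = np.sqrt(total)
        if norm > self.clip_norm:
            scale = self.clip_norm / norm
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale

    def step(self) -> None:
        if self.clip_norm is not None:
            self._clip()
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
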