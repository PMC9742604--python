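"""Layers and the Adam optimizer used by the generator, discriminator and classifier."""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from ._autodiff import Parameter, Tensor, conv3d

DTYPE = np.float64


class Module:
    """Base class: parameter discovery by attribute walk, train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            if isinstance(value, Parameter) and id(value) not in seen:
                seen.add(id(value))
                yield value
            elif isinstance(value, Module):
                for p in value.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        yield p
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                seen.add(id(p))
                                yield p
                    elif isinstance(item, Parameter) and id(item) not in seen:
                        seen.add(id(item))
                        yield item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for m in self._submodules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._submodules():
            m.eval()

    def _submodules(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter arrays, in discovery order (for checkpoints/tests)."""
        return [p.data for p in self.parameters()]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


def he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "glorot", bias: bool = True):
        super().__init__()
        if init == "zeros":
            w = np.zeros((n_in, n_out), dtype=DTYPE)
        elif init == "he":
            w = he(rng, (n_in, n_out), n_in)
        else:
            w = glorot(rng, (n_in, n_out), n_in, n_out)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None):
        super().__init__()
        fan_in = c_in * kernel ** 3
        self.weight = Parameter(he(rng, (c_out, c_in, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=DTYPE))
        self.padding = (kernel // 2) if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, padding=self.padding)


def avg_pool3d(x: Tensor, k: int = 2) -> Tensor:
    """k^3 average pooling with stride k; spatial dims must divide by k."""
    B, C, X, Y, Z = x.shape
    if X % k or Y % k or Z % k:
        raise ValueError(f"spatial dims {(X, Y, Z)} not divisible by pool size {k}")
    return x.reshape(B, C, X // k, k, Y // k, k, Z // k, k).mean(axis=(3, 5, 7))


class BatchNorm3d(Module):
    """Per-channel batch normalization over (batch, spatial) axes.

    The batch here is the set of time frames of one subject.  Running
    statistics (momentum 0.9) are used in eval mode.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data.reshape(-1))
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data.reshape(-1))
            xhat = xc * (var + self.eps) ** -0.5
        else:
            shape = (1, -1, 1, 1, 1)
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        shape = (1, -1, 1, 1, 1)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    """Row-wise layer normalization with learnable gain/bias over the last axis."""

    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(width, dtype=DTYPE))
        self.bias = Parameter(np.zeros(width, dtype=DTYPE))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gain + self.bias


class Adam:
    """Adaptive-moment optimizer (bias-corrected)."""

    def __init__(self, params: Iterable[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
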