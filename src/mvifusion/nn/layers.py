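"""Network building blocks on top of the autodiff core."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv3d, maxpool3d


class Module:
    """Base class: tracks parameters via attributes, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
            elif isinstance(v, dict):
                for k, item in v.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{k}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError(f"state dict keys mismatch: {sorted(set(own) ^ set(state))[:5]}")
        for name, p in own.items():
            p.data = np.asarray(state[name]).astype(p.data.dtype).copy()


# float32 keeps the training path in single precision end to end (parameters,
# activations, gradients); oracle tests can still feed float64 inputs to
# hand-weighted blocks, since ops follow NumPy promotion rules.
DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=DTYPE) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3, pad: int = 1):
        super().__init__()
        self.kernel, self.pad = kernel, pad
        fan_in = c_in * kernel**3
        self.weight = Tensor(_he_init(rng, (c_out, fan_in), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.kernel, self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool3d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool3d(x, self.k)


class Dropout(Module):
    """Inverted dropout on FC activations; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask.astype(x.data.dtype))


class SGD:
    """Momentum SGD with decoupled-into-gradient weight decay (classic L2)."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
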