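"""Small neural-network building blocks on top of :mod:`stemleaf.autodiff`.

Parameter initialisation is seeded explicitly; every module exposes its
parameters as a flat ``{name: Tensor}`` dict for the optimizer and for
checkpoint serialization.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, layer_norm

__all__ = ["Module", "Linear", "MLP", "LayerNorm", "SGD"]


class Module:
    """Base class: children registered as attributes are collected recursively."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=v.data.dtype)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / in_dim)
        self.W = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # flatten leading axes so the backward pass is a single GEMM rather
        # than a huge batch of per-row outer products
        if x.ndim > 2:
            lead = x.shape[:-1]
            y = x.reshape((-1, x.shape[-1])) @ self.W + self.b
            return y.reshape(lead + (self.W.shape[1],))
        return x @ self.W + self.b


class MLP(Module):
    """Shared multilayer perceptron; LeakyReLU(0.2) between layers.

    ``final_activation`` controls whether the last layer is also activated
    (segmentation head leaves raw scores).
    """

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        final_activation: bool = False,
        slope: float = 0.2,
    ):
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.final_activation = final_activation
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < last or self.final_activation:
                x = x.leaky_relu(self.slope)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


class SGD:
    """SGD with classical momentum and optional gradient-norm clipping."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float,
        momentum: float = 0.9,
        clip_norm: Optional[float] = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if self.clip_norm is not None and grads:
            total = math.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for g in grads.values():
                    g *= scale
        for k, p in self.params.items():
            if p.grad is None:
                continue
            v = self._velocity[k]
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


def cosine_lr(epoch: int, total_epochs: int, lr_max: float, lr_min: float) -> float:
    """Cosine annealing from ``lr_max`` (epoch 0) to ``lr_min`` (final epoch)."""
    if total_epochs <= 1:
        return lr_min
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t))
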