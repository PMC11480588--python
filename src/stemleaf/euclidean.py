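"""Euclidean channel: adaptive-kernel graph convolution with attention pooling.

For every edge (i, j) a kernel generator g_m maps the feature encoding
Δf_ij = [f_i; f_j - f_i] to a 6-dim kernel that is inner-producted with the
spatial encoding Δx_ij = [x_i; x_j - x_i]; the M per-edge responses are
softmax-attention pooled over the K neighbors and passed through a small
output MLP, yielding the point feature f_i^e.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, dot_last, softmax_pool
from .nn import Linear, Module, MLP

__all__ = ["adaptive_kernel_response", "attention_pool", "EuclideanChannel"]

_SLOPE = 0.2  # LeakyReLU negative slope


def adaptive_kernel_response(
    spatial: np.ndarray, kernels: np.ndarray, slope: float = _SLOPE
) -> np.ndarray:
    """Per-edge kernel responses h_ij[m] = LeakyReLU(<Δx_ij, g_m(Δf_ij)>).

    Parameters
    ----------
    spatial
        ``(..., K, 6)`` spatial edge encodings.
    kernels
        ``(..., K, M, 6)`` generated kernels, one 6-vector per channel m.

    Returns ``(..., K, M)`` responses. Reference (non-differentiable)
    implementation shared by the layer and by its tests.
    """
    spatial = np.asarray(spatial, dtype=np.float64)
    kernels = np.asarray(kernels, dtype=np.float64)
    if kernels.shape[-1] != 6 or spatial.shape[-1] != 6:
        raise ValueError("kernels and spatial encodings must be 6-dimensional")
    h = (kernels * spatial[..., None, :]).sum(axis=-1)
    return np.where(h > 0, h, slope * h)


def attention_pool(responses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Channel-wise softmax over the K-neighbor axis and weighted sum.

    Parameters
    ----------
    responses
        ``(..., K, M)`` kernel responses.

    Returns ``(pooled, weights)`` where pooled is ``(..., M)`` and weights
    sum to one along K per channel. Reference implementation (the
    differentiable path lives in :class:`EuclideanChannel`).
    """
    h = np.asarray(responses, dtype=np.float64)
    if h.shape[-2] == 0:
        raise ValueError("attention pooling requires a non-empty neighborhood")
    shifted = h - h.max(axis=-2, keepdims=True)
    e = np.exp(shifted)
    w = e / e.sum(axis=-2, keepdims=True)
    return (w * h).sum(axis=-2), w


class EuclideanChannel(Module):
    """Differentiable adaptive convolution producing f^e.

    The M kernel generators are realized as one shared two-layer perceptron
    emitting M*6 values per edge, sliced per m (equivalent to M separate
    maps, cheaper).
    """

    def __init__(self, in_dim: int, dim: int, rng: np.random.Generator, hidden: int | None = None):
        self.dim = dim
        hidden = hidden or dim
        self.kernel_mlp = MLP([2 * in_dim, hidden, dim * 6], rng)
        self.post = Linear(dim, dim, rng)

    def __call__(self, spatial: np.ndarray, feature: Tensor) -> Tensor:
        """spatial: (N, K, 6) constant; feature: (N, K, 2D) Tensor -> (N, M)."""
        n, k, _ = feature.shape
        kernels = self.kernel_mlp(feature).reshape(n, k, self.dim, 6)
        sp = np.asarray(spatial, dtype=kernels.data.dtype)[:, :, None, :]
        h = dot_last(kernels, sp).leaky_relu(_SLOPE)  # (N, K, M)
        pooled = softmax_pool(h, axis=1)  # attention over neighbors, channel-wise
        return self.post(pooled).leaky_relu(_SLOPE)
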