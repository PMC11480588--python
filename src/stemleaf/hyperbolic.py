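"""Poincaré-ball projections and the hyperbolic geometric structure encoder.

Point features are lifted into the Poincaré ball of curvature ``-c`` via the
exponential map at the origin; each point's K-neighborhood forms a star
graph (center = planet node, neighbors = a cyclic ring), over which stacked
star-transformer layers propagate shape-structure information. The planet
embedding re-enters Euclidean space through the logarithmic map for gate
fusion with the Euclidean channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, attention_core, concatenate
from .nn import LayerNorm, Linear, Module

__all__ = [
    "expmap0",
    "logmap0",
    "StarGraph",
    "build_star_graph",
    "HGSConfig",
    "HGSEncoder",
]

_BALL_EPS = 1e-5
# transformer arithmetic routinely leaves the ball; project back with a wide
# margin so artanh and its derivative stay bounded (artanh'(0.95) ~ 10 vs
# ~5e4 at 1-1e-5) — without it the gate receives huge, ill-conditioned
# hyperbolic features and early optimization stalls
_PROJECT_MARGIN = 0.05
_NORM_EPS = 1e-12


# -- exp/log maps (numpy) --------------------------------------------------------


def expmap0(f: np.ndarray, c: float) -> np.ndarray:
    """Exponential map at the origin of the ball of curvature -c.

    exp_0^c(f) = tanh(sqrt(c) ||f||) * f / (sqrt(c) ||f||); the origin is a
    fixed point and every output lies strictly inside the ball of radius
    1/sqrt(c).
    """
    f = np.asarray(f, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("expmap0: input must be finite")
    if c <= 0:
        raise ValueError("curvature parameter c must be positive")
    sqc = np.sqrt(c)
    norm = np.linalg.norm(f, axis=-1, keepdims=True)
    safe = np.maximum(norm, _NORM_EPS)
    # tanh rounds to 1.0 in floating point for large arguments; clamp just
    # inside the boundary so containment stays strict and logmap0 is defined
    factor = np.minimum(np.tanh(sqc * safe), 1.0 - 1e-12)
    return factor * f / (sqc * safe)


def logmap0(h: np.ndarray, c: float) -> np.ndarray:
    """Logarithmic map at the origin; inverse of :func:`expmap0`."""
    h = np.asarray(h, dtype=np.float64)
    if c <= 0:
        raise ValueError("curvature parameter c must be positive")
    sqc = np.sqrt(c)
    norm = np.linalg.norm(h, axis=-1, keepdims=True)
    if (sqc * norm >= 1.0).any():
        raise ValueError("logmap0: point lies outside the Poincaré ball")
    safe = np.maximum(norm, _NORM_EPS)
    return np.arctanh(sqc * safe) * h / (sqc * safe)


# -- exp/log maps (differentiable) ----------------------------------------------


def expmap0_t(f: Tensor, c: float) -> Tensor:
    sqc = np.sqrt(c)
    norm = ((f * f).sum(axis=-1, keepdims=True) + _NORM_EPS**2).sqrt()
    return (sqc * norm).tanh() * f / (sqc * norm)


def ball_project_t(h: Tensor, c: float, margin: float = _PROJECT_MARGIN) -> Tensor:
    """Rescale into the open ball when transformer arithmetic has left it."""
    sqc = np.sqrt(c)
    norm = ((h * h).sum(axis=-1, keepdims=True) + _NORM_EPS**2).sqrt()
    ratio = (norm * sqc / (1.0 - margin)).clip_min(1.0)
    return h / ratio


def logmap0_t(h: Tensor, c: float) -> Tensor:
    sqc = np.sqrt(c)
    norm = ((h * h).sum(axis=-1, keepdims=True) + _NORM_EPS**2).sqrt()
    x = norm * sqc
    # artanh via logs; inputs are inside the ball after ball_project_t
    artanh = 0.5 * ((1.0 + x) / (1.0 - x)).log()
    return artanh * h / (sqc * norm)


# -- star graph ------------------------------------------------------------------


@dataclass
class StarGraph:
    """Planet-and-ring view of one point's neighborhood.

    ``ring`` lists the K neighbor indices (distance order, treated as a
    cycle); ``ring_edge_mask[k]`` says whether the ring edge (k, k+1) was
    kept when ring edges are included with probability ``edge_prob``.
    """

    planet_index: int
    ring: np.ndarray
    ring_edge_mask: np.ndarray
    edge_prob: float

    def __post_init__(self) -> None:
        self.ring = np.asarray(self.ring, dtype=np.int64)
        self.ring_edge_mask = np.asarray(self.ring_edge_mask, dtype=bool)
        if len(set(self.ring.tolist())) != self.ring.size or self.planet_index in self.ring:
            raise ValueError("ring indices must be distinct and exclude the planet")


def build_star_graph(
    graph, center: int, edge_prob: float = 1.0, seed: int = 0
) -> StarGraph:
    """Star graph of one center point from a :class:`~stemleaf.graph.NeighborGraph`.

    Each ring edge is kept independently with probability ``edge_prob``
    (seeded); planet-ring spokes are always present.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    ring = graph.neighbor_indices[center]
    k = ring.size
    if edge_prob >= 1.0:
        mask = np.ones(k, dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        mask = rng.random(k) < edge_prob
    return StarGraph(planet_index=center, ring=ring, ring_edge_mask=mask, edge_prob=edge_prob)


def ring_edge_masks(n: int, k: int, edge_prob: float, seed: int) -> np.ndarray:
    """Seeded (N, K) ring-edge retention mask for a whole cloud."""
    if edge_prob >= 1.0:
        return np.ones((n, k), dtype=bool)
    rng = np.random.default_rng(seed)
    return rng.random((n, k)) < edge_prob


# -- HGS encoder -----------------------------------------------------------------


@dataclass
class HGSConfig:
    """Hyperparameters of the hyperbolic encoder.

    layers
        Number of stacked star-transformer layers (L).
    heads
        Attention heads; must divide the channel width.
    lam
        Residual scale λ applied to the planet embedding.
    curvature
        Positive c parameterizing the ball of curvature -c.
    edge_prob
        Ring-edge inclusion probability (1 = deterministic full ring).
    """

    layers: int = 2
    heads: int = 4
    lam: float = 1.0
    curvature: float = 1.0
    edge_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.curvature <= 0:
            raise ValueError("curvature parameter must be positive")


class _Attention(Module):
    """Multi-head scaled dot-product attention specialised for star contexts.

    Keys/values are projected once per node and *gathered* into each query's
    context, so the cost is one GEMM over the distinct nodes instead of one
    over every (query, slot) pair. ``context_idx`` has shape (..., Lq, Lk)
    holding indices into the projected node table.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"heads ({heads}) must divide the model dim ({dim})")
        self.dim = dim
        self.heads = heads
        self.Wq = Linear(dim, dim, rng)
        self.Wk = Linear(dim, dim, rng)
        self.Wv = Linear(dim, dim, rng)
        self.Wo = Linear(dim, dim, rng)

    def __call__(
        self,
        query_nodes: Tensor,  # (B, M) one query per row
        kv_nodes: Tensor,  # (T, M) node table
        context_idx: np.ndarray,  # (B, Lk) rows into kv_nodes
        key_mask: Optional[np.ndarray] = None,  # (B, Lk) True = attend
    ) -> Tensor:
        b, m = query_nodes.shape
        lk = context_idx.shape[1]
        h, dh = self.heads, self.dim // self.heads
        q = self.Wq(query_nodes).reshape(b, h, dh)
        # project K and V once over the distinct nodes, then gather contexts
        flat = context_idx.reshape(-1)
        k = self.Wk(kv_nodes).take(flat, axis=0).reshape(b, lk, h, dh)
        v = self.Wv(kv_nodes).take(flat, axis=0).reshape(b, lk, h, dh)
        out = attention_core(q, k, v, key_mask=key_mask).reshape(b, self.dim)
        return self.Wo(out)


class HGSLayer(Module):
    """One ring-then-planet update.

    Ring node k attends over its cyclic context
    ``[h_{k-1}; h_k; h_{k+1}; s]``; afterwards the planet attends over
    ``[s; H]``. Both updates are ReLU + LayerNorm on the attention output.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.ring_att = _Attention(dim, heads, rng)
        self.ring_ln = LayerNorm(dim)
        self.planet_att = _Attention(dim, heads, rng)
        self.planet_ln = LayerNorm(dim)

    def __call__(
        self, H: Tensor, s: Tensor, edge_mask: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        n, k, m = H.shape
        # node table: N*K ring embeddings followed by the N planet embeddings
        nodes = concatenate([H.reshape(n * k, m), s], axis=0)
        base = np.arange(n)[:, None] * k
        ring_ids = base + np.arange(k)  # (N, K) rows in the table
        left = base + np.roll(np.arange(k), 1)
        right = base + np.roll(np.arange(k), -1)
        planet_ids = n * k + np.repeat(np.arange(n)[:, None], k, axis=1)
        context_idx = np.stack([left, ring_ids, right, planet_ids], axis=2)  # (N,K,4)
        # a dropped ring edge (k,k+1) removes h_{k+1} from k's context and
        # h_k from (k+1)'s context; the planet spoke and self slot remain.
        keep_right = edge_mask  # edge (k, k+1)
        keep_left = np.roll(edge_mask, 1, axis=1)  # edge (k-1, k)
        ones = np.ones_like(keep_left)
        key_mask = np.stack([keep_left, ones, keep_right, ones], axis=2)  # (N,K,4)
        upd = self.ring_att(
            H.reshape(n * k, m),
            nodes,
            context_idx.reshape(n * k, 4),
            key_mask=key_mask.reshape(n * k, 4),
        )
        H_new = self.ring_ln(upd.relu()).reshape(n, k, m)
        # planet attends over [s ; H^l]
        planet_nodes = concatenate([s, H_new.reshape(n * k, m)], axis=0)
        self_ids = np.arange(n)[:, None]
        ring_rows = n + base + np.arange(k)
        planet_ctx = np.concatenate([self_ids, ring_rows], axis=1)  # (N, K+1)
        s_upd = self.planet_att(s, planet_nodes, planet_ctx)
        s_new = self.planet_ln(s_upd.relu())
        return H_new, s_new


class HGSEncoder(Module):
    """Hyperbolic channel: lift, project to the ball, L star layers, residual, log map.

    Returns the Euclidean-space feature f^{h'} consumed by the gate unit.
    """

    def __init__(self, in_dim: int, dim: int, cfg: HGSConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.lift = Linear(in_dim, dim, rng)
        self.layers = [HGSLayer(dim, cfg.heads, rng) for _ in range(cfg.layers)]

    def __call__(
        self, features: Tensor, neighbor_indices: np.ndarray, edge_mask: np.ndarray
    ) -> Tensor:
        c = self.cfg.curvature
        n, k = neighbor_indices.shape
        f = self.lift(features)  # (N, M)
        fh = expmap0_t(f, c)
        m = fh.shape[-1]
        H = fh.take(neighbor_indices.reshape(-1), axis=0).reshape(n, k, m)
        s = fh
        for layer in self.layers:
            H, s = layer(H, s, edge_mask)
        out = fh + self.cfg.lam * s  # residual on the planet's ball feature
        out = ball_project_t(out, c)
        return logmap0_t(out, c)
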