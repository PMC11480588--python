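"""Neighborhood graphs and hierarchical sampling over point clouds.

Provides the k-d-tree K-nearest-neighbor graph, farthest point sampling,
the spatial/feature edge encodings consumed by the Euclidean channel,
neighborhood max pooling for the coarsening stages, and inverse-distance
feature interpolation for the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "NeighborGraph",
    "EdgeEncoding",
    "kdtree_knn",
    "farthest_point_sampling",
    "edge_encode",
    "neighborhood_max_pool",
    "idw_interpolate",
]


@dataclass
class NeighborGraph:
    """K-nearest-neighbor table for a point cloud.

    ``neighbor_indices[i]`` lists the K neighbors of point i sorted by
    ascending distance, self excluded, distance ties broken by lower index.
    """

    neighbor_indices: np.ndarray  # (N, K) int
    K: int

    def __post_init__(self) -> None:
        self.neighbor_indices = np.asarray(self.neighbor_indices, dtype=np.int64)
        if self.neighbor_indices.ndim != 2 or self.neighbor_indices.shape[1] != self.K:
            raise ValueError("neighbor_indices must be (N, K)")

    @property
    def n(self) -> int:
        return self.neighbor_indices.shape[0]


@dataclass
class EdgeEncoding:
    """Per-edge inputs/outputs of the adaptive-kernel convolution.

    spatial  : (N, K, 6)  rows [x_i ; x_j - x_i]
    feature  : (N, K, 2D) rows [f_i ; f_j - f_i]
    kernel_responses : (N, K, M), filled by the Euclidean channel
    attention_weights: (N, K, M), softmax over K per channel
    """

    spatial: np.ndarray
    feature: np.ndarray
    kernel_responses: Optional[np.ndarray] = None
    attention_weights: Optional[np.ndarray] = None


def kdtree_knn(cloud: PointCloud, K: int) -> NeighborGraph:
    """Exact K nearest neighbors per point (k-d tree), self excluded.

    Distance ties are broken by the lower point index so the graph is
    reproducible on degenerate inputs.
    """
    n = cloud.n
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of points N={n}")
    tree = cKDTree(cloud.points)
    dist, idx = tree.query(cloud.points, k=K + 1)
    # drop the self column; with duplicate points self may not be first,
    # so mask it out explicitly and re-sort (distance, index).
    rows = np.arange(n)[:, None]
    self_mask = idx == rows
    # if self not found in the K+1 results (all-duplicate clouds), drop last
    fallback = ~self_mask.any(axis=1)
    if fallback.any():
        self_mask[fallback, K] = True
    order = np.lexsort((idx, dist), axis=1)
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    self_mask = np.take_along_axis(self_mask, order, axis=1)
    # exactly one entry per row is masked, so the reshape is well defined
    out = idx[~self_mask].reshape(n, K)
    return NeighborGraph(neighbor_indices=out.astype(np.int64), K=K)


def farthest_point_sampling(
    cloud: PointCloud, rate: int, seed: Optional[int] = None
) -> np.ndarray:
    """Greedy farthest point sampling at ``1/rate`` of the cloud.

    Returns ceil(N / rate) indices. By default the first pick is geometric
    (the point farthest from the centroid, coordinate-lexicographic
    tie-break), which makes the selected *set* independent of the point
    ordering — the property the segmentation network needs for permutation
    equivariance. Passing a ``seed`` draws a random first index instead.
    Each subsequent pick maximizes the minimum distance to the selected set
    (ties to the lower index).
    """
    if rate < 1:
        raise ValueError("rate must be >= 1")
    n = cloud.n
    m = int(np.ceil(n / rate))
    if m >= n:
        return np.arange(n, dtype=np.int64)
    pts = cloud.points
    selected = np.empty(m, dtype=np.int64)
    if seed is None:
        d0 = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        cand = np.flatnonzero(d0 == d0.max())
        if cand.size > 1:  # break geometric ties by coordinates, not index
            cand = cand[np.lexsort(pts[cand].T)]
        selected[0] = cand[0]
    else:
        rng = np.random.default_rng(seed)
        selected[0] = rng.integers(n)
    mind = np.linalg.norm(pts - pts[selected[0]], axis=1)
    for s in range(1, m):
        nxt = int(np.argmax(mind))
        selected[s] = nxt
        d = np.linalg.norm(pts - pts[nxt], axis=1)
        np.minimum(mind, d, out=mind)
    return selected


def edge_encode(cloud: PointCloud, features: np.ndarray, graph: NeighborGraph) -> EdgeEncoding:
    """Build the spatial [x_i; x_j-x_i] and feature [f_i; f_j-f_i] edge tables."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != cloud.n:
        raise ValueError("feature row count must equal the number of points")
    xi = cloud.points[:, None, :].repeat(graph.K, axis=1)  # (N,K,3)
    xj = cloud.points[graph.neighbor_indices]  # (N,K,3)
    fi = features[:, None, :].repeat(graph.K, axis=1)
    fj = features[graph.neighbor_indices]
    spatial = np.concatenate([xi, xj - xi], axis=2)
    feature = np.concatenate([fi, fj - fi], axis=2)
    return EdgeEncoding(spatial=spatial, feature=feature)


def neighborhood_max_pool(
    features: np.ndarray, graph: NeighborGraph, sampled: np.ndarray
) -> np.ndarray:
    """Channel-wise max over each sampled point's K-neighborhood (center included)."""
    features = np.asarray(features)
    sampled = np.asarray(sampled, dtype=np.int64)
    if sampled.min(initial=0) < 0 or (sampled.max(initial=0) >= features.shape[0]):
        raise ValueError("sampled indices out of range")
    idx = np.concatenate(
        [sampled[:, None], graph.neighbor_indices[sampled]], axis=1
    )  # (S, K+1)
    return features[idx].max(axis=1)


def idw_interpolate(
    coarse_points: np.ndarray,
    coarse_features: np.ndarray,
    fine_points: np.ndarray,
    k: int = 3,
    eps: float = 1e-8,
) -> np.ndarray:
    """Inverse-distance-weighted 3-NN interpolation of coarse features onto fine points.

    A fine point coinciding with a coarse point copies that coarse feature
    (the 1/(d+eps) weight saturates there).
    """
    coarse_points = np.asarray(coarse_points, dtype=np.float64)
    fine_points = np.asarray(fine_points, dtype=np.float64)
    coarse_features = np.asarray(coarse_features)
    k = min(k, coarse_points.shape[0])
    tree = cKDTree(coarse_points)
    dist, idx = tree.query(fine_points, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = 1.0 / (dist + eps)
    w = w / w.sum(axis=1, keepdims=True)
    return (coarse_features[idx] * w[:, :, None]).sum(axis=1)


def idw_weights(
    coarse_points: np.ndarray, fine_points: np.ndarray, k: int = 3, eps: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and normalized weights used by :func:`idw_interpolate`.

    Split out so the network can precompute them once per cloud and apply
    them inside the autodiff graph.
    """
    coarse_points = np.asarray(coarse_points, dtype=np.float64)
    k = min(k, coarse_points.shape[0])
    tree = cKDTree(coarse_points)
    dist, idx = tree.query(np.asarray(fine_points, dtype=np.float64), k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = 1.0 / (dist + eps)
    w = w / w.sum(axis=1, keepdims=True)
    return idx.astype(np.int64), w
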