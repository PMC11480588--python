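"""Leaf instance segmentation: K-means over leaf-labeled points.

The cluster count is chosen with the geometric elbow criterion on the
inertia curve (maximum perpendicular distance to the chord joining its
endpoints) and clusters are initialized with k-means++.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .cloud import PointCloud

log = logging.getLogger(__name__)

__all__ = ["ClusteringResult", "elbow_select_k", "kmeans_leaf_instances", "segment_leaf_instances"]

LEAF_LABEL = 0


@dataclass
class ClusteringResult:
    """Instance assignment of leaf points (stem keeps instance id -1)."""

    instance_ids: np.ndarray  # (N,) over the full cloud; -1 where not a leaf
    centroids: np.ndarray  # (K, 3)
    inertia_curve: list[tuple[int, float]]


def _leaf_points(cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    if cloud.semantic_labels is None:
        raise ValueError("cloud has no semantic labels")
    mask = cloud.semantic_labels == LEAF_LABEL
    if not mask.any():
        raise ValueError("no leaf-labeled points to cluster")
    return cloud.points[mask], mask


def _fit_kmeans(points: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(points)


def elbow_select_k(
    points: np.ndarray, k_range: tuple[int, int] = (1, 10), seed: int = 0
) -> tuple[int, list[tuple[int, float]]]:
    """Elbow selection of the cluster count.

    Runs seeded K-means across ``k_range`` and returns the K whose point on
    the log-inertia curve is farthest (perpendicularly) from the chord
    joining the curve's endpoints (kneedle-style geometric elbow). The log
    scale matters for leaf clusters: leaves are extended surface patches, so
    within-cluster scatter at the true K is sizable and the linear-scale
    curve has no sharp knee, while on a log scale the decay visibly flattens
    once every leaf has its own cluster.
    """
    points = np.asarray(points, dtype=np.float64)
    lo, hi = k_range
    if lo < 1:
        raise ValueError("k_range must start at >= 1")
    if hi > points.shape[0]:
        warnings.warn(
            f"k_range truncated to the number of points ({points.shape[0]})", stacklevel=2
        )
        hi = points.shape[0]
    ks = np.arange(lo, hi + 1)
    inertia = np.array([_fit_kmeans(points, int(k), seed).inertia_ for k in ks])
    curve = list(zip(ks.tolist(), inertia.tolist()))
    if inertia[0] <= 0.0:
        return int(ks[0]), curve  # already a perfect fit (duplicate points)
    if len(ks) == 1:
        return int(ks[0]), curve
    if len(ks) == 2:
        # no geometry to bend: accept the larger K only for a decisive drop
        return int(ks[1]) if inertia[1] < 0.5 * inertia[0] else int(ks[0]), curve
    floor = max(inertia[inertia > 0].min() * 1e-12, 1e-300)
    logy = np.log(np.maximum(inertia, floor))
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    rng_y = logy[0] - logy[-1]
    y = (logy - logy[-1]) / rng_y if rng_y > 0 else np.zeros_like(logy)
    # distance from (x, y) to the chord from (0, y0) to (1, y_end)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / np.hypot(y1 - y0, x1 - x0)
    return int(ks[int(np.argmax(dist))]), curve


def kmeans_leaf_instances(cloud: PointCloud, K: int, seed: int = 0) -> ClusteringResult:
    """K-means++ clustering of leaf points into K instances.

    Lloyd iterations run to convergence; stem points keep instance id -1.
    """
    leaf_pts, mask = _leaf_points(cloud)
    if K > leaf_pts.shape[0]:
        raise ValueError(f"K={K} exceeds the number of leaf points ({leaf_pts.shape[0]})")
    km = _fit_kmeans(leaf_pts, K, seed)
    ids = np.full(cloud.n, -1, dtype=np.int64)
    ids[mask] = km.labels_
    return ClusteringResult(
        instance_ids=ids,
        centroids=km.cluster_centers_,
        inertia_curve=[(K, float(km.inertia_))],
    )


def segment_leaf_instances(
    cloud: PointCloud, k_range: tuple[int, int] = (1, 10), seed: int = 0
) -> tuple[PointCloud, ClusteringResult]:
    """Elbow-selected K-means over the leaf subset; returns the instance-labeled cloud."""
    leaf_pts, _ = _leaf_points(cloud)
    k, curve = elbow_select_k(leaf_pts, k_range=k_range, seed=seed)
    log.info("elbow selected K=%d leaf instances", k)
    result = kmeans_leaf_instances(cloud, k, seed=seed)
    result.inertia_curve = curve
    out = PointCloud(
        points=cloud.points,
        semantic_labels=cloud.semantic_labels,
        instance_ids=result.instance_ids,
        normalized=cloud.normalized,
    )
    return out, result
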