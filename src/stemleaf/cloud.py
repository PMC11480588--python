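"""Labeled 3D point clouds and the standard preprocessing chain.

A plant is represented as an N x 3 coordinate array with optional per-point
semantic labels (0 = leaf, 1 = stem) and per-leaf instance ids.  Raw clouds
are cleaned with radius outlier removal, brought to a fixed size by seeded
uniform downsampling, and scaled into the unit cube [-1, 1]^3 with the
transform recorded so that metric phenotyping can run on restored
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "NormalizationTransform",
    "radius_outlier_removal",
    "uniform_downsample",
    "normalize",
    "denormalize",
]


@dataclass
class PointCloud:
    """Point set with optional semantic labels and instance ids.

    Parameters
    ----------
    points
        ``(N, 3)`` float array. Centimetres in raw space, dimensionless
        after normalization.
    semantic_labels
        Optional ``(N,)`` integer array; 0 = leaf, 1 = stem.
    instance_ids
        Optional ``(N,)`` integer array; -1 marks unassigned points.
    normalized
        True once coordinates have been scaled into ``[-1, 1]``.
    """

    points: np.ndarray
    semantic_labels: Optional[np.ndarray] = None
    instance_ids: Optional[np.ndarray] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        for name in ("semantic_labels", "instance_ids"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (self.n,):
                    raise ValueError(f"{name} must have shape ({self.n},)")
                setattr(self, name, arr)
        if self.normalized and np.abs(self.points).max() > 1.0 + 1e-9:
            raise ValueError("normalized cloud has coordinates outside [-1, 1]")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def select(self, idx: np.ndarray) -> "PointCloud":
        """New cloud restricted to (or re-ordered by) ``idx``."""
        idx = np.asarray(idx)
        return PointCloud(
            points=self.points[idx],
            semantic_labels=None if self.semantic_labels is None else self.semantic_labels[idx],
            instance_ids=None if self.instance_ids is None else self.instance_ids[idx],
            normalized=self.normalized,
        )

    def with_points(self, points: np.ndarray, normalized: Optional[bool] = None) -> "PointCloud":
        return PointCloud(
            points=points,
            semantic_labels=self.semantic_labels,
            instance_ids=self.instance_ids,
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass(frozen=True)
class NormalizationTransform:
    """Record of the [-1, 1] scaling: x_norm = (x - centroid) / scale."""

    centroid: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=np.float64))
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def forward(self, points: np.ndarray) -> np.ndarray:
        return (points - self.centroid) / self.scale

    def inverse(self, points: np.ndarray) -> np.ndarray:
        return points * self.scale + self.centroid


def radius_outlier_removal(cloud: PointCloud, radius: float, min_neighbors: int) -> PointCloud:
    """Drop points with fewer than ``min_neighbors`` other points within ``radius``.

    Standard ROR denoising: reconstruction artifacts hover off the leaf
    surface and are isolated, so a neighbor-count threshold removes them.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    tree = cKDTree(cloud.points)
    # counts include the query point itself
    counts = tree.query_ball_point(cloud.points, r=radius, return_length=True)
    keep = counts - 1 >= min_neighbors
    if not keep.any():
        raise ValueError(
            "radius outlier removal discarded every point; "
            "increase radius or decrease min_neighbors"
        )
    return cloud.select(np.flatnonzero(keep))


def default_ror_params(cloud: PointCloud) -> tuple[float, int]:
    """Heuristic ROR setting: radius = 2x mean nearest-neighbor distance, 4 neighbors."""
    tree = cKDTree(cloud.points)
    d, _ = tree.query(cloud.points, k=2)
    return 2.0 * float(d[:, 1].mean()), 4


def uniform_downsample(cloud: PointCloud, target_n: int, seed: int = 0) -> PointCloud:
    """Seeded uniform random sample of exactly ``target_n`` points.

    Without replacement when the cloud is large enough, with replacement
    otherwise (upsampling by duplication).
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(cloud.n, size=target_n, replace=cloud.n < target_n)
    return cloud.select(idx)


def normalize(cloud: PointCloud) -> tuple[PointCloud, NormalizationTransform]:
    """Center on the centroid and scale by the max centroid distance into [-1, 1]."""
    if cloud.normalized:
        raise ValueError("cloud is already normalized")
    centroid = cloud.points.mean(axis=0)
    centered = cloud.points - centroid
    scale = float(np.linalg.norm(centered, axis=1).max())
    if scale == 0.0:
        raise ValueError("cannot normalize: all points coincide (zero scale)")
    t = NormalizationTransform(centroid=centroid, scale=scale)
    out = cloud.with_points(centered / scale, normalized=True)
    return out, t


def denormalize(cloud: PointCloud, t: NormalizationTransform) -> PointCloud:
    """Invert :func:`normalize`, restoring metric coordinates."""
    if not cloud.normalized:
        raise ValueError("cloud is not normalized")
    return cloud.with_points(t.inverse(cloud.points), normalized=False)
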