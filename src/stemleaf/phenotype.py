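"""Phenotype parameter extraction from segmented plant point clouds.

Plant height is the z extent of the full cloud. Per-leaf length and width
are chord distances between the points extremal along the first and second
principal axes of the leaf. Leaf area is the summed Heron area of a surface
triangulation of the leaf points: triangles come from a Delaunay
triangulation on the leaf's principal plane, kept only when a pivot ball of
the configured radius could touch their three vertices (3D circumradius
<= radius — the alpha-complex approximation of ball-pivoting
reconstruction), and restricted to the largest connected sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .cloud import PointCloud

log = logging.getLogger(__name__)

__all__ = [
    "PhenotypeRecord",
    "LeafMesh",
    "plant_height",
    "leaf_length_width",
    "bpa_leaf_area",
    "heron_area",
    "reference_leaf_area",
    "extract_phenotypes",
]

REFERENCE_AREA_COEFF = 0.743  # manual leaf-area convention: 0.743 * L * W


@dataclass
class LeafMesh:
    """Triangulated leaf surface (vertices in cm)."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (T, 3) int

    def __post_init__(self) -> None:
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def export_ply(self, path) -> None:
        import trimesh

        trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False).export(
            str(path)
        )


@dataclass
class PhenotypeRecord:
    """Per-plant measurements: height (cm), per-leaf length/width (cm), area (cm^2)."""

    plant_height: float
    leaf_length: list[float] = field(default_factory=list)
    leaf_width: list[float] = field(default_factory=list)
    leaf_area: list[float] = field(default_factory=list)
    mesh_triangles: list[int] = field(default_factory=list)

    def as_frame(self, plant_id: int = 0) -> pd.DataFrame:
        rows = [
            {
                "plant_id": plant_id,
                "leaf_id": i,
                "C_h": self.plant_height,
                "C_l": l,
                "C_w": w,
                "C_a": a,
            }
            for i, (l, w, a) in enumerate(
                zip(self.leaf_length, self.leaf_width, self.leaf_area)
            )
        ]
        return pd.DataFrame(rows)


def plant_height(cloud: PointCloud) -> float:
    """C_h = z_max - z_min over the full (metric) cloud."""
    z = cloud.points[:, 2]
    return float(z.max() - z.min())


def leaf_length_width(leaf_points: np.ndarray) -> tuple[float, float]:
    """Chord length/width of a leaf along its first two principal axes.

    PCA aligns the leaf; length is the Euclidean distance between the two
    points extremal along the first principal axis, width the same along the
    second. Outputs are ordered so length >= width.
    """
    pts = np.asarray(leaf_points, dtype=np.float64)
    if pts.shape[0] < 3:
        raise ValueError("leaf needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    # principal axes of the leaf point set
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    if np.linalg.matrix_rank(centered) < 2:
        raise ValueError("leaf points are collinear; length/width undefined")
    proj1 = centered @ vt[0]
    proj2 = centered @ vt[1]
    l = float(np.linalg.norm(pts[np.argmax(proj1)] - pts[np.argmin(proj1)]))
    w = float(np.linalg.norm(pts[np.argmax(proj2)] - pts[np.argmin(proj2)]))
    return (l, w) if l >= w else (w, l)


def heron_area(edges: np.ndarray) -> np.ndarray:
    """Heron's formula from edge lengths ``(T, 3)``; degenerate triangles give 0."""
    e = np.asarray(edges, dtype=np.float64)
    s = e.sum(axis=-1) / 2.0
    prod = s * (s - e[..., 0]) * (s - e[..., 1]) * (s - e[..., 2])
    return np.sqrt(np.maximum(prod, 0.0))


def _triangle_edge_lengths(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p1, p2, p3 = (vertices[triangles[:, i]] for i in range(3))
    return np.stack(
        [
            np.linalg.norm(p1 - p2, axis=1),
            np.linalg.norm(p2 - p3, axis=1),
            np.linalg.norm(p3 - p1, axis=1),
        ],
        axis=1,
    )


def mean_nn_spacing(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].mean())


def default_bpa_radii(points: np.ndarray) -> list[float]:
    """Multi-radius default: {1.5, 3, 6} x mean nearest-neighbor spacing."""
    s = mean_nn_spacing(points)
    return [1.5 * s, 3.0 * s, 6.0 * s]


def bpa_leaf_area(
    leaf_points: np.ndarray, radii: Optional[Sequence[float]] = None
) -> tuple[float, LeafMesh]:
    """Leaf area from a pivot-ball surface triangulation (see module docstring).

    The leaf is parametrized on its principal plane and Delaunay-triangulated
    there; a triangle survives only if a ball of the largest configured
    radius could pivot onto it (3D circumradius <= radius), and only the
    largest connected sheet is kept. The area is the Heron-formula sum over
    the retained 3D triangles.
    """
    pts = np.asarray(leaf_points, dtype=np.float64)
    if pts.shape[0] < 3:
        raise ValueError("surface reconstruction needs at least 3 points")
    if radii is None:
        radii = default_bpa_radii(pts)
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii):
        raise ValueError("pivot radii must be positive")
    r_max = max(radii)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    uv = centered @ vt[:2].T  # leaf coordinates on the principal plane
    try:
        tri = Delaunay(uv)
    except Exception as exc:  # degenerate (collinear) input
        raise ValueError(f"surface reconstruction failed: {exc}") from exc
    simplices = tri.simplices
    # 3D circumradius filter — the ball criterion proper: a pivot ball of
    # radius r touches three points only if their circumradius is <= r, so
    # spurious "tent" triangles to off-surface points are rejected even when
    # their planar projection looks compact
    edges3d = _triangle_edge_lengths(pts, simplices)
    areas3d = heron_area(edges3d)
    with np.errstate(divide="ignore", invalid="ignore"):
        circum3d = np.where(
            areas3d > 1e-12, edges3d.prod(axis=1) / (4.0 * areas3d), np.inf
        )
    keep = circum3d <= r_max
    if not keep.any():
        raise ValueError(
            "no triangles survived reconstruction; increase the pivot radius"
        )
    kept = simplices[keep]
    kept_areas = areas3d[keep]
    # a leaf is one sheet: retain only the largest connected mesh component
    # (by area), which drops any residual triangle islands among outliers
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = pts.shape[0]
    rows = np.concatenate([kept[:, 0], kept[:, 1], kept[:, 2]])
    cols = np.concatenate([kept[:, 1], kept[:, 2], kept[:, 0]])
    adj = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    tri_label = labels[kept[:, 0]]
    comp_area = np.bincount(tri_label, weights=kept_areas)
    main = int(np.argmax(comp_area))
    sel = tri_label == main
    mesh = LeafMesh(vertices=pts, triangles=kept[sel])
    return float(kept_areas[sel].sum()), mesh


def reference_leaf_area(length: float, width: float) -> float:
    """Manual-measurement convention for the reference leaf area: 0.743 * L * W."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    return REFERENCE_AREA_COEFF * length * width


def extract_phenotypes(
    cloud: PointCloud, radii: Optional[Sequence[float]] = None
) -> PhenotypeRecord:
    """Height plus per-leaf-instance length, width, and area for one plant.

    Expects a denormalized (metric) cloud with instance ids on leaf points.
    """
    if cloud.normalized:
        raise ValueError("phenotyping expects metric (denormalized) coordinates")
    if cloud.instance_ids is None:
        raise ValueError("cloud has no instance ids; run instance segmentation first")
    record = PhenotypeRecord(plant_height=plant_height(cloud))
    leaf_ids = sorted(set(cloud.instance_ids[cloud.instance_ids >= 0].tolist()))
    for lid in leaf_ids:
        pts = cloud.points[cloud.instance_ids == lid]
        if pts.shape[0] < 3:
            log.warning("leaf instance %d has <3 points; skipped", lid)
            continue
        # all measurements are made on the reconstructed leaf sheet: the
        # mesh keeps only the largest connected surface, so stray points that
        # instance clustering pulled in from other organs neither add area
        # nor stretch the length/width chords
        try:
            area, mesh = bpa_leaf_area(pts, radii=radii)
            nt = mesh.n_triangles
            sheet = pts[np.unique(mesh.triangles)]
        except ValueError as exc:
            log.warning("leaf instance %d: %s", lid, exc)
            area, nt, sheet = float("nan"), 0, pts
        l, w = leaf_length_width(sheet)
        record.leaf_length.append(l)
        record.leaf_width.append(w)
        record.leaf_area.append(area)
        record.mesh_triangles.append(nt)
    return record
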