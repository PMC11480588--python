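"""Reading and writing labeled point clouds.

The on-disk interchange format is ShapeNet-Part-style whitespace text: one
point per line, ``x y z label`` (an optional fifth column carries the
instance id). PLY import/export for interoperability goes through trimesh.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Union

import numpy as np

from .cloud import PointCloud

log = logging.getLogger(__name__)

PathLike = Union[str, "os.PathLike[str]"]


def read_labeled_txt(path: PathLike) -> PointCloud:
    """Parse an ``x y z label [instance]`` text file into a :class:`PointCloud`."""
    pts: list[list[float]] = []
    labels: list[int] = []
    instances: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 fields, got {len(fields)}")
            try:
                x, y, z = (float(v) for v in fields[:3])
                lab = int(float(fields[3]))
                inst = int(float(fields[4])) if len(fields) >= 5 else None
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
            pts.append([x, y, z])
            labels.append(lab)
            if inst is not None:
                instances.append(inst)
    if not pts:
        raise ValueError(f"{path}: no data lines")
    inst_arr: Optional[np.ndarray] = None
    if instances and len(instances) == len(pts):
        inst_arr = np.asarray(instances, dtype=np.int64)
    log.info("read %d points from %s", len(pts), path)
    return PointCloud(
        points=np.asarray(pts, dtype=np.float64),
        semantic_labels=np.asarray(labels, dtype=np.int64),
        instance_ids=inst_arr,
    )


def write_labeled_txt(cloud: PointCloud, path: PathLike, include_instances: bool = False) -> PathLike:
    """Write ``x y z label`` lines (full float precision); optional instance column."""
    if cloud.semantic_labels is None:
        raise ValueError("cloud has no semantic labels to write")
    if include_instances and cloud.instance_ids is None:
        raise ValueError("include_instances=True but cloud has no instance ids")
    with open(path, "w") as fh:
        for i in range(cloud.n):
            x, y, z = cloud.points[i]
            row = f"{x:.17g} {y:.17g} {z:.17g} {cloud.semantic_labels[i]}"
            if include_instances:
                row += f" {cloud.instance_ids[i]}"
            fh.write(row + "\n")
    log.info("wrote %d points to %s", cloud.n, path)
    return path


def read_ply(path: PathLike) -> PointCloud:
    """Load vertex coordinates from a PLY file (labels are not carried by PLY here)."""
    import trimesh

    obj = trimesh.load(str(path), process=False)
    verts = np.asarray(obj.vertices, dtype=np.float64)
    log.info("read %d points from %s", len(verts), path)
    return PointCloud(points=verts)


def write_ply(cloud: PointCloud, path: PathLike) -> PathLike:
    """Export coordinates as an ASCII PLY point cloud via trimesh."""
    import trimesh

    pc = trimesh.PointCloud(cloud.points)
    pc.export(str(path))
    log.info("wrote %d points to %s", cloud.n, path)
    return path
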