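"""The stem-leaf segmentation network and its training loop.

Architecture: two geometric graph encoder (GGE) blocks at full resolution
followed by three GGE-P blocks (GGE + farthest-point-sampling pooling at
rate 4), giving the resolution cascade N -> N/4 -> N/16 -> N/64. All five
stage outputs are brought back to N rows by inverse-distance interpolation,
concatenated, and scored by a shared MLP head (512, 256, p). Each GGE block
fuses a Euclidean adaptive-kernel convolution with a hyperbolic
star-transformer encoder through an element-wise sigmoid gate.

Optimization combines softmax cross-entropy with a margin triplet loss on
the pre-head per-point embedding (L = alpha * L_C + beta * L_T), trained by
SGD with momentum under cosine-annealed learning rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concatenate, log_softmax, no_grad
from .cloud import PointCloud
from .graph import farthest_point_sampling, idw_weights, kdtree_knn
from .hyperbolic import HGSConfig, HGSEncoder, ring_edge_masks
from .euclidean import EuclideanChannel
from .nn import SGD, Linear, MLP, Module, cosine_lr

log = logging.getLogger(__name__)

__all__ = [
    "GGEConfig",
    "LossConfig",
    "OptConfig",
    "GGEBlock",
    "GGESegNet",
    "CloudGraphs",
    "build_cloud_graphs",
    "cross_entropy_loss",
    "triplet_loss",
    "combined_loss",
    "merge_graphs",
    "train_model",
    "predict",
]


@dataclass
class GGEConfig:
    """Architecture hyperparameters.

    ``stage_dims`` holds the five per-stage feature widths (2 GGE + 3
    GGE-P); ``K`` is the neighborhood size (clipped to N-1 on very coarse
    stages); ``pooling_rate`` the FPS downsampling factor.
    """

    stage_dims: tuple[int, ...] = (64, 64, 128, 256, 512)
    K: int = 20
    num_classes: int = 2
    pooling_rate: int = 4
    head_dims: tuple[int, int] = (512, 256)
    hgs: HGSConfig = field(default_factory=HGSConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_dims = tuple(self.stage_dims)
        self.head_dims = tuple(self.head_dims)
        if len(self.stage_dims) != 5:
            raise ValueError("stage_dims must list 5 widths (2 GGE + 3 GGE-P)")
        if self.pooling_rate < 2:
            raise ValueError("pooling_rate must be >= 2")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class LossConfig:
    """Loss mixing: L = alpha * cross-entropy + beta * triplet (alpha+beta=1)."""

    alpha: float = 0.9
    beta: float = 0.1
    margin: float = 0.2
    triplets_per_batch: int = 128

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha and beta must be non-negative and sum to 1")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class OptConfig:
    """SGD-with-momentum schedule (cosine annealing lr_max -> lr_min)."""

    lr_max: float = 0.1
    lr_min: float = 0.001
    momentum: float = 0.9
    batch_size: int = 4
    epochs: int = 200
    patience: int = 10
    clip_norm: float = 5.0
    seed: int = 0


class GGEBlock(Module):
    """One geometric graph encoder: dual channels + gate fusion."""

    def __init__(self, in_dim: int, dim: int, hgs: HGSConfig, rng: np.random.Generator):
        self.dim = dim
        self.euclid = EuclideanChannel(in_dim, dim, rng)
        self.hyper = HGSEncoder(in_dim, dim, hgs, rng)
        self.gate = Linear(2 * dim, dim, rng)
        # open the gate toward the Euclidean channel at init: the hyperbolic
        # branch is untrained noise at first and an even 50/50 mix slows the
        # first epochs; the bias is learnable and moves wherever training
        # wants it
        self.gate.b.data[:] = 2.0

    def __call__(
        self,
        coords: np.ndarray,
        features: Tensor,
        neighbor_idx: np.ndarray,
        edge_mask: np.ndarray,
    ) -> Tensor:
        n, k = neighbor_idx.shape
        d = features.shape[-1]
        fi = features.reshape(n, 1, d).take(np.zeros(k, dtype=np.int64), axis=1)
        fj = features.take(neighbor_idx.reshape(-1), axis=0).reshape(n, k, d)
        feat_edges = concatenate([fi, fj - fi], axis=2)  # (N,K,2D)
        xi = np.repeat(coords[:, None, :], k, axis=1)
        xj = coords[neighbor_idx]
        spatial = np.concatenate([xi, xj - xi], axis=2)  # (N,K,6)
        f_e = self.euclid(spatial, feat_edges)
        f_h = self.hyper(features, neighbor_idx, edge_mask)
        g = self.gate(concatenate([f_e, f_h], axis=-1)).sigmoid()
        return g * f_e + (1.0 - g) * f_h


class GGESegNet(Module):
    """Full segmentation network (see module docstring)."""

    def __init__(self, cfg: GGEConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        dims = cfg.stage_dims
        in_dims = (3,) + dims[:-1]
        self.blocks = [
            GGEBlock(in_dims[i], dims[i], cfg.hgs, rng) for i in range(5)
        ]
        self.head = MLP([sum(dims), *cfg.head_dims, cfg.num_classes], rng)

    def forward(self, graphs: "CloudGraphs") -> tuple[Tensor, Tensor]:
        """Returns (scores (N, p), pre-head embedding (N, sum(stage_dims)))."""
        cfg = self.cfg
        coords0 = graphs.levels[0].coords
        n = coords0.shape[0]
        feats: Tensor = Tensor(coords0)
        stage_outputs: list[tuple[int, Tensor]] = []  # (level index, features)
        level = 0
        # two full-resolution GGE stages
        for b in (0, 1):
            lv = graphs.levels[level]
            feats = self.blocks[b](lv.coords, feats, lv.neighbor_idx, lv.edge_mask)
            stage_outputs.append((level, feats))
        # three GGE-P stages: encode at the current level, pool to the next
        for b in (2, 3, 4):
            lv = graphs.levels[level]
            feats = self.blocks[b](lv.coords, feats, lv.neighbor_idx, lv.edge_mask)
            pool_idx = lv.pool_idx  # (S, K+1): sampled centers + their neighbors
            s, kk = pool_idx.shape
            m = feats.shape[-1]
            feats = feats.take(pool_idx.reshape(-1), axis=0).reshape(s, kk, m).max(axis=1)
            level += 1
            stage_outputs.append((level, feats))
        # decoder: bring every stage output to N rows and concatenate
        decoded = []
        for lvl, f in stage_outputs:
            if lvl == 0:
                decoded.append(f)
                continue
            idx, w = graphs.levels[lvl].interp_idx, graphs.levels[lvl].interp_w
            m = f.shape[-1]
            gathered = f.take(idx.reshape(-1), axis=0).reshape(n, idx.shape[1], m)
            decoded.append((gathered * Tensor(w[:, :, None])).sum(axis=1))
        embedding = concatenate(decoded, axis=-1)
        scores = self.head(embedding)
        return scores, embedding


@dataclass
class _Level:
    coords: np.ndarray
    neighbor_idx: np.ndarray
    edge_mask: np.ndarray
    pool_idx: Optional[np.ndarray] = None  # (S, K+1) centers + neighbors, this level
    interp_idx: Optional[np.ndarray] = None  # to level-0 rows
    interp_w: Optional[np.ndarray] = None


@dataclass
class CloudGraphs:
    """Per-cloud graph structure, precomputed once and reused every epoch."""

    levels: list[_Level]
    labels: Optional[np.ndarray] = None


def build_cloud_graphs(cloud: PointCloud, cfg: GGEConfig, seed: int = 0) -> CloudGraphs:
    """KNN graphs, FPS/pooling indices and decoder interpolation weights."""
    pts0 = cloud.points
    levels: list[_Level] = []
    pts = pts0
    n_levels = 4  # full resolution + three pooled levels
    for lvl in range(n_levels):
        n = pts.shape[0]
        k = min(cfg.K, n - 1)
        if k < 1:
            raise ValueError("cloud too small for the configured pooling cascade")
        if n < 64 * cfg.K and lvl == 0:
            log.debug("small cloud (N=%d): deep stages will be heavily clipped", n)
        pc = PointCloud(points=pts, normalized=False)
        graph = kdtree_knn(pc, k)
        mask = ring_edge_masks(n, k, cfg.hgs.edge_prob, seed=seed * 7919 + lvl)
        level = _Level(coords=pts, neighbor_idx=graph.neighbor_indices, edge_mask=mask)
        if lvl > 0:
            idx, w = idw_weights(pts, pts0)
            level.interp_idx, level.interp_w = idx, w
        levels.append(level)
        if lvl < n_levels - 1:
            # geometric FPS start: the sampled set is permutation-invariant
            sampled = farthest_point_sampling(pc, cfg.pooling_rate)
            levels[lvl].pool_idx = np.concatenate(
                [sampled[:, None], graph.neighbor_indices[sampled]], axis=1
            )
            pts = pts[sampled]
    return CloudGraphs(levels=levels, labels=cloud.semantic_labels)


def merge_graphs(graphs_list: Sequence[CloudGraphs]) -> CloudGraphs:
    """Stack several clouds into one block-diagonal graph structure.

    Neighborhoods, pooling and interpolation never cross cloud boundaries
    (indices are offset per cloud), so a single forward pass over the merged
    structure equals the per-cloud passes concatenated — but runs each tape
    op once per batch instead of once per cloud.
    """
    n_levels = len(graphs_list[0].levels)
    merged_levels = []
    for lvl in range(n_levels):
        coords, nidx, emask, pidx, iidx, iw = [], [], [], [], [], []
        off = 0  # rows at this level
        off0 = 0  # rows at level 0 (interpolation target side handled by order)
        for g in graphs_list:
            level = g.levels[lvl]
            n = level.coords.shape[0]
            coords.append(level.coords)
            nidx.append(level.neighbor_idx + off)
            emask.append(level.edge_mask)
            if level.pool_idx is not None:
                pidx.append(level.pool_idx + off)
            if level.interp_idx is not None:
                iidx.append(level.interp_idx + off)
                iw.append(level.interp_w)
            off += n
        merged_levels.append(
            _Level(
                coords=np.concatenate(coords),
                neighbor_idx=np.concatenate(nidx),
                edge_mask=np.concatenate(emask),
                pool_idx=np.concatenate(pidx) if pidx else None,
                interp_idx=np.concatenate(iidx) if iidx else None,
                interp_w=np.concatenate(iw) if iw else None,
            )
        )
    labels = None
    if all(g.labels is not None for g in graphs_list):
        labels = np.concatenate([g.labels for g in graphs_list])
    return CloudGraphs(levels=merged_levels, labels=labels)


# -- losses ----------------------------------------------------------------------


def cross_entropy_loss(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy, L_C = -(1/n) sum_i log p_{i, y_i}."""
    labels = np.asarray(labels, dtype=np.int64)
    n, p = scores.shape
    if labels.min() < 0 or labels.max() >= p:
        raise ValueError("labels out of range")
    onehot = np.zeros((n, p))
    onehot[np.arange(n), labels] = 1.0
    logp = log_softmax(scores, axis=-1)
    return -(Tensor(onehot) * logp).sum() / n


def triplet_loss(
    features: Tensor, labels: np.ndarray, cfg: LossConfig, seed: int = 0
) -> Tensor:
    """Margin triplet loss over seeded (anchor, positive, negative) samples.

    mean over triplets of max(0, ||f_a - f_+||^2 - ||f_a - f_-||^2 + margin).
    Returns 0 when the batch carries a single class (no negatives exist).
    """
    labels = np.asarray(labels, dtype=np.int64)
    classes, counts = np.unique(labels, return_counts=True)
    eligible = classes[counts >= 2]
    if classes.size < 2 or eligible.size == 0:
        warnings.warn("triplet loss skipped: need two classes with positives", stacklevel=2)
        return Tensor(0.0)
    rng = np.random.default_rng(seed)
    t = cfg.triplets_per_batch
    anchor_cls = rng.choice(eligible, size=t)
    a = np.empty(t, dtype=np.int64)
    p_ = np.empty(t, dtype=np.int64)
    n_ = np.empty(t, dtype=np.int64)
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for i, c in enumerate(anchor_cls):
        pos_pool = by_class[c]
        a[i], p_[i] = rng.choice(pos_pool, size=2, replace=False)
        neg_pool = np.flatnonzero(labels != c)
        n_[i] = rng.choice(neg_pool)
    fa = features.take(a, axis=0)
    fp = features.take(p_, axis=0)
    fn = features.take(n_, axis=0)
    d_pos = ((fa - fp) ** 2).sum(axis=-1)
    d_neg = ((fa - fn) ** 2).sum(axis=-1)
    return (d_pos - d_neg + cfg.margin).relu().mean()


def combined_loss(
    scores: Tensor,
    features: Tensor,
    labels: np.ndarray,
    cfg: LossConfig,
    seed: int = 0,
) -> Tensor:
    """alpha * L_C + beta * L_triplet."""
    ce = cross_entropy_loss(scores, labels)
    if cfg.beta == 0.0:
        return cfg.alpha * ce
    return cfg.alpha * ce + cfg.beta * triplet_loss(features, labels, cfg, seed=seed)


# -- training --------------------------------------------------------------------


def _oa(model: GGESegNet, graphs_list: Sequence[CloudGraphs]) -> float:
    correct = total = 0
    with no_grad():
        for g in graphs_list:
            scores, _ = model.forward(g)
            pred = scores.data.argmax(axis=1)
            correct += int((pred == g.labels).sum())
            total += g.labels.size
    return correct / total


def train_model(
    train_clouds: Sequence[PointCloud],
    cfg: GGEConfig,
    loss_cfg: LossConfig,
    opt_cfg: OptConfig,
    val_clouds: Sequence[PointCloud] = (),
    model: Optional[GGESegNet] = None,
) -> tuple[GGESegNet, list[dict]]:
    """Train the network; returns (model with best-validation weights, history).

    Early stopping: training halts once the validation loss has not improved
    for ``patience`` consecutive epochs (train loss is used when no
    validation set is given).
    """
    if not train_clouds:
        raise ValueError("empty training set")
    for c in train_clouds:
        if c.semantic_labels is None or not c.normalized:
            raise ValueError("training clouds must be labeled and normalized")
    model = model or GGESegNet(cfg)
    params = model.parameters()
    opt = SGD(params, lr=opt_cfg.lr_max, momentum=opt_cfg.momentum, clip_norm=opt_cfg.clip_norm)
    rng = np.random.default_rng(opt_cfg.seed)
    train_graphs = [
        build_cloud_graphs(c, cfg, seed=opt_cfg.seed + i) for i, c in enumerate(train_clouds)
    ]
    val_graphs = [
        build_cloud_graphs(c, cfg, seed=opt_cfg.seed + 10_000 + i)
        for i, c in enumerate(val_clouds)
    ]
    history: list[dict] = []
    best_loss = np.inf
    best_state = model.state_dict()
    stale = 0
    for epoch in range(opt_cfg.epochs):
        lr = cosine_lr(epoch, opt_cfg.epochs, opt_cfg.lr_max, opt_cfg.lr_min)
        opt.lr = lr
        order = rng.permutation(len(train_graphs))
        epoch_loss = 0.0
        n_batches = 0
        for b, start in enumerate(range(0, len(order), opt_cfg.batch_size)):
            batch = order[start : start + opt_cfg.batch_size]
            opt.zero_grad()
            # one block-diagonal forward per batch (see merge_graphs); with
            # equal-size clouds the point-mean loss equals the batch mean
            g = (
                merge_graphs([train_graphs[j] for j in batch])
                if len(batch) > 1
                else train_graphs[batch[0]]
            )
            scores, emb = model.forward(g)
            loss = combined_loss(
                scores, emb, g.labels, loss_cfg, seed=opt_cfg.seed + epoch * 1009 + b
            )
            value = float(loss.data)
            loss.backward()
            del scores, emb, loss  # release the tape before the optimizer step
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}; "
                    "lower the learning rate or check the input data"
                )
            opt.step()
            epoch_loss += value
            n_batches += 1
        train_loss = epoch_loss / n_batches
        if val_graphs:
            vl = 0.0
            with no_grad():
                for g in val_graphs:
                    scores, emb = model.forward(g)
                    vl += float(combined_loss(scores, emb, g.labels, loss_cfg, seed=0).data)
            monitor = vl / len(val_graphs)
            val_oa = _oa(model, val_graphs)
        else:
            monitor, val_oa = train_loss, float("nan")
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": train_loss,
                "val_loss": monitor,
                "val_oa": val_oa,
            }
        )
        log.info(
            "epoch %d lr=%.4f train_loss=%.4f val_loss=%.4f val_oa=%.3f",
            epoch, lr, train_loss, monitor, val_oa,
        )
        if monitor < best_loss - 1e-12:
            best_loss = monitor
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= opt_cfg.patience:
                log.info("early stop at epoch %d (patience %d)", epoch, opt_cfg.patience)
                break
    model.load_state_dict(best_state)
    return model, history


def predict(cloud: PointCloud, model: GGESegNet, seed: int = 0) -> PointCloud:
    """Per-point argmax class assignment; coordinates untouched."""
    graphs = build_cloud_graphs(cloud, model.cfg, seed=seed)
    with no_grad():
        scores, _ = model.forward(graphs)
    labels = scores.data.argmax(axis=1).astype(np.int64)
    return PointCloud(
        points=cloud.points,
        semantic_labels=labels,
        instance_ids=cloud.instance_ids,
        normalized=cloud.normalized,
    )


# -- checkpointing ----------------------------------------------------------------


def save_checkpoint(path, model: GGESegNet, opt_cfg: Optional[OptConfig] = None) -> None:
    """Versioned npz archive of parameters plus the full architecture config."""
    import json

    cfg = model.cfg
    meta = {
        "version": 1,
        "gge": {**asdict(cfg), "hgs": asdict(cfg.hgs)},
        "opt": asdict(opt_cfg) if opt_cfg else None,
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> GGESegNet:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    g = dict(meta["gge"])
    hgs = HGSConfig(**g.pop("hgs"))
    g["stage_dims"] = tuple(g["stage_dims"])
    g["head_dims"] = tuple(g["head_dims"])
    cfg = GGEConfig(**g, hgs=hgs)
    model = GGESegNet(cfg)
    model.load_state_dict(state)
    return model
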