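"""Network assembly: gate fusion, cascade shapes, losses, training mechanics."""

import numpy as np
import pytest

from stemleaf.autodiff import Tensor, default_dtype
from stemleaf.cloud import PointCloud, normalize
from stemleaf.hyperbolic import HGSConfig
from stemleaf.network import (
    CloudGraphs,
    GGEBlock,
    GGEConfig,
    LossConfig,
    OptConfig,
    GGESegNet,
    build_cloud_graphs,
    combined_loss,
    cross_entropy_loss,
    load_checkpoint,
    predict,
    save_checkpoint,
    train_model,
    triplet_loss,
)

TINY = GGEConfig(
    stage_dims=(8, 8, 8, 8, 8),
    K=4,
    head_dims=(16, 8),
    hgs=HGSConfig(layers=1, heads=2),
    seed=0,
)


@pytest.fixture
def tiny_cloud(rng):
    pts = rng.normal(size=(128, 3))
    pts /= np.abs(pts).max() + 1e-9
    return PointCloud(points=pts, semantic_labels=rng.integers(0, 2, 128), normalized=True)


class TestGateFusion:
    def _block(self, seed=0):
        return GGEBlock(3, 8, HGSConfig(layers=1, heads=2), np.random.default_rng(seed))

    def _inputs(self, rng, n=16, k=4):
        from stemleaf.graph import kdtree_knn

        pts = rng.normal(size=(n, 3))
        graph = kdtree_knn(PointCloud(points=pts), K=k)
        return pts, Tensor(pts), graph.neighbor_indices, np.ones((n, k), bool)

    def test_gate_saturation_recovers_each_channel(self, rng):
        block = self._block()
        coords, feats, nidx, mask = self._inputs(rng)
        f_e = block.euclid.__call__  # noqa: B023 - used below via forward pieces
        # saturate the gate by forcing a huge bias
        for bias, expect_euclid in ((50.0, True), (-50.0, False)):
            block.gate.b.data[:] = bias
            out = block(coords, feats, nidx, mask).data
            from stemleaf.autodiff import concatenate

            n, k = nidx.shape
            fi = feats.reshape(n, 1, 3).take(np.zeros(k, dtype=np.int64), axis=1)
            fj = feats.take(nidx.reshape(-1), axis=0).reshape(n, k, 3)
            feat_edges = concatenate([fi, fj - fi], axis=2)
            xi = np.repeat(coords[:, None, :], k, axis=1)
            spatial = np.concatenate([xi, coords[nidx] - xi], axis=2)
            fe = block.euclid(spatial, feat_edges).data
            fh = block.hyper(feats, nidx, mask).data
            assert np.allclose(out, fe if expect_euclid else fh, atol=1e-6)

    def test_output_convex_combination_of_channels(self, rng):
        for seed in range(5):
            block = self._block(seed)
            block.gate.W.data = rng.normal(size=block.gate.W.shape) * 3
            coords, feats, nidx, mask = self._inputs(rng)
            out = block(coords, feats, nidx, mask).data
            from stemleaf.autodiff import concatenate

            n, k = nidx.shape
            fi = feats.reshape(n, 1, 3).take(np.zeros(k, dtype=np.int64), axis=1)
            fj = feats.take(nidx.reshape(-1), axis=0).reshape(n, k, 3)
            feat_edges = concatenate([fi, fj - fi], axis=2)
            xi = np.repeat(coords[:, None, :], k, axis=1)
            spatial = np.concatenate([xi, coords[nidx] - xi], axis=2)
            fe = block.euclid(spatial, feat_edges).data
            fh = block.hyper(feats, nidx, mask).data
            lo = np.minimum(fe, fh) - 1e-9
            hi = np.maximum(fe, fh) + 1e-9
            assert np.all(out >= lo) and np.all(out <= hi)


class TestForwardPass:
    def test_cascade_and_output_shape(self, tiny_cloud):
        graphs = build_cloud_graphs(tiny_cloud, TINY, seed=0)
        sizes = [lv.coords.shape[0] for lv in graphs.levels]
        assert sizes == [128, 32, 8, 2]
        model = GGESegNet(TINY)
        scores, emb = model.forward(graphs)
        assert scores.shape == (128, 2)
        assert emb.shape == (128, sum(TINY.stage_dims))

    def test_permutation_equivariance(self, rng, tiny_cloud):
        model = GGESegNet(TINY)
        graphs = build_cloud_graphs(tiny_cloud, TINY, seed=0)
        scores, _ = model.forward(graphs)
        perm = rng.permutation(tiny_cloud.n)
        permuted = tiny_cloud.select(perm)
        # FPS tie-breaking depends on index order, so fix the same geometric
        # seed point by seeding identically; scores must follow the points
        graphs_p = build_cloud_graphs(permuted, TINY, seed=0)
        scores_p, _ = model.forward(graphs_p)
        # compare per-point by matching coordinates
        order = np.lexsort(tiny_cloud.points.T)
        order_p = np.lexsort(permuted.points.T)
        a = scores.data[order]
        b = scores_p.data[order_p]
        assert np.allclose(a, b, atol=1e-4)

    def test_deterministic_given_weights(self, tiny_cloud):
        model = GGESegNet(TINY)
        g = build_cloud_graphs(tiny_cloud, TINY, seed=0)
        a, _ = model.forward(g)
        b, _ = model.forward(g)
        assert np.array_equal(a.data, b.data)

    def test_predict_labels_in_range(self, tiny_cloud):
        model = GGESegNet(TINY)
        out = predict(tiny_cloud, model, seed=0)
        assert set(np.unique(out.semantic_labels)) <= {0, 1}
        assert np.array_equal(out.points, tiny_cloud.points)


class TestLosses:
    def test_cross_entropy_perfect_and_uniform(self):
        perfect = Tensor(np.array([[100.0, 0.0], [0.0, 100.0]]))
        labels = np.array([0, 1])
        assert float(cross_entropy_loss(perfect, labels).data) == pytest.approx(0.0, abs=1e-9)
        uniform = Tensor(np.zeros((4, 2)))
        val = float(cross_entropy_loss(uniform, np.array([0, 1, 0, 1])).data)
        assert val == pytest.approx(np.log(2), rel=1e-9)

    def test_cross_entropy_matches_naive_loop(self, rng):
        scores = rng.normal(size=(5, 3))
        labels = rng.integers(0, 3, 5)
        got = float(cross_entropy_loss(Tensor(scores), labels).data)
        total = 0.0
        for i in range(5):
            e = np.exp(scores[i] - scores[i].max())
            p = e / e.sum()
            total -= np.log(p[labels[i]])
        assert got == pytest.approx(total / 5)

    def test_triplet_margin_cases(self):
        cfg = LossConfig(alpha=0.5, beta=0.5, margin=0.2, triplets_per_batch=64)
        # f_+ = f_a, negatives far: loss 0
        feats = Tensor(np.array([[0.0, 0], [0, 0], [10, 0], [10, 0.0]]))
        labels = np.array([0, 0, 1, 1])
        assert float(triplet_loss(feats, labels, cfg, seed=0).data) == pytest.approx(0.0)
        # every point coincides: d_pos = d_neg = 0, loss is exactly the margin
        feats = Tensor(np.zeros((6, 2)))
        labels = np.array([0, 0, 1, 1, 0, 1])
        val = float(triplet_loss(feats, labels, LossConfig(margin=0.3), seed=1).data)
        assert val == pytest.approx(0.3, abs=1e-6)

    def test_triplet_single_class_warns_and_zero(self):
        feats = Tensor(np.zeros((4, 2)))
        with pytest.warns(UserWarning):
            val = triplet_loss(feats, np.zeros(4, dtype=int), LossConfig(), seed=0)
        assert float(val.data) == 0.0

    def test_triplet_hand_arithmetic(self):
        # one admissible triplet only: anchor/positive from class 0, negative class 1
        feats = Tensor(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        labels = np.array([0, 0, 1])
        cfg = LossConfig(margin=0.5, triplets_per_batch=8)
        val = float(triplet_loss(feats, labels, cfg, seed=0).data)
        # candidates: a=0,p=1,n=2 -> max(0, 1 - 4 + .5) = 0
        #             a=1,p=0,n=2 -> max(0, 1 - 1 + .5) = 0.5
        # seeded sampling mixes the two, so the mean lies in [0, 0.5]
        assert 0.0 <= val <= 0.5

    def test_combined_loss_mixing(self, rng):
        scores = Tensor(rng.normal(size=(6, 2)))
        feats = Tensor(rng.normal(size=(6, 4)))
        labels = rng.integers(0, 2, 6)
        ce = float(cross_entropy_loss(scores, labels).data)
        tri = float(triplet_loss(feats, labels, LossConfig(), seed=7).data)
        only_ce = combined_loss(scores, feats, labels, LossConfig(alpha=1.0, beta=0.0), seed=7)
        assert float(only_ce.data) == pytest.approx(ce)
        only_tri = combined_loss(scores, feats, labels, LossConfig(alpha=0.0, beta=1.0), seed=7)
        assert float(only_tri.data) == pytest.approx(tri)
        half = combined_loss(scores, feats, labels, LossConfig(alpha=0.5, beta=0.5), seed=7)
        assert float(half.data) == pytest.approx(0.5 * ce + 0.5 * tri)

    def test_invalid_mixing_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=0.8, beta=0.1)


class TestTraining:
    def _plants(self, n, points=128, seed=0):
        from stemleaf.synthetic import SyntheticPlantSpec, generate_plant

        clouds = []
        for i in range(n):
            spec = SyntheticPlantSpec(points_total=points, n_leaves=2, seed=seed + i)
            c, _ = generate_plant(spec)
            clouds.append(normalize(c)[0])
        return clouds

    def test_lr_schedule_endpoints(self):
        from stemleaf.nn import cosine_lr

        assert cosine_lr(0, 200, 0.1, 0.001) == pytest.approx(0.1)
        assert cosine_lr(199, 200, 0.1, 0.001) == pytest.approx(0.001)

    def test_early_stopping_on_stagnant_validation(self, tiny_cloud):
        # zero learning rate: validation loss never improves after epoch 0
        with default_dtype(np.float32):
            clouds = self._plants(4)
            opt = OptConfig(epochs=30, patience=3, lr_max=0.0, lr_min=0.0, seed=0)
            _, hist = train_model(clouds[:3], TINY, LossConfig(), opt, val_clouds=clouds[3:])
        assert len(hist) == 4  # epoch 0 improves from +inf, then 3 stagnant

    def test_loss_decreases_and_checkpoint_roundtrip(self, tmp_path):
        with default_dtype(np.float32):
            clouds = self._plants(6)
            opt = OptConfig(epochs=8, patience=8, seed=1, batch_size=2)
            model, hist = train_model(clouds, TINY, LossConfig(), opt)
            assert hist[-1]["train_loss"] < hist[0]["train_loss"]
            save_checkpoint(tmp_path / "ck.npz", model, opt)
            loaded = load_checkpoint(tmp_path / "ck.npz")
            g = build_cloud_graphs(clouds[0], TINY, seed=0)
            a, _ = model.forward(g)
            b, _ = loaded.forward(g)
        assert np.allclose(a.data, b.data, atol=1e-6)

    def test_merged_batch_equals_per_cloud_forward(self):
        from stemleaf.network import merge_graphs

        clouds = self._plants(3)
        model = GGESegNet(TINY)
        gs = [build_cloud_graphs(c, TINY, seed=i) for i, c in enumerate(clouds)]
        merged = merge_graphs(gs)
        sm, em = model.forward(merged)
        per_scores = np.concatenate([model.forward(g)[0].data for g in gs])
        assert np.array_equal(sm.data, per_scores)
        assert np.array_equal(merged.labels, np.concatenate([g.labels for g in gs]))

    def test_unlabeled_or_unnormalized_rejected(self, rng):
        pts = rng.normal(size=(64, 3))
        raw = PointCloud(points=pts, semantic_labels=rng.integers(0, 2, 64))
        with pytest.raises(ValueError):
            train_model([raw], TINY, LossConfig(), OptConfig(epochs=1))
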