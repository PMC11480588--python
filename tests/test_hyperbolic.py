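"""Poincaré-ball maps, star graphs, and the HGS star-transformer encoder."""

import numpy as np
import pytest

from stemleaf.autodiff import Tensor
from stemleaf.cloud import PointCloud
from stemleaf.graph import kdtree_knn
from stemleaf.hyperbolic import (
    HGSConfig,
    HGSEncoder,
    HGSLayer,
    StarGraph,
    build_star_graph,
    expmap0,
    logmap0,
    ring_edge_masks,
)


class TestExpLogMaps:
    def test_origin_fixed_point(self):
        assert np.allclose(expmap0(np.zeros(4), c=1.0), 0.0)
        assert np.allclose(logmap0(np.zeros(4), c=1.0), 0.0)

    def test_unit_vector_maps_to_tanh(self):
        out = expmap0(np.array([1.0, 0.0, 0.0]), c=1.0)
        assert np.allclose(out, [np.tanh(1.0), 0, 0], atol=1e-12)
        back = logmap0(np.array([np.tanh(1.0), 0.0, 0.0]), c=1.0)
        assert np.allclose(back, [1.0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0])
    def test_mutually_inverse_over_random_vectors(self, rng, c):
        # moderate norms: near the boundary tanh saturates and the inverse
        # is no longer representable in floating point
        f = rng.normal(size=(1000, 8)) * rng.uniform(0.01, 1.5, size=(1000, 1))
        h = expmap0(f, c)
        assert np.all(np.sqrt(c) * np.linalg.norm(h, axis=1) < 1.0)
        back = logmap0(h, c)
        assert np.abs(back - f).max() < 1e-6

    def test_ball_containment_for_huge_norms(self, rng):
        f = rng.normal(size=(100, 3))
        f = f / np.linalg.norm(f, axis=1, keepdims=True) * 1e3
        h = expmap0(f, c=2.0)
        assert np.all(np.sqrt(2.0) * np.linalg.norm(h, axis=1) < 1.0)

    def test_norm_monotonicity(self, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        norms = np.linspace(0.1, 5.0, 20)
        out = np.array([np.linalg.norm(expmap0(n * d, c=1.0)) for n in norms])
        assert np.all(np.diff(out) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            expmap0(np.array([np.nan, 0.0]), c=1.0)
        with pytest.raises(ValueError):
            expmap0(np.zeros(2), c=-1.0)
        with pytest.raises(ValueError):
            logmap0(np.array([1.5, 0.0]), c=1.0)  # outside the ball


class TestStarGraph:
    def _graph(self, rng, n=12, k=4):
        cloud = PointCloud(points=rng.normal(size=(n, 3)))
        return kdtree_knn(cloud, K=k)

    def test_full_ring_at_probability_one(self, rng):
        g = self._graph(rng)
        star = build_star_graph(g, center=0, edge_prob=1.0, seed=0)
        assert star.ring_edge_mask.all()
        assert star.ring.size == 4
        assert np.array_equal(star.ring, g.neighbor_indices[0])

    def test_zero_probability_keeps_only_spokes(self, rng):
        g = self._graph(rng)
        star = build_star_graph(g, center=3, edge_prob=0.0, seed=0)
        assert not star.ring_edge_mask.any()

    def test_retention_frequency_matches_probability(self):
        mask = ring_edge_masks(n=1000, k=10, edge_prob=0.5, seed=42)
        assert mask.mean() == pytest.approx(0.5, abs=0.02)

    def test_invalid_ring_rejected(self):
        with pytest.raises(ValueError):
            StarGraph(planet_index=0, ring=[0, 1], ring_edge_mask=[True, True], edge_prob=1.0)
        with pytest.raises(ValueError):
            StarGraph(planet_index=5, ring=[1, 1], ring_edge_mask=[True, True], edge_prob=1.0)


def naive_hgs_layer(H, s, Wq, Wk, Wv, Wo, ln_gain, ln_bias, eps=1e-5):
    """Loop-based single-head oracle for the ring update of one layer.

    Per ring node k: context = [h_{k-1}, h_k, h_{k+1}, s]; attention
    softmax(q . k_j / sqrt(M)); ReLU then LayerNorm.
    """
    n, K, m = H.shape
    H_new = np.zeros_like(H)
    for i in range(n):
        for k in range(K):
            ctx = np.stack([H[i, (k - 1) % K], H[i, k], H[i, (k + 1) % K], s[i]])
            q = H[i, k] @ Wq
            keys = ctx @ Wk
            vals = ctx @ Wv
            scores = keys @ q / np.sqrt(m)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            att = (w[:, None] * vals).sum(axis=0) @ Wo
            r = np.maximum(att, 0.0)
            H_new[i, k] = ln_gain * (r - r.mean()) / np.sqrt(r.var() + eps) + ln_bias
    return H_new


class TestHGSLayer:
    def _layer_and_inputs(self, rng, n=3, k=3, m=4, heads=1):
        layer = HGSLayer(m, heads, np.random.default_rng(3))
        H = Tensor(rng.normal(size=(n, k, m)))
        s = Tensor(rng.normal(size=(n, m)))
        mask = np.ones((n, k), dtype=bool)
        return layer, H, s, mask

    def test_ring_update_matches_single_head_oracle(self, rng):
        layer, H, s, mask = self._layer_and_inputs(rng)
        H_new, _ = layer(H, s, mask)
        att = layer.ring_att
        expected = naive_hgs_layer(
            H.data,
            s.data,
            att.Wq.W.data,  # bias is zero at init
            att.Wk.W.data,
            att.Wv.W.data,
            att.Wo.W.data,
            layer.ring_ln.gain.data,
            layer.ring_ln.bias.data,
        )
        assert np.allclose(H_new.data, expected, atol=1e-6)

    def test_zero_embeddings_stay_finite_and_deterministic(self):
        layer, _, _, _ = self._layer_and_inputs(np.random.default_rng(0))
        H = Tensor(np.zeros((2, 3, 4)))
        s = Tensor(np.zeros((2, 4)))
        mask = np.ones((2, 3), dtype=bool)
        a_H, a_s = layer(H, s, mask)
        b_H, b_s = layer(H, s, mask)
        assert np.isfinite(a_H.data).all() and np.isfinite(a_s.data).all()
        assert np.array_equal(a_H.data, b_H.data)
        assert np.array_equal(a_s.data, b_s.data)

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_planet_invariant_to_cyclic_ring_shift(self, rng, k):
        layer, _, _, _ = self._layer_and_inputs(rng, m=8, heads=2)
        H = Tensor(rng.normal(size=(2, k, 8)))
        s = Tensor(rng.normal(size=(2, 8)))
        mask = np.ones((2, k), dtype=bool)
        _, s_ref = layer(H, s, mask)
        for shift in range(1, k):
            Hs = Tensor(np.roll(H.data, shift, axis=1))
            _, s_shift = layer(Hs, s, mask)
            assert np.allclose(s_ref.data, s_shift.data, atol=1e-6)


class TestHGSEncoder:
    def _encode(self, rng, cfg, features=None, n=16, k=5, in_dim=3):
        enc = HGSEncoder(in_dim, 8, cfg, np.random.default_rng(1))
        cloud = PointCloud(points=rng.normal(size=(n, 3)))
        graph = kdtree_knn(cloud, K=k)
        feats = Tensor(rng.normal(size=(n, in_dim)) if features is None else features)
        mask = np.ones((n, k), dtype=bool)
        return enc, enc(feats, graph.neighbor_indices, mask), feats, graph, mask

    def test_lambda_zero_returns_planet_projection(self, rng):
        cfg = HGSConfig(layers=2, heads=2, lam=0.0)
        enc, out, feats, graph, mask = self._encode(rng, cfg)
        from stemleaf.hyperbolic import ball_project_t, expmap0_t, logmap0_t

        fh = expmap0_t(enc.lift(feats), cfg.curvature)
        expected = logmap0_t(ball_project_t(fh, cfg.curvature), cfg.curvature)
        assert np.allclose(out.data, expected.data, atol=1e-9)

    def test_residual_linear_in_lambda(self, rng):
        # small features and lambdas so the residual stays inside the ball
        # and the boundary projection never engages
        pts = rng.normal(size=(16, 3)) * 0.05
        outs = {}
        for lam in (0.0, 0.01, 0.02):
            cfg = HGSConfig(layers=1, heads=2, lam=lam)
            enc = HGSEncoder(3, 8, cfg, np.random.default_rng(1))
            cloud = PointCloud(points=pts)
            graph = kdtree_knn(cloud, K=5)
            feats = Tensor(pts)
            mask = np.ones((16, 5), dtype=bool)
            outs[lam] = enc(feats, graph.neighbor_indices, mask).data
        # the residual adds lam * s^L on the ball-side feature, so mapping
        # the outputs back onto the ball makes the lambda-linearity exact
        ball = {lam: expmap0(o, 1.0) for lam, o in outs.items()}
        assert np.linalg.norm(ball[0.02], axis=1).max() < 0.99  # no clipping
        d1 = ball[0.01] - ball[0.0]
        d2 = ball[0.02] - ball[0.0]
        assert np.allclose(d2, 2 * d1, rtol=1e-5, atol=1e-8)

    def test_bit_reproducible_with_full_ring(self, rng):
        cfg = HGSConfig(layers=2, heads=2, lam=1.0)
        _, out1, *_ = self._encode(rng, cfg, n=16)
        rng2 = np.random.default_rng(12345)
        _, out2, *_ = self._encode(rng2, cfg, n=16)
        assert np.array_equal(out1.data, out2.data)

    def test_output_finite_even_when_residual_leaves_ball(self, rng):
        cfg = HGSConfig(layers=2, heads=2, lam=100.0)
        _, out, *_ = self._encode(rng, cfg)
        assert np.isfinite(out.data).all()
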