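"""Encoder contracts: shapes, equivariance, reparameterization, GRL wiring."""

import numpy as np
import pytest

from gmdecon import GMGCN, ModelConfig, SpotGraph, mutual_knn
from gmdecon import autodiff as ad
from gmdecon import losses as L


def make_graph(rng, n=12, g=10, domain=0, dtype=np.float64):
    X = rng.standard_normal((n, g)).astype(dtype)
    A = mutual_knn(rng.standard_normal((n, 2)), 3)
    return SpotGraph(X=X, A=A, domain=domain, node_ids=[f"n{i}" for i in range(n)])


def small_cfg(**kw):
    defaults = dict(n_genes=10, n_types=4, n_components=3, hidden=16, embed=8,
                    head_hidden=8, disc_hidden=8, dtype="float64", seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def test_encode_shapes_and_responsibility_simplex():
    rng = np.random.default_rng(0)
    model = GMGCN(small_cfg())
    lat = model.encode(make_graph(rng))
    assert lat.mu.shape == (12, 3, 8)
    assert lat.logvar.shape == (12, 3, 8)
    assert lat.resp.shape == (12, 3)
    assert np.allclose(lat.resp.data.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(lat.sigma.data > 0)
    assert np.all(np.abs(lat.logvar.data) <= 10.0)


def test_feature_width_mismatch_rejected():
    rng = np.random.default_rng(1)
    model = GMGCN(small_cfg())
    with pytest.raises(ValueError, match="width"):
        model.encode(make_graph(rng, g=7))


def test_isolated_single_node_graph_is_finite():
    model = GMGCN(small_cfg())
    g = SpotGraph(X=np.ones((1, 10)), A=np.zeros((1, 1)), domain=1, node_ids=["solo"])
    out = model.forward(g, training=False)
    assert np.all(np.isfinite(out["Z"].data))
    assert abs(out["proportions"].data.sum() - 1.0) < 1e-6


def test_forward_is_permutation_equivariant():
    rng = np.random.default_rng(2)
    model = GMGCN(small_cfg())
    g = make_graph(rng, n=9)
    perm = rng.permutation(9)
    g_perm = SpotGraph(X=g.X[perm], A=g.A[np.ix_(perm, perm)], domain=g.domain,
                       node_ids=[g.node_ids[i] for i in perm])
    out = model.forward(g, training=False)["proportions"].data
    out_perm = model.forward(g_perm, training=False)["proportions"].data
    assert np.allclose(out[perm], out_perm, atol=1e-10)


class TestReparameterize:
    def test_zero_sigma_returns_weighted_means(self):
        rng = np.random.default_rng(3)
        model = GMGCN(small_cfg())
        lat = model.encode(make_graph(rng))
        lat.logvar.data[:] = -745.0  # exp(0.5 * logvar) underflows to exactly 0
        z = model.reparameterize(lat, rng=np.random.default_rng(0), training=True)
        expected = np.einsum("nk,nke->ne", lat.resp.data, lat.mu.data)
        assert np.allclose(z.data, expected, atol=1e-12)

    def test_fixed_seed_reproduces_z(self):
        rng = np.random.default_rng(4)
        model = GMGCN(small_cfg())
        lat = model.encode(make_graph(rng))
        z1 = model.reparameterize(lat, rng=np.random.default_rng(11), training=True)
        z2 = model.reparameterize(lat, rng=np.random.default_rng(11), training=True)
        assert np.array_equal(z1.data, z2.data)

    def test_single_component_matches_scalar_loop(self):
        rng = np.random.default_rng(5)
        model = GMGCN(small_cfg(n_components=1))
        lat = model.encode(make_graph(rng))
        eps_rng = np.random.default_rng(12)
        z = model.reparameterize(lat, rng=eps_rng, training=True)
        eps = np.random.default_rng(12).standard_normal(lat.mu.shape)
        n, _, e = lat.mu.shape
        for i in range(n):
            for d in range(e):
                expect = lat.mu.data[i, 0, d] + lat.sigma.data[i, 0, d] * eps[i, 0, d]
                assert abs(z.data[i, d] - expect) < 1e-9

    def test_inference_mode_ignores_noise(self):
        rng = np.random.default_rng(6)
        model = GMGCN(small_cfg())
        lat = model.encode(make_graph(rng))
        z1 = model.reparameterize(lat, rng=np.random.default_rng(1), training=False)
        z2 = model.reparameterize(lat, rng=np.random.default_rng(2), training=False)
        assert np.array_equal(z1.data, z2.data)


class TestHeads:
    def test_proportions_on_simplex(self):
        rng = np.random.default_rng(7)
        model = GMGCN(small_cfg())
        Z = ad.constant(rng.standard_normal((20, 8)))
        p = model.predict_proportions(Z).data
        assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_head_weights_give_uniform_rows(self):
        import gmdecon.autodiff as ad
        model = GMGCN(small_cfg())
        for k in ("W_h1", "b_h1", "W_h2", "b_h2"):
            model.params[k].data[:] = 0.0
        p = model.predict_proportions(ad.constant(np.ones((5, 8)))).data
        assert np.allclose(p, 0.25)

    def test_proportion_logits_match_matrix_loop(self):
        import gmdecon.autodiff as ad
        rng = np.random.default_rng(8)
        model = GMGCN(small_cfg())
        Z = rng.standard_normal((6, 8))
        p = model.predict_proportions(ad.constant(Z)).data
        W1, b1 = model.params["W_h1"].data, model.params["b_h1"].data
        W2, b2 = model.params["W_h2"].data, model.params["b_h2"].data
        for i in range(6):
            h = Z[i] @ W1 + b1
            h = np.where(h > 0, h, np.exp(h) - 1.0)
            logits = h @ W2 + b2
            e = np.exp(logits - logits.max())
            assert np.allclose(p[i], e / e.sum(), atol=1e-6)

    def test_discriminator_output_strictly_in_unit_interval(self):
        import gmdecon.autodiff as ad
        rng = np.random.default_rng(9)
        model = GMGCN(small_cfg())
        d = model.discriminate_domain(ad.constant(rng.standard_normal((10, 8)))).data
        assert np.all((d > 0) & (d < 1))


class TestGradientReversal:
    def _encoder_grads_from_domain_loss(self, alpha):
        rng = np.random.default_rng(10)
        model = GMGCN(small_cfg())
        g = make_graph(np.random.default_rng(20), domain=0)
        lat = model.encode(g)
        Z = model.reparameterize(lat, rng=np.random.default_rng(0), training=True)
        pred = model.discriminate_domain(Z, alpha=alpha)
        loss = L.domain_ce_loss(pred, np.zeros(g.n))
        model.zero_grad()
        loss.backward()
        return {k: (model.params[k].grad.copy() if model.params[k].grad is not None
                    else np.zeros_like(model.params[k].data))
                for k in GMGCN.ENCODER_KEYS}

    def test_alpha_zero_gives_zero_encoder_gradient(self):
        grads = self._encoder_grads_from_domain_loss(0.0)
        assert all(np.allclose(v, 0.0) for v in grads.values())

    def test_reversal_flips_every_gradient_component(self):
        plus = self._encoder_grads_from_domain_loss(1.0)
        # alpha = -1 undoes the reversal: the "reversal-disabled" reference run
        minus = self._encoder_grads_from_domain_loss(-1.0)
        for k in plus:
            assert np.allclose(plus[k], -minus[k], atol=1e-12)
            nz = np.abs(minus[k]) > 1e-12
            if nz.any():
                assert np.all(np.sign(plus[k][nz]) == -np.sign(minus[k][nz]))


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(13)
    model = GMGCN(small_cfg())
    g = make_graph(rng)
    before = model.forward(g, training=False)["proportions"].data
    model.save(tmp_path / "ckpt.npz")
    loaded = GMGCN.load(tmp_path / "ckpt.npz")
    after = loaded.forward(g, training=False)["proportions"].data
    assert np.array_equal(before, after)
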