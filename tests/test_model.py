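"""Dual-branch network: isomorphic layers, fusion, pooling, head, training."""

import numpy as np
import pytest

from specgin import (
    DualBranchGraphClassifier,
    DualBranchGraphRegressor,
    DualBranchModel,
    GINLayer,
    classification_loss,
    count_parameters,
    fuse_layers,
    global_mean_pool,
    smiles_to_graph,
)
from specgin.autodiff import Tensor
from specgin.spectral import graph_scaled_laplacian


def _identity_gin(dim, rng):
    layer = GINLayer(dim, dim, rng, batch_norm=False)
    layer.link.weight.data = np.eye(dim)
    layer.link.bias.data = np.zeros(dim)
    return layer


class TestIsoLayer:
    def test_isolated_node_returns_own_features(self, rng):
        layer = _identity_gin(3, rng)
        x = np.array([[1.0, -2.0, 3.0]])
        out = layer(Tensor(x), np.zeros((1, 1)), activate=False)
        np.testing.assert_allclose(out.data, x)

    def test_sum_aggregation_separates_multisets(self, rng):
        """{a, a} vs {a} neighbourhoods differ under sum but not mean."""
        layer = _identity_gin(2, rng)
        a = np.array([2.0, -1.0])
        self_feat = np.array([1.0, 1.0])
        # star: centre 0 with two identical neighbours
        x_star = np.stack([self_feat, a, a])
        adj_star = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        # pair: centre 0 with one such neighbour
        x_pair = np.stack([self_feat, a])
        adj_pair = np.array([[0, 1], [1, 0]], dtype=float)
        out_star = layer(Tensor(x_star), adj_star, activate=False).data[0]
        out_pair = layer(Tensor(x_pair), adj_pair, activate=False).data[0]
        np.testing.assert_allclose(out_star, self_feat + 2 * a)
        np.testing.assert_allclose(out_pair, self_feat + a)
        assert not np.allclose(out_star, out_pair)

    def test_permutation_equivariance(self, rng):
        layer = GINLayer(4, 6, rng)
        layer.eval()
        n = 5
        x = rng.standard_normal((n, 4))
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        out = layer(Tensor(x), a).data
        perm = rng.permutation(n)
        p = np.eye(n)[perm]
        out_p = layer(Tensor(p @ x), p @ a @ p.T).data
        np.testing.assert_allclose(out_p, p @ out, atol=1e-8)


class TestFusionAndPooling:
    def test_zero_iso_leaves_spectral(self, rng):
        s = rng.standard_normal((4, 8))
        np.testing.assert_array_equal(fuse_layers(s, np.zeros_like(s)), s)

    def test_fusion_commutes(self, rng):
        a, b = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        np.testing.assert_array_equal(fuse_layers(a, b), fuse_layers(b, a))

    def test_fusion_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_layers(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_pool_single_node(self):
        x = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(global_mean_pool(x), x[0])

    def test_pool_opposite_nodes_cancel(self):
        v = np.array([1.0, -2.0])
        np.testing.assert_allclose(global_mean_pool(np.stack([v, -v])), 0.0)

    def test_pool_permutation_invariant(self, rng):
        x = rng.standard_normal((6, 5))
        np.testing.assert_allclose(
            global_mean_pool(x), global_mean_pool(x[rng.permutation(6)])
        )

    def test_pool_empty_rejected(self):
        with pytest.raises(ValueError):
            global_mean_pool(np.zeros((0, 4)))


class TestHeadAndLoss:
    def test_zero_logits_give_half(self, rng):
        model = DualBranchModel(rng, n_tasks=3)
        model.eval()
        model.out.weight.data[:] = 0.0
        model.out.bias.data[:] = 0.0
        probs = model.predict_from_embedding(Tensor(rng.standard_normal((2, 512))))
        np.testing.assert_allclose(probs.data, 0.5)

    def test_probabilities_in_open_interval(self, rng):
        model = DualBranchModel(rng, n_tasks=2)
        model.eval()
        probs = model.predict_from_embedding(
            Tensor(rng.standard_normal((4, 512)) * 5)
        ).data
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_regression_head_unbounded(self, rng):
        model = DualBranchModel(rng, n_tasks=1, task_mode="regression")
        model.eval()
        emb = Tensor(rng.standard_normal((8, 512)) * 10)
        vals = model.predict_from_embedding(emb).data
        assert vals.min() < 0 or vals.max() > 1  # not squashed

    def test_loss_values(self):
        assert classification_loss([[1 - 1e-9]], [[1.0]]) == pytest.approx(0, abs=1e-6)
        assert classification_loss([[0.5]], [[1.0]]) == pytest.approx(np.log(2))

    def test_missing_labels_masked(self):
        probs = [[0.5, 0.9], [0.5, 0.1]]
        full = classification_loss([[0.5], [0.5]], [[1.0], [0.0]])
        masked = classification_loss(probs, [[1.0, np.nan], [0.0, np.nan]])
        assert masked == pytest.approx(full)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            classification_loss([[0.5]], [[np.nan]])


class TestParameterBudget:
    def test_first_spectral_layer_count(self, rng):
        model = DualBranchModel(rng, n_tasks=1)
        layer = model.spec1
        assert layer.theta.size + layer.bias.size == 3 * 56 * 128 + 128 == 21_632

    def test_under_one_million_for_all_k(self, rng):
        for k in (1, 2, 12):
            model = DualBranchModel(rng, n_tasks=k)
            assert count_parameters(model) < 1_000_000

    def test_width_doubling_quadruples_weights(self, rng):
        from specgin.nn import ChebConv

        small = ChebConv(8, 16, rng).theta.size
        large = ChebConv(16, 32, rng).theta.size
        assert large == 4 * small


@pytest.fixture(scope="module")
def tiny_task():
    smiles = ["CCO", "CCCO", "CCN", "CCCC", "CCOC",
              "c1ccccc1", "c1ccncc1", "C1CCCCC1", "Cc1ccccc1", "C1CCOC1"]
    graphs = [smiles_to_graph(s) for s in smiles]
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
    return graphs, y


class TestEndToEnd:
    def test_fit_is_deterministic(self, tiny_task):
        graphs, y = tiny_task
        kw = dict(epochs=2, random_state=3, validation_fraction=0.0)
        m1 = DualBranchGraphClassifier(**kw).fit(graphs, y)
        m2 = DualBranchGraphClassifier(**kw).fit(graphs, y)
        for (n1, w1), (n2, w2) in zip(
            sorted(m1.model_.state_dict().items()),
            sorted(m2.model_.state_dict().items()),
        ):
            assert n1 == n2
            np.testing.assert_array_equal(w1, w2)

    def test_overfits_tiny_dataset(self, tiny_task):
        graphs, y = tiny_task
        est = DualBranchGraphClassifier(
            epochs=300, random_state=0, validation_fraction=0.0
        ).fit(graphs, y)
        assert est.loss_trace_[-1]["train_loss"] < 0.05

    def test_prediction_invariant_to_node_order(self, rng):
        model = DualBranchModel(np.random.default_rng(5), n_tasks=2)
        model.eval()
        g = smiles_to_graph("CC(=O)Nc1ccc(O)cc1")
        lap = graph_scaled_laplacian(g)
        emb = model.graph_embedding(g.node_features, lap, g.adjacency()).data
        perm = rng.permutation(g.n_nodes)
        gp = g.permute(perm)
        lap_p = graph_scaled_laplacian(gp)
        emb_p = model.graph_embedding(gp.node_features, lap_p, gp.adjacency()).data
        np.testing.assert_allclose(emb, emb_p, atol=1e-5)

    def test_zeroed_iso_branch_reduces_to_spectral_path(self):
        model = DualBranchModel(np.random.default_rng(2), n_tasks=1)
        model.eval()
        for i in (1, 2, 3):
            layer = getattr(model, f"iso{i}")
            layer.link.weight.data[:] = 0.0
            layer.link.bias.data[:] = 0.0
            layer.bn.beta.data[:] = 0.0
        g = smiles_to_graph("CCOc1ccccc1")
        lap = graph_scaled_laplacian(g)
        fused = model.node_embeddings(g.node_features, lap, g.adjacency()).data
        spectral_only = model.spectral_embedding(g)
        np.testing.assert_allclose(fused, spectral_only, atol=1e-10)

    def test_backbone_transfer_shape_mismatch_reported(self):
        from specgin.spectral import ChebEncoder

        model = DualBranchModel(np.random.default_rng(0), n_tasks=1)
        bad = ChebEncoder(np.random.default_rng(0), dims=(56, 64, 128, 256))
        with pytest.raises(ValueError, match="layer 1"):
            model.load_backbone(bad)

    def test_regressor_predicts_reals(self, tiny_task):
        graphs, y = tiny_task
        est = DualBranchGraphRegressor(
            epochs=2, random_state=0, validation_fraction=0.0
        ).fit(graphs, y * 3.7 - 1.2)
        preds = est.predict(graphs)
        assert preds.shape == (10,)
        assert np.all(np.isfinite(preds))
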