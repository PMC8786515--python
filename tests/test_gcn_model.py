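import numpy as np
import pytest

from graphdbp.gcn_model import (
    ModelConfig,
    _forward_cache,
    backward,
    forward,
    gcn_layer_forward,
    init_params,
    load_checkpoint,
    normalize_adjacency,
    pool_graph,
    predict,
    save_checkpoint,
)
from graphdbp.graph_build import AdjacencyMatrix, ProteinGraph

from conftest import random_graph


def naive_normalized_adjacency(a):
    """Straight-line dense oracle: explicit D_hat^{-1/2}(A+I)D_hat^{-1/2}."""
    m = a.shape[0]
    a_hat = a.astype(float) + np.eye(m)
    d = np.diag(a_hat.sum(axis=1))
    d_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(d)))
    return d_inv_sqrt @ a_hat @ d_inv_sqrt


def naive_matmul(a, b):
    out = np.zeros((a.shape[0], b.shape[1]))
    for i in range(a.shape[0]):
        for j in range(b.shape[1]):
            for k in range(a.shape[1]):
                out[i, j] += a[i, k] * b[k, j]
    return out


def naive_conv_stack(graph, params, activation="relu"):
    """Triple-nested-loop re-implementation of the propagation stack."""
    n_adj = naive_normalized_adjacency(graph.adjacency.values)
    h = graph.features
    for w in params.conv_W:
        z = naive_matmul(naive_matmul(n_adj, h), w)
        h = np.maximum(z, 0.0) if activation == "relu" else z
    return h


class TestNormalizeAdjacency:
    def test_edgeless_graph_gives_identity(self):
        adj = AdjacencyMatrix(values=np.zeros((4, 4), dtype=int))
        assert np.allclose(normalize_adjacency(adj), np.eye(4))

    def test_two_nodes_one_edge_all_entries_half(self):
        adj = AdjacencyMatrix(values=np.array([[0, 1], [1, 0]]))
        assert np.allclose(normalize_adjacency(adj), 0.5 * np.ones((2, 2)))

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            g = random_graph(rng, int(rng.integers(2, 11)))
            n = normalize_adjacency(g.adjacency)
            assert np.allclose(n, naive_normalized_adjacency(g.adjacency.values),
                               atol=1e-12)
            assert np.allclose(n, n.T)
            # symmetric normalization bounds the spectrum, not the row sums
            eigs = np.linalg.eigvalsh(n)
            assert eigs.max() <= 1 + 1e-12
            assert (n >= 0).all()


class TestLayerForward:
    def test_edgeless_identity_weight_is_identity_map(self):
        adj = AdjacencyMatrix(values=np.zeros((3, 3), dtype=int))
        n = normalize_adjacency(adj)
        H = np.random.default_rng(0).standard_normal((3, 5))
        out = gcn_layer_forward(H, n, np.eye(5), activation="identity")
        assert np.allclose(out, H)

    def test_two_node_path_hand_example(self):
        adj = AdjacencyMatrix(values=np.array([[0, 1], [1, 0]]))
        n = normalize_adjacency(adj)
        out = gcn_layer_forward(np.eye(2), n, np.eye(2), activation="identity")
        assert np.allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_shape_mismatch_errors(self):
        adj = AdjacencyMatrix(values=np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            gcn_layer_forward(np.zeros((2, 3)), normalize_adjacency(adj),
                              np.zeros((4, 4)))


class TestPooling:
    def test_single_node_returns_its_row(self):
        H = np.array([[1.0, 2.0, 3.0]])
        for p in ("mean", "sum", "max"):
            assert np.allclose(pool_graph(H, p), [1, 2, 3])

    def test_mean_of_identical_rows(self):
        H = np.tile([1.0, -2.0], (4, 1))
        assert np.allclose(pool_graph(H, "mean"), [1, -2])

    def test_sum_is_m_times_mean(self):
        H = np.random.default_rng(1).standard_normal((7, 4))
        assert np.allclose(pool_graph(H, "sum"), 7 * pool_graph(H, "mean"))


class TestForward:
    def test_output_is_probability(self, default_model):
        config, params = default_model
        rng = np.random.default_rng(2)
        for _ in range(5):
            g = random_graph(rng, int(rng.integers(2, 15)))
            p = forward(g, params, config)
            assert 0.0 <= p <= 1.0

    def test_conv_stack_output_width_216(self, default_model):
        config, params = default_model
        g = random_graph(np.random.default_rng(3), 8)
        cache = _forward_cache(g, params, config)
        assert cache["H_last"].shape == (8, 216)

    def test_feature_width_mismatch_errors(self, default_model):
        config, params = default_model
        g = random_graph(np.random.default_rng(4), 5, n_features=20)
        with pytest.raises(ValueError):
            forward(g, params, config)

    def test_permutation_invariance(self, default_model):
        config, params = default_model
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_graph(rng, int(rng.integers(3, 12)))
            perm = rng.permutation(g.n_nodes)
            gp = ProteinGraph(
                id=g.id, features=g.features[perm],
                adjacency=AdjacencyMatrix(values=g.adjacency.values[np.ix_(perm, perm)]),
            )
            assert forward(gp, params, config) == pytest.approx(
                forward(g, params, config), abs=1e-9
            )

    def test_inference_is_deterministic_bitwise(self, default_model):
        config, params = default_model
        g = random_graph(np.random.default_rng(6), 10)
        assert forward(g, params, config) == forward(g, params, config)

    def test_conv_stack_matches_naive_dense_oracle(self):
        config = ModelConfig(use_bias=False)
        params = init_params(config, seed=77)
        rng = np.random.default_rng(7)
        for _ in range(5):
            g = random_graph(rng, int(rng.integers(2, 11)))
            cache = _forward_cache(g, params, config)
            assert np.allclose(cache["H_last"], naive_conv_stack(g, params),
                               atol=1e-10)

    def test_edgeless_graph_reduces_to_per_node_feedforward(self):
        # With A = 0 the normalized adjacency is I, so the conv stack is a
        # plain per-node MLP: rows can be computed independently.
        config = ModelConfig(use_bias=False)
        params = init_params(config, seed=8)
        rng = np.random.default_rng(8)
        feats = rng.standard_normal((4, 54))
        g = ProteinGraph(id="g", features=feats,
                         adjacency=AdjacencyMatrix(values=np.zeros((4, 4), dtype=int)))
        cache = _forward_cache(g, params, config)
        for m in range(4):
            h = feats[m:m + 1]
            for w in params.conv_W:
                h = np.maximum(h @ w, 0.0)
            assert np.allclose(cache["H_last"][m], h[0], atol=1e-12)


class TestPredict:
    @pytest.mark.parametrize("prob,expected", [(0.7, 1), (0.5, 1), (0.49, 0)])
    def test_decision_rule(self, prob, expected):
        assert predict(prob) == expected


class TestBackward:
    def test_gradients_match_finite_differences(self):
        # tanh keeps everything differentiable; small dims keep it exact.
        config = ModelConfig(conv_dims=((54, 6), (6, 8), (8, 10)),
                             fc_dims=(10, 5, 2), dropout=0.0, activation="tanh")
        params = init_params(config, seed=31)
        g = random_graph(np.random.default_rng(32), 5, label=1)

        def loss_fn():
            cache = _forward_cache(g, params, config)
            return -np.log(cache["probs"][1])

        cache = _forward_cache(g, params, config)
        _, grads = backward(cache, 1, params, config)
        eps = 1e-6
        rng = np.random.default_rng(33)
        for p_arr, g_arr in zip(params.flat(), grads.flat()):
            flat_p, flat_g = p_arr.ravel(), g_arr.ravel()
            for idx in rng.choice(flat_p.size, size=min(5, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss_fn()
                flat_p[idx] = orig - eps
                down = loss_fn()
                flat_p[idx] = orig
                assert (up - down) / (2 * eps) == pytest.approx(flat_g[idx], abs=1e-5)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, default_model):
        config, params = default_model
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, config)
        params2, config2 = load_checkpoint(path)
        assert config2 == config
        g = random_graph(np.random.default_rng(40), 9)
        assert forward(g, params2, config2) == forward(g, params, config)
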