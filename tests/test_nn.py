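"""Graph regressor: attention semantics, oracle equivalence, invariances."""

import numpy as np
import pytest

from brainage.autodiff import Tensor
from brainage.graphs import build_graph, stack_graphs
from brainage.nn import (
    BatchNorm1d,
    BrainAgeGNN,
    LayerNorm,
    ModelConfig,
    TransformerConv,
    load_checkpoint,
    save_checkpoint,
)
from conftest import make_random_fc
from _oracles import forward_loop, transformer_conv_loop


def small_graph(R=5, seed=0, threshold=0.0):
    fc = make_random_fc(R, seed=seed)
    return build_graph(fc, threshold=threshold, age=70.0)


def conv_inputs(graph):
    X, E, mask, _ = stack_graphs([graph])
    return Tensor(X), Tensor(E), mask


class TestTransformerConv:
    @pytest.mark.parametrize("heads,R", [(1, 4), (2, 5), (4, 6)])
    def test_matches_straight_loop_oracle(self, heads, R):
        g = small_graph(R=R, seed=R, threshold=0.3)
        conv = TransformerConv(R, 3, heads, np.random.default_rng(7))
        x, e, mask = conv_inputs(g)
        vec = conv(x, e, mask).data[0]
        loop = transformer_conv_loop(
            g.vertex_features, g.edges.tolist(), g.edge_features, conv
        )
        assert np.allclose(vec, loop, atol=1e-10)

    def test_attention_rows_sum_to_one(self):
        g = small_graph(R=6, seed=2, threshold=0.2)
        conv = TransformerConv(6, 4, 2, np.random.default_rng(0))
        x, e, mask = conv_inputs(g)
        alpha = conv.attention(x, e, mask)
        degree = mask.sum(axis=-1)
        sums = alpha.sum(axis=-1)  # (1, H, R)
        for h in range(2):
            connected = degree[0] > 0
            assert np.allclose(sums[0, h][connected], 1.0, atol=1e-6)
            assert np.allclose(sums[0, h][~connected], 0.0)

    def test_single_neighbor_gets_full_attention(self):
        # path graph 0-1 only: vertex 0 has exactly one in-neighbor
        import brainage.connectivity as conn

        mat = np.eye(3)
        mat[0, 1] = mat[1, 0] = 0.9
        g = build_graph(conn.ConnectivityMatrix("s", mat), threshold=0.5, age=70.0)
        conv = TransformerConv(3, 4, 1, np.random.default_rng(3))
        x, e, mask = conv_inputs(g)
        alpha = conv.attention(x, e, mask)
        assert alpha[0, 0, 0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_identical_neighbors_split_attention_evenly(self):
        # vertex 0 sees vertices 1 and 2 with identical features and edges
        X = np.zeros((1, 3, 3))
        X[0, 0] = [1.0, 0.5, 0.5]
        X[0, 1] = [0.2, 0.7, 0.1]
        X[0, 2] = [0.2, 0.7, 0.1]
        E = np.zeros((1, 3, 3))
        E[0, 0, 1] = E[0, 0, 2] = 0.4
        mask = np.zeros((1, 3, 3))
        mask[0, 0, 1] = mask[0, 0, 2] = 1.0
        conv = TransformerConv(3, 4, 1, np.random.default_rng(4))
        alpha = conv.attention(Tensor(X), Tensor(E), mask)
        assert alpha[0, 0, 0, 1] == pytest.approx(0.5, abs=1e-12)
        assert alpha[0, 0, 0, 2] == pytest.approx(0.5, abs=1e-12)

    def test_isolated_vertex_gets_skip_only(self):
        import brainage.connectivity as conn
        import warnings

        mat = np.eye(3)
        mat[0, 1] = mat[1, 0] = 0.9
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = build_graph(conn.ConnectivityMatrix("s", mat), threshold=0.5, age=70.0)
        conv = TransformerConv(3, 4, 1, np.random.default_rng(5))
        x, e, mask = conv_inputs(g)
        out = conv(x, e, mask).data[0]
        skip = g.vertex_features[2] @ conv.w_root.data + conv.b_root.data
        assert np.allclose(out[2], skip, atol=1e-12)


class TestNormalizationLayers:
    def test_layer_norm_centers_and_scales(self):
        ln = LayerNorm(8)
        x = Tensor(np.random.default_rng(0).normal(2.0, 3.0, size=(4, 8)))
        y = ln(x).data  # gain 1, bias 0 at init
        assert np.allclose(y.mean(axis=-1), 0.0, atol=1e-10)
        # variance is v/(v+eps): unity up to the epsilon guard
        assert np.allclose(y.var(axis=-1), 1.0, atol=1e-4)

    def test_layer_norm_constant_vector_stays_finite(self):
        ln = LayerNorm(4)
        y = ln(Tensor(np.full((1, 4), 3.0))).data
        assert np.all(np.isfinite(y))
        assert np.allclose(y, 0.0)

    def test_leaky_relu_piecewise(self):
        x = np.array([-2.0, -0.5, 0.0, 0.5, 2.0])
        y = Tensor(x).leaky_relu(0.01).data
        assert np.allclose(y, np.where(x >= 0, x, 0.01 * x))

    def test_batchnorm_train_vs_eval(self):
        bn = BatchNorm1d(3, momentum=1.0)
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 2.0, size=(64, 3))
        bn._training = True
        y = bn(Tensor(x)).data
        assert np.allclose(y.mean(axis=0), 0.0, atol=1e-10)
        bn._training = False
        y2 = bn(Tensor(x)).data  # running stats just set from this batch
        assert np.allclose(y2.mean(axis=0), 0.0, atol=1e-2)


class TestModelForward:
    def test_matches_straight_loop_forward(self):
        for R in (4, 6):
            cfg = ModelConfig(in_dim=R, hidden_dim=3, n_conv_layers=2, n_heads=2, seed=R)
            model = BrainAgeGNN(cfg)
            model.bn.running_mean = np.random.default_rng(1).normal(size=cfg.mlp_hidden)
            model.bn.running_var = np.random.default_rng(2).uniform(0.5, 2.0, cfg.mlp_hidden)
            model.out_loc, model.out_scale = 70.0, 10.0
            model.eval()
            g = small_graph(R=R, seed=R + 10, threshold=0.2)
            X, E, mask, _ = stack_graphs([g])
            pred = model.predict(X, E, mask)[0]
            oracle = forward_loop(model, g.vertex_features, g.edges.tolist(), g.edge_features)
            assert pred == pytest.approx(oracle, abs=1e-8)

    def test_prediction_finite_and_scalar(self):
        cfg = ModelConfig(in_dim=7, hidden_dim=4, seed=0)
        model = BrainAgeGNN(cfg)
        g = small_graph(R=7, seed=1)
        X, E, mask, _ = stack_graphs([g])
        out = model.predict(X, E, mask)
        assert out.shape == (1,)
        assert np.isfinite(out[0])

    def test_isomorphic_graphs_same_prediction(self):
        R = 8
        cfg = ModelConfig(in_dim=R, hidden_dim=4, n_heads=2, seed=3)
        model = BrainAgeGNN(cfg)
        fc = make_random_fc(R, seed=5)
        g = build_graph(fc, 0.0, 70.0)
        X, E, mask, _ = stack_graphs([g])
        p0 = model.predict(X, E, mask)[0]

        # relabel vertices: rows (vertices) permute, each vertex keeps its
        # feature vector as an opaque attribute; edges follow the relabeling
        perm = np.random.default_rng(0).permutation(R)
        Xp = X[:, perm, :]
        Ep = E[:, perm][:, :, perm]
        maskp = mask[:, perm][:, :, perm]
        p1 = model.predict(Xp, Ep, maskp)[0]
        assert p0 == pytest.approx(p1, abs=1e-6)

    def test_edge_order_irrelevant(self):
        g = small_graph(R=6, seed=9, threshold=0.1)
        cfg = ModelConfig(in_dim=6, hidden_dim=4, seed=1)
        model = BrainAgeGNN(cfg)
        X, E, mask, _ = stack_graphs([g])
        p0 = model.predict(X, E, mask)[0]
        rng = np.random.default_rng(0)
        order = rng.permutation(len(g.edges))
        g.edges = g.edges[order]
        g.edge_features = g.edge_features[order]
        X2, E2, mask2, _ = stack_graphs([g])
        assert model.predict(X2, E2, mask2)[0] == pytest.approx(p0, abs=1e-12)

    def test_zeroed_model_outputs_final_bias(self):
        cfg = ModelConfig(in_dim=5, hidden_dim=4, seed=0)
        model = BrainAgeGNN(cfg)
        for p in model.parameters():
            p.data = np.zeros_like(p.data)
        model.fc2.bias.data[:] = 42.0
        for seed in range(3):
            g = small_graph(R=5, seed=seed)
            X, E, mask, _ = stack_graphs([g])
            assert model.predict(X, E, mask)[0] == pytest.approx(42.0, abs=1e-12)

    def test_config_grid_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(n_conv_layers=5).validate()
        with pytest.raises(ValueError):
            ModelConfig(n_heads=3).validate()
        for L in (1, 2, 3, 4):
            for H in (1, 2, 4, 8):
                cfg = ModelConfig(in_dim=4, hidden_dim=2, n_conv_layers=L, n_heads=H)
                cfg.validate()
        # default depth is the two-block architecture
        assert ModelConfig().n_conv_layers == 2

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = ModelConfig(in_dim=6, hidden_dim=4, n_heads=2, seed=8)
        model = BrainAgeGNN(cfg)
        model.out_loc, model.out_scale = 73.0, 11.0
        g = small_graph(R=6, seed=0)
        X, E, mask, _ = stack_graphs([g])
        p0 = model.predict(X, E, mask)[0]
        path = tmp_path / "ckpt.json"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.predict(X, E, mask)[0] == pytest.approx(p0, abs=1e-12)
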