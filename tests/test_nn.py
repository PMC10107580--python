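"""NumPy networks: gradient correctness, training behaviour, determinism."""

import numpy as np
import pytest

from acqsar.gin import (
    GINEncoder,
    GraphBatch,
    GraphEncoderConfig,
    mol_graph,
    train_gin,
    train_gin_features,
)
from acqsar.nn import (
    AdamW,
    BatchNorm,
    Linear,
    Sequential,
    TrainConfig,
    TrainingDivergedError,
    make_mlp,
    predict_mlp,
    train_mlp,
)


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        hi = f()
        x[i] = old - eps
        lo = f()
        x[i] = old
        g[i] = (hi - lo) / (2 * eps)
    return g


class TestGradients:
    def test_mlp_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        net = make_mlp(4, (5,), 1, rng, dropout=0.0, batchnorm=True)
        x = rng.normal(size=(8, 4))
        y = rng.normal(size=(8, 1))

        def loss():
            return float(((net.forward(x, training=True) - y) ** 2).mean())

        pred = net.forward(x, training=True)
        net.backward(2.0 * (pred - y) / y.shape[0])
        analytic = [g.copy() for g in net.grads]
        for p, g in zip(net.params, analytic):
            num = numerical_grad(loss, p)
            np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-6)

    def test_gin_backward_matches_numerical_gradient(self):
        enc = GINEncoder(n_layers=1, hidden_dim=3, seed=0)
        rng = np.random.default_rng(1)
        head = Sequential([Linear(3, 1, rng)])
        graphs = [mol_graph(s) for s in ["CCO", "c1ccccc1", "CC(N)=O"]]
        batch = GraphBatch.from_graphs(graphs)
        y = rng.normal(size=(3, 1))

        def loss():
            pooled = enc.forward(batch, training=True)
            return float(((head.forward(pooled, training=True) - y) ** 2).mean())

        pooled = enc.forward(batch, training=True)
        diff = head.forward(pooled, training=True) - y
        enc.backward(head.backward(2.0 * diff / y.shape[0]))
        analytic = [g.copy() for g in enc.grads + head.grads]
        for p, g in zip(enc.params + head.params, analytic):
            num = numerical_grad(loss, p)
            np.testing.assert_allclose(g, num, rtol=1e-3, atol=1e-6)


class TestMLPTraining:
    def test_learns_linear_target(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(128, 2))
        y = 3.0 * x[:, 0] - x[:, 1]
        net, losses = train_mlp(x, y, TrainConfig(epochs=300, batch_size=64, hidden=(64,), lr=3e-3, seed=0))
        assert losses[-1] < 0.05 * np.var(y)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 3))
        y = x.sum(axis=1)
        cfg = TrainConfig(epochs=20, batch_size=8, hidden=(16,), dropout=0.2, seed=7)
        a, _ = train_mlp(x, y, cfg)
        b, _ = train_mlp(x, y, cfg)
        assert np.array_equal(predict_mlp(a, x), predict_mlp(b, x))

    def test_zero_epochs_returns_initialised_net(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3))
        y = x.sum(axis=1)
        cfg0 = TrainConfig(epochs=0, batch_size=8, hidden=(16,), seed=3)
        cfg = TrainConfig(epochs=30, batch_size=8, hidden=(16,), seed=3)
        net0, losses0 = train_mlp(x, y, cfg0)
        net, _ = train_mlp(x, y, cfg)
        assert losses0 == []
        assert not np.array_equal(predict_mlp(net0, x), predict_mlp(net, x))

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_detected(self):
        x = np.full((16, 1), 1e150)
        y = np.full(16, 1e150)
        with pytest.raises(TrainingDivergedError):
            train_mlp(x, y, TrainConfig(epochs=5, batch_size=8, hidden=(8,), lr=1e6, seed=0))

    def test_inference_mode_is_pure(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(32, 2))
        y = x[:, 0]
        net, _ = train_mlp(x, y, TrainConfig(epochs=10, batch_size=8, hidden=(8,), dropout=0.3, seed=0))
        assert np.array_equal(predict_mlp(net, x), predict_mlp(net, x))


class TestAdamW:
    def test_decoupled_weight_decay_shrinks_parameters(self):
        p = np.ones(4)
        opt_wd = AdamW([p], lr=0.1, weight_decay=0.5)
        opt_wd.step([np.zeros(4)])
        assert (p < 1.0).all()  # decay acts even at zero gradient

    def test_learning_rate_decay(self):
        opt = AdamW([np.zeros(1)], lr=1.0, lr_decay=0.5)
        opt.end_epoch()
        opt.end_epoch()
        assert opt.lr == pytest.approx(0.25)


class TestGINTraining:
    SMILES = ["CCO", "CCC", "CCN", "CCCl", "c1ccccc1O", "c1ccccc1C", "CCOC", "CCCC"]

    def test_linear_head_pretraining_freezes_encoder(self):
        graphs = [mol_graph(s) for s in self.SMILES]
        y = np.arange(len(graphs), dtype=float)
        enc, losses = train_gin_features(
            graphs, y, GraphEncoderConfig(2, 16), TrainConfig(epochs=40, batch_size=4, lr=1e-2, seed=0)
        )
        assert enc.frozen
        assert losses[-1] < losses[0]
        e = enc.embed(graphs)
        assert e.shape == (len(graphs), 16)
        assert np.array_equal(e, enc.embed(graphs))

    def test_end_to_end_mode_trains_mlp_head(self):
        graphs = [mol_graph(s) for s in self.SMILES]
        y = np.arange(len(graphs), dtype=float)
        cfg = TrainConfig(epochs=40, batch_size=4, lr=3e-3, hidden=(16,), seed=0)
        enc, head, losses = train_gin(graphs, y, GraphEncoderConfig(2, 16), cfg, head="mlp")
        assert losses[-1] < losses[0]

    def test_seeded_reruns_identical(self):
        graphs = [mol_graph(s) for s in self.SMILES]
        y = np.arange(len(graphs), dtype=float)
        cfg = TrainConfig(epochs=10, batch_size=4, lr=1e-2, seed=5)
        a, _ = train_gin_features(graphs, y, GraphEncoderConfig(1, 8), cfg)
        b, _ = train_gin_features(graphs, y, GraphEncoderConfig(1, 8), cfg)
        assert np.array_equal(a.embed(graphs), b.embed(graphs))
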