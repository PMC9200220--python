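import numpy as np
import pytest

from vscreen import dfcnn_core as core
from vscreen import eval_metrics as em
from vscreen.errors import ConfigError, ShapeError


def _zero_out(params):
    for w in params.weights:
        w[:] = 0.0
    for b in params.biases:
        b[:] = 0.0
    params.head_w[:] = 0.0
    params.head_b[:] = 0.0


def _separable_pairs(n, seed, dim=600, flip=False):
    """2-d linearly separable signal embedded in the first two coordinates."""
    rng = np.random.default_rng(seed)
    X2 = rng.standard_normal((n, 2))
    y = (X2[:, 0] + X2[:, 1] > 0).astype(int)
    if flip:
        y = rng.permutation(y)
    X = np.zeros((n, dim))  # zero padding: normalizer floors constant columns
    X[:, :2] = X2
    d = dim // 2
    return [
        core.PairSample(pocket=X[i, :d], ligand=X[i, d:], label=int(y[i]))
        for i in range(n)
    ]


class TestBuild:
    def test_default_widths(self):
        cfg = core.DFCNNConfig()
        assert cfg.block_input_width(1) == 600
        assert cfg.block_input_width(2) == 700
        assert cfg.head_input_width == 1600

    def test_single_block_head_width(self):
        assert core.DFCNNConfig(n_dense_blocks=1).head_input_width == 700

    def test_parameter_count_formula(self):
        cfg = core.DFCNNConfig(input_dim=10, n_dense_blocks=3, block_units=4)
        params = core.build_dfcnn(cfg)
        expected = (10 * 4 + 4) + (14 * 4 + 4) + (18 * 4 + 4) + (22 + 1)
        assert cfg.n_parameters == expected == params.n_parameters()

    def test_same_seed_identical_weights(self):
        p1 = core.build_dfcnn(core.DFCNNConfig(seed=5))
        p2 = core.build_dfcnn(core.DFCNNConfig(seed=5))
        for w1, w2 in zip(p1.weights, p2.weights):
            assert np.array_equal(w1, w2)
        assert np.array_equal(p1.head_w, p2.head_w)

    def test_exclude_input_widths(self):
        cfg = core.DFCNNConfig(include_input=False)
        assert cfg.block_input_width(1) == 600
        assert cfg.block_input_width(2) == 100
        assert cfg.head_input_width == 1000

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            core.DFCNNConfig(n_dense_blocks=0)


class TestScore:
    def test_zero_weights_score_half(self):
        params = core.build_dfcnn(core.DFCNNConfig(input_dim=8, n_dense_blocks=2, block_units=3))
        _zero_out(params)
        scores = core.score(params, np.random.default_rng(0).random((5, 8)))
        np.testing.assert_allclose(scores, 0.5)

    def test_batch_equals_per_row(self):
        params = core.build_dfcnn(core.DFCNNConfig(input_dim=12, n_dense_blocks=3, block_units=4))
        batch = np.random.default_rng(1).standard_normal((20, 12))
        whole = core.score(params, batch)
        rows = np.concatenate([core.score(params, batch[i : i + 1]) for i in range(20)])
        # BLAS reduction order differs between batch shapes: ulp-level only
        np.testing.assert_allclose(whole, rows, rtol=1e-12)

    def test_output_strictly_in_unit_interval(self):
        params = core.build_dfcnn(core.DFCNNConfig(input_dim=6, n_dense_blocks=1, block_units=2))
        params.head_b[:] = 1e6  # force saturation
        s = core.score(params, np.zeros((1, 6)))
        assert 0.0 < s[0] < 1.0

    def test_hand_forward_pass_tiny_network(self):
        # input_dim 4, two blocks of 2 units; hand-set weights, independent
        # numpy forward pass as the oracle
        cfg = core.DFCNNConfig(input_dim=4, n_dense_blocks=2, block_units=2)
        params = core.build_dfcnn(cfg)
        w1 = np.arange(8, dtype=float).reshape(4, 2) / 10.0
        b1 = np.array([0.1, -0.2])
        w2 = np.linspace(-0.5, 0.5, 12).reshape(6, 2)
        b2 = np.array([0.0, 0.3])
        hw = np.linspace(0.2, -0.2, 8).reshape(8, 1)
        hb = np.array([0.05])
        params.weights[0][:] = w1
        params.biases[0][:] = b1
        params.weights[1][:] = w2
        params.biases[1][:] = b2
        params.head_w[:] = hw
        params.head_b[:] = hb
        x = np.array([[0.3, -1.0, 0.5, 2.0]])
        # oracle
        a1 = np.maximum(x @ w1 + b1, 0)
        c2 = np.concatenate([x, a1], axis=1)
        a2 = np.maximum(c2 @ w2 + b2, 0)
        ch = np.concatenate([x, a1, a2], axis=1)
        expected = 1 / (1 + np.exp(-(ch @ hw + hb)))
        np.testing.assert_allclose(core.score(params, x), expected.ravel())

    def test_shape_mismatch(self):
        params = core.build_dfcnn(core.DFCNNConfig(input_dim=6, n_dense_blocks=1))
        with pytest.raises(ShapeError):
            core.score(params, np.zeros((2, 7)))

    def test_scoring_deterministic_with_dropout_config(self):
        cfg = core.DFCNNConfig(input_dim=8, n_dense_blocks=2, block_units=3, dropout=0.5)
        params = core.build_dfcnn(cfg)
        x = np.random.default_rng(2).random((4, 8))
        assert np.array_equal(core.score(params, x), core.score(params, x))


class TestNormalizer:
    def test_constant_column_floored(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10, dtype=float)])
        norm = core.fit_normalizer(X)
        t = norm.transform(X)
        np.testing.assert_allclose(t[:, 0], 0.0)

    def test_two_point_column(self):
        X = np.array([[0.0], [2.0]])
        t = core.fit_normalizer(X).transform(X)
        np.testing.assert_allclose(t.ravel(), [-1.0, 1.0])

    def test_standardized_data_near_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 4))
        X = (X - X.mean(0)) / X.std(0)
        t = core.fit_normalizer(X).transform(X)
        np.testing.assert_allclose(t, X, atol=1e-10)

    def test_transformed_moments(self):
        rng = np.random.default_rng(1)
        X = rng.random((200, 6)) * 7 + 3
        t = core.fit_normalizer(X).transform(X)
        np.testing.assert_allclose(t.mean(0), 0.0, atol=1e-6)
        np.testing.assert_allclose(t.std(0), 1.0, atol=1e-3)


class TestFit:
    def test_separable_data_high_auc(self):
        train = _separable_pairs(600, seed=0)
        test = _separable_pairs(300, seed=1)
        params = core.build_dfcnn(core.DFCNNConfig(seed=0))
        core.fit(params, train, epochs=15, seed=0)
        X, y = core.pairs_to_arrays(test)
        auc = em.roc_auc(core.score(params, X), y.astype(int))
        assert auc >= 0.95

    def test_permuted_labels_no_signal(self):
        train = _separable_pairs(800, seed=2, flip=True)
        test = _separable_pairs(400, seed=3, flip=True)
        params = core.build_dfcnn(core.DFCNNConfig(seed=0))
        core.fit(params, train, epochs=5, seed=0)
        X, y = core.pairs_to_arrays(test)
        auc = em.roc_auc(core.score(params, X), y.astype(int))
        assert 0.4 <= auc <= 0.6

    def test_reproducible_losses(self):
        train = _separable_pairs(200, seed=4, dim=20)
        cfg = core.DFCNNConfig(input_dim=20, n_dense_blocks=2, block_units=8, seed=1)
        p1 = core.fit(core.build_dfcnn(cfg), train, epochs=3, seed=9)
        p2 = core.fit(core.build_dfcnn(cfg), train, epochs=3, seed=9)
        assert p1.training_log["train_loss"] == p2.training_log["train_loss"]

    def test_validation_losses_logged(self):
        train = _separable_pairs(100, seed=5, dim=10)
        val = _separable_pairs(40, seed=6, dim=10)
        cfg = core.DFCNNConfig(input_dim=10, n_dense_blocks=1, block_units=4)
        params = core.fit(core.build_dfcnn(cfg), train, val, epochs=4, seed=0)
        assert len(params.training_log["train_loss"]) == 4
        assert len(params.training_log["val_loss"]) == 4

    def test_single_class_raises(self):
        pairs = [
            core.PairSample(pocket=np.zeros(5), ligand=np.zeros(5), label=1)
            for _ in range(10)
        ]
        params = core.build_dfcnn(core.DFCNNConfig(input_dim=10, n_dense_blocks=1))
        with pytest.raises(ConfigError):
            core.fit(params, pairs)


class TestPersistence:
    def test_roundtrip_identical_scores(self, tmp_path):
        train = _separable_pairs(100, seed=7, dim=16)
        cfg = core.DFCNNConfig(input_dim=16, n_dense_blocks=2, block_units=4, seed=3)
        params = core.fit(core.build_dfcnn(cfg), train, epochs=2, seed=0)
        path = tmp_path / "model.npz"
        core.save_params(params, path)
        loaded = core.load_params(path)
        batch = np.random.default_rng(8).standard_normal((100, 16))
        np.testing.assert_array_equal(core.score(params, batch), core.score(loaded, batch))

    def test_version_mismatch_raises(self, tmp_path):
        path = tmp_path / "bogus.npz"
        np.savez(path, __version__=np.array("something-else"))
        with pytest.raises(ConfigError):
            core.load_params(path)


class TestCNN:
    def _small_cfg(self, **kw):
        return core.CNNConfig(input_dim=32, conv_filters=(4, 8), dense_units=16, **kw)

    def test_zero_weights_score_half(self):
        p = core.build_cnn(self._small_cfg())
        for w in p.conv_w:
            w[:] = 0.0
        p.dense_w[:] = 0.0
        p.head_w[:] = 0.0
        scores = core.score_cnn(p, np.random.default_rng(0).random((3, 32)))
        np.testing.assert_allclose(scores, 0.5)

    def test_batch_equals_per_row(self):
        p = core.build_cnn(self._small_cfg(seed=2))
        batch = np.random.default_rng(1).standard_normal((10, 32))
        whole = core.score_cnn(p, batch)
        rows = np.concatenate([core.score_cnn(p, batch[i : i + 1]) for i in range(10)])
        np.testing.assert_allclose(whole, rows, atol=1e-12)

    def test_conv_layer_against_naive_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 9, 3))
        w = rng.standard_normal((3, 3, 4))
        b = rng.standard_normal(4)
        z, _ = core._conv1d_forward(x, w, b)
        expected = np.zeros((2, 7, 4))
        for n in range(2):
            for l in range(7):
                for o in range(4):
                    acc = b[o]
                    for kk in range(3):
                        for c in range(3):
                            acc += x[n, l + kk, c] * w[kk, c, o]
                    expected[n, l, o] = acc
        np.testing.assert_allclose(z, expected, atol=1e-12)

    def test_fit_cnn_learns_separable_data(self):
        train = _separable_pairs(400, seed=10, dim=32)
        test = _separable_pairs(200, seed=11, dim=32)
        p = core.build_cnn(self._small_cfg(seed=0))
        core.fit_cnn(p, train, epochs=30, seed=0, lr=1e-3)
        X, y = core.pairs_to_arrays(test)
        auc = em.roc_auc(core.score_cnn(p, X), y.astype(int))
        assert auc >= 0.95

    def test_fit_cnn_reproducible(self):
        train = _separable_pairs(120, seed=12, dim=32)
        p1 = core.fit_cnn(core.build_cnn(self._small_cfg(seed=1)), train, epochs=2, seed=4)
        p2 = core.fit_cnn(core.build_cnn(self._small_cfg(seed=1)), train, epochs=2, seed=4)
        assert p1.training_log["train_loss"] == p2.training_log["train_loss"]

    def test_dropout_inactive_at_scoring(self):
        p = core.build_cnn(self._small_cfg(seed=5))
        x = np.random.default_rng(6).random((4, 32))
        assert np.array_equal(core.score_cnn(p, x), core.score_cnn(p, x))
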