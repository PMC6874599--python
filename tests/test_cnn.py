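"""Architecture shape oracle, inference contract, training sanity."""

import numpy as np
import pytest

from strainnet import (CNNSpec, StrainCNN, StrainMeasure, TrainingConfig,
                       build, feature_map_shapes, flattened_width, predict)
from strainnet import nn


def conv_widths_by_hand(widths=(201,), layers=((10, 2), (10, 2), (5, 1))):
    """Independent valid-convolution arithmetic: floor((W-k)/s)+1."""
    w = widths[0]
    out = []
    for k, s in layers:
        w = (w - k) // s + 1
        out.append(w)
    return out


class TestShapeOracle:
    def test_intermediate_widths(self):
        shapes = feature_map_shapes(CNNSpec())
        assert [w for _, w, _ in shapes] == conv_widths_by_hand() == [96, 44, 40]
        assert [h for h, _, _ in shapes] == [1, 1, 1]
        assert [c for _, _, c in shapes] == [32, 32, 32]

    def test_flattened_width(self):
        assert flattened_width(CNNSpec()) == 1 * 40 * 32 == 1280

    def test_parameter_count_matches_shape_arithmetic(self):
        net = build(CNNSpec(), np.random.default_rng(0))
        fc = CNNSpec().fc_sizes
        expected = (32 * 3 * 10 + 32) + (32 * 32 * 10 + 32) + \
            (32 * 32 * 5 + 32) + (1280 * fc[0] + fc[0]) + (fc[0] * 1 + 1)
        assert net.n_parameters() == expected

    def test_oversized_kernel_rejected(self):
        bad = CNNSpec(conv_layers=((32, (3, 300), (1, 2)),))
        with pytest.raises(ValueError, match="exceeds"):
            build(bad, np.random.default_rng(0))


class TestPredict:
    @pytest.fixture(scope="class")
    def net(self):
        return build(CNNSpec(), np.random.default_rng(1))

    def test_nonnegative_outputs(self, net, rng):
        x = rng.normal(0, 20, size=(16, 3, 201))
        assert np.all(predict(net, x) >= 0)

    def test_deterministic(self, net, rng):
        x = rng.normal(0, 20, size=(4, 3, 201))
        np.testing.assert_array_equal(predict(net, x), predict(net, x))

    def test_batch_equals_singletons(self, net, rng):
        x = rng.normal(0, 20, size=(5, 3, 201))
        batch = predict(net, x)
        singles = np.concatenate([predict(net, x[i:i + 1]) for i in range(5)])
        np.testing.assert_allclose(batch, singles, rtol=1e-6)

    def test_wrong_shape_rejected(self, net):
        with pytest.raises(ValueError, match="shape"):
            predict(net, np.zeros((4, 3, 100)))


class TestTraining:
    def test_constant_labels_learned(self, rng):
        x = rng.normal(0, 10, size=(80, 3, 201))
        y = np.full(80, 0.25)
        model = StrainCNN(x, y, config=TrainingConfig(epochs=5, seed=0))
        res = model.fit()
        pred = res.predict(x)
        np.testing.assert_allclose(pred, 0.25, rtol=0.1)

    def test_early_stopping_restores_best(self, rng):
        x = rng.normal(0, 10, size=(100, 3, 201))
        y = rng.uniform(0, 0.4, size=100)
        model = StrainCNN(x, y, config=TrainingConfig(epochs=20, seed=1))
        res = model.fit()
        h = res.history
        assert h["best_val_loss"] <= h["val_loss"][-1] + 1e-12
        assert h["best_val_loss"] == min(h["val_loss"] + [h["init_val_loss"]])

    def test_loss_decreases_on_learnable_miniature(self):
        """At an elevated learning rate a tiny oracle-like problem is
        learnable: validation MSE of the fit beats predicting the mean."""
        local = np.random.default_rng(42)
        x = np.zeros((64, 3, 201))
        amp = local.uniform(10, 40, size=64)
        x[:, 0, 95:106] = amp[:, None]
        y = amp / 100.0
        cfg = TrainingConfig(epochs=60, learning_rate=1e-3, batch_size=16,
                             head_init_scale=1.0, seed=3)
        res = StrainCNN(x, y, config=cfg).fit()
        # compare against predict-the-mean baseline on the training inputs
        pred = res.predict(x)
        assert np.mean((pred - y) ** 2) < np.var(y)

    def test_reproducible_given_seed(self, rng):
        x = rng.normal(0, 10, size=(70, 3, 201))
        y = rng.uniform(0, 0.4, size=70)
        cfg = TrainingConfig(epochs=3, seed=7)
        r1 = StrainCNN(x, y, config=cfg).fit()
        r2 = StrainCNN(x, y, config=cfg).fit()
        np.testing.assert_array_equal(r1.predict(x), r2.predict(x))

    def test_nonnegative_label_contract(self, rng):
        x = rng.normal(size=(10, 3, 201))
        with pytest.raises(ValueError, match="non-negative"):
            StrainCNN(x, np.linspace(-0.1, 0.3, 10))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, rng):
        from strainnet import StrainCNNResults
        x = rng.normal(0, 10, size=(70, 3, 201))
        y = rng.uniform(0, 0.4, size=70)
        res = StrainCNN(x, y, measure=StrainMeasure.MPS_CC_95,
                        config=TrainingConfig(epochs=2, seed=2)).fit()
        res.save(tmp_path / "model")
        net, manifest = StrainCNNResults.load_network(tmp_path / "model")
        np.testing.assert_allclose(predict(net, x), res.predict(x), rtol=1e-6)
        assert manifest["measure"] == "MPS_CC_95"

    def test_summary_mentions_key_fields(self, rng):
        x = rng.normal(0, 10, size=(70, 3, 201))
        y = rng.uniform(0, 0.4, size=70)
        res = StrainCNN(x, y, measure=StrainMeasure.MPS_WB_95,
                        config=TrainingConfig(epochs=2, seed=2)).fit()
        text = res.summary()
        assert "MPS_WB_95" in text and "R^2" in text


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end gradient check of the conv/dense stack (float64)."""
        old_dtype = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            rng = np.random.default_rng(0)
            spec = CNNSpec(conv_layers=((4, (3, 5), (1, 2)),
                                        (4, (1, 3), (1, 2))),
                           fc_sizes=(5, 1), dropout_rate=0.0, init_gain=1.0,
                           first_fc_init_scale=1.0, hidden_bias_init=0.0)
            net = build(spec, rng, input_shape=(3, 21))
            x = rng.standard_normal((6, 3, 21))
            y = rng.standard_normal(6)

            def loss():
                p = net.forward(x, train=False).ravel()
                return np.mean((p - y) ** 2)

            p = net.forward(x, train=True, rng=rng).ravel()
            net.backward((2 * (p - y) / len(y))[:, None])
            for layer, key in net.parameters():
                W, g = layer.params[key], layer.grads[key]
                for idx in [tuple(rng.integers(0, s) for s in W.shape)
                            for _ in range(4)]:
                    eps, old = 1e-6, W[idx]
                    W[idx] = old + eps
                    lp = loss()
                    W[idx] = old - eps
                    lm = loss()
                    W[idx] = old
                    fd = (lp - lm) / (2 * eps)
                    assert fd == pytest.approx(g[idx], rel=1e-5, abs=1e-9)
        finally:
            nn.DTYPE = old_dtype
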