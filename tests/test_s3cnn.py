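"""Network architecture, gradients, training behaviour."""

import numpy as np
import pytest

from sleepmat import nn
from sleepmat.s3cnn import (S3CNN, PostureCNN, S3CNNConfig, build_s3cnn,
                            pack_features, predict, train_model,
                            unpack_features)


def _random_packed(n, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = np.stack([pack_features(rng.standard_normal((2, 90)),
                                rng.standard_normal((2, 180)),
                                rng.random((16, 32)), rng.random((16, 32)))
                  for _ in range(n)])
    y = np.array(["supine", "right_lateral", "left_lateral"] * (n // 3 + 1))[:n]
    if informative:
        for i, cls in enumerate(("supine", "right_lateral", "left_lateral")):
            X[y == cls, 30 * i:30 * (i + 1)] += 3.0
    return X, y


class TestArchitecture:
    def test_every_branch_yields_32_vector(self):
        model = build_s3cnn()
        feats = model.branch_features(model._dummy_inputs(4))
        assert set(feats) == {"F1", "F2", "E1", "E2"}
        for f in feats.values():
            assert f.shape == (4, 32)

    def test_stacked_features_32x4(self):
        model = build_s3cnn()
        assert model.stacked_features(model._dummy_inputs(3)).shape == (3, 32, 4)

    def test_first_conv1d_layer_spec(self):
        model = build_s3cnn()
        layer = model.temporal_branches[0].layers[0]
        assert isinstance(layer, nn.Conv1D)
        assert layer.c_out == 16 and layer.k == 11 and layer.s == 1
        assert layer.padding == "same"

    def test_head_widths_64_96_3(self):
        model = build_s3cnn()
        dense = [l for l in model.head.iter_layers() if isinstance(l, nn.Dense)]
        assert [d.W.shape for d in dense] == [(128, 64), (64, 96), (96, 3)]

    def test_softmax_normalised(self):
        model = build_s3cnn(seed=1)
        rng = np.random.default_rng(0)
        ins = {k: rng.standard_normal(v.shape).astype(np.float32)
               for k, v in model._dummy_inputs(6).items()}
        probs = model.predict_proba(ins)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_parameter_count_small(self):
        assert build_s3cnn().parameter_count() < 1_000_000

    def test_ablation_variants_shapes(self):
        for branches, n_br in (("temporal", 2), ("spatial", 2), ("combined", 4)):
            model = build_s3cnn(branches=branches)
            stacked = model.stacked_features(model._dummy_inputs(2))
            assert stacked.shape == (2, 32, n_br)

    def test_infeasible_config_names_branch(self):
        cfg = S3CNNConfig(conv1d_1=((16, 11, 1), (24, 11, 2), (24, 11, 2)))
        with pytest.raises(ValueError, match="F1"):
            build_s3cnn(cfg)


class TestGradients:
    @pytest.fixture(autouse=True)
    def _double_precision(self, monkeypatch):
        monkeypatch.setattr(nn, "DTYPE", np.float64)

    def test_backprop_matches_finite_differences(self):
        model = S3CNN(seed=0)
        rng = np.random.default_rng(0)
        ins = {k: rng.standard_normal(v.shape)
               for k, v in model._dummy_inputs(4).items()}
        onehot = np.eye(3)[[0, 1, 2, 0]]
        _, dl = nn.softmax_xent(model.forward(ins), onehot)
        model.backward(dl)
        checks = [
            model.temporal_branches[0].layers[0],    # Conv1D
            model.temporal_branches[1].layers[5],    # MaxPool1D follows
            model.spatial_branches[0].layers[0],     # Conv2D
            model.head.layers[0],                    # Dense
        ]
        eps = 1e-6
        for layer in checks:
            if not layer.params:
                continue
            W = layer.params[0]
            idx = np.unravel_index(7 % W.size, W.shape)
            analytic = layer.grads[0][idx]
            W[idx] += eps
            up, _ = nn.softmax_xent(model.forward(ins), onehot)
            W[idx] -= 2 * eps
            down, _ = nn.softmax_xent(model.forward(ins), onehot)
            W[idx] += eps
            numeric = (up - down) / (2 * eps)
            assert analytic == pytest.approx(numeric, abs=1e-7)


class TestTraining:
    def test_one_step_decreases_loss(self):
        X, y = _random_packed(48, seed=1)
        clf_a = PostureCNN(epochs=1, dropout=0.0, random_state=0)
        clf_a.fit(X, y)
        assert clf_a.history_["loss"][0] < np.log(3) + 0.5

        model = build_s3cnn(seed=0)
        inputs = unpack_features(X)
        labels = np.unique(y, return_inverse=True)[1]
        onehot = np.eye(3)[labels]
        opt = nn.Adam(model.all_layers(), lr=1e-3)
        l0, dl = nn.softmax_xent(model.forward(inputs, training=False), onehot)
        model.backward(dl)
        opt.step()
        l1, _ = nn.softmax_xent(model.forward(inputs, training=False), onehot)
        assert l1 < l0

    def test_memorises_single_batch(self):
        # repeated passes over one batch of 48 drive training accuracy
        # (dropout off at evaluation) to 100%
        X, y = _random_packed(48, seed=2)
        clf = PostureCNN(epochs=100, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_functional_trainer_history(self):
        X, y = _random_packed(24, seed=11)
        cfg = S3CNNConfig(max_epochs=5)
        labels = np.unique(y, return_inverse=True)[1]
        model, history = train_model(S3CNN(cfg, seed=0),
                                     (unpack_features(X), labels), cfg, seed=0)
        assert len(history["loss"]) == 5
        with pytest.raises(ValueError):
            train_model(S3CNN(cfg, seed=0),
                        (unpack_features(X), np.zeros(24, dtype=int)), cfg)

    def test_epoch_cap_honoured(self):
        X, y = _random_packed(24, seed=3)
        clf = PostureCNN(epochs=150, random_state=0)
        clf.epochs = 3                      # keep the test fast
        clf.fit(X, y)
        assert len(clf.history_["loss"]) <= 100

    def test_history_recorded(self):
        X, y = _random_packed(24, seed=4)
        clf = PostureCNN(epochs=4, random_state=0).fit(X, y)
        assert len(clf.history_["loss"]) == 4
        assert len(clf.history_["accuracy"]) == 4

    def test_deterministic_given_seed(self):
        X, y = _random_packed(30, seed=5)
        w1 = PostureCNN(epochs=3, random_state=9).fit(X, y).model_.get_weights()
        w2 = PostureCNN(epochs=3, random_state=9).fit(X, y).model_.get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_missing_class_rejected(self):
        X, y = _random_packed(20, seed=6)
        with pytest.raises(ValueError):
            PostureCNN(epochs=1).fit(X, np.array(["supine"] * 20))


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, y = _random_packed(48, seed=7)
        return PostureCNN(epochs=10, random_state=0).fit(X, y), X, y

    def test_probability_rows_sum_to_one(self, fitted):
        clf, X, _ = fitted
        np.testing.assert_allclose(clf.predict_proba(X).sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_batch_permutation_equivariance(self, fitted):
        clf, X, _ = fitted
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(clf.predict_proba(X)[perm],
                                   clf.predict_proba(X[perm]), atol=1e-6)

    def test_unfitted_predict_rejected(self):
        from sklearn.exceptions import NotFittedError
        X, _ = _random_packed(5)
        with pytest.raises(NotFittedError):
            PostureCNN().predict(X)

    def test_functional_predict(self, fitted):
        clf, X, _ = fitted
        probs, labels = predict(clf.model_, clf._normalise(unpack_features(X)))
        assert probs.shape == (48, 3)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        from sleepmat.s3cnn import load_model, save_model
        X, y = _random_packed(30, seed=8)
        clf = PostureCNN(epochs=3, random_state=2).fit(X, y)
        save_model(clf, tmp_path / "model.npz")
        back = load_model(tmp_path / "model.npz")
        np.testing.assert_allclose(back.predict_proba(X),
                                   clf.predict_proba(X), atol=1e-6)
        np.testing.assert_array_equal(back.predict(X), clf.predict(X))


class TestPacking:
    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        m1, m2 = rng.random((2, 90)), rng.random((2, 180))
        rmap, bmap = rng.random((16, 32)), rng.random((16, 32))
        x = pack_features(m1, m2, rmap, bmap)
        parts = unpack_features(x)
        np.testing.assert_allclose(parts["M1"][0], m1)
        np.testing.assert_allclose(parts["M2"][0], m2)
        np.testing.assert_allclose(parts["N1"][0, 0], (rmap / rmap.max()).T)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            unpack_features(np.zeros((3, 100)))
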