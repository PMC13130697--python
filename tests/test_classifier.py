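"""Network forward pass, gradients, training and prediction."""

import numpy as np
import pytest

from ccband import (
    ClassifierModel,
    NetworkConfig,
    fit_standardizer,
    forward,
    loss_and_gradient,
    predict,
    train,
)
from ccband.classifier import (
    MlpClassifier,
    _init_params,
    _layer_dims,
    _pack,
    _unpack,
)


def toy_model(n_features=2, hidden=(1, 1, 1), seed=0, zero=False):
    cfg = NetworkConfig(hidden_sizes=hidden, init_seed=seed)
    dims = _layer_dims(n_features, cfg.hidden_sizes)
    params = _init_params(dims, seed)
    if zero:
        params = [np.zeros_like(p) for p in params]
    return ClassifierModel(
        weights=params,
        mu=np.zeros(n_features),
        sigma=np.ones(n_features),
        config=cfg,
    )


class TestStandardizer:
    def test_two_point_population_convention(self):
        mu, sigma = fit_standardizer(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.allclose(mu, [1, 1]) and np.allclose(sigma, [1, 1])

    def test_constant_feature_floored(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        mu, sigma = fit_standardizer(x)
        assert sigma[0] == 1e-8
        assert np.allclose((x[:, 0] - mu[0]) / sigma[0], 0.0)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.random((50, 7))
        mu, sigma = fit_standardizer(x)
        mu2 = np.array([x[:, j].sum() / 50 for j in range(7)])
        sd2 = np.array(
            [np.sqrt(((x[:, j] - mu2[j]) ** 2).sum() / 50) for j in range(7)]
        )
        assert np.allclose(mu, mu2) and np.allclose(sigma, sd2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.empty((1, 3)))


class TestForward:
    def test_zero_weights_give_uniform_probabilities(self, rng):
        model = toy_model(4, zero=True)
        probs = forward(model, rng.random((10, 4)))
        assert np.allclose(probs, 0.5)

    def test_probabilities_valid_for_random_models(self, rng):
        for seed in range(5):
            model = toy_model(6, hidden=(10, 10, 10), seed=seed)
            probs = forward(model, rng.standard_normal((20, 6)))
            assert (probs > 0).all() and (probs < 1).all()
            assert np.abs(probs.sum(axis=1) - 1).max() < 1e-12

    def test_matches_hand_unrolled_toy_network(self):
        # 2 features, one unit per hidden layer: fully explicit arithmetic
        model = toy_model(2, hidden=(1, 1, 1), seed=3)
        x = np.array([[0.3, -1.2]])
        w1, b1, w2, b2, w3, b3, w4, b4 = model.weights
        a1 = np.tanh(x @ w1 + b1)
        a2 = np.tanh(a1 @ w2 + b2)
        a3 = np.tanh(a2 @ w3 + b3)
        z = a3 @ w4 + b4
        expected = np.exp(z) / np.exp(z).sum()
        assert np.allclose(forward(model, x), expected)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            forward(toy_model(4), rng.random((3, 5)))


class TestLossAndGradient:
    def test_uniform_predictions_give_ln2(self):
        model = toy_model(4, zero=True)
        loss, _ = loss_and_gradient(
            model.weights, np.zeros((8, 4)), np.array([0, 1] * 4)
        )
        assert loss == pytest.approx(np.log(2), rel=1e-12)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        model = toy_model(1, hidden=(1,))
        model.weights[-2] = np.array([[-50.0, 50.0]])  # huge final layer
        model.weights[-1] = np.zeros(2)
        xs = np.ones((4, 1))
        loss, _ = loss_and_gradient(model.weights, xs, np.ones(4, dtype=int))
        assert loss < 1e-10

    @pytest.mark.parametrize("seed", range(20))
    def test_gradient_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = int(rng.integers(2, 8))
        hidden = tuple(rng.integers(1, 6, size=rng.integers(1, 4)))
        dims = _layer_dims(n_feat, hidden)
        params = _init_params(dims, seed)
        xs = rng.standard_normal((12, n_feat))
        y = rng.integers(0, 2, 12)
        l2 = float(rng.choice([0.0, 1e-3]))
        _, grads = loss_and_gradient(params, xs, y, l2)
        flat = _pack(params)
        gflat = _pack(grads)
        eps = 1e-6
        idx = rng.choice(len(flat), size=min(30, len(flat)), replace=False)
        for i in idx:
            fp = flat.copy()
            fp[i] += eps
            lp, _ = loss_and_gradient(_unpack(fp, dims), xs, y, l2)
            fm = flat.copy()
            fm[i] -= eps
            lm, _ = loss_and_gradient(_unpack(fm, dims), xs, y, l2)
            numeric = (lp - lm) / (2 * eps)
            denom = max(abs(numeric), abs(gflat[i]), 1e-8)
            assert abs(gflat[i] - numeric) / denom < 1e-5


def blobs(n=200, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack(
        [
            rng.normal((-2, -2), 0.5, (half, 2)),
            rng.normal((2, 2), 0.5, (half, 2)),
        ]
    )
    y = np.array([0] * half + [1] * half)
    return x, y


def xor_clusters(n=400, seed=0):
    rng = np.random.default_rng(seed)
    quarter = n // 4
    centres = [(-2, -2), (2, 2), (-2, 2), (2, -2)]
    labels = [0, 0, 1, 1]
    x = np.vstack([rng.normal(c, 0.5, (quarter, 2)) for c in centres])
    y = np.concatenate([[l] * quarter for l in labels])
    return x, y


class TestTraining:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        x, y = blobs()
        model = train(x, NetworkConfig(init_seed=0), labels=y)
        pred, _ = predict(model, x)
        assert (pred == y).mean() == 1.0

    def test_final_loss_below_initial(self):
        x, y = blobs()
        model = train(x, NetworkConfig(init_seed=1), labels=y)
        assert model.final_loss <= model.initial_loss

    def test_xor_clusters_need_nonlinearity(self):
        x, y = xor_clusters()
        model = train(x, NetworkConfig(init_seed=0), labels=y)
        pred, _ = predict(model, x)
        assert (pred == y).mean() >= 0.95

    def test_deterministic_given_seed(self):
        x, y = blobs()
        m1 = train(x, NetworkConfig(init_seed=7), labels=y)
        m2 = train(x, NetworkConfig(init_seed=7), labels=y)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError):
            train(x, NetworkConfig(), labels=np.zeros(10, dtype=int))

    def test_standardizer_uses_training_rows_only(self):
        x, y = blobs()
        model = train(x, NetworkConfig(init_seed=0), labels=y)
        mu, sigma = fit_standardizer(x)
        assert np.allclose(model.mu, mu) and np.allclose(model.sigma, sigma)

    def test_agrees_with_independent_mlp_implementation(self):
        # cross-check against scikit-learn's lbfgs MLP on the same task
        from sklearn.neural_network import MLPClassifier

        x, y = xor_clusters(seed=3)
        ours = train(x, NetworkConfig(init_seed=0), labels=y)
        ours_acc = (predict(ours, x)[0] == y).mean()
        sk = MLPClassifier(
            (10, 10, 10), activation="tanh", solver="lbfgs",
            max_iter=1000, random_state=0,
        )
        mu, sd = x.mean(0), x.std(0)
        sk.fit((x - mu) / sd, y)
        sk_acc = (sk.predict((x - mu) / sd) == y).mean()
        assert abs(ours_acc - sk_acc) <= 0.05


class TestPredict:
    def test_argmax_and_conservative_tie_break(self):
        model = toy_model(4, zero=True)  # exact 0.5/0.5 everywhere
        pred, proba = predict(model, np.zeros((5, 4)))
        assert (pred == 0).all()
        assert np.allclose(proba, 0.5)

    def test_confident_probability_wins(self):
        x, y = blobs()
        model = train(x, NetworkConfig(init_seed=0), labels=y)
        pred, proba = predict(model, x)
        assert ((proba > 0.5) == (pred == 1)).all()


class TestSerializationAndResults:
    def test_model_json_roundtrip(self):
        x, y = blobs(60)
        model = train(x, NetworkConfig(init_seed=2), labels=y)
        back = ClassifierModel.from_json(model.to_json())
        assert np.allclose(forward(back, x), forward(model, x))

    def test_results_summary_mentions_architecture(self, rng):
        from ccband.dataset import LabeledDataset

        n, bins = 40, 4
        feats = rng.random((n, 3 * bins)).reshape(n, 3, bins)
        feats /= feats.sum(axis=2, keepdims=True)
        ds = LabeledDataset(
            features=feats.reshape(n, -1),
            labels=np.array([0, 1] * (n // 2), dtype=np.int8),
            image_ids=np.array(["a"] * n, dtype=object),
            superpixel_ids=np.arange(n),
            origin=np.array(["real"] * n, dtype=object),
            parent_index=np.full(n, -1),
            bins_per_channel=bins,
        )
        res = MlpClassifier(ds).fit()
        text = res.summary()
        assert "12 -> 10 -> 10 -> 10 -> 2" in text
        assert 0.0 <= res.train_accuracy <= 1.0
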