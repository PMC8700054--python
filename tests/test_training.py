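"""Adam update arithmetic and training-loop behaviour."""

import numpy as np
import pytest

from croak.classifiers import DNNSpec, build_dnn
from croak.training import (
    AdamState,
    TrainConfig,
    adam_step,
    predict,
    softmax_cross_entropy,
    train,
)


class TestAdamStep:
    def test_zero_gradient_is_fixed_point(self):
        params = [np.array([1.0, -2.0])]
        state = AdamState.init(params, learning_rate=0.1)
        adam_step(state, params, [np.zeros(2)])
        assert np.array_equal(params[0], [1.0, -2.0])

    def test_first_step_magnitude_is_learning_rate(self):
        # bias correction makes the first update lr * g/(|g| + eps') ~ lr
        params = [np.array([0.0])]
        state = AdamState.init(params, learning_rate=0.01)
        adam_step(state, params, [np.array([4.0])])
        assert params[0][0] == pytest.approx(-0.01, rel=1e-6)

    def test_two_steps_match_hand_unrolled_recurrences(self):
        lr, rho, rho_f, eps = 0.05, 0.999, 0.9, 1e-8
        g = 2.0
        w = 1.0
        # hand unroll
        x = f = 0.0
        w_ref = w
        for t in (1, 2):
            x = rho * x + (1 - rho) * g * g
            f = rho_f * f + (1 - rho_f) * g
            x_hat = x / (1 - rho**t)
            f_hat = f / (1 - rho_f**t)
            w_ref -= lr * f_hat / (np.sqrt(x_hat) + eps)
        params = [np.array([w])]
        state = AdamState.init(params, learning_rate=lr, rho=rho, rho_f=rho_f, epsilon=eps)
        adam_step(state, params, [np.array([g])])
        adam_step(state, params, [np.array([g])])
        assert params[0][0] == pytest.approx(w_ref, abs=1e-12)

    def test_zero_decay_limit_is_sign_gradient_descent(self):
        # rho = rho_f = 0: update -> lr * g/(|g| + eps) ~ lr * sign(g)
        params = [np.array([0.0, 0.0])]
        state = AdamState.init(params, learning_rate=0.1, rho=0.0, rho_f=0.0, epsilon=1e-15)
        adam_step(state, params, [np.array([3.0, -0.002])])
        assert np.allclose(params[0], [-0.1, 0.1], rtol=1e-9)

    def test_nonfinite_gradient_raises_with_block_index(self):
        params = [np.zeros(2), np.zeros(3)]
        state = AdamState.init(params, learning_rate=0.1)
        with pytest.raises(FloatingPointError, match="block 1"):
            adam_step(state, params, [np.zeros(2), np.array([1.0, np.nan, 0.0])])


class TestSoftmaxCrossEntropy:
    def test_uniform_logits_give_log_c(self):
        loss, _ = softmax_cross_entropy(np.zeros((4, 5)), np.array([1, 2, 3, 4]))
        assert loss == pytest.approx(np.log(5))

    def test_gradient_sums_to_zero_per_row(self, rng):
        logits = rng.normal(size=(6, 4))
        _, grad = softmax_cross_entropy(logits, rng.integers(1, 5, 6))
        assert np.allclose(grad.sum(axis=1), 0, atol=1e-12)

    def test_label_range_validated(self):
        with pytest.raises(ValueError):
            softmax_cross_entropy(np.zeros((2, 3)), np.array([0, 1]))
        with pytest.raises(ValueError):
            softmax_cross_entropy(np.zeros((2, 3)), np.array([1, 4]))


class TestTrainLoop:
    @pytest.fixture()
    def separable_data(self, rng):
        # two well-separated Gaussian blobs
        X = np.vstack([rng.normal(-2, 0.3, size=(30, 8)), rng.normal(2, 0.3, size=(30, 8))])
        y = np.array([1] * 30 + [2] * 30)
        return X, y

    def test_separable_data_reaches_perfect_training_accuracy(self, separable_data):
        X, y = separable_data
        model = build_dnn(DNNSpec(8, (6,), 2), seed=0)
        history = train(model, X, y, TrainConfig(epochs=200, learning_rate=1e-2, batch_size=60, seed=0))
        assert len(history) == 200
        assert np.mean(predict(model, X) == y) == 1.0

    def test_loss_history_reproducible_bitwise(self, separable_data):
        X, y = separable_data
        cfg = TrainConfig(epochs=50, learning_rate=1e-3, batch_size=16, seed=5)
        h1 = train(build_dnn(DNNSpec(8, (6,), 2), seed=3), X, y, cfg)
        h2 = train(build_dnn(DNNSpec(8, (6,), 2), seed=3), X, y, cfg)
        assert h1 == h2

    def test_descent_property_late_loss_below_initial(self, separable_data):
        X, y = separable_data
        model = build_dnn(DNNSpec(8, (6,), 2), seed=1)
        history = train(model, X, y, TrainConfig(epochs=300, learning_rate=1e-3, batch_size=60, seed=0))
        assert np.mean(history[-100:]) <= history[0]

    def test_label_out_of_range_rejected(self, separable_data):
        X, y = separable_data
        model = build_dnn(DNNSpec(8, (6,), 2), seed=0)
        with pytest.raises(ValueError):
            train(model, X, y + 5, TrainConfig(epochs=1, learning_rate=1e-3, batch_size=60, seed=0))


@pytest.fixture(scope="module")
def reduced_features():
    from croak.audio_io import standardize
    from croak.dataset import build_dataset, split
    from croak.evaluation import prepare_features
    from croak.synthetic_calls import generate_corpus

    corpus = [standardize(c) for c in generate_corpus(35, 1, seed=0)]
    data = build_dataset(corpus, "LPC", n_points=320)
    tr, te = split(data, 0.3, seed=0)
    reduced = prepare_features(tr, te, use_pca=True, n_components=200)
    return tr, reduced[0]


class TestStudyScaleTrainability:
    """All sixteen named configurations fit the 35-class synthetic corpus.

    Feature length is reduced (LPC envelopes at 320 points) to keep the
    sweep tractable; each configuration must exceed 0.95 training accuracy
    within the epoch budget.
    """

    @staticmethod
    def _train_until(model, x, y, chunk_epochs, max_epochs):
        """Warm-restart training in chunks, stopping at 0.95 train accuracy."""
        done = 0
        while done < max_epochs:
            cfg = TrainConfig(epochs=chunk_epochs, learning_rate=1e-3,
                              batch_size=128, seed=done)
            train(model, x, y, cfg)
            done += chunk_epochs
            acc = np.mean(predict(model, x) == y)
            if acc >= 0.95:
                return acc
        return acc

    @pytest.mark.parametrize("name", ["dnn12", "dnn16", "dnn20", "dnn24"])
    def test_dnn_configs_fit_training_set(self, reduced_features, name):
        from croak.classifiers import build_model

        tr, x_train = reduced_features
        model = build_model(name, x_train.shape[1], output_dim=35, seed=0)
        acc = self._train_until(model, x_train, tr.species_labels, 100, 600)
        assert acc >= 0.95, f"{name}: train accuracy {acc:.3f}"

    @pytest.mark.parametrize("name", ["lstm200", "lstm300", "lstm500", "lstm700"])
    def test_lstm_configs_fit_training_set(self, reduced_features, name):
        from croak.classifiers import build_model

        tr, x_train = reduced_features
        model = build_model(name, x_train.shape[1], output_dim=35, seed=0)
        acc = self._train_until(model, x_train, tr.species_labels, 5, 30)
        assert acc >= 0.95, f"{name}: train accuracy {acc:.3f}"
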