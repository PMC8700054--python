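"""Architecture contracts, forward-pass arithmetic and gradient correctness."""

import numpy as np
import pytest

from croak.classifiers import (
    DNN_HIDDEN_LAYERS,
    DNNSpec,
    LSTMCellParams,
    LSTMSpec,
    LSTMState,
    build_dnn,
    build_lstm,
    build_model,
    default_seq_len,
    dnn_forward,
    lstm_cell_step,
    reshape_to_sequence,
)
from croak.training import softmax_cross_entropy


def _zero_cell(h, d):
    z = np.zeros
    return LSTMCellParams(
        M_xi=z((h, d)), M_xf=z((h, d)), M_xz=z((h, d)), M_xo=z((h, d)),
        M_hi=z((h, h)), M_hf=z((h, h)), M_hz=z((h, h)), M_ho=z((h, h)),
        b_i=z(h), b_f=z(h), b_z=z(h), b_o=z(h),
    )


def _numerical_grads(model, X, y, eps=1e-6):
    grads = []
    for p in model.params:
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        while not it.finished:
            ix = it.multi_index
            old = p[ix]
            p[ix] = old + eps
            l1, _ = softmax_cross_entropy(model.forward(X), y)
            p[ix] = old - eps
            l2, _ = softmax_cross_entropy(model.forward(X), y)
            p[ix] = old
            g[ix] = (l1 - l2) / (2 * eps)
            it.iternext()
        grads.append(g)
    return grads


class TestDNN:
    @pytest.mark.parametrize("depth", [12, 16, 20, 24])
    def test_named_depths_have_listed_widths_and_35_outputs(self, depth):
        model = build_model(f"dnn{depth}", 10240, seed=0)
        assert model.n_hidden_layers == depth
        widths = [w.shape[1] for w in model.params[0:-2:2]]
        assert widths == DNN_HIDDEN_LAYERS[depth]
        assert model.params[-2].shape[1] == 35

    def test_zero_weights_give_uniform_logits(self):
        model = build_dnn(DNNSpec(4, (3, 3), 5), seed=0)
        for p in model.params:
            p[...] = 0.0
        logits = model.forward(np.random.default_rng(0).normal(size=(6, 4)))
        assert np.allclose(logits, logits[0, 0])

    def test_sigmoid_of_zero_is_half(self):
        model = build_dnn(DNNSpec(1, (1,), 1), seed=0)
        for p in model.params:
            p[...] = 0.0
        model.forward(np.array([[3.0]]))
        hidden = model._cache[1]
        assert hidden[0, 0] == pytest.approx(0.5)

    def test_hand_computed_2_2_2_network(self):
        model = build_dnn(DNNSpec(2, (2,), 2), seed=0)
        w1 = np.array([[1.0, -1.0], [0.5, 0.25]])
        b1 = np.array([0.1, -0.1])
        w2 = np.array([[2.0, 0.0], [1.0, -1.0]])
        b2 = np.array([0.0, 0.5])
        model.params[0][...] = w1
        model.params[1][...] = b1
        model.params[2][...] = w2
        model.params[3][...] = b2
        x = np.array([0.3, -0.2])
        hidden = 1 / (1 + np.exp(-(x @ w1 + b1)))
        expected = hidden @ w2 + b2
        assert np.allclose(dnn_forward(model, x), expected, atol=1e-10)

    def test_output_weight_scaling_raises_class_logit(self, rng):
        model = build_dnn(DNNSpec(3, (4,), 3), seed=1)
        x = rng.normal(size=3)
        before = dnn_forward(model, x)[2]
        model.params[-2][:, 2] *= 2.0
        model.params[-2][:, 2] += 0.5
        after = dnn_forward(model, x)[2]
        assert after != before

    def test_distinct_biases_dominate_with_zero_weights(self, rng):
        model = build_dnn(DNNSpec(4, (3,), 4), seed=0)
        for p in model.params:
            p[...] = 0.0
        model.params[-1][...] = np.array([0.0, 2.0, -1.0, 0.5])
        logits = model.forward(rng.normal(size=(10, 4)))
        assert np.all(np.argmax(logits, axis=1) == 1)

    def test_gradients_match_finite_differences(self, rng):
        model = build_dnn(DNNSpec(6, (5, 4), 3), seed=1)
        X = rng.normal(size=(7, 6))
        y = rng.integers(1, 4, 7)
        _, dlogits = softmax_cross_entropy(model.forward(X), y)
        analytic = model.backward(dlogits)
        numeric = _numerical_grads(model, X, y)
        for a, n in zip(analytic, numeric):
            assert np.allclose(a, n, atol=1e-8)


class TestLSTMCell:
    def test_zero_params_halve_cell_state(self):
        params = _zero_cell(3, 2)
        c = np.array([1.0, -2.0, 0.5])
        state, (i, f, z, o) = lstm_cell_step(
            params, np.zeros(2), LSTMState(h=np.zeros(3), c=c)
        )
        assert np.allclose(i, 0.5) and np.allclose(f, 0.5) and np.allclose(o, 0.5)
        assert np.allclose(z, 0.0)
        assert np.allclose(state.c, 0.5 * c)
        assert np.allclose(state.h, 0.5 * np.tanh(0.5 * c))

    def test_zero_everything_stays_zero(self):
        params = _zero_cell(3, 2)
        state, _ = lstm_cell_step(
            params, np.zeros(2), LSTMState(h=np.zeros(3), c=np.zeros(3))
        )
        assert np.allclose(state.h, 0) and np.allclose(state.c, 0)

    def test_matches_independent_reference_cell(self, rng):
        """Hand-written reference computation of the gate equations."""
        h, d = 4, 3
        mats = {k: rng.normal(size=(h, d)) for k in ("xi", "xf", "xz", "xo")}
        rec = {k: rng.normal(size=(h, h)) for k in ("hi", "hf", "hz", "ho")}
        bias = {k: rng.normal(size=h) for k in ("i", "f", "z", "o")}
        params = LSTMCellParams(
            M_xi=mats["xi"], M_xf=mats["xf"], M_xz=mats["xz"], M_xo=mats["xo"],
            M_hi=rec["hi"], M_hf=rec["hf"], M_hz=rec["hz"], M_ho=rec["ho"],
            b_i=bias["i"], b_f=bias["f"], b_z=bias["z"], b_o=bias["o"],
        )
        x = rng.normal(size=d)
        h_prev, c_prev = rng.normal(size=h), rng.normal(size=h)
        state, (i, f, z, o) = lstm_cell_step(params, x, LSTMState(h_prev, c_prev))

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        i_ref = sig(mats["xi"] @ x + rec["hi"] @ h_prev + bias["i"])
        f_ref = sig(mats["xf"] @ x + rec["hf"] @ h_prev + bias["f"])
        z_ref = np.tanh(mats["xz"] @ x + rec["hz"] @ h_prev + bias["z"])
        o_ref = sig(mats["xo"] @ x + rec["ho"] @ h_prev + bias["o"])
        c_ref = c_prev * f_ref + i_ref * z_ref
        h_ref = o_ref * np.tanh(c_ref)
        assert np.allclose(state.c, c_ref, atol=1e-6)
        assert np.allclose(state.h, h_ref, atol=1e-6)
        assert np.allclose(i, i_ref) and np.allclose(f, f_ref)
        assert np.allclose(z, z_ref) and np.allclose(o, o_ref)

    def test_gate_ranges(self, rng):
        h, d = 5, 4
        params = LSTMCellParams(
            *(rng.normal(size=(h, d)) for _ in range(4)),
            *(rng.normal(size=(h, h)) for _ in range(4)),
            *(rng.normal(size=h) for _ in range(4)),
        )
        state, (i, f, z, o) = lstm_cell_step(
            params, rng.normal(size=d) * 3, LSTMState(rng.normal(size=h), rng.normal(size=h))
        )
        for g in (i, f, o):
            assert np.all((g > 0) & (g < 1))
        assert np.all((z > -1) & (z < 1))


class TestReshape:
    @pytest.mark.parametrize("length, t, d", [(10240, 40, 256), (200, 8, 25)])
    def test_layout(self, length, t, d):
        x = np.arange(length, dtype=float)
        seq = reshape_to_sequence(x, t)
        assert seq.shape == (t, d)
        assert np.array_equal(seq.ravel(), x)
        assert np.array_equal(seq[1], x[d : 2 * d])

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            reshape_to_sequence(np.arange(10), 3)

    def test_default_seq_len_convention(self):
        assert default_seq_len(10240) == 40
        assert default_seq_len(200) == 8


class TestLSTMClassifier:
    def test_shape_propagation_2x200(self):
        model = build_model("lstm200", 10240, seed=0)
        assert model.spec.seq_len == 40 and model.spec.input_dim == 256
        assert model.params[0].shape == (256, 800)  # layer-1 input weights
        assert model.params[3].shape == (200, 800)  # layer-2 input weights
        assert model.params[-2].shape == (200, 35)

    def test_forward_equals_unrolled_cell_steps(self, rng):
        spec = LSTMSpec(input_dim=3, hidden_size=4, seq_len=5, n_layers=2, output_dim=3)
        model = build_lstm(spec, seed=3)
        x = rng.normal(size=15)
        logits = model.forward(x)[0]
        seq = reshape_to_sequence(x, 5)
        states = [LSTMState(np.zeros(4), np.zeros(4)) for _ in range(2)]
        out = None
        for t in range(5):
            xt = seq[t]
            for layer in range(2):
                states[layer], _ = lstm_cell_step(model.cell_params(layer), xt, states[layer])
                xt = states[layer].h
            out = xt
        manual = out @ model.params[-2] + model.params[-1]
        assert np.allclose(manual, logits, atol=1e-12)

    def test_deterministic_in_seed(self, rng):
        X = rng.normal(size=(4, 15))
        spec = LSTMSpec(input_dim=3, hidden_size=4, seq_len=5, output_dim=3)
        a = build_lstm(spec, seed=9).forward(X)
        b = build_lstm(spec, seed=9).forward(X)
        assert np.array_equal(a, b)

    def test_gradients_match_finite_differences(self, rng):
        spec = LSTMSpec(input_dim=3, hidden_size=4, seq_len=5, n_layers=2, output_dim=3)
        model = build_lstm(spec, seed=2)
        X = rng.normal(size=(6, 15))
        y = rng.integers(1, 4, 6)
        _, dlogits = softmax_cross_entropy(model.forward(X), y)
        analytic = model.backward(dlogits)
        numeric = _numerical_grads(model, X, y)
        for a, n in zip(analytic, numeric):
            assert np.allclose(a, n, atol=1e-8)

    def test_input_length_mismatch_rejected(self):
        model = build_model("lstm200", 10240, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 100)))


def test_unknown_model_names_rejected():
    with pytest.raises(ValueError):
        build_model("dnn13", 100)
    with pytest.raises(ValueError):
        build_model("cnn", 100)
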