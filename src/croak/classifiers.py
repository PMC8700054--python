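"""DNN and LSTM classifiers implemented from their defining equations.

Two families, both ending in a 35-way (configurable) affine output:

* Fully connected stacks with logistic-sigmoid hidden units.  Four named
  depths — 12, 16, 20 and 24 hidden layers — with the fixed width lists in
  :data:`DNN_HIDDEN_LAYERS`.
* Two-layer LSTMs with 200/300/500/700 hidden units.  The cell follows the
  standard gate equations
      i_t = sigma(M_xi x_t + M_hi h_{t-1} + b_i)
      f_t = sigma(M_xf x_t + M_hf h_{t-1} + b_f)
      z_t = tanh (M_xz x_t + M_hz h_{t-1} + b_z)
      c_t = c_{t-1} * f_t + i_t * z_t
      o_t = sigma(M_xo x_t + M_ho h_{t-1} + b_o)
      h_t = o_t * tanh(c_t)
  with zero initial state; the class label is read from the top layer's
  final hidden state through an affine map.

Forward passes and backpropagation (including truncation-free BPTT for the
LSTM) are written directly in NumPy; gradients are verified against finite
differences in the test suite.  A feature vector enters the LSTM as a T x D
sequence via :func:`reshape_to_sequence` (T = 40 for raw length-10240
features, T = 8 for 200-dimensional PCA scores by default).

Model parameters are exposed as a flat list of arrays (``model.params``)
that the optimizer updates in place; ``model.backward`` returns gradients
aligned with that list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

DEFAULT_OUTPUT_DIM = 35

#: Hidden-layer width lists of the four named DNN depths.
DNN_HIDDEN_LAYERS: dict[int, list[int]] = {
    12: [50, 80, 100, 120, 180, 200, 200, 180, 120, 100, 80, 50],
    16: [50, 80, 100, 120, 180, 200, 240, 300, 300, 240, 200, 180, 120, 100, 80, 50],
    20: [50, 80, 100, 120, 180, 200, 240, 300, 320, 360,
         360, 320, 300, 240, 200, 180, 120, 100, 80, 50],
    24: [50, 80, 100, 120, 180, 200, 240, 300, 320, 360, 400, 480,
         480, 400, 360, 320, 300, 240, 200, 180, 120, 100, 80, 50],
}

#: Hidden sizes of the four named two-layer LSTMs.
LSTM_HIDDEN_SIZES = (200, 300, 500, 700)

MODEL_NAMES = tuple(f"dnn{d}" for d in sorted(DNN_HIDDEN_LAYERS)) + tuple(
    f"lstm{h}" for h in LSTM_HIDDEN_SIZES
)


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class DNNSpec:
    input_dim: int
    hidden_widths: tuple[int, ...]
    output_dim: int = DEFAULT_OUTPUT_DIM

    def __post_init__(self) -> None:
        if not self.hidden_widths:
            raise ValueError("hidden_widths must be non-empty")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("all hidden widths must be >= 1")
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))


@dataclass(frozen=True)
class LSTMSpec:
    input_dim: int  # D, per-step input width
    hidden_size: int  # H
    seq_len: int  # T
    n_layers: int = 2
    output_dim: int = DEFAULT_OUTPUT_DIM

    def __post_init__(self) -> None:
        if self.seq_len < 1 or self.input_dim < 1:
            raise ValueError("seq_len and input_dim must be >= 1")
        if self.hidden_size < 1 or self.n_layers < 1:
            raise ValueError("hidden_size and n_layers must be >= 1")

    @property
    def feature_len(self) -> int:
        return self.seq_len * self.input_dim


@dataclass(frozen=True)
class LSTMCellParams:
    """Per-gate weight view of one LSTM layer (input, forget, cell, output)."""

    M_xi: np.ndarray
    M_xf: np.ndarray
    M_xz: np.ndarray
    M_xo: np.ndarray
    M_hi: np.ndarray
    M_hf: np.ndarray
    M_hz: np.ndarray
    M_ho: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_z: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.M_xi.shape
        for name in ("M_xf", "M_xz", "M_xo"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must have shape {(h, d)}")
        for name in ("M_hi", "M_hf", "M_hz", "M_ho"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")
        for name in ("b_i", "b_f", "b_z", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape {(h,)}")


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


def lstm_cell_step(
    params: LSTMCellParams, x_t: np.ndarray, state: LSTMState
) -> tuple[LSTMState, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """One cell update; returns the new state and the gates (i, f, z, o)."""
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape[-1] != params.M_xi.shape[1]:
        raise ValueError(
            f"x_t has width {x_t.shape[-1]}, cell expects {params.M_xi.shape[1]}"
        )
    h_prev, c_prev = state.h, state.c
    i = sigmoid(params.M_xi @ x_t + params.M_hi @ h_prev + params.b_i)
    f = sigmoid(params.M_xf @ x_t + params.M_hf @ h_prev + params.b_f)
    z = np.tanh(params.M_xz @ x_t + params.M_hz @ h_prev + params.b_z)
    o = sigmoid(params.M_xo @ x_t + params.M_ho @ h_prev + params.b_o)
    c = c_prev * f + i * z
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c), (i, f, z, o)


def reshape_to_sequence(x: np.ndarray, seq_len: int) -> np.ndarray:
    """View a length-(T*D) feature vector as a T x D step sequence."""
    x = np.asarray(x)
    if x.shape[-1] % seq_len != 0:
        raise ValueError(
            f"feature length {x.shape[-1]} is not divisible by seq_len {seq_len}; "
            "pad the vector or pick a divisor"
        )
    return x.reshape(*x.shape[:-1], seq_len, x.shape[-1] // seq_len)


def default_seq_len(feature_len: int) -> int:
    """Sequence layout convention: 40 steps for long raw features (10240 ->
    40 x 256), 8 steps for short PCA-score vectors (200 -> 8 x 25)."""
    if feature_len >= 1280 and feature_len % 40 == 0:
        return 40
    if feature_len % 8 == 0:
        return 8
    for t in range(min(40, feature_len), 0, -1):
        if feature_len % t == 0:
            return t
    raise ValueError(f"no valid sequence length for feature_len={feature_len}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Random matrix with orthonormal columns (or rows if wide)."""
    u, _, vt = np.linalg.svd(rng.normal(size=shape), full_matrices=False)
    return u @ vt


# ---------------------------------------------------------------------------
# DNN


class MLPClassifier:
    """Sigmoid-hidden fully connected stack with an affine output layer."""

    def __init__(self, spec: DNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim, *spec.hidden_widths, spec.output_dim]
        self.params: list[np.ndarray] = []
        n_maps = len(dims) - 1
        for layer, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            if layer < n_maps - 1:
                # scaled-orthogonal init for the sigmoid stack: the logistic
                # slope at 0 is 1/4, so a gain of 4 makes the layer Jacobian
                # isometric at initialization; the extra 1.5 keeps the
                # deepest stacks (20-24 layers) just above the attenuation
                # threshold so gradients survive to the bottom
                w = _orthogonal(rng, (d_in, d_out)) * 6.0
            else:
                w = _glorot(rng, d_in, d_out, (d_in, d_out))
            # layers fed by sigmoid outputs see inputs with mean ~0.5;
            # center each unit's pre-activation so the stack starts
            # unsaturated instead of pinned at the rails
            b = -0.5 * w.sum(axis=0) if layer > 0 else np.zeros(d_out)
            self.params.append(w)
            self.params.append(b)
        self._cache: list[np.ndarray] | None = None

    @property
    def n_hidden_layers(self) -> int:
        return len(self.spec.hidden_widths)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects {self.spec.input_dim}"
            )
        activations = [X]
        a = X
        n_layers = len(self.params) // 2
        for layer in range(n_layers):
            w, b = self.params[2 * layer], self.params[2 * layer + 1]
            pre = a @ w + b
            a = pre if layer == n_layers - 1 else sigmoid(pre)
            activations.append(a)
        self._cache = activations
        return a

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. every parameter, aligned with ``self.params``."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        activations = self._cache
        n_layers = len(self.params) // 2
        grads: list[np.ndarray] = [np.empty(0)] * len(self.params)
        delta = np.asarray(dlogits, dtype=np.float64)
        for layer in range(n_layers - 1, -1, -1):
            a_in = activations[layer]
            grads[2 * layer] = a_in.T @ delta
            grads[2 * layer + 1] = delta.sum(axis=0)
            if layer > 0:
                a_prev_out = activations[layer]  # sigmoid output of layer-1
                w = self.params[2 * layer]
                delta = (delta @ w.T) * a_prev_out * (1.0 - a_prev_out)
        return grads


def build_dnn(spec: DNNSpec, seed: int = 0) -> MLPClassifier:
    return MLPClassifier(spec, seed=seed)


def dnn_forward(model: MLPClassifier, x: np.ndarray) -> np.ndarray:
    """Logits for a single feature vector (or a batch of rows)."""
    out = model.forward(x)
    return out[0] if np.asarray(x).ndim == 1 else out


# ---------------------------------------------------------------------------
# LSTM

_GATES = slice(None)  # packed gate order along the 4H axis: i, f, z, o


class LSTMClassifier:
    """Stacked LSTM over a T x D sequence view of each feature vector.

    Per layer the four gate blocks are packed into single matrices
    Wx (D_l x 4H), Wh (H x 4H) and bias b (4H), gate order i, f, z, o;
    :meth:`cell_params` exposes the per-gate view.  Classification reads
    the top layer's final hidden state through an affine output map.
    """

    def __init__(self, spec: LSTMSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        h = spec.hidden_size
        self.params: list[np.ndarray] = []
        d_in = spec.input_dim
        for _ in range(spec.n_layers):
            self.params.append(_glorot(rng, d_in, h, (d_in, 4 * h)))
            self.params.append(_glorot(rng, h, h, (h, 4 * h)))
            self.params.append(np.zeros(4 * h))
            d_in = h
        self.params.append(_glorot(rng, h, spec.output_dim, (h, spec.output_dim)))
        self.params.append(np.zeros(spec.output_dim))
        self._cache = None

    def _layer_params(self, layer: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.params[3 * layer],
            self.params[3 * layer + 1],
            self.params[3 * layer + 2],
        )

    def cell_params(self, layer: int) -> LSTMCellParams:
        """Per-gate view of one layer's packed weights (shares memory)."""
        wx, wh, b = self._layer_params(layer)
        h = self.spec.hidden_size
        blocks = [slice(k * h, (k + 1) * h) for k in range(4)]
        return LSTMCellParams(
            M_xi=wx[:, blocks[0]].T, M_xf=wx[:, blocks[1]].T,
            M_xz=wx[:, blocks[2]].T, M_xo=wx[:, blocks[3]].T,
            M_hi=wh[:, blocks[0]].T, M_hf=wh[:, blocks[1]].T,
            M_hz=wh[:, blocks[2]].T, M_ho=wh[:, blocks[3]].T,
            b_i=b[blocks[0]], b_f=b[blocks[1]], b_z=b[blocks[2]], b_o=b[blocks[3]],
        )

    def forward(self, X: np.ndarray) -> np.ndarray:
        spec = self.spec
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != spec.feature_len:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects "
                f"{spec.feature_len} (= {spec.seq_len} x {spec.input_dim})"
            )
        seq = reshape_to_sequence(X, spec.seq_len)  # N x T x D
        n, t_len, _ = seq.shape
        h_size = spec.hidden_size
        layer_caches = []
        inputs = np.swapaxes(seq, 0, 1)  # T x N x D
        for layer in range(spec.n_layers):
            wx, wh, b = self._layer_params(layer)
            h = np.zeros((n, h_size))
            c = np.zeros((n, h_size))
            gates_i = np.empty((t_len, n, h_size))
            gates_f = np.empty((t_len, n, h_size))
            gates_z = np.empty((t_len, n, h_size))
            gates_o = np.empty((t_len, n, h_size))
            cells = np.empty((t_len, n, h_size))
            hs = np.empty((t_len, n, h_size))
            c_prevs = np.empty((t_len, n, h_size))
            for t in range(t_len):
                g = inputs[t] @ wx + h @ wh + b
                i = sigmoid(g[:, :h_size])
                f = sigmoid(g[:, h_size : 2 * h_size])
                z = np.tanh(g[:, 2 * h_size : 3 * h_size])
                o = sigmoid(g[:, 3 * h_size :])
                c_prevs[t] = c
                c = c * f + i * z
                h = o * np.tanh(c)
                gates_i[t], gates_f[t], gates_z[t], gates_o[t] = i, f, z, o
                cells[t], hs[t] = c, h
            layer_caches.append(
                dict(inputs=inputs, i=gates_i, f=gates_f, z=gates_z, o=gates_o,
                     c=cells, c_prev=c_prevs, h=hs)
            )
            inputs = hs
        w_out, b_out = self.params[-2], self.params[-1]
        h_final = layer_caches[-1]["h"][-1]
        logits = h_final @ w_out + b_out
        self._cache = (layer_caches, h_final, n, t_len)
        return logits

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        layer_caches, h_final, n, t_len = self._cache
        spec = self.spec
        h_size = spec.hidden_size
        dlogits = np.asarray(dlogits, dtype=np.float64)
        grads: list[np.ndarray] = [np.zeros_like(p) for p in self.params]
        w_out = self.params[-2]
        grads[-2] = h_final.T @ dlogits
        grads[-1] = dlogits.sum(axis=0)
        # upstream gradient on each layer's output sequence (T x N x H)
        d_out_seq = np.zeros((t_len, n, h_size))
        d_out_seq[-1] = dlogits @ w_out.T
        for layer in range(spec.n_layers - 1, -1, -1):
            cache = layer_caches[layer]
            wx, wh, _ = self._layer_params(layer)
            d_in_dim = wx.shape[0]
            d_inputs = np.zeros((t_len, n, d_in_dim))
            dwx, dwh = grads[3 * layer], grads[3 * layer + 1]
            db = grads[3 * layer + 2]
            dh_next = np.zeros((n, h_size))
            dc_next = np.zeros((n, h_size))
            for t in range(t_len - 1, -1, -1):
                i, f, z, o = cache["i"][t], cache["f"][t], cache["z"][t], cache["o"][t]
                c, c_prev = cache["c"][t], cache["c_prev"][t]
                tanh_c = np.tanh(c)
                dh = d_out_seq[t] + dh_next
                dc = dc_next + dh * o * (1.0 - tanh_c**2)
                dg = np.empty((n, 4 * h_size))
                dg[:, :h_size] = dc * z * i * (1.0 - i)  # input gate
                dg[:, h_size : 2 * h_size] = dc * c_prev * f * (1.0 - f)  # forget
                dg[:, 2 * h_size : 3 * h_size] = dc * i * (1.0 - z**2)  # cell cand.
                dg[:, 3 * h_size :] = dh * tanh_c * o * (1.0 - o)  # output gate
                x_t = cache["inputs"][t]
                h_prev = cache["h"][t - 1] if t > 0 else np.zeros((n, h_size))
                dwx += x_t.T @ dg
                dwh += h_prev.T @ dg
                db += dg.sum(axis=0)
                d_inputs[t] = dg @ wx.T
                dh_next = dg @ wh.T
                dc_next = dc * f
            d_out_seq = d_inputs  # becomes upstream for the layer below
        return grads


def build_lstm(spec: LSTMSpec, seed: int = 0) -> LSTMClassifier:
    return LSTMClassifier(spec, seed=seed)


def build_model(
    name: str,
    feature_len: int,
    output_dim: int = DEFAULT_OUTPUT_DIM,
    seed: int = 0,
    seq_len: int | None = None,
):
    """Build any named model ('dnn12'..'dnn24', 'lstm200'..'lstm700')."""
    name = name.lower()
    if name.startswith("dnn"):
        depth = int(name[3:])
        if depth not in DNN_HIDDEN_LAYERS:
            raise ValueError(f"unknown DNN depth {depth}; have {sorted(DNN_HIDDEN_LAYERS)}")
        spec = DNNSpec(feature_len, tuple(DNN_HIDDEN_LAYERS[depth]), output_dim)
        return build_dnn(spec, seed=seed)
    if name.startswith("lstm"):
        hidden = int(name[4:])
        if hidden not in LSTM_HIDDEN_SIZES:
            raise ValueError(f"unknown LSTM size {hidden}; have {LSTM_HIDDEN_SIZES}")
        t = seq_len if seq_len is not None else default_seq_len(feature_len)
        spec = LSTMSpec(
            input_dim=feature_len // t, hidden_size=hidden, seq_len=t,
            output_dim=output_dim,
        )
        return build_lstm(spec, seed=seed)
    raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")


__all__ = [
    "DEFAULT_OUTPUT_DIM",
    "DNN_HIDDEN_LAYERS",
    "LSTM_HIDDEN_SIZES",
    "MODEL_NAMES",
    "DNNSpec",
    "LSTMSpec",
    "LSTMCellParams",
    "LSTMState",
    "lstm_cell_step",
    "reshape_to_sequence",
    "default_seq_len",
    "MLPClassifier",
    "LSTMClassifier",
    "build_dnn",
    "build_lstm",
    "build_model",
    "dnn_forward",
]
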