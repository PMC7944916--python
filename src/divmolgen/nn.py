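"""Minimal NumPy neural-network core for the sequence models.

Implements exactly what the generator and QSAR predictor need: stacked
LSTM/GRU layers with full backpropagation through time, an embedding
layer, dense layers, inverted dropout, elementwise gradient clipping and
the Adam optimizer. Parameters and gradients are plain ``dict[str,
ndarray]`` keyed by layer name, which keeps checkpointing (``np.savez``)
and optimizer state trivial.

Conventions: batches are (B, T) integer token ids or (B, T, D) float
features; hidden states are (B, H). LSTM gates are ordered i, f, g, o;
GRU gates z, r, n with h_t = (1 - z) * n + z * h_{t-1}.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def clip_gradients(grads: Params, bound: float) -> Params:
    """Elementwise clip of every gradient array to [-bound, bound]."""
    return {k: np.clip(g, -bound, bound) for k, g in grads.items()}


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: Params = {}
        self._v: Params = {}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            if key not in self._m:
                self._m[key] = np.zeros_like(g)
                self._v[key] = np.zeros_like(g)
            self._m[key] = b1 * self._m[key] + (1 - b1) * g
            self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            m_hat = self._m[key] / (1 - b1 ** self.t)
            v_hat = self._v[key] / (1 - b2 ** self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Recurrent stacks
# ---------------------------------------------------------------------------

class LSTMStack:
    """Stacked LSTM layers with dropout between layers.

    Parameter keys: ``lstm{l}_W`` of shape (D_in + H, 4H) and ``lstm{l}_b``
    of shape (4H,) for layer l. The forget-gate bias is initialized to 1.
    """

    def __init__(self, input_dim: int, hidden: int, layers: int,
                 dropout: float, rng: np.random.Generator) -> None:
        self.input_dim = input_dim
        self.hidden = hidden
        self.layers = layers
        self.dropout = dropout
        self.params: Params = {}
        for l in range(layers):
            d_in = input_dim if l == 0 else hidden
            self.params[f"lstm{l}_W"] = glorot(rng, (d_in + hidden, 4 * hidden))
            b = np.zeros(4 * hidden)
            b[hidden: 2 * hidden] = 1.0
            self.params[f"lstm{l}_b"] = b

    def init_state(self, batch: int) -> list[tuple[np.ndarray, np.ndarray]]:
        H = self.hidden
        return [(np.zeros((batch, H)), np.zeros((batch, H)))
                for _ in range(self.layers)]

    def step(self, x: np.ndarray,
             state: list[tuple[np.ndarray, np.ndarray]]
             ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]], list]:
        """One timestep through all layers (no dropout — inference path)."""
        H = self.hidden
        new_state = []
        caches = []
        inp = x
        for l in range(self.layers):
            h_prev, c_prev = state[l]
            W = self.params[f"lstm{l}_W"]
            b = self.params[f"lstm{l}_b"]
            xh = np.concatenate([inp, h_prev], axis=1)
            z = xh @ W + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            caches.append((xh, i, f, g, o, c_prev, tc))
            new_state.append((h, c))
            inp = h
        return inp, new_state, caches

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, dict]:
        """Full-sequence forward. x: (B, T, D_in) -> (B, T, H).

        With ``train=True`` inverted dropout masks (one per layer junction,
        shared across time) are applied to each layer's output.
        """
        B, T, _ = x.shape
        H = self.hidden
        state = self.init_state(B)
        caches: list[list] = []
        outputs = np.empty((B, T, H))
        masks = []
        if train and self.dropout > 0:
            assert rng is not None
            keep = 1.0 - self.dropout
            masks = [(rng.random((B, H)) < keep) / keep
                     for _ in range(self.layers)]
        layer_inputs = x
        # iterate layer-major so the dropout mask applies to a whole layer
        all_caches = []
        for l in range(self.layers):
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            W = self.params[f"lstm{l}_W"]
            b = self.params[f"lstm{l}_b"]
            layer_cache = []
            layer_out = np.empty((B, T, H))
            for t in range(T):
                xh = np.concatenate([layer_inputs[:, t, :], h], axis=1)
                z = xh @ W + b
                i = sigmoid(z[:, :H])
                f = sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = sigmoid(z[:, 3 * H:])
                c_prev = c
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h = o * tc
                layer_cache.append((xh, i, f, g, o, c_prev, tc))
                layer_out[:, t, :] = h
            dropped = layer_out
            if masks:
                dropped = layer_out * masks[l][:, None, :]
            all_caches.append((layer_cache, layer_inputs))
            layer_inputs = dropped
            outputs = dropped
        cache = {"caches": all_caches, "masks": masks, "T": T, "B": B}
        return outputs, cache

    def backward(self, d_out: np.ndarray, cache: dict
                 ) -> tuple[Params, np.ndarray]:
        """BPTT. d_out: gradient wrt the stack output at every timestep.

        Returns (parameter grads, gradient wrt the stack input x).
        """
        H = self.hidden
        B, T = cache["B"], cache["T"]
        masks = cache["masks"]
        grads: Params = {k: np.zeros_like(v) for k, v in self.params.items()}
        d_layer_out = d_out
        d_input = None
        for l in range(self.layers - 1, -1, -1):
            layer_cache, layer_inputs = cache["caches"][l]
            W = self.params[f"lstm{l}_W"]
            dW = grads[f"lstm{l}_W"]
            db = grads[f"lstm{l}_b"]
            if masks:
                d_layer_out = d_layer_out * masks[l][:, None, :]
            d_in_dim = layer_inputs.shape[2]
            d_input = np.zeros((B, T, d_in_dim))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                xh, i, f, g, o, c_prev, tc = layer_cache[t]
                dh = d_layer_out[:, t, :] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate([
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ], axis=1)
                dW += xh.T @ dz
                db += dz.sum(axis=0)
                dxh = dz @ W.T
                d_input[:, t, :] = dxh[:, :d_in_dim]
                dh_next = dxh[:, d_in_dim:]
            d_layer_out = d_input
        return grads, d_input


class GRUStack:
    """Stacked GRU layers (no inter-layer dropout; QSAR model path).

    Parameter keys per layer l: ``gru{l}_W`` (D_in, 3H), ``gru{l}_U``
    (H, 3H), ``gru{l}_b`` (3H,). Gate order z, r, n;
    n = tanh(x W_n + (r * h_prev) U_n + b_n).
    """

    def __init__(self, input_dim: int, hidden: int, layers: int,
                 rng: np.random.Generator) -> None:
        self.input_dim = input_dim
        self.hidden = hidden
        self.layers = layers
        self.params: Params = {}
        for l in range(layers):
            d_in = input_dim if l == 0 else hidden
            self.params[f"gru{l}_W"] = glorot(rng, (d_in, 3 * hidden))
            self.params[f"gru{l}_U"] = glorot(rng, (hidden, 3 * hidden))
            self.params[f"gru{l}_b"] = np.zeros(3 * hidden)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """x: (B, T, D_in) -> outputs (B, T, H) of the top layer."""
        B, T, _ = x.shape
        H = self.hidden
        all_caches = []
        layer_inputs = x
        outputs = None
        for l in range(self.layers):
            W = self.params[f"gru{l}_W"]
            U = self.params[f"gru{l}_U"]
            b = self.params[f"gru{l}_b"]
            h = np.zeros((B, H))
            layer_cache = []
            layer_out = np.empty((B, T, H))
            for t in range(T):
                xt = layer_inputs[:, t, :]
                xw = xt @ W + b
                hu = h @ U
                z = sigmoid(xw[:, :H] + hu[:, :H])
                r = sigmoid(xw[:, H:2 * H] + hu[:, H:2 * H])
                rh = r * h
                n = np.tanh(xw[:, 2 * H:] + rh @ U[:, 2 * H:])
                h_prev = h
                h = (1.0 - z) * n + z * h_prev
                layer_cache.append((xt, h_prev, z, r, n, rh))
                layer_out[:, t, :] = h
            all_caches.append((layer_cache, layer_inputs))
            layer_inputs = layer_out
            outputs = layer_out
        return outputs, {"caches": all_caches, "B": B, "T": T}

    def backward(self, d_out: np.ndarray, cache: dict
                 ) -> tuple[Params, np.ndarray]:
        H = self.hidden
        B, T = cache["B"], cache["T"]
        grads: Params = {k: np.zeros_like(v) for k, v in self.params.items()}
        d_layer_out = d_out
        d_input = None
        for l in range(self.layers - 1, -1, -1):
            layer_cache, layer_inputs = cache["caches"][l]
            W = self.params[f"gru{l}_W"]
            U = self.params[f"gru{l}_U"]
            dW = grads[f"gru{l}_W"]
            dU = grads[f"gru{l}_U"]
            db = grads[f"gru{l}_b"]
            d_in_dim = layer_inputs.shape[2]
            d_input = np.zeros((B, T, d_in_dim))
            dh_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                xt, h_prev, z, r, n, rh = layer_cache[t]
                dh = d_layer_out[:, t, :] + dh_next
                dz = dh * (h_prev - n)
                dn = dh * (1.0 - z)
                dh_prev = dh * z
                dn_pre = dn * (1.0 - n * n)
                dz_pre = dz * z * (1.0 - z)
                # n-gate pieces
                drh = dn_pre @ U[:, 2 * H:].T
                dr = drh * h_prev
                dh_prev += drh * r
                dr_pre = dr * r * (1.0 - r)
                # accumulate parameter grads
                dxw = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
                dW += xt.T @ dxw
                db += dxw.sum(axis=0)
                dU[:, :2 * H] += h_prev.T @ np.concatenate([dz_pre, dr_pre], axis=1)
                dU[:, 2 * H:] += rh.T @ dn_pre
                # downstream grads
                d_input[:, t, :] = dxw @ W.T
                dh_prev += np.concatenate([dz_pre, dr_pre], axis=1) @ U[:, :2 * H].T
                dh_next = dh_prev
            d_layer_out = d_input
        return grads, d_input


# ---------------------------------------------------------------------------
# Dense / embedding layers
# ---------------------------------------------------------------------------

class Dense:
    """Affine layer y = x W + b with optional ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str, relu: bool = False) -> None:
        self.name = name
        self.relu = relu
        self.params: Params = {
            f"{name}_W": glorot(rng, (d_in, d_out)),
            f"{name}_b": np.zeros(d_out),
        }

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        y = x @ self.params[f"{self.name}_W"] + self.params[f"{self.name}_b"]
        cache = {"x": x}
        if self.relu:
            cache["pre"] = y
            y = np.maximum(y, 0.0)
        return y, cache

    def backward(self, dy: np.ndarray, cache: dict) -> tuple[Params, np.ndarray]:
        if self.relu:
            dy = dy * (cache["pre"] > 0)
        x = cache["x"]
        W = self.params[f"{self.name}_W"]
        flat_x = x.reshape(-1, x.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        grads = {
            f"{self.name}_W": flat_x.T @ flat_dy,
            f"{self.name}_b": flat_dy.sum(axis=0),
        }
        return grads, dy @ W.T


class Embedding:
    """Token-id -> dense-vector lookup."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator,
                 name: str = "emb") -> None:
        self.name = name
        self.params: Params = {
            f"{name}_W": rng.normal(0.0, 0.1, size=(vocab_size, dim)),
        }

    def forward(self, ids: np.ndarray) -> tuple[np.ndarray, dict]:
        return self.params[f"{self.name}_W"][ids], {"ids": ids}

    def backward(self, dvec: np.ndarray, cache: dict) -> Params:
        dW = np.zeros_like(self.params[f"{self.name}_W"])
        np.add.at(dW, cache["ids"].reshape(-1),
                  dvec.reshape(-1, dvec.shape[-1]))
        return {f"{self.name}_W": dW}
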