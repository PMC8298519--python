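"""A small NumPy neural-network stack for sequence classification.

Implements exactly the architecture the task recognizer needs: a
single-layer LSTM read out at the final timestep, inverted dropout, a dense
ReLU layer and a softmax output, trained with Adam on categorical
cross-entropy.  Forward, backward (backpropagation through time) and the
optimizer are written against float32 BLAS matmuls, which keeps a
100-unit/100-step model trainable on one CPU core in seconds per epoch.

The implementation is deliberately self-contained and deterministic: all
randomness (initialization, batch shuffling, dropout masks) flows from one
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DTYPE = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class LSTMClassifier:
    """LSTM(H) -> dropout -> Dense(D, ReLU) -> softmax(C) on (B, T, F) inputs."""

    n_features: int
    lstm_units: int
    dense_units: int
    n_classes: int
    dropout_rate: float = 0.5

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        F, H, D, C = self.n_features, self.lstm_units, self.dense_units, self.n_classes

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape).astype(DTYPE)

        b_lstm = np.zeros(4 * H, dtype=DTYPE)
        b_lstm[H : 2 * H] = 1.0  # forget-gate bias at 1 stabilizes early training
        return {
            "Wx": glorot((F, 4 * H)),
            "Wh": glorot((H, 4 * H)),
            "b": b_lstm,
            "W1": glorot((H, D)),
            "b1": np.zeros(D, dtype=DTYPE),
            "W2": glorot((D, C)),
            "b2": np.zeros(C, dtype=DTYPE),
        }

    # -- forward -----------------------------------------------------------

    def _lstm_forward(self, params, X):
        """Run the LSTM over (B, T, F); returns final h and the BPTT cache."""
        B, T, F = X.shape
        H = self.lstm_units
        Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
        # input contributions for every timestep in one matmul
        pre_x = X.reshape(B * T, F) @ Wx
        pre_x = pre_x.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            z = pre_x[:, t, :] + h @ Wh + b
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h, cache

    def forward(self, params, X, rng=None, train=False):
        """Forward pass; returns (probs, cache). Dropout only when training."""
        h_last, lstm_cache = self._lstm_forward(params, X)
        if train and self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(h_last.shape) < keep).astype(DTYPE) / DTYPE(keep)
        else:
            mask = np.ones_like(h_last)
        h_drop = h_last * mask
        a1 = h_drop @ params["W1"] + params["b1"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ params["W2"] + params["b2"]
        probs = softmax(logits.astype(np.float64)).astype(DTYPE)
        cache = (X, lstm_cache, h_last, mask, h_drop, a1, r1)
        return probs, cache

    # -- backward ----------------------------------------------------------

    def backward(self, params, probs, y_onehot, cache):
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        X, lstm_cache, h_last, mask, h_drop, a1, r1 = cache
        B, T, F = X.shape
        H = self.lstm_units
        Wx, Wh = params["Wx"], params["Wh"]

        dlogits = (probs - y_onehot) / DTYPE(B)
        grads = {
            "W2": r1.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dr1 = dlogits @ params["W2"].T
        da1 = dr1 * (a1 > 0)
        grads["W1"] = h_drop.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dh = (da1 @ params["W1"].T) * mask  # gradient into the final hidden state

        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(params["b"])
        dpre_x = np.zeros((B, T, 4 * H), dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = lstm_cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.empty((B, 4 * H), dtype=DTYPE)
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dpre_x[:, t, :] = dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ Wh.T
            dc = dc * f
        grads["Wx"] = X.reshape(B * T, F).T @ dpre_x.reshape(B * T, 4 * H)
        grads["Wh"] = dWh
        grads["b"] = db
        return grads


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(DTYPE)


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    p = np.clip(probs.astype(np.float64), 1e-12, 1.0)
    return float(-np.mean(np.sum(y_onehot * np.log(p), axis=1)))


def train_classifier(
    model: LSTMClassifier,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    lr: float = 1e-3,
) -> dict[str, np.ndarray]:
    """Train with Adam on categorical cross-entropy; returns the parameters."""
    X = X.astype(DTYPE)
    n, C = len(X), model.n_classes
    y_onehot = np.eye(C, dtype=DTYPE)[y]
    params = model.init_params(rng)
    opt = Adam(params, lr=lr)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            probs, cache = model.forward(params, X[idx], rng=rng, train=True)
            grads = model.backward(params, probs, y_onehot[idx], cache)
            opt.step(params, grads)
    return params


def predict_proba(model: LSTMClassifier, params, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    X = X.astype(DTYPE)
    chunks = []
    for start in range(0, len(X), batch_size):
        probs, _ = model.forward(params, X[start : start + batch_size], train=False)
        chunks.append(probs.astype(np.float64))
    return np.concatenate(chunks, axis=0)
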