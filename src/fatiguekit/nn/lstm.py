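"""A single-layer LSTM binary classifier with manual BPTT.

Input is a batch of sequences shaped (N, T, D); the final hidden state
feeds a 1-logit dense head. Gates use the usual [input, forget, cell,
output] block layout in one combined weight matrix; the forget-gate bias
is initialised to 1 so early training does not wash out the cell state.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidDataError
from .core import Adam, DTYPE, bce_with_logits, sigmoid


class LSTMClassifier:
    def __init__(self, n_features: int, hidden_size: int = 32, seed: int = 0):
        self.n_features = n_features
        self.hidden_size = hidden_size
        rng = np.random.default_rng(seed)
        d, h = n_features, hidden_size
        scale = 1.0 / np.sqrt(d + h)
        self.w = rng.normal(0.0, scale, (d + h, 4 * h)).astype(DTYPE)
        self.b = np.zeros(4 * h, dtype=DTYPE)
        self.b[h : 2 * h] = 1.0  # forget gate
        self.wo = rng.normal(0.0, 1.0 / np.sqrt(h), (h, 1)).astype(DTYPE)
        self.bo = np.zeros(1, dtype=DTYPE)
        self.params = [self.w, self.b, self.wo, self.bo]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache: dict | None = None

    def forward_logits(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        x = x.astype(DTYPE, copy=False)
        n, t, d = x.shape
        h_size = self.hidden_size
        h = np.zeros((n, h_size), dtype=DTYPE)
        c = np.zeros((n, h_size), dtype=DTYPE)
        steps = []
        for ti in range(t):
            z = np.concatenate([x[:, ti], h], axis=1)
            a = z @ self.w + self.b
            i = sigmoid(a[:, :h_size])
            f = sigmoid(a[:, h_size : 2 * h_size])
            g = np.tanh(a[:, 2 * h_size : 3 * h_size])
            o = sigmoid(a[:, 3 * h_size :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            if keep_cache:
                steps.append((z, i, f, g, o, c_prev, tanh_c))
        logits = (h @ self.wo + self.bo).reshape(-1)
        if keep_cache:
            self._cache = {"steps": steps, "h_last": h}
        return logits

    def _backward(self, grad: np.ndarray) -> None:
        cache = self._cache
        steps = cache["steps"]
        h_size = self.hidden_size
        d = self.n_features
        grad = grad.reshape(-1, 1).astype(DTYPE)

        for g_ in self.grads:
            g_[...] = 0.0
        self.grads[2][...] = cache["h_last"].T @ grad
        self.grads[3][...] = grad.sum(axis=0)

        dh = grad @ self.wo.T
        dc = np.zeros_like(dh)
        for z, i, f, g, o, c_prev, tanh_c in reversed(steps):
            dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
            da = np.concatenate(
                [
                    dc * g * i * (1.0 - i),
                    dc * c_prev * f * (1.0 - f),
                    dc * i * (1.0 - g * g),
                    dh * tanh_c * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads[0] += z.T @ da
            self.grads[1] += da.sum(axis=0)
            dz = da @ self.w.T
            dh = dz[:, d:]
            dc = dc * f
        self._cache = None

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        probs = []
        for start in range(0, x.shape[0], batch_size):
            probs.append(sigmoid(self.forward_logits(x[start : start + batch_size])))
        return np.concatenate(probs).astype(np.float64)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 8,
        batch_size: int = 64,
        lr: float = 3e-3,
        seed: int = 0,
    ) -> dict:
        y = np.asarray(y).reshape(-1)
        if np.unique(y).size < 2:
            raise InvalidDataError("training data must contain both classes")
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, self.grads, lr=lr)
        history: dict = {"loss": [], "accuracy": []}
        for _epoch in range(epochs):
            order = rng.permutation(x.shape[0])
            losses = []
            correct = 0
            for start in range(0, x.shape[0], batch_size):
                sel = order[start : start + batch_size]
                logits = self.forward_logits(x[sel], keep_cache=True)
                loss, grad = bce_with_logits(logits, y[sel])
                self._backward(grad)
                opt.step()
                losses.append(loss * sel.size)
                correct += int(np.sum((logits >= 0).astype(int) == y[sel]))
            history["loss"].append(float(np.sum(losses) / x.shape[0]))
            history["accuracy"].append(correct / x.shape[0])
        return history
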