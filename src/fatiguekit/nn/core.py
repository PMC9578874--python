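"""Feed-forward layers with manual backprop.

Conventions: activations are float32 arrays shaped (N, H, W, C) for
convolutional layers and (N, D) for dense layers. Convolutions are
stride-1 'same' with odd kernels; pooling is non-overlapping max pooling
that truncates odd trailing rows/cols. The final Dense layer emits logits;
the binary cross-entropy loss applies the sigmoid internally for
stability.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import InvalidDataError, InvalidSpecError

DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    logits = logits.reshape(-1)
    y = y.reshape(-1).astype(DTYPE)
    loss = float(np.mean(_softplus(logits) - y * logits))
    grad = ((sigmoid(logits) - y) / logits.size).astype(DTYPE)
    return loss, grad


class Layer:
    """Base class; layers with weights expose aligned params/grads lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' convolution with an odd square kernel, He init."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1 or kernel < 1:
            raise InvalidSpecError("conv kernel must be odd and positive")
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = kernel * kernel * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_channels, kernel, kernel, out_channels))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @staticmethod
    def _correlate_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """'Same' cross-correlation of (N,H,W,Cin) with (Cin,k,k,Cout)."""
        k = w.shape[1]
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,Cin,k,k)
        n, h, ww_, cin = x.shape
        cols = win.reshape(n * h * ww_, cin * k * k)
        out = cols @ w.reshape(cin * k * k, w.shape[3])
        return cols, out.reshape(n, h, ww_, w.shape[3])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._cols, y = self._correlate_same(x, self.w)
        return y + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w_, cout = grad.shape
        gflat = grad.reshape(n * h * w_, cout)
        dw = self._cols.T @ gflat
        self.grads[0][...] = dw.reshape(self.w.shape)
        self.grads[1][...] = gflat.sum(axis=0)
        # dx: full convolution = 'same' correlation with the flipped kernel,
        # swapping the in/out channel roles.
        w_rot = self.w[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (Cout,k,k,Cin)
        _, dx = self._correlate_same(grad, np.ascontiguousarray(w_rot))
        self._cols = None
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; odd trailing rows/cols are dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        if pool < 2:
            raise InvalidSpecError("pool size must be >= 2")
        self.pool = pool
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        n, h, w, c = x.shape
        h2, w2 = h // p, w // p
        if h2 == 0 or w2 == 0:
            raise InvalidSpecError("input smaller than pooling window")
        xr = (
            x[:, : h2 * p, : w2 * p]
            .reshape(n, h2, p, w2, p, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, p * p)
        )
        idx = np.argmax(xr, axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, h, w, c), idx = self._cache
        p = self.pool
        h2, w2 = h // p, w // p
        dgrid = np.zeros((n, h2, w2, c, p * p), dtype=grad.dtype)
        np.put_along_axis(dgrid, idx[..., None], grad[..., None], axis=-1)
        dx_core = (
            dgrid.reshape(n, h2, w2, c, p, p)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * p, w2 * p, c)
        )
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        dx[:, : h2 * p, : w2 * p] = dx_core
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, grad, 0.0)
        self._mask = None
        return out


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A feed-forward stack ending in a 1-logit Dense; binary classifier."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        out = x.astype(DTYPE, copy=False)
        for layer in self.layers:
            out = layer.forward(out)
        return out.reshape(-1)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Probability of the positive class, in [0, 1]."""
        probs = []
        for start in range(0, x.shape[0], batch_size):
            probs.append(sigmoid(self.forward_logits(x[start : start + batch_size])))
        return np.concatenate(probs).astype(np.float64)

    def _backward(self, grad: np.ndarray) -> None:
        g: np.ndarray = grad.reshape(-1, 1).astype(DTYPE)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 5,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> dict:
        """Minibatch Adam on binary cross-entropy; returns the history dict."""
        y = np.asarray(y).reshape(-1)
        if np.unique(y).size < 2:
            raise InvalidDataError("training data must contain both classes")
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, self.grads, lr=lr)
        history: dict = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
        x = x.astype(DTYPE, copy=False)
        for _epoch in range(epochs):
            order = rng.permutation(x.shape[0])
            losses = []
            correct = 0
            for start in range(0, x.shape[0], batch_size):
                sel = order[start : start + batch_size]
                logits = self.forward_logits(x[sel])
                loss, grad = bce_with_logits(logits, y[sel])
                self._backward(grad)
                opt.step()
                losses.append(loss * sel.size)
                correct += int(np.sum((logits >= 0).astype(int) == y[sel]))
            history["loss"].append(float(np.sum(losses) / x.shape[0]))
            history["accuracy"].append(correct / x.shape[0])
            if validation is not None:
                xv, yv = validation
                pv = self.predict_proba(xv)
                lv, _ = bce_with_logits(
                    np.log(np.clip(pv, 1e-7, 1 - 1e-7) / np.clip(1 - pv, 1e-7, 1)),
                    np.asarray(yv),
                )
                history["val_loss"].append(lv)
                history["val_accuracy"].append(
                    float(np.mean((pv >= 0.5).astype(int) == np.asarray(yv).reshape(-1)))
                )
        return history
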