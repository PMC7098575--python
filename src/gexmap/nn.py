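"""A small feed-forward / convolutional network engine on numpy.

Supports exactly the architectures needed for the gene-expression image
experiments: 2-D valid convolutions (stride 1) with max pooling for the
image models, dense layers with batch normalization, ReLU and dropout for
the vector models, a sigmoid/binary-cross-entropy head, and Adam.
Everything is seeded and single-threaded, so training is reproducible
bit-for-bit on a fixed machine.

Arrays are float32 internally; images enter as (batch, rows, cols) and are
given a channel axis, vectors as (batch, features).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Dropout",
    "BatchNorm1d",
    "Conv2d",
    "MaxPool2d",
    "Flatten",
    "Sequential",
]

_DT = np.float32


class Layer:
    """Base layer: ``params``/``grads`` are dicts of same-keyed arrays."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": (rng.standard_normal((n_in, n_out)) * scale).astype(_DT),
            "b": np.zeros(n_out, dtype=_DT),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm1d(Layer):
    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {
            "gamma": np.ones(n_features, dtype=_DT),
            "beta": np.zeros(n_features, dtype=_DT),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features, dtype=_DT)
        self.running_var = np.ones(n_features, dtype=_DT)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(_DT)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(_DT)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        n = grad.shape[0]
        xhat = self._xhat
        self.grads["gamma"][...] = (grad * xhat).sum(axis=0)
        self.grads["beta"][...] = grad.sum(axis=0)
        g = self.params["gamma"] / (self._std * n)
        return g * (n * grad - grad.sum(axis=0) - xhat * (grad * xhat).sum(axis=0))


class Conv2d(Layer):
    """Valid 2-D convolution, stride 1, implemented via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": (rng.standard_normal((fan_in, c_out)) * scale).astype(_DT),
            "b": np.zeros(c_out, dtype=_DT),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        b, c, h, w = x.shape
        k = self.kernel
        if k > h or k > w:
            raise ValueError(f"kernel {k} larger than input {h}x{w}")
        oh, ow = h - k + 1, w - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (b, c, oh, ow, k, k) -> (b, oh*ow, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k)
        self._cols = cols
        self._shape = (b, c, h, w, oh, ow)
        out = cols @ self.params["W"] + self.params["b"]
        return out.transpose(0, 2, 1).reshape(b, self.c_out, oh, ow)

    def backward(self, grad):
        b, c, h, w, oh, ow = self._shape
        k = self.kernel
        g = grad.reshape(b, self.c_out, oh * ow).transpose(0, 2, 1)  # (b, ohow, F)
        cols2 = self._cols.reshape(b * oh * ow, -1)
        g2 = g.reshape(b * oh * ow, self.c_out)
        self.grads["W"][...] = cols2.T @ g2
        self.grads["b"][...] = g2.sum(axis=0)
        dcols = (g @ self.params["W"].T).reshape(b, oh, ow, c, k, k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (b, c, k, k, oh, ow)
        dx = np.zeros((b, c, h, w), dtype=_DT)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, i, j]
        return dx


class MaxPool2d(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        p = self.pool
        b, c, h, w = x.shape
        oh, ow = h // p, w // p
        if oh == 0 or ow == 0:
            raise ValueError(f"pool {p} larger than input {h}x{w}")
        xr = x[:, :, :oh * p, :ow * p].reshape(b, c, oh, p, ow, p)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, oh, ow, p * p)
        self._argmax = xr.argmax(axis=-1)
        self._shape = (b, c, h, w, oh, ow)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        b, c, h, w, oh, ow = self._shape
        p = self.pool
        flat = np.zeros((b, c, oh, ow, p * p), dtype=_DT)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(b, c, oh, ow, p, p).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((b, c, h, w), dtype=_DT)
        dx[:, :, :oh * p, :ow * p] = flat.reshape(b, c, oh * p, ow * p)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, layers, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                key = (li, name)
                g = layer.grads[name]
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DT)


class Sequential:
    """A seeded stack of layers with a sigmoid / binary-cross-entropy head.

    ``input_kind`` is "image" (inputs (batch, rows, cols), a channel axis is
    inserted) or "vector".  Optimizer state persists across ``fit`` calls,
    so pre-training and fine-tuning can use different learning rates while
    continuing from the same weights.
    """

    def __init__(self, layers, input_kind: str = "vector") -> None:
        if input_kind not in ("vector", "image"):
            raise ValueError("input_kind must be 'vector' or 'image'")
        self.layers = list(layers)
        self.input_kind = input_kind
        self._adam = _Adam()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_DT)
        if self.input_kind == "image":
            if X.ndim == 3:
                X = X[:, None, :, :]
            elif X.ndim != 4:
                raise ValueError("image input must be (batch, rows, cols)")
        elif X.ndim != 2:
            raise ValueError("vector input must be (batch, features)")
        return X

    def forward_logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._prepare(X)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out.reshape(-1)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X)
        chunks = [
            _sigmoid(self.forward_logits(X[i:i + batch_size], train=False))
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(chunks).astype(float)

    def fit(self, X, y, epochs: int, lr: float, batch_size: int = 32,
            seed: int = 0) -> list:
        """Minibatch Adam on binary cross-entropy; returns per-epoch mean loss."""
        X = np.asarray(X)
        y = np.asarray(y, dtype=_DT).reshape(-1)
        if epochs == 0:
            return []
        rng = np.random.default_rng(seed)
        history = []
        n = len(y)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                z = self.forward_logits(xb, train=True)
                # softplus(z) - y*z is BCE-with-logits
                loss = float(np.mean(np.logaddexp(0.0, z) - yb * z))
                losses.append(loss)
                dz = ((_sigmoid(z) - yb) / len(yb)).astype(_DT)[:, None]
                grad = dz
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self._adam.step(self.layers, lr)
            history.append(float(np.mean(losses)))
        return history

    def get_weights(self) -> list:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]
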