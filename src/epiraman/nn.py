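"""Minimal seeded 1-D convolutional network engine (pure numpy).

Implements exactly what the spectral autoencoder and the tissue classifier
need: same-padded 1-D convolutions, max pooling, nearest-neighbour
upsampling, dense layers, ReLU/sigmoid activations, softmax/sigmoid
cross-entropy and MSE losses, glorot-uniform initialization and the Adam
optimizer.  Everything is driven by explicit integer seeds; given the same
seed, data and architecture, training is bit-reproducible on one thread.

Arrays flow as ``(batch, length, channels)`` float32 tensors; dense layers
take ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "MaxPool1D",
    "Upsample1D",
    "Flatten",
    "Dense",
    "Sequential",
    "LOSSES",
]

_EPS = 1e-7


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _activate(z: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray | None]:
    if kind == "relu":
        mask = z > 0
        return z * mask, mask
    if kind == "sigmoid":
        y = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
        return y, y
    if kind == "linear":
        return z, None
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(dy: np.ndarray, cache: np.ndarray | None, kind: str
                   ) -> np.ndarray:
    if kind == "relu":
        return dy * cache
    if kind == "sigmoid":
        return dy * cache * (1.0 - cache)
    return dy


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def build(self, rng: np.random.Generator, in_shape: tuple) -> tuple:
        return in_shape

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 correlation of (N, L, C) with (K, C, F)."""
    n, length, _ = x.shape
    k, c, f = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # N,L,C,K
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))          # N,L,K,C
    return (cols.reshape(n * length, k * c) @ w.reshape(k * c, f)
            ).reshape(n, length, f), cols


class Conv1D(Layer):
    """Same-padded stride-1 1-D convolution with an optional activation."""

    def __init__(self, filters: int, kernel: int, activation: str = "relu"
                 ) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only (same padding)")
        self.filters, self.kernel, self.activation = filters, kernel, activation

    def build(self, rng, in_shape):
        length, channels = in_shape
        self.in_channels = channels
        w = _glorot(rng, (self.kernel, channels, self.filters),
                    fan_in=self.kernel * channels,
                    fan_out=self.kernel * self.filters)
        b = np.zeros(self.filters, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        return (length, self.filters)

    def forward(self, x):
        w, b = self.params
        z, self._cols = _conv_same(x, w)
        z += b
        y, self._act_cache = _activate(z, self.activation)
        return y

    def backward(self, dy):
        w, _ = self.params
        k, c, f = w.shape
        dz = _activate_grad(dy, self._act_cache, self.activation)
        n, length, _ = dz.shape
        self.grads[1][...] = dz.sum(axis=(0, 1))
        dw = (self._cols.reshape(n * length, k * c).T
              @ dz.reshape(n * length, f))
        self.grads[0][...] = dw.reshape(k, c, f)
        w_rot = w[::-1].transpose(0, 2, 1)  # (K, F, C)
        dx, _ = _conv_same(dz, np.ascontiguousarray(w_rot))
        self._cols = None
        return dx


class MaxPool1D(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def build(self, rng, in_shape):
        length, channels = in_shape
        return (length // self.size, channels)

    def forward(self, x):
        n, length, c = x.shape
        self._in_len = length
        l2 = length // self.size
        xt = x[:, : l2 * self.size].reshape(n, l2, self.size, c)
        self._argmax = xt.argmax(axis=2)
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2
                                  )[:, :, 0, :]

    def backward(self, dy):
        n, l2, c = dy.shape
        dxt = np.zeros((n, l2, self.size, c), dtype=dy.dtype)
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        dx = np.zeros((n, self._in_len, c), dtype=dy.dtype)
        dx[:, : l2 * self.size] = dxt.reshape(n, l2 * self.size, c)
        return dx


class Upsample1D(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def build(self, rng, in_shape):
        length, channels = in_shape
        return (length * self.size, channels)

    def forward(self, x):
        return np.repeat(x, self.size, axis=1)

    def backward(self, dy):
        n, length, c = dy.shape
        return dy.reshape(n, length // self.size, self.size, c).sum(axis=2)


class Flatten(Layer):
    def build(self, rng, in_shape):
        self._in_shape = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, dy):
        return dy.reshape(self._n, *self._in_shape)


class Dense(Layer):
    def __init__(self, units: int, activation: str = "linear") -> None:
        super().__init__()
        self.units, self.activation = units, activation

    def build(self, rng, in_shape):
        (features,) = in_shape
        w = _glorot(rng, (features, self.units), features, self.units)
        b = np.zeros(self.units, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        return (self.units,)

    def forward(self, x):
        self._x = x
        z = x @ self.params[0] + self.params[1]
        y, self._act_cache = _activate(z, self.activation)
        return y

    def backward(self, dy):
        dz = _activate_grad(dy, self._act_cache, self.activation)
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        dx = dz @ self.params[0].T
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# losses: each maps final-layer logits -> (output, loss, dlogits)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _softmax_ce(z, t):
    p = _softmax(z)
    loss = -np.mean(np.sum(t * np.log(p + _EPS), axis=1))
    return p, loss, (p - t) / z.shape[0]


def _sigmoid_ce(z, t):
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
    loss = -np.mean(np.sum(t * np.log(p + _EPS)
                           + (1 - t) * np.log(1 - p + _EPS), axis=1))
    return p, loss, (p - t) / z.shape[0]


def _sigmoid_mse(z, t):
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
    loss = np.mean(np.sum((p - t) ** 2, axis=1))
    return p, loss, 2.0 * (p - t) * p * (1 - p) / z.shape[0]


LOSSES = {
    "categorical_crossentropy": _softmax_ce,
    "crossentropy": _sigmoid_ce,
    "mse": _sigmoid_mse,
}


class _Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m, v = self.state.setdefault(
                i, (np.zeros_like(p), np.zeros_like(p)))
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class Sequential:
    """A feed-forward stack trained with Adam and mini-batch SGD.

    The final layer's nonlinearity lives in the loss (softmax for
    ``categorical_crossentropy``, sigmoid for ``crossentropy``/``mse``), so
    the last layer should be linear.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int
                 ) -> None:
        self.layers = layers
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        shape = input_shape
        for layer in layers:
            shape = layer.build(rng, shape)
        self.output_shape = shape

    # -- plumbing -----------------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def _backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- training -----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray, *, loss: str, epochs: int,
            batch_size: int, lr: float = 1e-3,
            validation_data: tuple[np.ndarray, np.ndarray] | None = None,
            min_epochs: int = 1, patience: int | None = None,
            verbose: bool = False) -> dict:
        """Train and return a history dict.

        Early stopping (when ``patience`` is set and validation data given)
        monitors validation loss, never stops before ``min_epochs``, and
        restores the best-validation weights at the end.
        """
        loss_fn = LOSSES[loss]
        x = np.asarray(x, np.float32)
        y = np.asarray(y, np.float32)
        rng = np.random.default_rng(self.seed + 1)
        opt = _Adam(lr=lr)
        n = x.shape[0]
        history: dict[str, list] = {"loss": [], "val_loss": []}
        best = (np.inf, None, 0)
        for epoch in range(epochs):
            perm = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                out = self._forward(x[idx])
                _, batch_loss, dlogits = loss_fn(out, y[idx])
                total += batch_loss * idx.size
                self._backward(dlogits.astype(np.float32))
                opt.step(self.parameters(), self.gradients())
            history["loss"].append(total / n)
            if validation_data is not None:
                vx, vy = validation_data
                vout = self.predict_logits(vx)
                _, vloss, _ = loss_fn(vout, np.asarray(vy, np.float32))
                history["val_loss"].append(float(vloss))
                if vloss < best[0] - 1e-6:
                    best = (vloss, self.get_weights(), epoch)
                if (patience is not None and epoch + 1 >= min_epochs
                        and epoch - best[2] >= patience):
                    break
            if verbose:  # pragma: no cover
                msg = f"epoch {epoch + 1}: loss {history['loss'][-1]:.4f}"
                if history["val_loss"]:
                    msg += f" val {history['val_loss'][-1]:.4f}"
                print(msg)
        if best[1] is not None:
            self.set_weights(best[1])
        history["epochs_run"] = len(history["loss"])
        return history

    def predict_logits(self, x: np.ndarray, batch_size: int = 512
                       ) -> np.ndarray:
        x = np.asarray(x, np.float32)
        outs = [self._forward(x[i:i + batch_size])
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, loss: str, batch_size: int = 512
                ) -> np.ndarray:
        """Network output after the loss's output nonlinearity."""
        z = self.predict_logits(x, batch_size)
        if loss == "categorical_crossentropy":
            return _softmax(z)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
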