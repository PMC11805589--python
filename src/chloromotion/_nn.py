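"""Minimal numpy neural-network core for spectral classifiers.

Implements exactly the layer set the spectral models need — 1-D "same"
convolution, max-pooling, dense layers, batch normalization, ReLU, softmax
cross-entropy — trained with Adam. Sizes here are tiny (inputs of ~160
bands, <100k parameters), so plain vectorised numpy is fast enough and
keeps training bit-reproducible from a seed on a single thread.
"""

from __future__ import annotations

import numpy as np

from .errors import ChloromotionError


class DivergenceError(ChloromotionError):
    """Training loss became non-finite."""


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.dW[...] = self._x.T @ gout
        self.db[...] = gout.sum(axis=0)
        return gout @ self.W.T


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding (odd kernel width)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel width must be odd for same padding")
        self.k = k
        self.W = rng.normal(0.0, np.sqrt(2.0 / (c_in * k)), size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @staticmethod
    def _windows(xp: np.ndarray, k: int) -> np.ndarray:
        n, c, lp = xp.shape
        s0, s1, s2 = xp.strides
        return np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, lp - k + 1, k), strides=(s0, s1, s2, s2), writeable=False
        )

    def forward(self, x, train):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._win = self._windows(xp, self.k)
        self._in_shape = x.shape
        return np.einsum("nclk,ock->nol", self._win, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, gout):
        self.dW[...] = np.einsum("nol,nclk->ock", gout, self._win, optimize=True)
        self.db[...] = gout.sum(axis=(0, 2))
        n, c, length = self._in_shape
        p = self.k // 2
        dxp = np.zeros((n, c, length + 2 * p))
        contrib = np.einsum("nol,ock->nckl", gout, self.W, optimize=True)
        for t in range(self.k):
            dxp[:, :, t : t + length] += contrib[:, :, t, :]
        return dxp[:, :, p : p + length]


class MaxPool1D(Layer):
    def __init__(self, k: int = 5, stride: int = 2):
        self.k, self.stride = k, stride

    def forward(self, x, train):
        n, c, length = x.shape
        out_l = (length - self.k) // self.stride + 1
        s0, s1, s2 = x.strides
        win = np.lib.stride_tricks.as_strided(
            x,
            shape=(n, c, out_l, self.k),
            strides=(s0, s1, s2 * self.stride, s2),
            writeable=False,
        )
        self._arg = win.argmax(axis=3)
        self._in_shape = x.shape
        return win.max(axis=3)

    def backward(self, gout):
        n, c, length = self._in_shape
        dx = np.zeros((n, c, length))
        out_l = gout.shape[2]
        ni, ci, oi = np.indices((n, c, out_l))
        np.add.at(dx, (ni, ci, oi * self.stride + self._arg), gout)
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over the batch axis of (N, F) activations."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            if getattr(self, "_accumulating", False):
                self._acc_mean += mean
                self._acc_var += var
                self._acc_count += 1
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, gout):
        n = gout.shape[0]
        self.dgamma[...] = (gout * self._xhat).sum(axis=0)
        self.dbeta[...] = gout.sum(axis=0)
        gx = gout * self.gamma
        return (
            gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)
        ) / self._std if n > 1 else gx / self._std


def recalibrate_batchnorm(net: "SequentialNet", x: np.ndarray, batch_size: int = 64) -> None:
    """Replace BN running statistics with full-dataset population estimates.

    Momentum-averaged running statistics lag the final weights; a single
    train-mode sweep over the training set gives the population mean/var
    each BN layer actually sees at convergence, which stabilises
    evaluation-mode predictions.
    """
    bns = [layer for layer in net.layers if isinstance(layer, BatchNorm)]
    if not bns:
        return
    for bn in bns:
        bn._accumulating = True
        bn._acc_mean = np.zeros_like(bn.running_mean)
        bn._acc_var = np.zeros_like(bn.running_var)
        bn._acc_count = 0
    for start in range(0, x.shape[0], batch_size):
        batch = x[start : start + batch_size]
        if batch.shape[0] < 2:
            continue
        net.forward(batch, train=True)
    for bn in bns:
        if bn._acc_count:
            bn.running_mean = bn._acc_mean / bn._acc_count
            bn.running_var = bn._acc_var / bn._acc_count
        bn._accumulating = False


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SequentialNet:
    """A feed-forward stack trained with softmax cross-entropy + Adam."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.vstack(out)

    def fit(
        self,
        x: np.ndarray,
        y_index: np.ndarray,
        n_classes: int,
        epochs: int,
        batch_size: int = 64,
        lr: float = 1e-3,
        rng: np.random.Generator | None = None,
    ) -> list[float]:
        """Minimise multinomial negative log-likelihood; returns epoch losses."""
        rng = rng or np.random.default_rng(0)
        params = [p for layer in self.layers for p in layer.params()]
        grads = [g for layer in self.layers for g in layer.grads()]
        opt = Adam(params, lr=lr)
        onehot = np.eye(n_classes)[y_index]
        n = x.shape[0]
        losses = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], onehot[idx]
                logits = self.forward(xb, train=True)
                probs = softmax(logits)
                loss = -np.sum(yb * np.log(probs + 1e-12)) / len(idx)
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                total += loss * len(idx)
                gout = (probs - yb) / len(idx)
                for layer in reversed(self.layers):
                    gout = layer.backward(gout)
                opt.step(grads)
            losses.append(total / n)
        recalibrate_batchnorm(self, x, batch_size)
        return losses


def build_mlp(n_in: int, layer_sizes: tuple[int, ...], rng: np.random.Generator) -> SequentialNet:
    """Dense stack; every layer but the last is followed by BN + ReLU."""
    layers: list[Layer] = []
    prev = n_in
    for i, size in enumerate(layer_sizes):
        layers.append(Dense(prev, size, rng))
        if i < len(layer_sizes) - 1:
            layers.append(BatchNorm(size))
            layers.append(ReLU())
        prev = size
    return SequentialNet(layers)


def build_cnn(
    n_in: int,
    conv_widths: tuple[int, ...],
    feature_maps: tuple[int, ...],
    dense_sizes: tuple[int, ...],
    rng: np.random.Generator,
    pool_k: int = 5,
    pool_stride: int = 2,
) -> SequentialNet:
    """Conv blocks (conv → ReLU → max-pool) then a dense head.

    Kernel widths must decrease and feature-map counts increase block by
    block; the first three dense layers are each followed by BN + ReLU,
    the final one feeds the softmax.
    """
    if list(conv_widths) != sorted(conv_widths, reverse=True) or len(set(conv_widths)) != len(conv_widths):
        raise ValueError("conv kernel widths must be strictly decreasing")
    if list(feature_maps) != sorted(feature_maps) or len(set(feature_maps)) != len(feature_maps):
        raise ValueError("feature-map counts must be strictly increasing")
    layers: list[Layer] = []
    c_prev, length = 1, n_in
    for k, c_out in zip(conv_widths, feature_maps):
        layers.append(Conv1D(c_prev, c_out, k, rng))
        layers.append(ReLU())
        layers.append(MaxPool1D(pool_k, pool_stride))
        length = (length - pool_k) // pool_stride + 1
        if length < 1:
            raise ValueError("input too short for this conv/pool stack")
        c_prev = c_out
    layers.append(Flatten())
    prev = c_prev * length
    for i, size in enumerate(dense_sizes):
        layers.append(Dense(prev, size, rng))
        if i < len(dense_sizes) - 1:
            layers.append(BatchNorm(size))
            layers.append(ReLU())
        prev = size
    return SequentialNet(layers)
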