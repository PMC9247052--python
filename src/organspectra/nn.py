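"""Minimal numpy neural-network engine for 1-D spectral CNNs.

Implements exactly the layers the spectral classifier needs — valid
(no-padding) 1-D convolution, batch normalization, ELU, average pooling,
dropout, fully connected layers — with manual backpropagation and an Adam
optimizer.  Convolutions are evaluated as matrix products over sliding
windows.  All randomness (initialization, dropout masks) flows through a
single :class:`numpy.random.Generator`.

Gradient correctness is verified by finite-difference checks in the test
suite rather than assumed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm",
    "ELU",
    "AvgPool1d",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: stateless by default, no trainable parameters."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Valid 1-D convolution: (N, C_in, L) -> (N, C_out, L - k + 1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        fan_in = in_channels * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel

    def forward(self, x, train):
        if x.shape[2] < self.kernel:
            raise ValueError(f"input length {x.shape[2]} < kernel {self.kernel}")
        self._cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        # cols: (N, C_in, L_out, k)
        return np.einsum("nclk,ock->nol", self._cols, self.W, optimize=True) + self.b[:, None]

    def backward(self, grad):
        self.dW = np.einsum("nol,nclk->ock", grad, self._cols, optimize=True)
        self.db = grad.sum(axis=(0, 2))
        k = self.kernel
        pad = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        windows = np.lib.stride_tricks.sliding_window_view(pad, k, axis=2)
        return np.einsum("notk,ock->nct", windows, self.W[:, :, ::-1], optimize=True)

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axis for conv maps).

    ``n_features`` is the channel count; inputs are (N, C, L) or (N, C).
    Training uses batch statistics and updates running moments; evaluation
    uses the running moments.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _expand(self, v, ndim):
        return v[:, None] if ndim == 3 else v

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        e = lambda v: self._expand(v, x.ndim)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - e(mean)) * e(self._inv_std)
        self._m = x.size // x.shape[1]
        self._train = train
        return e(self.gamma) * self._xhat + e(self.beta)

    def backward(self, grad):
        axes = self._axes(grad)
        e = lambda v: self._expand(v, grad.ndim)
        self.dgamma = (grad * self._xhat).sum(axis=axes)
        self.dbeta = grad.sum(axis=axes)
        if not self._train:
            return grad * e(self.gamma) * e(self._inv_std)
        m = self._m
        dxhat = grad * e(self.gamma)
        return (
            e(self._inv_std)
            / m
            * (m * dxhat - e(dxhat.sum(axis=axes)) - self._xhat * e((dxhat * self._xhat).sum(axes)))
        )

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train):
        self._out = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._pos = x > 0
        return self._out

    def backward(self, grad):
        return grad * np.where(self._pos, 1.0, self._out + self.alpha)


class AvgPool1d(Layer):
    """Average pooling with stride = kernel; trailing remainder is dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x, train):
        n, c, L = x.shape
        L_out = L // self.kernel
        if L_out < 1:
            raise ValueError(f"input length {L} too short for pooling kernel {self.kernel}")
        self._in_len = L
        return x[:, :, : L_out * self.kernel].reshape(n, c, L_out, self.kernel).mean(axis=3)

    def backward(self, grad):
        n, c, L_out = grad.shape
        dx = np.zeros((n, c, self._in_len))
        expanded = np.repeat(grad / self.kernel, self.kernel, axis=2)
        dx[:, :, : L_out * self.kernel] = expanded
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Adam:
    """Adam with in-place parameter updates; ``lr`` may be reassigned
    between epochs (exponential decay is applied by the training loop)."""

    def __init__(self, params: list[np.ndarray], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def calibrate_batchnorm(model: Sequential, X: np.ndarray, max_rows: int = 4096) -> None:
    """Re-estimate batch-norm running statistics with one large forward pass.

    With short training schedules the exponential running moments lag the
    rapidly changing activations; this replaces them with the statistics of
    (up to ``max_rows`` of) the training data under the final weights.
    Dropout is disabled during the pass.
    """
    if len(X) > max_rows:
        step = int(np.ceil(len(X) / max_rows))
        X = X[::step]
    saved = []
    for layer in model.layers:
        if isinstance(layer, BatchNorm):
            saved.append((layer, "momentum", layer.momentum))
            layer.momentum = 1.0
        elif isinstance(layer, Dropout):
            saved.append((layer, "p", layer.p))
            layer.p = 0.0
    try:
        model.forward(X, train=True)
    finally:
        for obj, attr, value in saved:
            setattr(obj, attr, value)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
):
    """Weighted multiclass cross-entropy; returns (loss, dloss/dlogits).

    Per-sample weights are the class weights of the true labels,
    normalized by their batch sum so the loss stays on a per-sample scale.
    """
    n = len(labels)
    probs = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[labels]
    wsum = w.sum()
    logp = np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    loss = float(-(w * logp).sum() / wsum)
    grad = probs * (w / wsum)[:, None]
    grad[np.arange(n), labels] -= w / wsum
    return loss, grad
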