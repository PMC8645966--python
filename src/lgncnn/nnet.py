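"""A small NumPy forward/backward engine for the convolutional models here.

Covers exactly what the architecture needs: same-padded stride-1
convolutions (im2col + BLAS matmul, chunked over the batch to bound
memory), batch normalization, ReLU, 2x2 max pooling, dense layers,
inverted dropout, a lateral-mixing layer driven by a 4-D connectivity
kernel (with DropConnect-style masking of kernel entries), softmax
cross-entropy and SGD with momentum.  Everything is float32 and runs on a
single CPU; reproducibility comes from a single generator owned by the
network.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "LateralMix",
    "softmax_cross_entropy",
    "SGD",
]

_DTYPE = np.float32
_CHUNK_BYTES = 96 * 2**20  # cap on the im2col scratch buffer


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches of the same-padded input."""
    N, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) view -> copy into matmul-friendly layout
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N, H * W, C * k * k
    )


def _conv_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 correlation: (N,C,H,W) x (O,C,k,k) -> (N,O,H,W)."""
    N, C, H, W_ = x.shape
    O, _, k, _ = W.shape
    Wmat = W.reshape(O, C * k * k)
    dtype = np.result_type(x, W)
    out = np.empty((N, O, H, W_), dtype=dtype)
    per = C * H * W_ * k * k * dtype.itemsize
    chunk = max(1, int(_CHUNK_BYTES // max(per, 1)))
    for i in range(0, N, chunk):
        cols = _im2col(x[i : i + chunk], k)  # (n, HW, CKK)
        out[i : i + chunk] = (cols @ Wmat.T).transpose(0, 2, 1).reshape(
            -1, O, H, W_
        )
    return out


def _conv_grad_w(x: np.ndarray, dy: np.ndarray, k: int) -> np.ndarray:
    """Gradient of _conv_same w.r.t. the weights."""
    N, C, H, W_ = x.shape
    O = dy.shape[1]
    dW = np.zeros((O, C * k * k), dtype=_DTYPE)
    per = C * H * W_ * k * k * 4
    chunk = max(1, int(_CHUNK_BYTES // max(per, 1)))
    dyf = dy.reshape(N, O, H * W_)
    for i in range(0, N, chunk):
        cols = _im2col(x[i : i + chunk], k)  # (n, HW, CKK)
        dW += np.tensordot(dyf[i : i + chunk], cols, axes=([0, 2], [0, 1]))
    return dW.reshape(O, C, k, k)


class Layer:
    train_mode = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1, same-padded convolutional layer with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = Param(rng.normal(0.0, scale, (out_ch, in_ch, k, k)), "conv_w")
        self.b = Param(np.zeros(out_ch), "conv_b")
        self.k = k
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return _conv_same(x, self.W.value) + self.b.value[None, :, None, None]

    def backward(self, dy):
        self.W.grad += _conv_grad_w(self._x, dy, self.k)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        Wflip = self.W.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return _conv_same(dy, np.ascontiguousarray(Wflip))


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch), "bn_gamma")
        self.beta = Param(np.zeros(n_ch), "bn_beta")
        self.running_mean = np.zeros(n_ch, dtype=_DTYPE)
        self.running_var = np.ones(n_ch, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        axes = (0, 2, 3)
        if self.train_mode:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(_DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv = xhat, inv
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy):
        axes = (0, 2, 3)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not self.train_mode:
            return dy * g * self._inv[None, :, None, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        )
        return term * self._inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (odd trailing row/col dropped)."""

    def forward(self, x):
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        self._in_shape = x.shape
        xr = x[:, :, : H2 * 2, : W2 * 2].reshape(N, C, H2, 2, W2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dy):
        N, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        dx4 = np.zeros((N, C, H2, W2, 4), dtype=_DTYPE)
        np.put_along_axis(dx4, self._arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dx[:, :, : H2 * 2, : W2 * 2] = (
            dx4.reshape(N, C, H2, W2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H2 * 2, W2 * 2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, (n_out, n_in)), "dense_w")
        self.b = Param(np.zeros(n_out), "dense_b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Dropout(Layer):
    """Inverted dropout on activations; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if not self.train_mode or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LateralMix(Layer):
    """Lateral propagation on a feature layer: y = (x + K * x) / 2.

    ``K`` is the 4-D connectivity kernel indexed (i, j, f, g) — spatial
    displacement and source/target filter indices.  During training a
    Bernoulli mask drops a fraction of the kernel entries per update
    (DropConnect on the lateral weights), with inverted scaling so that
    evaluation uses the full kernel unscaled.  The whole operation is
    linear in the activation.
    """

    def __init__(
        self,
        n_ch: int,
        size: int,
        rng: np.random.Generator,
        drop_rate: float = 0.0,
    ):
        if size % 2 == 0:
            raise ValueError("lateral kernel size must be odd")
        self.K = Param(np.zeros((size, size, n_ch, n_ch)), "lateral_K")
        self.size = size
        self.n_ch = n_ch
        self.drop_rate = drop_rate
        self.rng = rng
        self.enabled = True

    def params(self):
        return [self.K] if self.enabled else []

    def init_random(self, rng: np.random.Generator) -> None:
        """Zero-mean uniform init scaled by 1/(n_ch * size^2)."""
        bound = 1.0 / (self.n_ch * self.size**2)
        self.K.value = rng.uniform(
            -bound, bound, self.K.value.shape
        ).astype(_DTYPE)
        self.K.grad = np.zeros_like(self.K.value)

    def _weights(self) -> np.ndarray:
        """Connectivity kernel rearranged as correlation weights (g, f, a, b)."""
        Kf = self.K.value[::-1, ::-1]  # flip: true convolution, not correlation
        return np.ascontiguousarray(Kf.transpose(3, 2, 0, 1))

    def forward(self, x):
        if not self.enabled:
            self._mask = None
            return x
        self._x = x
        W = self._weights()
        if self.train_mode and self.drop_rate > 0.0:
            keep = 1.0 - self.drop_rate
            self._mask = (self.rng.random(W.shape) < keep).astype(_DTYPE) / keep
            W = W * self._mask
        else:
            self._mask = None
        self._W_used = W
        return 0.5 * (x + _conv_same(x, W))

    def backward(self, dy):
        if not self.enabled:
            return dy
        dyh = 0.5 * dy
        dW = _conv_grad_w(self._x, dyh, self.size)
        if self._mask is not None:
            dW = dW * self._mask
        # map the correlation-weight gradient back to kernel indexing
        self.K.grad += dW.transpose(2, 3, 1, 0)[::-1, ::-1]
        Wflip = self._W_used.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return dyh + _conv_same(dyh, np.ascontiguousarray(Wflip))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(_DTYPE)


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay and p.value.ndim > 1:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v
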