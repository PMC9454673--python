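"""A small, seeded numpy engine for 1-D convolutional sequence classifiers.

Implements exactly the layer vocabulary the SUMOylation classifiers need —
1-D convolution with "same" padding, batch normalization, ReLU, max-pooling
(pool 2, stride 1, "same"), dropout, dense layers with L2 penalty, and a
residual module block computing

    x_t = P( R( x_{t-1} + delta(x_{t-1}, w_t) ) )

where ``delta`` is conv -> batch-norm -> ReLU -> conv -> batch-norm with
shape-preserving padding, ``R`` is ReLU and ``P`` max-pooling. Tensors are
``(batch, length, channels)`` float32. Every source of randomness (weight
init, dropout masks) draws from a caller-supplied ``numpy`` Generator, so
single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

_DT = np.float32


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0


class Conv1D(Layer):
    """Stride-1 cross-correlation with zero "same" padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        std = np.sqrt(2.0 / (kernel_size * c_in))  # He init for ReLU stacks
        self.W = (rng.standard_normal((kernel_size, c_in, c_out)) * std).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train, rng):
        B, L, c_in = x.shape
        if c_in != self.W.shape[1]:
            raise ValueError(
                f"channel mismatch: input {c_in}, kernel expects {self.W.shape[1]}"
            )
        p = self.k // 2
        xpad = np.zeros((B, L + 2 * p, c_in), dtype=_DT)
        xpad[:, p : p + L] = x
        y = np.broadcast_to(self.b, (B, L, self.W.shape[2])).copy()
        for j in range(self.k):
            y += xpad[:, j : j + L] @ self.W[j]
        self._xpad, self._L = xpad, L
        return y

    def backward(self, dy):
        xpad, L = self._xpad, self._L
        B = dy.shape[0]
        p = self.k // 2
        self.db[...] = dy.sum(axis=(0, 1))
        dxpad = np.zeros_like(xpad)
        dy2 = dy.reshape(B * L, -1)
        for j in range(self.k):
            xs = xpad[:, j : j + L].reshape(B * L, -1)
            self.dW[j] = xs.T @ dy2
            dxpad[:, j : j + L] += dy @ self.W[j].T
        return dxpad[:, p : p + L]


class BatchNorm(Layer):
    """Per-channel batch normalization over the (batch, length) axes.

    Inference uses exponential moving averages of the batch statistics
    (momentum 0.99), the standard streaming estimate.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train, rng):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._n = xhat, inv.astype(_DT), x.shape[0] * x.shape[1]
        return (self.gamma * xhat + self.beta).astype(_DT)

    def backward(self, dy):
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return (
            inv / n * (
                n * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        ).astype(_DT)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool1D(Layer):
    """Max-pooling, pool 2 / stride 1 / "same": output length equals input.

    ``out[i] = max(x[i], x[i+1])`` with the final slot compared against an
    implicit -inf pad, i.e. ``out[L-1] = x[L-1]``.
    """

    def __init__(self, pool_size: int = 2):
        super().__init__()
        if pool_size != 2:
            raise NotImplementedError("only pool_size=2 (stride 1, same) is used")

    def forward(self, x, train, rng):
        right = np.full_like(x, -np.inf)
        right[:, :-1] = x[:, 1:]
        self._left_wins = x >= right
        return np.where(self._left_wins, x, right)

    def backward(self, dy):
        dx = np.where(self._left_wins, dy, 0)
        carried = np.where(self._left_wins, 0, dy)
        dx[:, 1:] += carried[:, :-1]
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng, relu: bool = False,
                 l2: float = 0.0):
        super().__init__()
        std = np.sqrt(2.0 / n_in) if relu else np.sqrt(1.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * std).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self.relu = relu
        self.l2 = l2

    def forward(self, x, train, rng):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0)
        return y

    def backward(self, dy):
        if self.relu:
            dy = np.where(self._mask, dy, 0)
        self.dW[...] = self._x.T @ dy + 2.0 * self.l2 * self.W
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2))


class ResidualBlock(Layer):
    """Residual module: ``P(R(x + delta(x)))`` with a 128-channel identity skip.

    ``delta`` = conv -> BN -> ReLU -> conv -> BN, both convolutions with
    "same" padding so the skip addition is shape-exact. Input and output
    channel counts must match.
    """

    def __init__(self, channels: int, kernel_size: int, rng):
        super().__init__()
        self.conv1 = Conv1D(channels, channels, kernel_size, rng)
        self.bn1 = BatchNorm(channels)
        self.relu_inner = ReLU()
        self.conv2 = Conv1D(channels, channels, kernel_size, rng)
        self.bn2 = BatchNorm(channels)
        self.pool = MaxPool1D(2)
        self._sub = [self.conv1, self.bn1, self.conv2, self.bn2]
        self.params = [p for s in self._sub for p in s.params]
        self.grads = [g for s in self._sub for g in s.grads]

    def forward(self, x, train, rng):
        d = self.conv1.forward(x, train, rng)
        d = self.bn1.forward(d, train, rng)
        d = self.relu_inner.forward(d, train, rng)
        d = self.conv2.forward(d, train, rng)
        d = self.bn2.forward(d, train, rng)
        s = x + d
        self._pre_act = s
        return self.pool.forward(np.where(s > 0, s, 0), train, rng)

    def backward(self, dy):
        ds = np.where(self._pre_act > 0, self.pool.backward(dy), 0)
        dd = self.bn2.backward(ds)
        dd = self.conv2.backward(dd)
        dd = self.relu_inner.backward(dd)
        dd = self.bn1.backward(dd)
        dd = self.conv1.backward(dd)
        return ds + dd  # identity skip + transform path


class Network:
    """A feed-forward stack ending in a single-logit dense layer.

    ``predict_proba`` applies the logistic sigmoid to the final logit;
    training uses the numerically fused sigmoid + binary cross-entropy.
    """

    def __init__(self, layers: list[Layer], rng: np.random.Generator):
        self.layers = layers
        self.rng = rng

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = np.asarray(x, dtype=_DT)
        for layer in self.layers:
            h = layer.forward(h, train, self.rng)
        return h[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(sigmoid(self.forward_logits(x[i : i + batch_size], False)))
        return np.concatenate(out) if out else np.empty(0)

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass; returns the mean penalized loss and
        leaves gradients in ``self.grads`` for the optimizer."""
        logits = self.forward_logits(x, True).astype(np.float64)
        y = np.asarray(y, dtype=np.float64)
        loss = float(np.mean(bce_with_logits(logits, y)))
        loss += sum(l.l2_loss() for l in self.layers)
        p = sigmoid(logits)
        dlogits = ((p - y) / len(y)).astype(_DT)[:, None]
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for l in self._bn_layers():
            state += [l.running_mean.copy(), l.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        extras = state[n:]
        for i, l in enumerate(self._bn_layers()):
            l.running_mean[...] = extras[2 * i]
            l.running_var[...] = extras[2 * i + 1]

    def _bn_layers(self) -> list[BatchNorm]:
        found: list[BatchNorm] = []
        for l in self.layers:
            if isinstance(l, BatchNorm):
                found.append(l)
            elif isinstance(l, ResidualBlock):
                found += [l.bn1, l.bn2]
        return found


class Adam:
    """Adam optimizer with bias correction (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function 1/(1+e^-x), computed stably for large |x|."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log(1+e^z) - y*z, stabilized as max(z,0) - y*z + log(1+e^-|z|)
    return np.maximum(logits, 0) - y * logits + np.log1p(np.exp(-np.abs(logits)))
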