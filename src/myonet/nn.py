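"""Minimal NumPy neural-network primitives with manual backpropagation.

Implements exactly the layers the LRCN needs — 1-D convolution, ReLU,
max-pooling, inverted dropout, dense, LSTM — plus the Adam optimizer.
Everything is float32, single-threaded and deterministic given the
`numpy.random.Generator` passed in: same seed, same weights, same
trajectory.

Layout conventions: activations are ``[batch, length, channels]`` for
convolutional layers and ``[batch, time, features]`` for recurrent ones.
Each layer caches what its backward pass needs on ``self``; a layer is
therefore used for one forward/backward pair at a time, which is all a
plain minibatch loop requires.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def named_params(self) -> dict[str, Param]:
        return {}


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' or 'valid' padding.

    Weight layout ``[c_in * k, c_out]`` matching the im2col column layout
    ``[batch, length, c_in, k]``.
    """

    def __init__(self, c_in: int, c_out: int, k: int, padding: str,
                 rng: np.random.Generator, input_layer: bool = False):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.c_in, self.c_out, self.k, self.padding = c_in, c_out, k, padding
        fan_in = c_in * k
        bound = np.sqrt(6.0 / (fan_in + c_out))
        self.W = Param(rng.uniform(-bound, bound, size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.input_layer = input_layer  # skip dx for the very first layer

    def out_length(self, L: int) -> int:
        return L if self.padding == "same" else L - self.k + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        if self.padding == "same":
            lo = (self.k - 1) // 2
            hi = self.k - 1 - lo
            xp = np.pad(x, ((0, 0), (lo, hi), (0, 0)))
        else:
            xp = x
        # [B, Lout, C, k]
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        Lout = cols.shape[1]
        cols2 = np.ascontiguousarray(cols).reshape(B * Lout, C * self.k)
        out = cols2 @ self.W.value + self.b.value
        self._cache = (cols2, xp.shape, Lout, B)
        return out.reshape(B, Lout, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        cols2, xp_shape, Lout, B = self._cache
        d2 = dout.reshape(B * Lout, self.c_out)
        self.W.grad += cols2.T @ d2
        self.b.grad += d2.sum(axis=0)
        if self.input_layer:
            return None
        dcols = (d2 @ self.W.value.T).reshape(B, Lout, self.c_in, self.k)
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for j in range(self.k):
            dxp[:, j:j + Lout, :] += dcols[:, :, :, j]
        if self.padding == "same":
            lo = (self.k - 1) // 2
            return dxp[:, lo:lo + Lout, :]
        return dxp

    def named_params(self):
        return {"W": self.W, "b": self.b}

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; the length must be divisible by ``pool``."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train):
        B, L, C = x.shape
        if L % self.pool:
            raise ValueError(
                f"length {L} not divisible by pool size {self.pool}"
            )
        xr = x.reshape(B, L // self.pool, self.pool, C)
        idx = xr.argmax(axis=2)
        out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, shape = self._cache
        B, L, C = shape
        dxr = np.zeros((B, L // self.pool, self.pool, C), dtype=DTYPE)
        np.put_along_axis(dxr, idx[:, :, None, :], dout[:, :, None, :], axis=2)
        return dxr.reshape(B, L, C)


class Dropout(Layer):
    """Inverted dropout over feature maps, active only when ``train`` is true.

    On ``[batch, length, channels]`` activations the mask is drawn per
    (sample, channel) and held constant along the time axis (spatial
    dropout): whole feature maps are dropped.  Element-wise masking of a
    band-limited feature sequence feeds the downstream recurrence a
    spiky train-time distribution that its saturating gates never see at
    inference; map-wise masking regularizes just as hard while keeping the
    temporal shape of the surviving maps intact.  2-D inputs fall back to
    element-wise masking.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        shape = ((x.shape[0], 1, x.shape[2])) if x.ndim == 3 else x.shape
        self._mask = (self.rng.random(shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = Param(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T

    def named_params(self):
        return {"W": self.W, "b": self.b}

    def params(self):
        return [self.W, self.b]


def _sigmoid(x):
    # exp overflow for very negative gates saturates cleanly to 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single-layer LSTM over ``[batch, time, features]``.

    Gate order in the fused weight matrix is input, forget, cell, output;
    the forget-gate bias starts at 1.  ``return_sequences`` selects the
    full hidden sequence versus the final hidden state.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool):
        self.d_in, self.units = d_in, units
        self.return_sequences = return_sequences
        bound = 1.0 / np.sqrt(units)
        self.W = Param(rng.uniform(-bound, bound, size=(d_in + units, 4 * units)))
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.b = Param(b)

    def forward(self, x, train):
        B, T, D = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        caches = []
        hs = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            xh = np.concatenate([x[:, t, :], h], axis=1)
            z = xh @ self.W.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h = o * tc
            caches.append((xh, c, i, f, g, o, tc))
            c = c_new
            hs[:, t, :] = h
        self._caches = caches
        self._T, self._B = T, B
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, dout):
        T, B, H = self._T, self._B, self.units
        dx = np.empty((B, T, self.d_in), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            xh, c_prev, i, f, g, o, tc = self._caches[t]
            if self.return_sequences:
                dh = dout[:, t, :] + dh_next
            else:
                dh = (dout + dh_next) if t == T - 1 else dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            self.W.grad += xh.T @ dz
            self.b.grad += dz.sum(axis=0)
            dxh = dz @ self.W.value.T
            dx[:, t, :] = dxh[:, :self.d_in]
            dh_next = dxh[:, self.d_in:]
            dc_next = dc * f
        return dx

    def named_params(self):
        return {"W": self.W, "b": self.b}

    def params(self):
        return [self.W, self.b]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * (p.grad * p.grad)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(DTYPE).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


def regression_loss(pred: np.ndarray, target: np.ndarray, kind: str = "mse"):
    """MSE (default) or MAE over all elements, with gradient."""
    diff = pred - target
    n = diff.size
    if kind == "mse":
        return float(np.mean(diff * diff)), (2.0 / n) * diff
    if kind == "mae":
        return float(np.mean(np.abs(diff))), np.sign(diff) / n
    raise ValueError(f"unknown regression loss {kind!r}")
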