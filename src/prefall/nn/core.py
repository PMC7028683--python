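"""A compact NumPy neural-network core: layers, backprop, Adam.

Layers operate on channels-last arrays — sequences are ``[B, T, C]`` and
flat features ``[B, F]`` — so 1-D convolution reduces to a single matrix
product against an im2col view and the recurrent layers consume conv output
directly, with no layout transposes anywhere in a model.

Every layer implements ``forward(x, training)`` caching what its
``backward(dy)`` needs; ``backward`` returns the gradient with respect to
the input and accumulates parameter gradients in place.  Gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ArchitectureError

__all__ = [
    "Parameter",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Dropout",
    "LSTM",
    "LastStep",
    "Softmax",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    name: str = ""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1d(Layer):
    """1-D convolution over [B, T, C_in] -> [B, T', C_out] (stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int,
                 rng: np.random.Generator, name: str = "conv") -> None:
        if kernel < 1 or padding < 0:
            raise ArchitectureError(f"{name}: invalid kernel/padding")
        bound = np.sqrt(6.0 / (in_ch * kernel))
        self.W = Parameter(
            rng.uniform(-bound, bound, size=(kernel * in_ch, out_ch)), f"{name}.W"
        )
        self.b = Parameter(np.zeros(out_ch), f"{name}.b")
        self.kernel = kernel
        self.padding = padding
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.name = name

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def out_len(self, t: int) -> int:
        t_out = t + 2 * self.padding - self.kernel + 1
        if t_out < 1:
            raise ArchitectureError(
                f"{self.name}: input length {t} too short for kernel "
                f"{self.kernel} with padding {self.padding}"
            )
        return t_out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, t, c = x.shape
        t_out = self.out_len(t)
        if self.padding:
            x = np.pad(x, ((0, 0), (self.padding, self.padding), (0, 0)))
        # [B, T_out, K, C] -> [B, T_out, K*C]
        win = sliding_window_view(x, self.kernel, axis=1)  # [B, T_out, C, K]
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b, t_out, -1)
        self._cols = cols
        self._in_len = t
        return cols @ self.W.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t_out, _ = dy.shape
        cols2 = self._cols.reshape(-1, self.kernel * self.in_ch)
        dy2 = dy.reshape(-1, self.out_ch)
        self.W.grad += cols2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.data.T).reshape(b, t_out, self.kernel, self.in_ch)
        t_pad = self._in_len + 2 * self.padding
        dxp = np.zeros((b, t_pad, self.in_ch))
        for k in range(self.kernel):
            dxp[:, k:k + t_out, :] += dcols[:, :, k, :]
        if self.padding:
            dxp = dxp[:, self.padding:-self.padding, :]
        return dxp


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time axes.

    Training uses batch statistics and updates running averages; inference
    uses the running averages.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.name = name

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            n = x.shape[0] * x.shape[1]
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, training)
        return xhat * self.gamma.data + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.data
        if not training:
            dxhat *= invstd
            return dxhat
        n = dy.shape[0] * dy.shape[1]
        mean_d = dxhat.mean(axis=(0, 1))
        mean_dx = np.einsum("btc,btc->c", dxhat, xhat) / n
        dxhat -= mean_d
        dxhat -= xhat * mean_dx
        dxhat *= invstd
        return dxhat


class ReLU(Layer):
    def __init__(self, name: str = "relu") -> None:
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Max pooling over the time axis (floor division on the output length)."""

    def __init__(self, kernel: int = 3, stride: int = 2, name: str = "pool") -> None:
        self.kernel = kernel
        self.stride = stride
        self.name = name

    def out_len(self, t: int) -> int:
        if t < self.kernel:
            raise ArchitectureError(
                f"{self.name}: input length {t} shorter than pooling kernel {self.kernel}"
            )
        return (t - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        t = x.shape[1]
        t_out = self.out_len(t)
        span = (t_out - 1) * self.stride + 1
        # elementwise max over the k shifted strided slices; first max wins
        y = x[:, 0:span:self.stride, :].copy()
        idx = np.zeros(y.shape, dtype=np.int8)
        for i in range(1, self.kernel):
            s = x[:, i:i + span:self.stride, :]
            m = s > y
            np.copyto(y, s, where=m)
            idx[m] = i
        self._idx = idx
        self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t, c = self._in_shape
        t_out = dy.shape[1]
        span = (t_out - 1) * self.stride + 1
        dx = np.zeros((b, t, c))
        for i in range(self.kernel):
            dx[:, i:i + span:self.stride, :] += dy * (self._idx == i)
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 name: str = "fc") -> None:
        bound = np.sqrt(6.0 / in_f)
        self.W = Parameter(rng.uniform(-bound, bound, size=(in_f, out_f)), f"{name}.W")
        self.b = Parameter(np.zeros(out_f), f"{name}.b")
        self.name = name

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator | None = None,
                 name: str = "dropout") -> None:
        if not 0.0 <= p < 1.0:
            raise ArchitectureError(f"{name}: dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Single LSTM layer over [B, T, C] -> full hidden sequence [B, T, H].

    Gate order i, f, g, o; forget-gate bias initialized to 1 (standard trick
    to keep the memory path open early in training).
    """

    def __init__(self, in_f: int, hidden: int, rng: np.random.Generator,
                 name: str = "lstm") -> None:
        bound = 1.0 / np.sqrt(hidden)
        self.Wx = Parameter(rng.uniform(-bound, bound, size=(in_f, 4 * hidden)), f"{name}.Wx")
        self.Wh = Parameter(rng.uniform(-bound, bound, size=(hidden, 4 * hidden)), f"{name}.Wh")
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Parameter(b, f"{name}.b")
        self.hidden = hidden
        self.in_f = in_f
        self.name = name

    def params(self) -> list[Parameter]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        h = self.hidden
        I = np.empty((b, t, h)); F = np.empty((b, t, h))
        G = np.empty((b, t, h)); O = np.empty((b, t, h))
        C = np.empty((b, t, h)); HC = np.empty((b, t, h))
        hs = np.empty((b, t, h))
        h_prev = np.zeros((b, h))
        c_prev = np.zeros((b, h))
        xz = x @ self.Wx.data + self.b.data  # precompute input contribution
        for ti in range(t):
            z = xz[:, ti] + h_prev @ self.Wh.data
            I[:, ti] = _sigmoid(z[:, :h])
            F[:, ti] = _sigmoid(z[:, h:2 * h])
            G[:, ti] = np.tanh(z[:, 2 * h:3 * h])
            O[:, ti] = _sigmoid(z[:, 3 * h:])
            C[:, ti] = F[:, ti] * c_prev + I[:, ti] * G[:, ti]
            HC[:, ti] = np.tanh(C[:, ti])
            hs[:, ti] = O[:, ti] * HC[:, ti]
            h_prev = hs[:, ti]
            c_prev = C[:, ti]
        self._cache = (x, I, F, G, O, C, HC, hs)
        return hs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, I, F, G, O, C, HC, hs = self._cache
        b, t, h = dy.shape
        dx = np.empty_like(x)
        dz_all = np.empty((b, t, 4 * h))
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for ti in range(t - 1, -1, -1):
            dh = dy[:, ti] + dh_next
            c_prev = C[:, ti - 1] if ti > 0 else np.zeros((b, h))
            do = dh * HC[:, ti]
            dc = dh * O[:, ti] * (1.0 - HC[:, ti] ** 2) + dc_next
            di = dc * G[:, ti]
            df = dc * c_prev
            dg = dc * I[:, ti]
            dz = dz_all[:, ti]
            dz[:, :h] = di * I[:, ti] * (1 - I[:, ti])
            dz[:, h:2 * h] = df * F[:, ti] * (1 - F[:, ti])
            dz[:, 2 * h:3 * h] = dg * (1 - G[:, ti] ** 2)
            dz[:, 3 * h:] = do * O[:, ti] * (1 - O[:, ti])
            dh_next = dz @ self.Wh.data.T
            dc_next = dc * F[:, ti]
        # parameter gradients in two big matmuls
        dz2 = dz_all.reshape(-1, 4 * h)
        self.Wx.grad += x.reshape(-1, self.in_f).T @ dz2
        h_prev_seq = np.concatenate([np.zeros((b, 1, h)), hs[:, :-1]], axis=1)
        self.Wh.grad += h_prev_seq.reshape(-1, h).T @ dz2
        self.b.grad += dz2.sum(axis=0)
        dx[...] = (dz2 @ self.Wx.data.T).reshape(x.shape)
        return dx


class LastStep(Layer):
    """Read the final time step: [B, T, C] -> [B, C] (causal head)."""

    def __init__(self, name: str = "last_step") -> None:
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dy
        return dx


class Softmax(Layer):
    def __init__(self, name: str = "softmax") -> None:
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class Sequential:
    """An ordered layer stack with reverse-order backprop."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def forward_traced(self, x: np.ndarray) -> list[tuple[str, tuple]]:
        """Inference-mode forward recording each layer's output shape."""
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            shapes.append((layer.name, x.shape))
        return shapes

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


class Adam:
    """Adam optimizer (no weight decay, no schedule)."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
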