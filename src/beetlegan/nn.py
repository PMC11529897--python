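"""Minimal neural-network engine on numpy.

Layers cache their forward state and implement an explicit backward pass;
gradients accumulate into ``Param.grad`` until :meth:`Module.zero_grad`.
Everything runs in float32.

Internal activation layout is (C, N, H, W) — channel first, then batch. With
this layout im2col/col2im are pure slice arithmetic and every convolution
(forward, input-gradient and weight-gradient) is a single large BLAS matmul
over a (C*k*k) x (N*H*W) patch matrix, which is what makes CPU GAN training
tractable. The model classes convert from/to the conventional NCHW at their
public boundaries.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        # weight decay is conventionally not applied to norm/bias params
        self.decay = decay


# ---------------------------------------------------------------------------
# convolution primitives on (C, N, H, W) activations
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """(C, N, Hp, Wp) -> (C*k*k, N*oh*ow) patch matrix."""
    c, n = xp.shape[:2]
    cols = np.empty((c, k, k, n, oh, ow), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, ki, kj] = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
    return cols.reshape(c * k * k, n * oh * ow)


def _col2im(cols: np.ndarray, c: int, k: int, s: int, p: int,
            n: int, h: int, w: int, oh: int, ow: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`; returns (C, N, H, W)."""
    xp = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(c, k, k, n, oh, ow)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += cols[:, ki, kj]
    if p:
        return np.ascontiguousarray(xp[:, :, p:h + p, p:w + p])
    return xp


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def to_cnhw(x: np.ndarray) -> np.ndarray:
    """Public NCHW batch -> internal CNHW."""
    return np.ascontiguousarray(np.moveaxis(x, 0, 1), dtype=F32)


def to_nchw(x: np.ndarray) -> np.ndarray:
    """Internal CNHW -> public NCHW."""
    return np.ascontiguousarray(np.moveaxis(x, 0, 1))


class Module:
    """Base class: a layer or a container of layers."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)

    # --- serialization -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (params + buffers) in a stable order."""
        out: list[np.ndarray] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v.value)
            elif isinstance(v, Module):
                out.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.state_arrays())
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(
                f"state mismatch: expected {len(own)} arrays, got {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(
                    f"state mismatch: shape {dst.shape} vs {src.shape}")
            dst[...] = src


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, bias: bool = True):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        self.w = Param(rng.normal(0.0, 0.02, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout), decay=False) if bias else None
        self._cache = None

    def forward(self, x, training=False):
        c, n, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = _im2col(_pad(x, p), k, s, oh, ow)           # (CK, NL)
        wmat = self.w.value.reshape(self.cout, -1)
        y = wmat @ cols                                    # (F, NL)
        if self.b is not None:
            y += self.b.value[:, None]
        self._cache = (cols, (n, h, w), (oh, ow))
        return y.reshape(self.cout, n, oh, ow)

    def backward(self, dy):
        cols, (n, h, w), (oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dym = dy.reshape(self.cout, -1)                    # (F, NL)
        self.w.grad += (dym @ cols.T).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dym.sum(axis=1)
        wmat = self.w.value.reshape(self.cout, -1)
        dcols = wmat.T @ dym                               # (CK, NL)
        return _col2im(dcols, self.cin, k, s, p, n, h, w, oh, ow)


class ConvTranspose2d(Module):
    """Fractionally-strided convolution; the adjoint of :class:`Conv2d`."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, bias: bool = True):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        self.w = Param(rng.normal(0.0, 0.02, (cin, cout, k, k)))
        self.b = Param(np.zeros(cout), decay=False) if bias else None
        self._cache = None

    def forward(self, x, training=False):
        c, n, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        ho = (h - 1) * s - 2 * p + k
        wo = (w - 1) * s - 2 * p + k
        xm = x.reshape(c, -1)                              # (Cin, NL)
        wmat = self.w.value.reshape(self.cin, -1)          # (Cin, CoutKK)
        cols = wmat.T @ xm                                 # (CoutKK, NL)
        y = _col2im(cols, self.cout, k, s, p, n, ho, wo, h, w)
        if self.b is not None:
            y += self.b.value[:, None, None, None]
        self._cache = (xm, (n, h, w), (ho, wo))
        return y

    def backward(self, dy):
        xm, (n, h, w), (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        cols_dy = _im2col(_pad(dy, p), k, s, h, w)         # (CoutKK, NL)
        self.w.grad += (xm @ cols_dy.T).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(1, 2, 3))
        wmat = self.w.value.reshape(self.cin, -1)
        dx = wmat @ cols_dy                                # (Cin, NL)
        return dx.reshape(self.cin, n, h, w)


class BatchNorm2d(Module):
    def __init__(self, c: int, rng: np.random.Generator,
                 eps: float = 1e-5, momentum: float = 0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(rng.normal(1.0, 0.02, c), decay=False)
        self.beta = Param(np.zeros(c), decay=False)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            m = self.momentum
            self.run_mean = ((1 - m) * self.run_mean + m * mean).astype(F32)
            self.run_var = ((1 - m) * self.run_var + m * var).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean.astype(F32)[:, None, None, None]) \
            * inv[:, None, None, None]
        self._cache = (xhat, inv, training)
        return self.gamma.value[:, None, None, None] * xhat \
            + self.beta.value[:, None, None, None]

    def backward(self, dy):
        xhat, inv, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        g = (self.gamma.value * inv)[:, None, None, None]
        if not training:
            return dy * g
        m = dy.shape[1] * dy.shape[2] * dy.shape[3]
        dy_mean = dy.mean(axis=(1, 2, 3))[:, None, None, None]
        proj = ((dy * xhat).sum(axis=(1, 2, 3)) / m)[:, None, None, None]
        return g * (dy - dy_mean - xhat * proj)

    def state_arrays(self):
        return [self.gamma.value, self.beta.value, self.run_mean, self.run_var]


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = F32(slope)

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Tanh(Module):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class Dropout(Module):
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Linear(Module):
    """Dense layer on (batch, features) inputs."""

    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.nin, self.nout = nin, nout
        self.w = Param(rng.normal(0.0, 0.02, (nout, nin)))
        self.b = Param(np.zeros(nout), decay=False)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class ChannelAttention(Module):
    """Squeeze-excite channel gating: pool -> C/r bottleneck -> sigmoid scale.

    The gate re-weights feature-map channels so the generator can emphasise
    the spectrally informative ones.
    """

    def __init__(self, c: int, reduction: int, rng: np.random.Generator):
        if c % reduction != 0:
            raise ValueError(
                f"channel count {c} not divisible by reduction {reduction}")
        self.c, self.reduction = c, reduction
        self.fc1 = Linear(c, c // reduction, rng)
        self.relu = ReLU()
        self.fc2 = Linear(c // reduction, c, rng)
        self._cache = None

    def _gate(self, x: np.ndarray) -> np.ndarray:
        pooled = x.mean(axis=(2, 3)).T                      # (N, C)
        z = self.fc2(self.relu(self.fc1(pooled)))
        return (1.0 / (1.0 + np.exp(-z))).astype(F32)       # sigmoid

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gate values in (0, 1); shape (N, C)."""
        return self._gate(x)

    def forward(self, x, training=False):
        wgt = self._gate(x)                                 # (N, C)
        self._cache = (x, wgt, x.shape[2] * x.shape[3])
        return x * wgt.T[:, :, None, None]

    def backward(self, dy):
        x, wgt, hw = self._cache
        dwgt = (dy * x).sum(axis=(2, 3)).T                  # (N, C)
        dz = dwgt * wgt * (1.0 - wgt)
        dpooled = self.fc1.backward(self.relu.backward(self.fc2.backward(dz)))
        dx = dy * wgt.T[:, :, None, None]
        dx += dpooled.T[:, :, None, None] / F32(hw)
        return dx


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, _EPS, 1.0 - _EPS)


def log_softmax(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def bce_loss(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy against a constant 0/1 target.

    Returns (mean loss, gradient w.r.t. p).
    """
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly inside (0, 1); "
                         "is a sigmoid missing?")
    p64 = p.astype(np.float64)
    n = p.size
    if target >= 0.5:
        loss = -np.log(p64).mean()
        grad = (-1.0 / p64) / n
    else:
        loss = -np.log1p(-p64).mean()
        grad = (1.0 / (1.0 - p64)) / n
    return float(loss), grad.astype(F32)


def nll_loss(logp: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood of integer labels under log-probabilities."""
    n = logp.shape[0]
    idx = np.arange(n)
    loss = -float(logp[idx, labels].mean())
    grad = np.zeros_like(logp)
    grad[idx, labels] = -1.0 / n
    return loss, grad


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2-coupled weight decay (grad += wd * param)."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
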