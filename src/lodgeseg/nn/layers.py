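"""Layer primitives with explicit forward/backward passes.

Conventions: activations are float32 arrays shaped (B, C, H, W); each layer
caches what its backward pass needs during forward and frees it on backward.
7x7 convolutions use a shift-and-accumulate scheme (49 vectorized adds) that
avoids materializing im2col buffers, keeping peak memory at a few activation
maps even for wide layers.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

_F32 = np.float32
_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class; subclasses define forward(x) and backward(dout)."""

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for value in vars(self).values():
            if isinstance(value, Param):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _init_conv(
    rng: np.random.Generator, shape: tuple[int, ...], std: float | None = None, fan_in: int = 0
) -> np.ndarray:
    """He (fan-in) normal initialization unless an explicit std is given."""
    if std is None:
        std = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape)


class PointwiseConv(Module):
    """1x1 convolution: channel mixing via a (C_out, C_in) matrix plus bias."""

    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator, std: float | None = None
    ):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(_init_conv(rng, (c_out, c_in), std, fan_in=c_in))
        self.bias = Param(np.zeros(c_out))
        self._x2 = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        x2 = x.reshape(b, c, h * w)
        y = np.matmul(self.weight.data, x2) + self.bias.data[:, None]
        self._x2, self._shape = x2, (b, c, h, w)
        return y.reshape(b, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        d2 = dout.reshape(b, self.c_out, h * w)
        self.weight.grad += np.einsum("bow,bcw->oc", d2, self._x2, optimize=True)
        self.bias.grad += d2.sum(axis=(0, 2))
        dx = np.matmul(self.weight.data.T, d2)
        self._x2 = None
        return dx.reshape(b, c, h, w)


class DenseConv7(Module):
    """Full 7x7 convolution, stride 1, padding 3 (used for the RGB stem)."""

    K = 7
    PAD = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(
            _init_conv(rng, (c_out, c_in, self.K, self.K), fan_in=self.K * self.K * c_in)
        )
        self.bias = Param(np.zeros(c_out))
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.PAD, self.PAD), (self.PAD, self.PAD)))
        out = np.broadcast_to(
            self.bias.data[None, :, None, None], (b, self.c_out, h, w)
        ).copy()
        wgt = self.weight.data
        for u in range(self.K):
            for v in range(self.K):
                out += np.einsum(
                    "bchw,oc->bohw", xp[:, :, u : u + h, v : v + w], wgt[:, :, u, v],
                    optimize=True,
                )
        self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h, w = dout.shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        wgt = self.weight.data
        for u in range(self.K):
            for v in range(self.K):
                patch = xp[:, :, u : u + h, v : v + w]
                self.weight.grad[:, :, u, v] += np.einsum(
                    "bohw,bchw->oc", dout, patch, optimize=True
                )
                dxp[:, :, u : u + h, v : v + w] += np.einsum(
                    "bohw,oc->bchw", dout, wgt[:, :, u, v], optimize=True
                )
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        self._xp = None
        return dxp[:, :, self.PAD : -self.PAD, self.PAD : -self.PAD]


class DepthwiseConv7(Module):
    """7x7 depthwise convolution: one 7x7 filter per channel, padding 3."""

    K = 7
    PAD = 3

    def __init__(self, channels: int, rng: np.random.Generator, std: float | None = None):
        self.channels = channels
        self.weight = Param(
            _init_conv(rng, (channels, self.K, self.K), std, fan_in=self.K * self.K)
        )
        self.bias = Param(np.zeros(channels))
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.PAD, self.PAD), (self.PAD, self.PAD)))
        out = np.broadcast_to(self.bias.data[None, :, None, None], x.shape).copy()
        wgt = self.weight.data
        for u in range(self.K):
            for v in range(self.K):
                out += wgt[None, :, u, v, None, None] * xp[:, :, u : u + h, v : v + w]
        self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = dout.shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        wgt = self.weight.data
        for u in range(self.K):
            for v in range(self.K):
                patch = xp[:, :, u : u + h, v : v + w]
                self.weight.grad[:, u, v] += np.einsum("bchw,bchw->c", dout, patch)
                dxp[:, :, u : u + h, v : v + w] += wgt[None, :, u, v, None, None] * dout
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        self._xp = None
        return dxp[:, :, self.PAD : -self.PAD, self.PAD : -self.PAD]


class Downsample2x2(Module):
    """2x2 stride-2 convolution via space-to-depth + channel mixing.

    Equivalent to a standard K=2, S=2 convolution with weight (C_out, C_in, 2, 2);
    the weight is stored flattened as (C_out, 4*C_in) in (c, u, v) order.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, std: float | None = None):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(_init_conv(rng, (c_out, 4 * c_in), std, fan_in=4 * c_in))
        self.bias = Param(np.zeros(c_out))
        self._cols = None
        self._shape = None

    @staticmethod
    def _space_to_depth(x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        y = x.reshape(b, c, h // 2, 2, w // 2, 2)
        return y.transpose(0, 1, 3, 5, 2, 4).reshape(b, 4 * c, h // 2, w // 2)

    @staticmethod
    def _depth_to_space(y: np.ndarray, c: int) -> np.ndarray:
        b, c4, hh, ww = y.shape
        x = y.reshape(b, c, 2, 2, hh, ww).transpose(0, 1, 4, 2, 5, 3)
        return x.reshape(b, c, hh * 2, ww * 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h},{w}) not divisible by 2")
        cols = self._space_to_depth(x).reshape(b, 4 * c, (h // 2) * (w // 2))
        y = np.matmul(self.weight.data, cols) + self.bias.data[:, None]
        self._cols, self._shape = cols, (b, c, h, w)
        return y.reshape(b, self.c_out, h // 2, w // 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        d2 = dout.reshape(b, self.c_out, (h // 2) * (w // 2))
        self.weight.grad += np.einsum("bow,bcw->oc", d2, self._cols, optimize=True)
        self.bias.grad += d2.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.data.T, d2).reshape(b, 4 * c, h // 2, w // 2)
        self._cols = None
        return self._depth_to_space(dcols, c)


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis at each spatial position."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.channels = channels
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        c = self.channels
        self.gamma.grad += np.einsum("bchw,bchw->c", dout, xhat)
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        mean_d = dxhat.mean(axis=1, keepdims=True)
        mean_dx = np.mean(dxhat * xhat, axis=1, keepdims=True)
        self._cache = None
        return inv * (dxhat - mean_d - xhat * mean_dx)


class GELU(Module):
    """Exact Gaussian error linear unit."""

    def __init__(self):
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (0.5 * x * (1.0 + erf(x * _INV_SQRT2))).astype(_F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        self._x = None
        return (dout * (cdf + x * pdf)).astype(_F32)


class BilinearUp2(Module):
    """x2 bilinear upsampling (half-pixel centers), separable matrix form."""

    def __init__(self):
        self._mats: dict[int, np.ndarray] = {}
        self._size = None

    def _matrix(self, n: int) -> np.ndarray:
        m = self._mats.get(n)
        if m is None:
            m = np.zeros((2 * n, n), dtype=_F32)
            for i in range(2 * n):
                src = (i + 0.5) / 2.0 - 0.5
                i0 = int(math.floor(src))
                frac = src - i0
                i0c = min(max(i0, 0), n - 1)
                i1c = min(max(i0 + 1, 0), n - 1)
                m[i, i0c] += 1.0 - frac
                m[i, i1c] += frac
            self._mats[n] = m
        return m

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        mh, mw = self._matrix(h), self._matrix(w)
        self._size = (h, w)
        y = np.einsum("oh,bchw->bcow", mh, x, optimize=True)
        return np.einsum("pw,bcow->bcop", mw, y, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._size
        mh, mw = self._matrix(h), self._matrix(w)
        d = np.einsum("pw,bcop->bcow", mw, dout, optimize=True)
        return np.einsum("oh,bcow->bchw", mh, d, optimize=True)


class ConvNeXtBlock(Module):
    """dw7x7 -> channel LN -> 1x1 expand -> GELU -> 1x1 project -> residual.

    When the input width differs from the projection output the residual is
    aligned parameter-free: surplus input channels are cropped, missing ones
    zero-padded.  This keeps the residual path out of the parameter and FLOP
    budgets, so independently tuned per-layer widths never add hidden cost.
    """

    def __init__(self, c_in: int, c_expand: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_expand, self.c_out = c_in, c_expand, c_out
        self.dw = DepthwiseConv7(c_in, rng)
        self.norm = ChannelLayerNorm(c_in)
        self.expand = PointwiseConv(c_in, c_expand, rng)
        self.act = GELU()
        self.project = PointwiseConv(c_expand, c_out, rng)

    def _align(self, x: np.ndarray) -> np.ndarray:
        if self.c_in == self.c_out:
            return x
        if self.c_in > self.c_out:
            return x[:, : self.c_out]
        pad = self.c_out - self.c_in
        return np.pad(x, ((0, 0), (0, pad), (0, 0), (0, 0)))

    def _align_grad(self, dout: np.ndarray) -> np.ndarray:
        if self.c_in == self.c_out:
            return dout
        if self.c_in > self.c_out:
            pad = self.c_in - self.c_out
            return np.pad(dout, ((0, 0), (0, pad), (0, 0), (0, 0)))
        return dout[:, : self.c_in]

    def forward(self, x: np.ndarray) -> np.ndarray:
        t = self.dw.forward(x)
        t = self.norm.forward(t)
        t = self.expand.forward(t)
        t = self.act.forward(t)
        t = self.project.forward(t)
        return t + self._align(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ds = self._align_grad(dout)
        d = self.project.backward(dout)
        d = self.act.backward(d)
        d = self.expand.backward(d)
        d = self.norm.backward(d)
        d = self.dw.backward(d)
        return d + ds
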