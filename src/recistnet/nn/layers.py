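from __future__ import annotations

import numpy as np

from .core import Module, Parameter

_OFFSETS3 = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def _pad_spatial(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


class Conv3d(Module):
    """Full (non-separated) 3x3x3 convolution, stride 1, padding 1.

    Used for the stem; implemented as a shift-and-accumulate over the 27
    kernel taps so no im2col buffer is ever materialised.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.w = Parameter(_he_init(rng, (c_out, c_in, 3, 3, 3), c_in * 27, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self._cache = None

    def forward(self, x, train=False):
        if x.ndim != 5 or x.shape[1] != self.c_in:
            raise ValueError(f"expected input (N,{self.c_in},D,H,W), got {x.shape}")
        n, _, d, h, w = x.shape
        xp = _pad_spatial(x)
        out = np.zeros((n, self.c_out, d, h, w), dtype=x.dtype)
        for dz, dy, dx in _OFFSETS3:
            win = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
            # (c_out,c_in) x (n,c_in,d,h,w) -> (c_out,n,d,h,w)
            out += np.tensordot(self.w.value[:, :, dz, dy, dx], win, axes=([1], [1])).transpose(1, 0, 2, 3, 4)
        out += self.b.value[None, :, None, None, None]
        self._cache = xp
        return out

    def backward(self, grad):
        xp = self._cache
        self._cache = None
        n, _, dp, hp, wp = xp.shape
        d, h, w = dp - 2, hp - 2, wp - 2
        gxp = np.zeros_like(xp)
        for dz, dy, dx in _OFFSETS3:
            win = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
            self.w.grad[:, :, dz, dy, dx] += np.tensordot(grad, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            gxp[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += np.tensordot(
                self.w.value[:, :, dz, dy, dx], grad, axes=([0], [1])
            ).transpose(1, 0, 2, 3, 4)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        return gxp[:, :, 1:-1, 1:-1, 1:-1]


class DepthwiseConv3d(Module):
    """Per-channel 3x3x3 convolution, stride 1, padding 1, no bias."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float64):
        self.channels = channels
        self.w = Parameter(_he_init(rng, (channels, 3, 3, 3), 27, dtype))
        self._cache = None

    def forward(self, x, train=False):
        if x.ndim != 5 or x.shape[1] != self.channels:
            raise ValueError(f"expected input (N,{self.channels},D,H,W), got {x.shape}")
        n, c, d, h, w = x.shape
        xp = _pad_spatial(x)
        out = np.zeros_like(x)
        for dz, dy, dx in _OFFSETS3:
            out += self.w.value[None, :, dz, dy, dx, None, None, None] * xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
        self._cache = xp
        return out

    def backward(self, grad):
        xp = self._cache
        self._cache = None
        n, c, dp, hp, wp = xp.shape
        d, h, w = dp - 2, hp - 2, wp - 2
        gxp = np.zeros_like(xp)
        for dz, dy, dx in _OFFSETS3:
            win = xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w]
            self.w.grad[:, dz, dy, dx] += (grad * win).sum(axis=(0, 2, 3, 4))
            gxp[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += self.w.value[None, :, dz, dy, dx, None, None, None] * grad
        return gxp[:, :, 1:-1, 1:-1, 1:-1]


class PointwiseConv3d(Module):
    """1x1x1 convolution (pure channel mixing)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True, dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.w = Parameter(_he_init(rng, (c_out, c_in), c_in, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None
        self._cache = None

    def named_parameters(self, prefix: str = ""):
        yield (prefix + "w" if prefix else "w"), self.w
        if self.b is not None:
            yield (prefix + "b" if prefix else "b"), self.b

    def forward(self, x, train=False):
        if x.ndim != 5 or x.shape[1] != self.c_in:
            raise ValueError(f"expected input (N,{self.c_in},D,H,W), got {x.shape}")
        out = np.tensordot(self.w.value, x, axes=([1], [1])).transpose(1, 0, 2, 3, 4)
        if self.b is not None:
            out = out + self.b.value[None, :, None, None, None]
        self._cache = x
        return out

    def backward(self, grad):
        x = self._cache
        self._cache = None
        self.w.grad += np.tensordot(grad, x, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        return np.tensordot(self.w.value, grad, axes=([0], [1])).transpose(1, 0, 2, 3, 4)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float64):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[None, :, None, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return out

    def backward(self, grad):
        xhat, inv, train, shape = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        if not train:
            return grad * g * inv[None, :, None, None, None]
        m = shape[0] * shape[2] * shape[3] * shape[4]
        gxhat = grad * g
        # standard batch-norm backward over the normalisation axes
        return (inv[None, :, None, None, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=axes, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
        )


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        mask = self._mask
        self._mask = None
        return np.where(mask, grad, 0.0)


class MaxPool3d(Module):
    """Max pooling, nominal kernel/stride 2, clamped per axis to min(2, size).

    An axis already reduced to 1 passes through unchanged, so repeated
    application converges to a 1x1x1 spatial map.  Trailing elements of an
    odd-sized axis are dropped (floor division), matching stride-2 pooling.
    """

    def __init__(self):
        self._cache = None

    @staticmethod
    def kernel_for(shape) -> tuple[int, int, int]:
        return tuple(min(2, s) for s in shape)

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        kd, kh, kw = self.kernel_for((d, h, w))
        od, oh, ow = d // kd, h // kh, w // kw
        xc = x[:, :, : od * kd, : oh * kh, : ow * kw]
        xr = xc.reshape(n, c, od, kd, oh, kh, ow, kw).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        flat = xr.reshape(n, c, od, oh, ow, kd * kh * kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, (kd, kh, kw), idx)
        return out

    def backward(self, grad):
        (n, c, d, h, w), (kd, kh, kw), idx = self._cache
        self._cache = None
        od, oh, ow = d // kd, h // kh, w // kw
        flat = np.zeros((n, c, od, oh, ow, kd * kh * kw), dtype=grad.dtype)
        np.put_along_axis(flat, idx[..., None], grad[..., None], axis=-1)
        xr = flat.reshape(n, c, od, oh, ow, kd, kh, kw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros((n, c, d, h, w), dtype=grad.dtype)
        gx[:, :, : od * kd, : oh * kh, : ow * kw] = xr.reshape(n, c, od * kd, oh * kh, ow * kw)
        return gx


class Flatten(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        shape = self._shape
        self._shape = None
        return grad.reshape(shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float64):
        self.n_in, self.n_out = n_in, n_out
        self.w = Parameter(_he_init(rng, (n_out, n_in), n_in, dtype))
        self.b = Parameter(np.zeros(n_out, dtype=dtype))
        self._cache = None

    def forward(self, x, train=False):
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"expected input (N,{self.n_in}), got {x.shape}")
        self._cache = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        x = self._cache
        self._cache = None
        self.w.grad += grad.T @ x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
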