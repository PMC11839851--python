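"""Minimal CPU neural-network layers with explicit backpropagation.

All tensors are float32 ``numpy`` arrays in NCHW layout.  Each layer caches
what its backward pass needs during ``forward`` and releases it afterwards;
layers are therefore stateful and not re-entrant, which is fine for the
single-threaded training loops used here.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

DTYPE = np.float32


class Parameter:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter discovery by attribute reflection."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data[...] = arr


def _im2col(xp: np.ndarray, k: int, stride: int, h_out: int, w_out: int) -> np.ndarray:
    """Lower a padded NCHW tensor to GEMM form (B, C*k*k, Ho*Wo).

    The copy keeps the W axis innermost, so for stride 1 each row is a
    contiguous memcpy.
    """
    b, c, _, _ = xp.shape
    sb, sc, sh, sw = xp.strides
    windows = as_strided(
        xp,
        shape=(b, c, k, k, h_out, w_out),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(windows).reshape(b, c * k * k, h_out * w_out)


class Conv2d(Module):
    """2D convolution (cross-correlation), bias-free by default.

    He-normal weight init: std = sqrt(2 / fan_in), fan_in = C_in * k * k.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Parameter(w, "conv.weight")
        self.bias = Parameter(np.zeros(out_channels), "conv.bias") if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected input of shape (B, {self.in_channels}, H, W), got {x.shape}"
            )
        b, _, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        h_out = (h + 2 * p - k) // s + 1
        w_out = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, h_out, w_out)
        w2 = self.weight.data.reshape(self.out_channels, -1)
        y = np.matmul(w2, cols)  # (B, O, Ho*Wo), batched GEMM
        if self.bias is not None:
            y += self.bias.data[:, None]
        self._cache = (cols, x.shape, h_out, w_out)
        return y.reshape(b, self.out_channels, h_out, w_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, h_out, w_out = self._cache
        self._cache = None
        b, c, h, w = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        dy3 = dy.reshape(b, self.out_channels, h_out * w_out)
        self.weight.grad += np.tensordot(dy3, cols, axes=([0, 2], [0, 2])).reshape(
            self.weight.data.shape
        )
        if self.bias is not None:
            self.bias.grad += dy3.sum(axis=(0, 2))
        w2 = self.weight.data.reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, dy3).reshape(b, c, k, k, h_out, w_out)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        # fold columns back with k*k vectorized slice-adds
        for kh in range(k):
            for kw in range(k):
                dxp[:, :, kh : kh + s * h_out : s, kw : kw + s * w_out : s] += dcols[
                    :, :, kh, kw
                ]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with affine transform and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.weight = Parameter(np.ones(channels), "bn.weight")
        self.bias = Parameter(np.zeros(channels), "bn.bias")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        y = self.weight.data[:, None, None] * xhat + self.bias.data[:, None, None]
        if self.training:
            self._cache = (xhat, inv_std)
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.weight.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        g = dy * self.weight.data[:, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = inv_std[:, None, None] * (g - gsum / n - xhat * gxsum / n)
        return dx.astype(DTYPE, copy=False)


class ReLU(Module):
    """Rectifier; operates in place (inputs here are always freshly
    allocated by the preceding layer)."""

    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.maximum(x, 0.0, out=x) if x.flags.writeable else np.maximum(x, 0.0)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        dy = dy if dy.flags.writeable else dy.copy()
        dy[y <= 0] = 0.0
        return dy


class MaxPool2d(Module):
    """Max pooling with overlapping windows (kernel 3, stride 2, pad 1 default)."""

    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        h_out = (h + 2 * p - k) // s + 1
        w_out = (w + 2 * p - k) // s + 1
        sb, sc, sh, sw = xp.strides
        windows = as_strided(
            xp,
            shape=(b, c, h_out, w_out, k, k),
            strides=(sb, sc, sh * s, sw * s, sh, sw),
            writeable=False,
        )
        flat = windows.reshape(b, c, h_out, w_out, k * k)
        idx = flat.argmax(axis=4)
        y = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        self._cache = None
        b, c, h, w = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        h_out, w_out = dy.shape[2], dy.shape[3]
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        bb, cc, ho, wo = np.indices((b, c, h_out, w_out), sparse=False)
        h_in = ho * s + idx // k
        w_in = wo * s + idx % k
        np.add.at(dxp, (bb, cc, h_in, w_in), dy)
        return dxp[:, :, p : p + h, p : p + w]


class GlobalAvgPool(Module):
    def __init__(self):
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(
            dy[:, :, None, None] / (h * w), dy.shape + (h, w)
        ).astype(DTYPE)


class Linear(Module):
    """Fully connected layer; uniform fan-in init (U[-1/sqrt(n), 1/sqrt(n)])."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)), "fc.weight"
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features), "fc.bias")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data
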