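"""Minimal NumPy layers with explicit forward/backward passes.

All layers operate on 5-D video tensors shaped ``(N, C, T, H, W)`` in
``float32`` by default (``float64`` is supported for numerical gradient
checks).  Each layer caches whatever its backward pass needs during
``forward(..., training=True)``; ``backward`` accumulates into
``Param.grad`` and returns the gradient with respect to its input.

Convolutions use "same"-style symmetric padding of ``(k - 1) // 2`` per
axis, so a kernel never shrinks an axis beyond what its stride dictates:
``out = floor((L + 2p - k) / s) + 1``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool3d",
    "Linear",
    "Dropout",
    "softmax",
    "cross_entropy",
    "conv_output_len",
]


def conv_output_len(length: int, kernel: int, stride: int, pad: int) -> int:
    """Output extent of a padded, strided correlation along one axis."""
    return (length + 2 * pad - kernel) // stride + 1


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3-D correlation without bias (normalization supplies the shift).

    Weight shape is ``(c_out, c_in, kt, kh, kw)``; padding is fixed at
    ``(k - 1) // 2`` per axis.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int],
        stride: tuple[int, int, int] = (1, 1, 1),
        dtype=np.float32,
        name: str = "conv",
        input_grad: bool = True,
    ):
        kt, kh, kw = kernel
        self.stride = tuple(stride)
        self.pad = ((kt - 1) // 2, (kh - 1) // 2, (kw - 1) // 2)
        self.weight = Param(
            np.zeros((c_out, c_in, kt, kh, kw), dtype=dtype), f"{name}.weight"
        )
        # first layers may skip the input-gradient scatter entirely
        self.input_grad = input_grad
        self._cols: np.ndarray | None = None
        self._xp_shape: tuple | None = None
        self._out_sizes: tuple | None = None

    @property
    def fan_in(self) -> int:
        return int(np.prod(self.weight.value.shape[1:]))

    def params(self) -> list[Param]:
        return [self.weight]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """Materialize windows as a (N*To*Ho*Wo, C*kt*kh*kw) matrix."""
        (pt, ph, pw), (st, sh, sw) = self.pad, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        self._xp_shape = xp.shape
        win = sliding_window_view(xp, self.weight.value.shape[2:], axis=(2, 3, 4))
        win = win[:, :, ::st, ::sh, ::sw]
        n, c, to, ho, wo, kt, kh, kw = win.shape
        self._out_sizes = (n, to, ho, wo)
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            n * to * ho * wo, c * kt * kh * kw
        )
        return cols  # the reshape copies: cols is contiguous

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cols = self._im2col(x)
        self._cols = cols if training else None
        c_out = self.weight.value.shape[0]
        out = cols @ self.weight.value.reshape(c_out, -1).T
        n, to, ho, wo = self._out_sizes
        return np.ascontiguousarray(
            out.reshape(n, to, ho, wo, c_out).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        if self._cols is None:
            raise RuntimeError("backward called without a training-mode forward")
        c_out = self.weight.value.shape[0]
        d2d = dout.transpose(0, 2, 3, 4, 1).reshape(-1, c_out)
        self.weight.grad += (d2d.T @ self._cols).reshape(self.weight.value.shape)
        self._cols = None
        if not self.input_grad:
            return None
        # scatter gradient back through the overlapping windows
        W2d = self.weight.value.reshape(c_out, -1)
        n, to, ho, wo = self._out_sizes
        c_in = self.weight.value.shape[1]
        kt, kh, kw = self.weight.value.shape[2:]
        dcols = (d2d @ W2d).reshape(n, to, ho, wo, c_in, kt, kh, kw)
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        (st, sh, sw) = self.stride
        for i in range(kt):
            ti = slice(i, i + (to - 1) * st + 1, st)
            for j in range(kh):
                hj = slice(j, j + (ho - 1) * sh + 1, sh)
                for k in range(kw):
                    wk = slice(k, k + (wo - 1) * sw + 1, sw)
                    dxp[:, :, ti, hj, wk] += dcols[..., i, j, k].transpose(
                        0, 4, 1, 2, 3
                    )
        (pt, ph, pw) = self.pad
        _, _, Tp, Hp, Wp = self._xp_shape
        return dxp[:, :, pt : Tp - pt, ph : Hp - ph, pw : Wp - pw]


class BatchNorm3d(Layer):
    """Batch normalization over (N, T, H, W) per channel, affine."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn"):
        self.gamma = Param(np.ones(c, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v[None, :, None, None, None]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[1]
            unbiased = var * (n / max(n - 1, 1))
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(inv_std)
        if training:
            self._cache = (xhat, inv_std)
        return self._bc(self.gamma.value) * xhat + self._bc(self.beta.value)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        self.beta.grad += dout.sum(axis=axes)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        n = dout.size // dout.shape[1]
        dxhat = dout * self._bc(self.gamma.value)
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        dx = (dxhat - self._bc(s1 / n) - xhat * self._bc(s2 / n)) * self._bc(inv_std)
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """Spatial max pooling; temporal kernel extent must be 1."""

    def __init__(self, kernel: tuple[int, int, int] = (1, 3, 3),
                 stride: tuple[int, int, int] = (1, 2, 2)):
        if kernel[0] != 1 or stride[0] != 1:
            raise ValueError("only spatial pooling is supported")
        self.kernel = kernel
        self.stride = stride
        self.pad = (0, (kernel[1] - 1) // 2, (kernel[2] - 1) // 2)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        _, ph, pw = self.pad
        _, kh, kw = self.kernel
        _, sh, sw = self.stride
        xp = np.pad(
            x, ((0, 0), (0, 0), (0, 0), (ph, ph), (pw, pw)),
            constant_values=-np.inf,
        )
        win = sliding_window_view(xp, (kh, kw), axis=(3, 4))[:, :, :, ::sh, ::sw]
        flat = win.reshape(*win.shape[:5], kh * kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, xp.shape, out.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xp_shape, out_shape = self._cache
        _, kh, kw = self.kernel
        _, sh, sw = self.stride
        _, ph, pw = self.pad
        Ho, Wo = out_shape[3], out_shape[4]
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for j in range(kh):
            hj = slice(j, j + (Ho - 1) * sh + 1, sh)
            for k in range(kw):
                wk = slice(k, k + (Wo - 1) * sw + 1, sw)
                mask = idx == (j * kw + k)
                dxp[:, :, :, hj, wk] += dout * mask
        Hp, Wp = xp_shape[3], xp_shape[4]
        self._cache = None
        return dxp[:, :, :, ph : Hp - ph, pw : Wp - pw]


class GlobalAvgPool3d(Layer):
    """Mean over (T, H, W), producing (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, T, H, W = self._shape
        scale = 1.0 / (T * H * W)
        self._shape = None
        return np.broadcast_to(
            dout[:, :, None, None, None] * scale, (N, C, T, H, W)
        ).astype(dout.dtype).copy()


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, dtype=np.float32, name: str = "fc"):
        self.weight = Param(np.zeros((n_out, n_in), dtype=dtype), f"{name}.weight")
        self.bias = Param(np.zeros(n_out, dtype=dtype), f"{name}.bias")
        self._x = None

    @property
    def fan_in(self) -> int:
        return self.weight.value.shape[1]

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate is 0."""

    def __init__(self, rate: float = 0.5):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns ``(loss, dlogits)``."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
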