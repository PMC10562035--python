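"""Minimal CPU engine for small 3D convolutional networks.

Implements exactly the pieces the dose-prediction U-Net needs — 3D "same"
convolution (im2col + matmul), ReLU, 2x max pooling, stride-2 transposed
convolution, channel concatenation, mean-L1 loss and the Adam update — with
hand-written reverse-mode gradients.  Single-sample layout ``(C, X, Y, Z)``
in float32 (training uses batch size 1).

The design goal is reproducibility and clarity at desk scale, not speed at
clinical scale: all heavy lifting is delegated to BLAS through ``matmul``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "ConvTranspose3d",
    "ReLU",
    "MaxPool3d",
    "l1_loss",
    "Adam",
]


@dataclass
class Param:
    """A trainable tensor with its gradient accumulator."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d:
    """3D convolution, odd kernel, zero "same" padding, unit stride."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, kernel
        self.weight = Param(_he_init(rng, (cout, cin * kernel**3), cin * kernel**3))
        self.bias = Param(np.zeros(cout, dtype=np.float32))
        self._col: np.ndarray | None = None
        self._spatial: tuple[int, int, int] | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        c = x.shape[0]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # (c, X, Y, Z, k, k, k) -> (X*Y*Z, c*k^3)
        n = x.shape[1] * x.shape[2] * x.shape[3]
        return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(n, c * k**3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[1:]
        col = self._im2col(x)
        self._col = col
        out = col @ self.weight.value.T + self.bias.value
        return np.ascontiguousarray(out.reshape(*self._spatial, self.cout).transpose(3, 0, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = int(np.prod(self._spatial))
        dflat = np.ascontiguousarray(dout.transpose(1, 2, 3, 0)).reshape(n, self.cout)
        self.weight.grad += dflat.T @ self._col
        self.bias.grad += dflat.sum(axis=0)
        # dx = "full" correlation of dout with the spatially flipped,
        # channel-transposed kernel == same-padded conv with that kernel
        k = self.k
        w = self.weight.value.reshape(self.cout, self.cin, k, k, k)
        w_rot = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).reshape(
            self.cin, self.cout * k**3
        )
        p = k // 2
        dp = np.pad(dout, ((0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(dp, (k, k, k), axis=(1, 2, 3))
        col = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            n, self.cout * k**3
        )
        dx = (col @ w_rot.T).reshape(*self._spatial, self.cin).transpose(3, 0, 1, 2)
        self._col = None
        return np.ascontiguousarray(dx)


class ConvTranspose3d:
    """Transposed convolution with kernel 2 and stride 2 (doubles each
    spatial dimension); the standard learned-upsampling block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.weight = Param(_he_init(rng, (cin, cout * 8), cin))
        self.bias = Param(np.zeros(cout, dtype=np.float32))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        c, X, Y, Z = x.shape
        flat = np.ascontiguousarray(x.transpose(1, 2, 3, 0)).reshape(-1, c)
        out = (flat @ self.weight.value).reshape(X, Y, Z, self.cout, 2, 2, 2)
        out = out.transpose(3, 0, 4, 1, 5, 2, 6).reshape(self.cout, 2 * X, 2 * Y, 2 * Z)
        return np.ascontiguousarray(out + self.bias.value[:, None, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, X, Y, Z = self._x.shape
        self.bias.grad += dout.sum(axis=(1, 2, 3))
        d = dout.reshape(self.cout, X, 2, Y, 2, Z, 2).transpose(1, 3, 5, 0, 2, 4, 6)
        dflat = np.ascontiguousarray(d).reshape(-1, self.cout * 8)
        xflat = np.ascontiguousarray(self._x.transpose(1, 2, 3, 0)).reshape(-1, c)
        self.weight.grad += xflat.T @ dflat
        dx = (dflat @ self.weight.value.T).reshape(X, Y, Z, c).transpose(3, 0, 1, 2)
        self._x = None
        return np.ascontiguousarray(dx)


class ReLU:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool3d:
    """2x2x2 max pooling, stride 2; spatial dims must be even."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"pooling needs even spatial dims, got {(X, Y, Z)}")
        blocks = x.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, X // 2, Y // 2, Z // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._shape = (c, X, Y, Z)
        return blocks.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, X, Y, Z = self._shape
        flat = np.zeros((c, X // 2, Y // 2, Z // 2, 8), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        flat = flat.reshape(c, X // 2, Y // 2, Z // 2, 2, 2, 2)
        return np.ascontiguousarray(
            flat.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, X, Y, Z)
        )


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(pred.dtype)
    return loss, grad


class Adam:
    """Adam with the framework-default moments (0.9, 0.999, eps 1e-7)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
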