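"""Minimal NumPy layers with hand-written backprop, plus Adam.

Only what the compact U-Net needs: 2-D convolution (im2col + BLAS matmul),
instance normalization, ReLU, 2x2 max pooling, nearest-neighbor x2
upsampling.  All layer tensors are ``(N, H, W, C)`` float32 — channels-last
keeps the im2col matrices contiguous, so the conv matmuls need no transpose
copies.  Every layer caches what its backward pass needs, so layer instances
are stateful within a forward/backward pair.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "InstanceNorm", "ReLU", "MaxPool2", "Upsample2", "Adam"]


class Param:
    """A learnable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """k x k convolution with 'same' zero padding (k odd), He-normal init.

    Weight layout is ``(out_ch, in_ch*k*k)`` with patch order ``(c, ki, kj)``.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.ksize = ksize
        fan_in = in_ch * ksize * ksize
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)))
        self.b = Param(np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _w_rot(self) -> np.ndarray:
        """Weights rearranged so dL/dx is a plain correlation of dL/dy.

        (out_ch, in_ch*k*k) -> (in_ch, out_ch*k*k) with each kernel rotated
        180 degrees, matching the transposed-convolution identity.
        """
        k = self.ksize
        w4 = self.w.value.reshape(self.out_ch, self.in_ch, k, k)
        return np.ascontiguousarray(
            w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        ).reshape(self.in_ch, self.out_ch * k * k)

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(n, h, w, c) -> (n*h*w, c*k*k) patch matrix, patch order (c, ki, kj)."""
        n, h, w, c = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # view is (n, h, w, c, k, k); reshape gathers it into one contiguous copy
        return windows.reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        if self.ksize == 1:
            cols = x.reshape(n * h * w, c)
        else:
            cols = self._im2col(x, self.ksize)
        self._cols = cols
        self._shape = (n, h, w, c)
        out = cols @ self.w.value.T + self.b.value
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dmat = np.ascontiguousarray(dout).reshape(n * h * w, self.out_ch)
        self.w.grad += dmat.T @ self._cols
        self.b.grad += dmat.sum(axis=0)
        if self.ksize == 1:
            return (dmat @ self.w.value).reshape(n, h, w, c)
        # dx = dout (*) rot180(W): correlation via the same im2col + matmul
        dout_cols = self._im2col(dmat.reshape(n, h, w, self.out_ch), self.ksize)
        return (dout_cols @ self._w_rot().T).reshape(n, h, w, c)


class InstanceNorm:
    """Per-sample, per-channel spatial normalization with learnable affine.

    Keeps activations (and hence output logits) well-scaled so the sigmoid
    head does not saturate irrecoverably under region losses like dice.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5):
        self.g = Param(np.ones(n_ch))
        self.b = Param(np.zeros(n_ch))
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.g.value * self._xhat + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.g.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.b.grad += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.g.value
        m1 = dxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return (inv * (dxhat - m1 - xhat * m2)).astype(np.float32)


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; spatial extents must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"extents must be even for 2x2 pooling, got {h}x{w}")
        windows = np.ascontiguousarray(
            x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        ).reshape(n, h // 2, w // 2, c, 4)
        self._argmax = windows.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        return (
            dwin.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class Upsample2:
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
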