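"""Minimal 3D convolutional network engine (numpy, hand-written backprop).

Implements exactly the pieces the patchwork's per-level U-Net needs:
3x3x3 and 1x1x1 convolutions, 2x max pooling, 2x stride-2 transposed
convolutions, instance normalization, ReLU, channel softmax and Adam.
Convolutions are lowered to GEMMs (per-sample im2col via sliding windows),
which keeps a one-CPU training run of the desk-scale patchwork tractable.
Every backward pass is gradient-checked against numerical differentiation
in the test suite.

Layers cache what their backward pass needs; call ``forward`` then
``backward`` in matching order.  All arrays are channel-first:
``(batch, channels, x, y, z)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # fast direct kernels; the numpy paths below are the reference
    from . import _conv_kernels as _k

    _HAVE_JIT = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_JIT = False

__all__ = [
    "Param",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "InstanceNorm3d",
    "ReLU",
    "softmax",
    "softmax_backward",
    "Adam",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, Ci, D, H, W) -> (B*D*H*W, Ci*k^3) patch matrix (same padding)."""
    pad = k // 2
    B, Ci, D, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (B,Ci,D,H,W,k,k,k)
    return win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B * D * H * Wd, Ci * k**3)


def _f32(*arrays) -> bool:
    return _HAVE_JIT and all(a.dtype == np.float32 for a in arrays)


def _use_jit(x: np.ndarray, W: np.ndarray) -> bool:
    return _f32(x, W) and W.shape[2] in (1, 3)


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


def conv3d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Same-padding stride-1 3D convolution (odd kernel).

    Dispatches to the direct jitted kernel for float32 k=3 (the hot path)
    and to a GEMM lowering otherwise.
    """
    B, Ci, D, H, Wd = x.shape
    Co, _, k, _, _ = W.shape
    if _use_jit(x, W):
        out = np.zeros((B, Co, D, H, Wd), dtype=np.float32)
        if b is not None:
            out += b[None, :, None, None, None]
        if k == 3:
            _k.conv3d_k3(_pad1(x), W, out)
        else:
            _k.conv3d_k1(np.ascontiguousarray(x), W[:, :, 0, 0, 0].copy(), out)
        return out
    if k == 1:
        xm = x.transpose(0, 2, 3, 4, 1).reshape(-1, Ci)
        out = xm @ W.reshape(Co, Ci).T
    else:
        out = _im2col(x, k) @ W.reshape(Co, -1).T
    out = np.ascontiguousarray(out.reshape(B, D, H, Wd, Co).transpose(0, 4, 1, 2, 3))
    if b is not None:
        out += b[None, :, None, None, None]
    return out


def conv3d_backward(
    x: np.ndarray, W: np.ndarray, gy: np.ndarray, xp: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv3d` w.r.t. input, kernel and bias."""
    B, Ci, D, H, Wd = x.shape
    Co, _, k, _, _ = W.shape
    gb = gy.sum(axis=(0, 2, 3, 4))
    if _use_jit(x, W) and gy.dtype == np.float32:
        gy = np.ascontiguousarray(gy)
        xc = np.ascontiguousarray(x)
        gW = np.zeros_like(W)
        gx = np.zeros_like(x)
        if k == 3:
            _k.conv3d_k3_gw(xp if xp is not None else _pad1(xc), gy, gW)
            Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            _k.conv3d_k3(_pad1(gy), Wt, gx)
        else:
            gW1 = np.zeros((Co, Ci), dtype=np.float32)
            _k.conv3d_k1_gw(xc, gy, gW1)
            gW[:, :, 0, 0, 0] = gW1
            Wt1 = np.ascontiguousarray(W[:, :, 0, 0, 0].T)
            _k.conv3d_k1(gy, Wt1, gx)
        return gx, gW, gb
    gym = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, Co)
    if k == 1:
        xm = x.transpose(0, 2, 3, 4, 1).reshape(-1, Ci)
        gW = (gym.T @ xm).reshape(W.shape)
        gx = (gym @ W.reshape(Co, Ci)).reshape(B, D, H, Wd, Ci).transpose(0, 4, 1, 2, 3)
        return np.ascontiguousarray(gx), gW, gb
    gW = (gym.T @ _im2col(x, k)).reshape(W.shape)
    # input gradient = convolution of gy with the flipped, channel-transposed kernel
    Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    gx = conv3d(gy, Wt, None)
    return gx, gW, gb


class Conv3d:
    """Same-padding convolution with He-initialized weights."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k**3))
        self.W = Param(rng.normal(0.0, scale, (cout, cin, k, k, k)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return conv3d(x, self.W.value, self.b.value)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx, gW, gb = conv3d_backward(self._x, self.W.value, gy)
        self.W.grad += gW
        self.b.grad += gb
        return gx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ConvTranspose3d:
    """Kernel-2 stride-2 transposed convolution (doubles each spatial axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 8))
        self.W = Param(rng.normal(0.0, scale, (cin, cout, 2, 2, 2)).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, Ci, D, H, Wd = x.shape
        Co = self.W.value.shape[1]
        if _f32(x, self.W.value):
            x = np.ascontiguousarray(x)
            self._x = x
            out = np.empty((B, Co, 2 * D, 2 * H, 2 * Wd), dtype=np.float32)
            out[...] = self.b.value[None, :, None, None, None]
            _k.tconv2_fwd(x, self.W.value, out)
            return out
        t = np.tensordot(x, self.W.value, axes=([1], [0]))  # (B,D,H,W,Co,2,2,2)
        out = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(B, Co, 2 * D, 2 * H, 2 * Wd)
        out = np.ascontiguousarray(out)
        out += self.b.value[None, :, None, None, None]
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        B, Ci, D, H, Wd = x.shape
        Co = self.W.value.shape[1]
        if _f32(x, self.W.value, gy):
            gy = np.ascontiguousarray(gy)
            gx = np.zeros_like(x)
            _k.tconv2_bwd(x, self.W.value, gy, gx, self.W.grad)
            self.b.grad += gy.sum(axis=(0, 2, 3, 4))
            return gx
        gt = gy.reshape(B, Co, D, 2, H, 2, Wd, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        gx = np.tensordot(gt, self.W.value, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        gx = np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3))
        gW = np.tensordot(x, gt, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
        self.W.grad += gW
        self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        return gx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class MaxPool3d:
    """2x2x2 max pooling; spatial sizes must be even."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        self._shape = x.shape
        if _f32(x):
            out = np.empty((B, C, D // 2, H // 2, W // 2), dtype=np.float32)
            idx = np.empty(out.shape, dtype=np.uint8)
            _k.maxpool2_fwd(np.ascontiguousarray(x), out, idx)
            self._idx = idx
            return out
        xr = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xr = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            B, C, D // 2, H // 2, W // 2, 8
        )
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, D, H, W = self._shape
        if _f32(gy) and self._idx.dtype == np.uint8:
            gx = np.zeros((B, C, D, H, W), dtype=np.float32)
            _k.maxpool2_bwd(np.ascontiguousarray(gy), self._idx, gx)
            return gx
        g = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
        g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, D, H, W)
        return np.ascontiguousarray(g)

    def params(self) -> list[Param]:
        return []


class InstanceNorm3d:
    """Per-sample, per-channel normalization over space with affine parameters."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._istd: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if _f32(x, self.gamma.value):
            x = np.ascontiguousarray(x)
            y = np.empty_like(x)
            xhat = np.empty_like(x)
            istd = np.empty(x.shape[:2], dtype=np.float32)
            _k.instnorm_fwd(x, self.gamma.value, self.beta.value, self.eps, y, xhat, istd)
            self._xhat, self._istd = xhat, istd
            return y
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        self._xhat, self._istd = xhat, istd
        return self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[
            None, :, None, None, None
        ]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        if _f32(gy, xhat) and istd.ndim == 2:
            gy = np.ascontiguousarray(gy)
            gx = np.empty_like(gy)
            _k.instnorm_bwd(
                gy, xhat, istd, self.gamma.value, gx, self.gamma.grad, self.beta.grad
            )
            return gx
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += gy.sum(axis=(0, 2, 3, 4))
        gxhat = gy * self.gamma.value[None, :, None, None, None]
        m1 = gxhat.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return istd * (gxhat - m1 - xhat * m2)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask

    def params(self) -> list[Param]:
        return []


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    zs = z - z.max(axis=axis, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, gp: np.ndarray, axis: int = 1) -> np.ndarray:
    """Gradient w.r.t. logits given probabilities ``p`` and dL/dp."""
    dot = (gp * p).sum(axis=axis, keepdims=True)
    return p * (gp - dot)


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
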