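"""Minimal 3D convolutional layers with hand-written forward/backward passes.

The heart-rate network needs only a small, fixed vocabulary of operations:
3D convolution (optionally strided), transposed 3D convolution, batch
normalization, non-overlapping max pooling, ReLU, sigmoid, and global
spatial averaging.  Each layer caches what its backward pass needs and
exposes parameters as named :class:`Param` objects so an optimizer can walk
the whole model generically.

Convolutions run as im2col + GEMM, chunked along the temporal axis so the
column buffer stays within a fixed memory budget even for full-resolution
inputs.  Transposed convolutions use the adjoint scatter of the same
decomposition.  All math is float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "MaxPool3d",
    "ReLU",
    "Sigmoid",
    "SpatialGlobalAvgPool",
]

# column-buffer budget per GEMM chunk (bytes)
_COL_BUDGET = 256 * 1024 * 1024
# forward col buffers up to this size are kept for the backward pass
_COL_CACHE = 128 * 1024 * 1024


@dataclass
class Param:
    """A learnable array with its gradient accumulator."""

    name: str
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.ascontiguousarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: ``forward`` caches, ``backward`` consumes the cache."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a 3-tuple, got {v}")
    return t


def _same_padding(kernel: tuple[int, int, int]) -> tuple[int, int, int]:
    if any(k % 2 == 0 for k in kernel):
        raise ValueError(f"'same' padding needs odd kernel dims, got {kernel}")
    return tuple(k // 2 for k in kernel)


class Conv3d(Layer):
    """3D convolution with odd kernels, 'same' padding and optional stride.

    Output dims are ``floor((L + 2p - k) / s) + 1`` per axis with
    ``p = (k - 1) // 2``; for even lengths and any odd kernel this halves the
    axis exactly when ``s = 2`` and preserves it when ``s = 1``.
    """

    def __init__(self, cin: int, cout: int, kernel, stride=1, bias: bool = False,
                 name: str = "conv"):
        self.cin, self.cout = int(cin), int(cout)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _same_padding(self.kernel)
        self.name = name
        self.weight = Param(f"{name}.weight",
                            np.zeros((cout, cin, *self.kernel), np.float32))
        self.bias = Param(f"{name}.bias", np.zeros(cout, np.float32)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.cin * int(np.prod(self.kernel))
        bound = np.sqrt(6.0 / fan_in)
        self.weight.value[...] = rng.uniform(-bound, bound,
                                             self.weight.value.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.value[...] = 0.0

    # -- geometry -----------------------------------------------------------
    def out_dims(self, dims: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple((d + 2 * p - k) // s + 1
                     for d, k, s, p in zip(dims, self.kernel, self.stride,
                                           self.padding))

    def _pad(self, x: np.ndarray) -> np.ndarray:
        pt, ph, pw = self.padding
        if pt == ph == pw == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))

    def _t_chunk(self, B: int, Ho: int, Wo: int) -> int:
        kvol = int(np.prod(self.kernel))
        bytes_per_t = B * Ho * Wo * self.cin * kvol * 4
        return max(1, _COL_BUDGET // max(1, bytes_per_t))

    def _col(self, xp: np.ndarray, t0: int, t1: int, Ho: int, Wo: int) -> np.ndarray:
        """im2col for output frames [t0, t1): returns (cin*kvol, B*Tc*Ho*Wo).

        Row order is (cin, dt, dh, dw), matching ``weight.reshape(cout, -1)``;
        each row is a contiguous copy of one strided input slice, so assembly
        runs at memcpy speed.
        """
        B = xp.shape[0]
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        Tc = t1 - t0
        kvol = kt * kh * kw
        col = np.empty((self.cin, kvol, B, Tc, Ho, Wo), np.float32)
        j = 0
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    sl = xp[:, :,
                            t0 * st + dt: t0 * st + dt + Tc * st: st,
                            dh: dh + Ho * sh: sh,
                            dw: dw + Wo * sw: sw]
                    col[:, j] = sl.transpose(1, 0, 2, 3, 4)
                    j += 1
        return col.reshape(self.cin * kvol, B * Tc * Ho * Wo)

    # -- FFT path (stride 1): same result, far less memory traffic ----------
    def _use_fft(self) -> bool:
        return self.stride == (1, 1, 1) and int(np.prod(self.kernel)) >= 15

    def _fft_shapes(self, dims):
        return tuple(sfft.next_fast_len(d + k - 1)
                     for d, k in zip(dims, self.kernel))

    def _forward_fft(self, x: np.ndarray, training: bool) -> np.ndarray:
        dims = x.shape[2:]
        N = self._fft_shapes(dims)
        axes = (-3, -2, -1)
        Xh = sfft.rfftn(x, N, axes=axes)
        gf = self.weight.value[:, :, ::-1, ::-1, ::-1]  # correlation = conv(flip)
        Gh = sfft.rfftn(gf, N, axes=axes)
        Yh = np.einsum("bcthw,octhw->bothw", Xh, Gh, optimize=True)
        yfull = sfft.irfftn(Yh, N, axes=axes)
        pt, ph, pw = self.padding
        T, H, W = dims
        y = np.ascontiguousarray(
            yfull[:, :, pt:pt + T, ph:ph + H, pw:pw + W], dtype=np.float32)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None, None]
        if training:
            self._cache = ("fft", Xh, x.shape, N)
        return y

    def _backward_fft(self, dy: np.ndarray) -> np.ndarray:
        _, Xh, xshape, N = self._cache
        self._cache = None
        dims = xshape[2:]
        axes = (-3, -2, -1)
        pads = [(p, n - l - p) for p, n, l in zip(self.padding, N, dims)]
        dyp = np.pad(dy, [(0, 0), (0, 0)] + pads)
        Dh = sfft.rfftn(dyp, axes=axes)
        gf = self.weight.value[:, :, ::-1, ::-1, ::-1]
        Gh = sfft.rfftn(gf, N, axes=axes)
        dXh = np.einsum("bothw,octhw->bcthw", Dh, np.conj(Gh), optimize=True)
        dxfull = sfft.irfftn(dXh, N, axes=axes)
        T, H, W = dims
        dx = np.ascontiguousarray(dxfull[:, :, :T, :H, :W], dtype=np.float32)

        # weight gradient: cross-correlation of input with the output grad
        dy0 = np.pad(dy, [(0, 0), (0, 0)] + [(0, n - s)
                                             for n, s in zip(N, dy.shape[2:])])
        D0 = sfft.rfftn(dy0, axes=axes)
        Rh = np.einsum("bothw,bcthw->octhw", np.conj(D0), Xh, optimize=True)
        r = sfft.irfftn(Rh, N, axes=axes)
        kt, kh, kw = self.kernel
        pt, ph, pw = self.padding
        lag_t = (np.arange(kt) - pt) % N[0]
        lag_h = (np.arange(kh) - ph) % N[1]
        lag_w = (np.arange(kw) - pw) % N[2]
        dw = r[:, :, lag_t][:, :, :, lag_h][:, :, :, :, lag_w]
        self.weight.grad += dw.astype(np.float32)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        return dx

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C = x.shape[:2]
        if C != self.cin:
            raise ValueError(f"{self.name}: expected {self.cin} channels, got {C}")
        if self._use_fft():
            return self._forward_fft(np.ascontiguousarray(x, np.float32),
                                     training)
        To, Ho, Wo = self.out_dims(x.shape[2:])
        xp = self._pad(x)
        wmat = self.weight.value.reshape(self.cout, -1)  # (cout, cin*kvol)
        y = np.empty((B, self.cout, To, Ho, Wo), np.float32)
        step = self._t_chunk(B, Ho, Wo)
        kvol = int(np.prod(self.kernel))
        col_bytes = self.cin * kvol * B * To * Ho * Wo * 4
        keep = training and step >= To and col_bytes <= _COL_CACHE
        col_kept = None
        for t0 in range(0, To, step):
            t1 = min(To, t0 + step)
            col = self._col(xp, t0, t1, Ho, Wo)
            if keep:
                col_kept = col
            out = wmat @ col  # (cout, B*Tc*Ho*Wo)
            y[:, :, t0:t1] = out.reshape(self.cout, B, t1 - t0, Ho,
                                         Wo).transpose(1, 0, 2, 3, 4)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None, None]
        if training:
            self._cache = (xp, x.shape, (To, Ho, Wo), col_kept)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is not None and isinstance(self._cache[0], str):
            return self._backward_fft(dy)
        xp, xshape, (To, Ho, Wo), col_kept = self._cache
        self._cache = None
        B = dy.shape[0]
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        kvol = kt * kh * kw
        wmat = self.weight.value.reshape(self.cout, -1)  # (cout, cin*kvol)
        dw = np.zeros_like(wmat)
        dxp = np.zeros_like(xp)
        step = self._t_chunk(B, Ho, Wo)
        for t0 in range(0, To, step):
            t1 = min(To, t0 + step)
            Tc = t1 - t0
            col = col_kept if col_kept is not None else self._col(
                xp, t0, t1, Ho, Wo)
            g = np.ascontiguousarray(
                dy[:, :, t0:t1].transpose(1, 0, 2, 3, 4)).reshape(self.cout, -1)
            dw += g @ col.T
            dcol = (wmat.T @ g).reshape(self.cin, kvol, B, Tc, Ho, Wo)
            j = 0
            for dt in range(kt):
                for dh in range(kh):
                    for dw_ in range(kw):
                        dxp[:, :,
                            t0 * st + dt: t0 * st + dt + Tc * st: st,
                            dh: dh + Ho * sh: sh,
                            dw_: dw_ + Wo * sw: sw] += dcol[:, j].transpose(
                                1, 0, 2, 3, 4)
                        j += 1
        self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        pt, ph, pw = self.padding
        T, H, W = xshape[2:]
        return dxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W]


class ConvTranspose3d(Layer):
    """Transposed 3D convolution (the adjoint of a strided convolution).

    Geometry: ``out = (in - 1) * stride - 2 * padding + kernel + output_padding``.
    The upsampling stages use either kernel == stride (exact factor-2
    unpooling) or kernel 3, stride 2, padding 1, output_padding 1.
    """

    def __init__(self, cin: int, cout: int, kernel, stride, padding=0,
                 output_padding=0, bias: bool = True, name: str = "convT"):
        self.cin, self.cout = int(cin), int(cout)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.output_padding = _triple(output_padding)
        self.name = name
        self.weight = Param(f"{name}.weight",
                            np.zeros((cin, cout, *self.kernel), np.float32))
        self.bias = Param(f"{name}.bias", np.zeros(cout, np.float32)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.cin * int(np.prod(self.kernel))
        bound = np.sqrt(6.0 / fan_in)
        self.weight.value[...] = rng.uniform(-bound, bound,
                                             self.weight.value.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.value[...] = 0.0

    def out_dims(self, dims: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple((d - 1) * s - 2 * p + k + op
                     for d, k, s, p, op in zip(dims, self.kernel, self.stride,
                                               self.padding, self.output_padding))

    def _full_dims(self, dims: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple((d - 1) * s + k
                     for d, k, s in zip(dims, self.kernel, self.stride))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, Ti, Hi, Wi = x.shape
        if C != self.cin:
            raise ValueError(f"{self.name}: expected {self.cin} channels, got {C}")
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        Tf, Hf, Wf = self._full_dims((Ti, Hi, Wi))
        yfull = np.zeros((B, self.cout, Tf, Hf, Wf), np.float32)
        xm = np.moveaxis(x, 1, -1)  # (B, Ti, Hi, Wi, cin)
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    contrib = xm @ self.weight.value[:, :, dt, dh, dw]
                    yfull[:, :,
                          dt: dt + Ti * st: st,
                          dh: dh + Hi * sh: sh,
                          dw: dw + Wi * sw: sw] += np.moveaxis(contrib, -1, 1)
        pt, ph, pw = self.padding
        To, Ho, Wo = self.out_dims((Ti, Hi, Wi))
        y = yfull[:, :, pt:pt + To, ph:ph + Ho, pw:pw + Wo]
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None, None]
        if training:
            self._cache = (x, (Ti, Hi, Wi), (Tf, Hf, Wf))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (Ti, Hi, Wi), (Tf, Hf, Wf) = self._cache
        self._cache = None
        B = dy.shape[0]
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        To, Ho, Wo = self.out_dims((Ti, Hi, Wi))
        gfull = np.zeros((B, self.cout, Tf, Hf, Wf), np.float32)
        gfull[:, :, pt:pt + To, ph:ph + Ho, pw:pw + Wo] = dy
        xm = np.moveaxis(x, 1, -1)  # (B, Ti, Hi, Wi, cin)
        dx = np.zeros_like(xm)
        for dt in range(kt):
            for dh in range(kh):
                for dw in range(kw):
                    g = np.moveaxis(gfull[:, :,
                                          dt: dt + Ti * st: st,
                                          dh: dh + Hi * sh: sh,
                                          dw: dw + Wi * sw: sw], 1, -1)
                    w_off = self.weight.value[:, :, dt, dh, dw]  # (cin, cout)
                    dx += g @ w_off.T
                    self.weight.grad[:, :, dt, dh, dw] += np.einsum(
                        "bthwc,bthwo->co", xm, g, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        return np.moveaxis(dx, -1, 1)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (B, T, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.channels = int(channels)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.gamma = Param(f"{name}.weight", np.ones(channels, np.float32))
        self.beta = Param(f"{name}.bias", np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None
        self._collect = None  # when set, accumulates (sum_mean, sum_var, count)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def init(self, rng: np.random.Generator) -> None:
        self.gamma.value[...] = 1.0
        self.beta.value[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[1]
            unbiased = var * n / max(1, n - 1)
            if self._collect is not None:
                self._collect[0] += mean
                self._collect[1] += unbiased
                self._collect[2] += 1
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        y = self.gamma.value[None, :, None, None, None] * xhat \
            + self.beta.value[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        n = dy.size // dy.shape[1]
        self.beta.grad += dy.sum(axis=axes)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        mean_dy = dy.mean(axis=axes)[None, :, None, None, None]
        mean_dyx = (dy * xhat).mean(axis=axes)[None, :, None, None, None]
        dx = g * inv[None, :, None, None, None] * (dy - mean_dy - xhat * mean_dyx)
        return dx.astype(np.float32)


class MaxPool3d(Layer):
    """Non-overlapping max pooling by integer factors (kernel == stride)."""

    def __init__(self, factors, name: str = "pool"):
        self.factors = _triple(factors)
        self.name = name
        self._cache = None

    def out_dims(self, dims: tuple[int, int, int]) -> tuple[int, int, int]:
        for d, f in zip(dims, self.factors):
            if d % f:
                raise ValueError(f"{self.name}: dim {d} not divisible by {f}")
        return tuple(d // f for d, f in zip(dims, self.factors))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C = x.shape[:2]
        ft, fh, fw = self.factors
        To, Ho, Wo = self.out_dims(x.shape[2:])
        blocks = x.reshape(B, C, To, ft, Ho, fh, Wo, fw)
        blocks = np.moveaxis(blocks, (3, 5, 7), (5, 6, 7)).reshape(
            B, C, To, Ho, Wo, ft * fh * fw)
        arg = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (arg, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, xshape = self._cache
        self._cache = None
        B, C, T, H, W = xshape
        ft, fh, fw = self.factors
        To, Ho, Wo = T // ft, H // fh, W // fw
        dblocks = np.zeros((B, C, To, Ho, Wo, ft * fh * fw), np.float32)
        np.put_along_axis(dblocks, arg[..., None], dy[..., None], axis=-1)
        dblocks = dblocks.reshape(B, C, To, Ho, Wo, ft, fh, fw)
        dx = np.moveaxis(dblocks, (5, 6, 7), (3, 5, 7)).reshape(xshape)
        return np.ascontiguousarray(dx)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dy * mask


class Sigmoid(Layer):
    def __init__(self, name: str = "sigmoid"):
        self.name = name
        self._y = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # numerically stable logistic
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                     np.exp(x) / (1.0 + np.exp(x))).astype(np.float32)
        if training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return dy * y * (1.0 - y)


class SpatialGlobalAvgPool(Layer):
    """Average over the spatial axes, preserving the temporal axis.

    Input (B, C, T, H, W) -> output (B, C, T, 1, 1).
    """

    def __init__(self, name: str = "gap"):
        self.name = name
        self._hw = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._hw = x.shape[3:]
        return x.mean(axis=(3, 4), keepdims=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H, W = self._hw
        return np.broadcast_to(dy / (H * W),
                               dy.shape[:3] + (H, W)).astype(np.float32)
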