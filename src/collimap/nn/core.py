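"""Minimal NumPy neural-network substrate with manual backpropagation.

Every layer implements ``forward`` (caching what its backward pass needs,
unless gradients are globally disabled) and ``backward`` (accumulating
parameter gradients and returning the gradient w.r.t. its input).  The
module is deliberately small: it provides exactly the primitives the
volumetric regression network needs — 3D convolution and transposed
convolution (implemented as kernel-offset batched matmuls, which keeps
memory bounded and uses BLAS), depthwise 3D convolution, batch/layer
normalisation, SiLU/Tanh, linear layers, multi-head self-attention, and a
pre-norm Transformer layer.

Convention: volumetric tensors are ``(B, C, D, H, W)`` with depth D the
slice axis; token tensors are ``(S, N, C)`` with S independent sequences.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv3d",
    "DepthwiseConv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "LayerNorm",
    "Linear",
    "SiLU",
    "Tanh",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "no_grad",
    "grad_enabled",
]

_GRAD_STACK = [True]


def grad_enabled() -> bool:
    return _GRAD_STACK[-1]


@contextlib.contextmanager
def no_grad():
    """Disable activation caching (inference mode)."""
    _GRAD_STACK.append(False)
    try:
        yield
    finally:
        _GRAD_STACK.pop()


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class; sub-layers and Params are discovered from attributes."""

    def __init__(self) -> None:
        self.training = True

    # -- parameter / sub-layer discovery -------------------------------
    def _children(self) -> Iterator["Layer"]:
        for v in vars(self).values():
            if isinstance(v, Layer):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        yield item

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def train(self, mode: bool = True) -> "Layer":
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Layer":
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- interface ------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError("expected a 3-tuple")
        return tuple(int(x) for x in v)  # type: ignore[return-value]
    return (int(v),) * 3


def conv_output_size(size: int, k: int, s: int, p: int) -> int:
    out = (size + 2 * p - k) // s + 1
    if out < 1:
        raise ValueError(f"conv output size {out} < 1 (in={size}, k={k}, s={s}, p={p})")
    return out


class Conv3d(Layer):
    """Dense 3D convolution via accumulation over kernel offsets.

    For each of the k_d*k_h*k_w kernel offsets the padded input is sliced
    with the stride and contracted with the corresponding (C_out, C_in)
    weight plane by a batched matmul; this avoids the large im2col buffer.
    """

    def __init__(self, cin: int, cout: int, kernel, stride=(1, 1, 1),
                 padding=(0, 0, 0), bias: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32,
                 weight_scale: float | None = None):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = cin * int(np.prod(self.kernel))
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, scale, size=(cout, cin) + self.kernel).astype(dtype))
        self.bias = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._xp: np.ndarray | None = None

    def _slices(self, i, j, k, Do, Ho, Wo):
        sd, sh, sw = self.stride
        return (
            slice(i, i + (Do - 1) * sd + 1, sd),
            slice(j, j + (Ho - 1) * sh + 1, sh),
            slice(k, k + (Wo - 1) * sw + 1, sw),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"Conv3d expected {self.cin} channels, got {C}")
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        Do = conv_output_size(D, kd, sd, pd)
        Ho = conv_output_size(H, kh, sh, ph)
        Wo = conv_output_size(W, kw, sw, pw)
        out = np.zeros((B, self.cout, Do * Ho * Wo), dtype=x.dtype)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    zs, ys, xs_ = self._slices(i, j, k, Do, Ho, Wo)
                    patch = np.ascontiguousarray(xp[:, :, zs, ys, xs_]).reshape(B, C, -1)
                    out += np.matmul(self.weight.data[:, :, i, j, k], patch)
        out = out.reshape(B, self.cout, Do, Ho, Wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        if grad_enabled():
            self._xp = xp
            self._oshape = (Do, Ho, Wo)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "forward was run without gradients enabled"
        xp = self._xp
        B = xp.shape[0]
        kd, kh, kw = self.kernel
        pd, ph, pw = self.padding
        Do, Ho, Wo = self._oshape
        dy2 = dy.reshape(B, self.cout, -1)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    zs, ys, xs_ = self._slices(i, j, k, Do, Ho, Wo)
                    patch = np.ascontiguousarray(xp[:, :, zs, ys, xs_]).reshape(B, self.cin, -1)
                    self.weight.grad[:, :, i, j, k] += np.matmul(
                        dy2, patch.transpose(0, 2, 1)).sum(axis=0)
                    dpatch = np.matmul(self.weight.data[:, :, i, j, k].T, dy2)
                    dxp[:, :, zs, ys, xs_] += dpatch.reshape(B, self.cin, Do, Ho, Wo)
        D = xp.shape[2] - 2 * pd
        H = xp.shape[3] - 2 * ph
        W = xp.shape[4] - 2 * pw
        self._xp = None
        return dxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]


class DepthwiseConv3d(Layer):
    """Per-channel 3D convolution (groups == channels)."""

    def __init__(self, channels: int, kernel=3, stride=(1, 1, 1), padding=(1, 1, 1),
                 bias: bool = True, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = int(np.prod(self.kernel))
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                       size=(channels,) + self.kernel).astype(dtype))
        self.bias = Param(np.zeros(channels, dtype=dtype)) if bias else None
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"DepthwiseConv3d expected {self.channels} channels, got {C}")
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        Do = conv_output_size(D, kd, sd, pd)
        Ho = conv_output_size(H, kh, sh, ph)
        Wo = conv_output_size(W, kw, sw, pw)
        out = np.zeros((B, C, Do, Ho, Wo), dtype=x.dtype)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    xs = xp[:, :,
                            i:i + (Do - 1) * sd + 1:sd,
                            j:j + (Ho - 1) * sh + 1:sh,
                            k:k + (Wo - 1) * sw + 1:sw]
                    out += self.weight.data[None, :, i, j, k, None, None, None] * xs
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        if grad_enabled():
            self._xp = xp
            self._oshape = (Do, Ho, Wo)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None
        xp = self._xp
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        Do, Ho, Wo = self._oshape
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    sl = (slice(None), slice(None),
                          slice(i, i + (Do - 1) * sd + 1, sd),
                          slice(j, j + (Ho - 1) * sh + 1, sh),
                          slice(k, k + (Wo - 1) * sw + 1, sw))
                    xs = xp[sl]
                    self.weight.grad[:, i, j, k] += (dy * xs).sum(axis=(0, 2, 3, 4))
                    dxp[sl] += self.weight.data[None, :, i, j, k, None, None, None] * dy
        D = xp.shape[2] - 2 * pd
        H = xp.shape[3] - 2 * ph
        W = xp.shape[4] - 2 * pw
        self._xp = None
        return dxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]


class ConvTranspose3d(Layer):
    """3D transposed convolution (fractionally-strided), scatter-add form."""

    def __init__(self, cin: int, cout: int, kernel=3, stride=(1, 2, 2),
                 padding=(1, 1, 1), output_padding=(0, 1, 1), bias: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.output_padding = _triple(output_padding)
        for op, s in zip(self.output_padding, self.stride):
            if op >= max(s, 1) and op > 0 and op >= s:
                raise ValueError("output_padding must be smaller than stride")
        fan_in = cin * int(np.prod(self.kernel))
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                       size=(cin, cout) + self.kernel).astype(dtype))
        self.bias = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._x: np.ndarray | None = None

    def output_shape(self, D: int, H: int, W: int) -> tuple[int, int, int]:
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        od, oh, ow = self.output_padding
        return ((D - 1) * sd - 2 * pd + kd + od,
                (H - 1) * sh - 2 * ph + kh + oh,
                (W - 1) * sw - 2 * pw + kw + ow)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"ConvTranspose3d expected {self.cin} channels, got {C}")
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        od, oh, ow = self.output_padding
        Do, Ho, Wo = self.output_shape(D, H, W)
        full = np.zeros((B, self.cout,
                         (D - 1) * sd + kd + od,
                         (H - 1) * sh + kh + oh,
                         (W - 1) * sw + kw + ow), dtype=x.dtype)
        x2 = x.reshape(B, C, -1)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    contrib = np.matmul(self.weight.data[:, :, i, j, k].T, x2)
                    full[:, :,
                         i:i + (D - 1) * sd + 1:sd,
                         j:j + (H - 1) * sh + 1:sh,
                         k:k + (W - 1) * sw + 1:sw] += contrib.reshape(B, self.cout, D, H, W)
        out = full[:, :, pd:pd + Do, ph:ph + Ho, pw:pw + Wo]
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None, None]
        if grad_enabled():
            self._x = x
            self._full_shape = full.shape
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        x = self._x
        B, C, D, H, W = x.shape
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        Do, Ho, Wo = self.output_shape(D, H, W)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        dfull = np.zeros(self._full_shape, dtype=dy.dtype)
        dfull[:, :, pd:pd + Do, ph:ph + Ho, pw:pw + Wo] = dy
        x2 = x.reshape(B, C, -1)
        dx2 = np.zeros_like(x2)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dslice = np.ascontiguousarray(
                        dfull[:, :,
                              i:i + (D - 1) * sd + 1:sd,
                              j:j + (H - 1) * sh + 1:sh,
                              k:k + (W - 1) * sw + 1:sw]).reshape(B, self.cout, -1)
                    self.weight.grad[:, :, i, j, k] += np.matmul(
                        x2, dslice.transpose(0, 2, 1)).sum(axis=0)
                    dx2 += np.matmul(self.weight.data[:, :, i, j, k], dslice)
        self._x = None
        return dx2.reshape(B, C, D, H, W)


# ---------------------------------------------------------------------------
# normalisation / activations
# ---------------------------------------------------------------------------


class BatchNorm3d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = self.gamma.data[None, :, None, None, None] * xhat \
            + self.beta.data[None, :, None, None, None]
        if grad_enabled():
            self._xhat = xhat
            self._inv = inv
            self._m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        return out.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, inv, m = self._xhat, self._inv, self._m
        self.beta.grad += dy.sum(axis=axes)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        dxhat = dy * self.gamma.data[None, :, None, None, None]
        if self.training:
            s1 = dxhat.sum(axis=axes)[None, :, None, None, None]
            s2 = (dxhat * xhat).sum(axis=axes)[None, :, None, None, None]
            dx = (inv[None, :, None, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * inv[None, :, None, None, None]
        self._xhat = None
        return dx.astype(dy.dtype)


class LayerNorm(Layer):
    """Normalisation over the trailing feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Param(np.ones(dim, dtype=dtype))
        self.beta = Param(np.zeros(dim, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if grad_enabled():
            self._xhat, self._inv = xhat, inv
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        n = self.dim
        red = tuple(range(dy.ndim - 1))
        self.beta.grad += dy.sum(axis=red)
        self.gamma.grad += (dy * xhat).sum(axis=red)
        dxhat = dy * self.gamma.data
        s1 = dxhat.sum(axis=-1, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=-1, keepdims=True)
        dx = (inv / n) * (n * dxhat - s1 - xhat * s2)
        self._xhat = None
        return dx.astype(dy.dtype)


class SiLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        s = expit(x)  # numerically stable sigmoid
        if grad_enabled():
            self._x, self._s = x, s
        return x * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        dx = dy * (s * (1.0 + x * (1.0 - s)))
        self._x = None
        return dx


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.tanh(x)
        if grad_enabled():
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * (1.0 - self._y ** 2)
        self._y = None
        return dx


class Linear(Layer):
    def __init__(self, cin: int, cout: int, bias: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / (cin + cout))
        self.weight = Param(rng.normal(0.0, scale, size=(cin, cout)).astype(dtype))
        self.bias = Param(np.zeros(cout, dtype=dtype)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if grad_enabled():
            self._x = x
        out = x @ self.weight.data
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, self.cin)
        dyf = dy.reshape(-1, self.cout)
        self.weight.grad += xf.T @ dyf
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        self._x = None
        return (dy @ self.weight.data.T).astype(dy.dtype)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


class MultiHeadSelfAttention(Layer):
    """Self-attention over the N axis of ``(S, N, C)`` token tensors."""

    def __init__(self, dim: int, heads: int = 4, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"heads ({heads}) must divide the embedding dim ({dim})")
        self.dim, self.heads = dim, heads
        self.dh = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng=rng, dtype=dtype)
        self.proj = Linear(dim, dim, rng=rng, dtype=dtype)

    @staticmethod
    def _softmax(x: np.ndarray) -> np.ndarray:
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        return e / e.sum(axis=-1, keepdims=True)

    def _split(self, t: np.ndarray) -> np.ndarray:
        S, N, _ = t.shape
        return t.reshape(S, N, self.heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, t: np.ndarray) -> np.ndarray:
        S, h, N, dh = t.shape
        return t.transpose(0, 2, 1, 3).reshape(S, N, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        qkv = self.qkv(x)
        q, k, v = np.split(qkv, 3, axis=-1)
        qh, kh, vh = self._split(q), self._split(k), self._split(v)
        scale = 1.0 / np.sqrt(self.dh)
        scores = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale
        attn = self._softmax(scores)
        oh = np.matmul(attn, vh)
        out = self._merge(oh)
        y = self.proj(out)
        if grad_enabled():
            self._cache = (qh, kh, vh, attn)
        return y

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Return softmax attention (S, heads, N, N) for inspection."""
        qkv = self.qkv(x)
        q, k, _ = np.split(qkv, 3, axis=-1)
        scores = np.matmul(self._split(q), self._split(k).transpose(0, 1, 3, 2))
        return self._softmax(scores / np.sqrt(self.dh))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        qh, kh, vh, attn = self._cache
        scale = 1.0 / np.sqrt(self.dh)
        dout = self.proj.backward(dy)
        doh = self._split(dout)
        dattn = np.matmul(doh, vh.transpose(0, 1, 3, 2))
        dvh = np.matmul(attn.transpose(0, 1, 3, 2), doh)
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dqh = np.matmul(ds, kh) * scale
        dkh = np.matmul(ds.transpose(0, 1, 3, 2), qh) * scale
        dqkv = np.concatenate(
            [self._merge(dqh), self._merge(dkh), self._merge(dvh)], axis=-1)
        self._cache = None
        return self.qkv.backward(dqkv)


class TransformerLayer(Layer):
    """Pre-norm Transformer encoder layer (MHSA + 2-layer SiLU MLP)."""

    def __init__(self, dim: int, heads: int = 4, mlp_ratio: float = 2.0, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        hidden = int(round(dim * mlp_ratio))
        self.ln1 = LayerNorm(dim, dtype=dtype)
        self.attn = MultiHeadSelfAttention(dim, heads, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.fc1 = Linear(dim, hidden, rng=rng, dtype=dtype)
        self.act = SiLU()
        self.fc2 = Linear(hidden, dim, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x + self.attn(self.ln1(x))
        z = y + self.fc2(self.act(self.fc1(self.ln2(y))))
        return z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        dmlp = self.ln2.backward(self.fc1.backward(self.act.backward(self.fc2.backward(dz))))
        dy = dz + dmlp
        dattn = self.ln1.backward(self.attn.backward(dy))
        return dy + dattn
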