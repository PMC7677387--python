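"""Minimal 3D conv-net layers with manual backpropagation.

All layers operate on float32 arrays of shape ``(N, C, D, H, W)``.
Forward passes cache whatever the matching backward pass needs; calling
``backward`` before ``forward`` is a programming error.  Convolutions are
expressed as window-view/tensordot contractions so the heavy lifting is
done by BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# SELU constants from the self-normalizing network definition
SELU_LAMBDA = np.float32(1.0507009873554805)
SELU_ALPHA = np.float32(1.6732632423543772)


class Layer:
    """Base class: layers expose ``params`` as (weight, grad) pairs."""

    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


def _lecun_normal(rng, shape, fan_in):
    # variance-scaling init on fan-in; required for SELU self-normalization
    std = 1.0 / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Layer):
    """Stride-1 'same'-padded 3D convolution with odd (or 1) kernel size."""

    def __init__(self, c_in, c_out, kernel, rng):
        if kernel % 2 == 0:
            raise ValueError("same-padded Conv3d needs an odd kernel size")
        self.c_in, self.c_out, self.k = int(c_in), int(c_out), int(kernel)
        fan_in = c_in * kernel ** 3
        self.w = _lecun_normal(rng, (c_out, c_in, kernel, kernel, kernel), fan_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _windows(self, xp):
        k = self.k
        return sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))

    def forward(self, x):
        p = self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        else:
            xp = x
        self._xp = xp
        win = self._windows(xp)  # (N, C, D, H, W, k, k, k)
        y = np.tensordot(win, self.w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        y = np.moveaxis(y, -1, 1)
        y += self.b[None, :, None, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy):
        k, p = self.k, self.k // 2
        win = self._windows(self._xp)
        self.db += dy.sum(axis=(0, 2, 3, 4))
        self.dw += np.tensordot(dy, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        # grad wrt input = 'same' correlation of dy with spatially flipped,
        # channel-transposed weights
        if p:
            dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        else:
            dyp = dy
        dywin = sliding_window_view(dyp, (k, k, k), axis=(2, 3, 4))
        wflip = self.w[:, :, ::-1, ::-1, ::-1]
        dx = np.tensordot(dywin, wflip, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
        self._xp = None
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class DownConv(Layer):
    """2x2x2 convolution with stride 2 (halves every spatial axis)."""

    def __init__(self, c_in, c_out, rng):
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.w = _lecun_normal(rng, (c_out, c_in, 2, 2, 2), c_in * 8)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xt = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"DownConv needs even spatial dims, got {x.shape}")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xt = np.ascontiguousarray(xr.transpose(0, 2, 4, 6, 1, 3, 5, 7))
        self._xt = xt  # (N, d, h, w, C, 2, 2, 2)
        y = np.tensordot(xt, self.w, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        y = np.moveaxis(y, -1, 1)
        y += self.b[None, :, None, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy):
        xt = self._xt
        dym = np.moveaxis(dy, 1, -1)  # (N, d, h, w, Cout)
        self.db += dy.sum(axis=(0, 2, 3, 4))
        self.dw += np.tensordot(dym, xt, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        t = np.tensordot(dym, self.w, axes=([4], [0]))  # (N,d,h,w,Cin,2,2,2)
        n, d, h, w = t.shape[:4]
        dx = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, self.c_in, d * 2, h * 2, w * 2
        )
        self._xt = None
        return np.ascontiguousarray(dx)


class UpConv(Layer):
    """2x2x2 transpose convolution with stride 2 (doubles spatial axes)."""

    def __init__(self, c_in, c_out, rng):
        self.c_in, self.c_out = int(c_in), int(c_out)
        # ICNR-style init: identical weights at all 8 sub-positions, so
        # upsampling starts checkerboard-free (stride-2 transpose convs
        # otherwise seed a voxel-parity pattern the Dice loss can latch
        # onto as a ~0.5 local optimum)
        base = _lecun_normal(rng, (c_in, c_out, 1, 1, 1), c_in)
        self.w = np.broadcast_to(base, (c_in, c_out, 2, 2, 2)).copy()
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        t = np.tensordot(x, self.w, axes=([1], [0]))  # (N,d,h,w,Cout,2,2,2)
        n, d, h, w = t.shape[:4]
        y = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, self.c_out, d * 2, h * 2, w * 2
        )
        y = np.ascontiguousarray(y)
        y += self.b[None, :, None, None, None]
        return y

    def backward(self, dy):
        n, co, dd, hh, ww = dy.shape
        d, h, w = dd // 2, hh // 2, ww // 2
        dyr = dy.reshape(n, co, d, 2, h, 2, w, 2)
        dyt = np.ascontiguousarray(dyr.transpose(0, 2, 4, 6, 1, 3, 5, 7))
        self.db += dy.sum(axis=(0, 2, 3, 4))
        xm = np.moveaxis(self._x, 1, -1)  # (N, d, h, w, Cin)
        self.dw += np.tensordot(xm, dyt, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        dx = np.tensordot(dyt, self.w, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        self._x = None
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class SELU(Layer):
    def forward(self, x):
        pos = x > 0
        neg = np.expm1(np.minimum(x, 0.0))  # clamp keeps expm1 in range
        y = np.where(pos, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * neg)
        self._pos = pos
        self._y = y
        return y.astype(np.float32, copy=False)

    def backward(self, dy):
        grad = np.where(
            self._pos, SELU_LAMBDA, self._y + SELU_LAMBDA * SELU_ALPHA
        )
        self._pos = None
        self._y = None
        return (dy * grad).astype(np.float32, copy=False)


class Sigmoid(Layer):
    def forward(self, x):
        z = np.clip(x, -60.0, 60.0)
        y = 1.0 / (1.0 + np.exp(-z, dtype=np.float32))
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        self._y = None
        return (dy * y * (1.0 - y)).astype(np.float32, copy=False)


class ConvStack(Layer):
    """``n`` SELU convolutions with a residual connection input -> output.

    A 1x1x1 linear projection bridges the residual path when the channel
    count changes.
    """

    def __init__(self, n_convs, c_in, c_out, kernel, rng):
        self.convs = []
        self.acts = []
        c = c_in
        for _ in range(n_convs):
            self.convs.append(Conv3d(c, c_out, kernel, rng))
            self.acts.append(SELU())
            c = c_out
        self.proj = Conv3d(c_in, c_out, 1, rng) if c_in != c_out else None

    def params(self):
        out = []
        for conv in self.convs:
            out.extend(conv.params())
        if self.proj is not None:
            out.extend(self.proj.params())
        return out

    def forward(self, x):
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
        res = x if self.proj is None else self.proj.forward(x)
        return h + res

    def backward(self, dy):
        dres = dy if self.proj is None else self.proj.backward(dy)
        dh = dy
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            dh = conv.backward(act.backward(dh))
        return dh + dres


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
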