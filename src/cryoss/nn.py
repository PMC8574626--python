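"""Minimal CPU neural-network layers for volumetric models.

Dense 3D convolution, batch normalization, ReLU, 2x max pooling, and 2x
trilinear upsampling, each with a hand-derived backward pass, plus an Adam
optimizer.  Layers operate on arrays of shape (N, C, D, H, W).  Convolution
is im2col + BLAS matmul, processed one sample at a time to bound memory;
the column matrix is recomputed during the backward pass instead of cached.

The design goal is a small, predictable engine for desk-scale 3D
segmentation models, not a general autograd.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding for odd kernels.

    Implemented as the sum over the k^3 kernel offsets of a (cout, cin)
    matmul against the correspondingly shifted input -- a decomposition
    whose data movement is plain contiguous-run slice copies, which is what
    keeps a pure-numpy convolution at BLAS-limited speed.  Weights are kept
    as (cout, cin, k, k, k).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel, kernel)
                       ).astype(dtype)
        )
        self.bias = Param(np.zeros(out_channels, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _kmats(self, kernel: np.ndarray, flip: bool) -> dict:
        """Per-(a, b) stacked tap matrices (k*cout, cin) for the shift GEMMs."""
        k = self.k
        out = {}
        for a in range(k):
            for b in range(k):
                taps = (
                    kernel[:, :, k - 1 - a, k - 1 - b, ::-1] if flip
                    else kernel[:, :, a, b, :]
                )
                out[(a, b)] = np.ascontiguousarray(np.moveaxis(taps, 2, 0)).reshape(
                    k * kernel.shape[0], kernel.shape[1]
                )
        return out

    def _shift_conv_sample(
        self, src: np.ndarray, kmats: dict, out_channels: int, y: np.ndarray
    ) -> None:
        """One sample: correlate padded ``src`` (c, Dp, Hp, Wp) into the
        full-width accumulator ``y`` (cout, D, H, Wp).

        The two outer kernel offsets select a contiguous slice copy; the
        innermost offset is folded into a single stacked matmul followed by
        shifted accumulates.  Processing per sample keeps the working set
        cache-resident, which is what makes this path fast.
        """
        c = src.shape[0]
        k = self.k
        d, h, wp = y.shape[1], y.shape[2], y.shape[3]
        for a in range(k):
            for b in range(k):
                xs = np.ascontiguousarray(src[:, a : a + d, b : b + h, :]).reshape(
                    c, -1
                )
                z = (kmats[(a, b)] @ xs).reshape(k, out_channels, d, h, wp)
                for cc in range(k):
                    y[..., : wp - cc] += z[cc][..., cc:]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        p = self.pad
        xpad = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=x.dtype)
        xpad[:, :, p : p + d, p : p + h, p : p + w] = x
        self._xpad = xpad
        self._out_shape = (n, c, d, h, w)
        kmats = self._kmats(self.weight.data, flip=False)
        out = np.empty((n, self.cout, d, h, w), dtype=x.dtype)
        y = np.empty((self.cout, d, h, w + 2 * p), dtype=x.dtype)
        for s in range(n):
            y[...] = 0.0
            self._shift_conv_sample(xpad[s], kmats, self.cout, y)
            out[s] = y[..., :w]
        out += self.bias.data[None, :, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._out_shape
        k, p = self.k, self.pad
        xpad = self._xpad
        wp = w + 2 * p
        self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        wk = self.weight.data
        kmats_flip = self._kmats(np.swapaxes(wk, 0, 1), flip=True)
        dx = np.empty((n, c, d, h, w), dtype=dy.dtype)
        dwk = np.zeros((k, k, k, self.cout, c), dtype=np.float64)
        emb = np.zeros((k * self.cout, d, h, wp), dtype=dy.dtype)
        emb3 = emb.reshape(k, self.cout, d, h, wp)
        dy_pad = np.zeros((self.cout, d + 2 * p, h + 2 * p, wp), dtype=dy.dtype)
        dxy = np.empty((c, d, h, wp), dtype=dy.dtype)
        for s in range(n):
            # weight gradient: embed dy at each innermost lag -> one matmul
            for cc in range(k):
                emb3[cc, ..., cc : cc + w] = dy[s]
            emb_flat = emb.reshape(k * self.cout, -1)
            for a in range(k):
                for b in range(k):
                    xs = np.ascontiguousarray(
                        xpad[s, :, a : a + d, b : b + h, :]
                    ).reshape(c, -1)
                    g = (emb_flat @ xs.T).reshape(k, self.cout, c)
                    for cc in range(k):
                        dwk[a, b, cc] += g[cc]
            # input gradient: full convolution of dy with the flipped kernel
            dy_pad[:, p : p + d, p : p + h, p : p + w] = dy[s]
            dxy[...] = 0.0
            self._shift_conv_sample(dy_pad, kmats_flip, c, dxy)
            dx[s] = dxy[..., :w]
        self.weight.grad += np.transpose(dwk, (3, 4, 0, 1, 2)).astype(
            self.weight.grad.dtype
        )
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.calibrating = False
        self._cal_n = 0

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def begin_calibration(self) -> None:
        """Switch the running statistics to an exact arithmetic average of
        subsequent training-mode batch statistics ("precise BN")."""
        self.calibrating = True
        self._cal_n = 0

    def end_calibration(self) -> None:
        self.calibrating = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.calibrating:
                self._cal_n += 1
                self.running_mean += (mean - self.running_mean) / self._cal_n
                self.running_var += (var - self.running_var) / self._cal_n
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std)
        return (self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        shape = (1, -1, 1, 1, 1)
        dg = (dy * xhat).sum(axis=axes)
        db = dy.sum(axis=axes)
        self.gamma.grad += dg
        self.beta.grad += db
        dx = (
            self.gamma.data.reshape(shape)
            * inv_std.reshape(shape)
            / m
            * (m * dy - db.reshape(shape) - xhat * dg.reshape(shape))
        )
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"maxpool needs even spatial dims, got {(d, h, w)}")
        win = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        win = np.ascontiguousarray(np.transpose(win, (0, 1, 2, 4, 6, 3, 5, 7)))
        flat = win.reshape(n, c, d // 2, h // 2, w // 2, 8)
        self._arg = np.argmax(flat, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        flat = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        win = flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        win = np.transpose(win, (0, 1, 2, 5, 3, 6, 4, 7))
        return win.reshape(n, c, d, h, w)


def _upsample_matrix(n_in: int, dtype) -> np.ndarray:
    """(2n, n) trilinear factor-2 interpolation matrix for one axis.

    Output center i maps to input coordinate (i + 0.5)/2 - 0.5, clamped at
    the borders (the usual half-pixel-center convention).
    """
    n_out = 2 * n_in
    u = np.zeros((n_out, n_in), dtype=dtype)
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    u[np.arange(n_out), lo] += 1.0 - frac
    u[np.arange(n_out), hi] += frac
    return u


class Upsample3d(Layer):
    """Non-learned trilinear upsampling with zoom factor 2."""

    _matrices: dict[tuple[int, str], np.ndarray] = {}

    def _u(self, n: int, dtype) -> np.ndarray:
        key = (n, np.dtype(dtype).name)
        if key not in Upsample3d._matrices:
            Upsample3d._matrices[key] = _upsample_matrix(n, dtype)
        return Upsample3d._matrices[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        n, c, d, h, w = x.shape
        y = np.einsum("ad,ncdhw->ncahw", self._u(d, x.dtype), x)
        y = np.einsum("bh,ncahw->ncabw", self._u(h, x.dtype), y)
        y = np.einsum("cw,nkabw->nkabc", self._u(w, x.dtype), y)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        g = np.einsum("cw,nkabc->nkabw", self._u(w, dy.dtype), dy)
        g = np.einsum("bh,ncabw->ncahw", self._u(h, dy.dtype), g)
        g = np.einsum("ad,ncahw->ncdhw", self._u(d, dy.dtype), g)
        return np.ascontiguousarray(g)


class ConvBlock(Layer):
    """(conv3 -> batchnorm -> ReLU) twice; mid channels equal out channels."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv3d(in_channels, out_channels, 3, rng, dtype)
        self.bn1 = BatchNorm3d(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng, dtype)
        self.bn2 = BatchNorm3d(out_channels, dtype=dtype)
        self.relu2 = ReLU()

    def params(self) -> list[Param]:
        return (
            self.conv1.params() + self.bn1.params()
            + self.conv2.params() + self.bn2.params()
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), training))
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(y), training))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.conv2.backward(self.bn2.backward(self.relu2.backward(dy)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Channel-axis softmax for (N, C, ...) or (C, ...) arrays."""
    axis = 1 if logits.ndim == 5 else 0
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
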