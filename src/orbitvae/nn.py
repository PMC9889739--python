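"""Minimal NumPy neural-network layer used by the 3D VAE.

Implements exactly the pieces the autoencoder needs — 3D convolution
(stride 1, arbitrary zero padding), stride-2 transposed convolution
(kernel 4, padding 1, realised as eight phase-wise 2x2x2 convolutions),
batch normalization, max pooling, dropout, dense layers, trilinear x2
upsampling and the Adam optimizer — with hand-written backward passes.
Convolutions are evaluated as im2col matrix products so the heavy
lifting happens in BLAS; im2col buffers are chunked over the batch to
bound memory.

All layers follow the same contract: ``forward(x, train=...)`` caches
what the backward pass needs, ``backward(dy)`` returns the gradient
with respect to the input and accumulates parameter gradients in
``layer.grads``.  Parameters live in ``layer.params``.  Everything is
deterministic given the ``numpy.random.Generator`` objects passed in.
"""

from __future__ import annotations

from itertools import product as _product

import numpy as np

DTYPE = np.float32

# cap on im2col scratch (elements); keeps peak memory a few hundred MB
_MAX_COL_ELEMS = 1 << 26


# ---------------------------------------------------------------------------
# functional 3D convolution (stride 1)

def _im2col(xp: np.ndarray, k: int, outs) -> np.ndarray:
    """(M, C, Dp, Hp, Wp) padded input -> (C*k^3, M*P) patch matrix.

    Built with k^3 block-contiguous slice copies (cache-friendly),
    laid out so the convolution is one large GEMM.
    """
    m, c = xp.shape[:2]
    p = outs[0] * outs[1] * outs[2]
    cols = np.empty((c, k ** 3, m, p), dtype=xp.dtype)
    t = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                src = xp[:, :, i:i + outs[0], j:j + outs[1], l:l + outs[2]]
                cols[:, t].reshape(c, m, *outs)[...] = src.transpose(1, 0, 2, 3, 4)
                t += 1
    return cols.reshape(c * k ** 3, m * p)


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
           pad=((1, 1), (1, 1), (1, 1)), want_cols: bool = False):
    """Stride-1 3D cross-correlation. w: (Cout, Cin, k, k, k).

    With ``want_cols=True`` also returns the patch matrix for reuse by
    the weight-gradient (or None when the batch had to be chunked).
    """
    n, cin = x.shape[:2]
    cout, _, k = w.shape[0], w.shape[1], w.shape[2]
    outs = tuple(x.shape[2 + i] + pad[i][0] + pad[i][1] - k + 1 for i in range(3))
    p = outs[0] * outs[1] * outs[2]
    wmat = w.reshape(cout, -1)
    y = np.empty((n, cout) + outs, dtype=x.dtype)
    per = cin * k ** 3 * p
    chunk = max(1, _MAX_COL_ELEMS // max(per, 1))
    kept = None
    for s in range(0, n, chunk):
        xp = np.pad(x[s:s + chunk], ((0, 0), (0, 0)) + tuple(pad))
        m = xp.shape[0]
        cols = _im2col(xp, k, outs)                 # (CK, M*P)
        yc = (wmat @ cols).reshape(cout, m, *outs)  # (Cout, M, ...)
        y[s:s + chunk] = yc.transpose(1, 0, 2, 3, 4)
        if want_cols and chunk >= n:
            kept = cols
    if b is not None:
        y += b.reshape(1, -1, 1, 1, 1)
    return (y, kept) if want_cols else y


def conv3d_grad_weights(x: np.ndarray, dy: np.ndarray, k: int, pad):
    """Gradients (dW, db) of conv3d; recomputes im2col chunk-wise."""
    n, cin = x.shape[:2]
    cout = dy.shape[1]
    outs = dy.shape[2:]
    p = outs[0] * outs[1] * outs[2]
    dwmat = np.zeros((cout, cin * k ** 3), dtype=x.dtype)
    per = cin * k ** 3 * p
    chunk = max(1, _MAX_COL_ELEMS // max(per, 1))
    for s in range(0, n, chunk):
        xp = np.pad(x[s:s + chunk], ((0, 0), (0, 0)) + tuple(pad))
        m = xp.shape[0]
        cols = _im2col(xp, k, outs)                               # (CK, M*P)
        dym = np.ascontiguousarray(
            dy[s:s + chunk].transpose(1, 0, 2, 3, 4)).reshape(cout, m * p)
        dwmat += dym @ cols.T
    db = dy.sum(axis=(0, 2, 3, 4))
    return dwmat.reshape(cout, cin, k, k, k), db


def conv3d_grad_input(dy: np.ndarray, w: np.ndarray, pad) -> np.ndarray:
    """Gradient w.r.t. the (unpadded) input: full conv with rotated kernel."""
    k = w.shape[2]
    wr = np.ascontiguousarray(np.flip(w, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
    padb = tuple((k - 1 - lo, k - 1 - hi) for (lo, hi) in pad)
    return conv3d(dy, wr, None, padb)


# ---------------------------------------------------------------------------
# layers

class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grads(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv3d(Layer):
    """3x3x3 (by default) convolution, stride 1, symmetric zero padding.

    ``first_layer=True`` skips the input-gradient computation (the
    gradient w.r.t. raw network input is never used).
    """

    def __init__(self, cin, cout, k=3, pad=1, rng=None, dtype=DTYPE,
                 first_layer=False):
        super().__init__()
        self.k, self.pad = k, ((pad, pad),) * 3
        self.first_layer = first_layer
        fan_in = cin * k ** 3
        rng = rng or np.random.default_rng(0)
        self.params["w"] = (rng.standard_normal((cout, cin, k, k, k))
                            * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False):
        self._x = x
        y, cols = conv3d(x, self.params["w"], self.params["b"], self.pad,
                         want_cols=True)
        self._cols = cols if train else None
        return y

    def backward(self, dy):
        if self._cols is not None:
            n, cout = dy.shape[:2]
            p = dy.shape[2] * dy.shape[3] * dy.shape[4]
            dym = np.ascontiguousarray(
                dy.transpose(1, 0, 2, 3, 4)).reshape(cout, n * p)
            dwmat = dym @ self._cols.T
            self.grads["w"] += dwmat.reshape(self.params["w"].shape)
            self.grads["b"] += dy.sum(axis=(0, 2, 3, 4))
            self._cols = None
        else:
            dw, db = conv3d_grad_weights(self._x, dy, self.k, self.pad)
            self.grads["w"] += dw
            self.grads["b"] += db
        if self.first_layer:
            return None
        return conv3d_grad_input(dy, self.params["w"], self.pad)


class ConvTranspose3d(Layer):
    """Transposed 3D convolution, kernel 4, stride 2, padding 1 (doubles size).

    Evaluated as eight phase-wise 2x2x2 stride-1 convolutions (the
    sub-pixel decomposition), which avoids zero-stuffed inputs.
    """

    _TMAP = {0: (3, 1), 1: (2, 0)}     # kernel taps feeding each output parity
    _PADS = {0: (1, 0), 1: (0, 1)}

    def __init__(self, cin, cout, rng=None, dtype=DTYPE):
        super().__init__()
        fan_in = cin * 4 ** 3
        rng = rng or np.random.default_rng(0)
        self.params["w"] = (rng.standard_normal((cout, cin, 4, 4, 4))
                            * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grads()

    def _phase_kernel(self, w, a, b, c):
        ta, tb, tc = self._TMAP[a], self._TMAP[b], self._TMAP[c]
        return np.ascontiguousarray(w[:, :, ta][:, :, :, tb][:, :, :, :, tc])

    def forward(self, x, train=False):
        self._x = x
        w, bias = self.params["w"], self.params["b"]
        n, _, d, h, wd = x.shape
        cout = w.shape[0]
        y = np.empty((n, cout, 2 * d, 2 * h, 2 * wd), dtype=x.dtype)
        for a, b, c in _product((0, 1), repeat=3):
            k = self._phase_kernel(w, a, b, c)
            pad = (self._PADS[a], self._PADS[b], self._PADS[c])
            y[:, :, a::2, b::2, c::2] = conv3d(x, k, None, pad)
        y += bias.reshape(1, -1, 1, 1, 1)
        return y

    def backward(self, dy):
        w = self.params["w"]
        dx = np.zeros_like(self._x)
        for a, b, c in _product((0, 1), repeat=3):
            k = self._phase_kernel(w, a, b, c)
            pad = (self._PADS[a], self._PADS[b], self._PADS[c])
            dyp = np.ascontiguousarray(dy[:, :, a::2, b::2, c::2])
            dx += conv3d_grad_input(dyp, k, pad)
            dkp, _ = conv3d_grad_weights(self._x, dyp, 2, pad)
            ta, tb, tc = self._TMAP[a], self._TMAP[b], self._TMAP[c]
            for i, j, l in _product((0, 1), repeat=3):
                self.grads["w"][:, :, ta[i], tb[j], tc[l]] += dkp[:, :, i, j, l]
        self.grads["b"] += dy.sum(axis=(0, 2, 3, 4))
        return dx


class BatchNorm3d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=DTYPE):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.zero_grads()

    @staticmethod
    def _bc(v):
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x, train=False):
        if train:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean)) * self._bc(invstd)
        self._cache = (xhat, invstd, train, x.shape)
        return self._bc(self.params["gamma"]) * xhat + self._bc(self.params["beta"])

    def backward(self, dy):
        xhat, invstd, train, shape = self._cache
        axes = (0, 2, 3, 4)
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self._bc(self.params["gamma"] * invstd)
        if not train:
            return dy * g
        m = shape[0] * shape[2] * shape[3] * shape[4]
        dy_sum = self._bc(dy.sum(axis=axes))
        dyx_sum = self._bc((dy * xhat).sum(axis=axes))
        return (g / m) * (m * dy - dy_sum - xhat * dyx_sum)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs ``layer.rng`` in train mode."""

    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training forward")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2. Gradient is split evenly among ties."""

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        self._cache = (xr, y)
        return y

    def backward(self, dy):
        xr, y = self._cache
        ye = y[:, :, :, None, :, None, :, None]
        mask = (xr == ye).astype(dy.dtype)
        cnt = mask.sum(axis=(3, 5, 7), keepdims=True)
        dye = dy[:, :, :, None, :, None, :, None]
        dxr = mask * (dye / cnt)
        n, c = xr.shape[:2]
        return dxr.reshape(n, c, xr.shape[2] * 2, xr.shape[4] * 2, xr.shape[6] * 2)


class Upsample2(Layer):
    """Trilinear x2 upsampling (half-pixel alignment, edges clamped)."""

    @staticmethod
    def _up_axis(x, axis):
        xm = np.moveaxis(x, axis, 0)
        prev = np.concatenate([xm[:1], xm[:-1]], axis=0)
        nxt = np.concatenate([xm[1:], xm[-1:]], axis=0)
        out = np.empty((2 * xm.shape[0],) + xm.shape[1:], dtype=x.dtype)
        out[0::2] = 0.25 * prev + 0.75 * xm
        out[1::2] = 0.75 * xm + 0.25 * nxt
        return np.moveaxis(out, 0, axis)

    @staticmethod
    def _down_axis(dy, axis):
        dm = np.moveaxis(dy, axis, 0)
        de, do = dm[0::2], dm[1::2]
        dx = 0.75 * (de + do)
        dx[:-1] += 0.25 * de[1:]
        dx[0] += 0.25 * de[0]
        dx[1:] += 0.25 * do[:-1]
        dx[-1] += 0.25 * do[-1]
        return np.moveaxis(dx, 0, axis)

    def forward(self, x, train=False):
        y = x
        for ax in (2, 3, 4):
            y = self._up_axis(y, ax)
        return y

    def backward(self, dy):
        dx = dy
        for ax in (4, 3, 2):
            dx = self._down_axis(dx, ax)
        return dx


class Linear(Layer):
    def __init__(self, nin, nout, rng=None, dtype=DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = (rng.standard_normal((nin, nout))
                            * np.sqrt(2.0 / nin)).astype(dtype)
        self.params["b"] = np.zeros(nout, dtype=dtype)
        self.zero_grads()

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"].T


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def zero_grads(self):
        for lay in self.layers:
            lay.zero_grads()


def iter_params(layers):
    """Yield (layer, name) for every learnable parameter in ``layers``."""
    for lay in layers:
        if isinstance(lay, Sequential):
            yield from iter_params(lay.layers)
        else:
            for name in lay.params:
                yield lay, name


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(iter_params(layers))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(lay.params[n]) for lay, n in self.slots]
        self.v = [np.zeros_like(lay.params[n]) for lay, n in self.slots]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, (lay, name) in enumerate(self.slots):
            g = lay.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            lay.params[name] -= (self.lr * mhat /
                                 (np.sqrt(vhat) + self.eps)).astype(lay.params[name].dtype)

    def zero_grads(self):
        for lay, name in self.slots:
            lay.grads[name] = np.zeros_like(lay.params[name])
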