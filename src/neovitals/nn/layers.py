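"""Layer implementations with explicit forward/backward passes.

Every layer exposes ``forward(x, train)``, ``backward(dy)`` (returning the
gradient with respect to its input and caching parameter gradients) and
``parameters()`` yielding ``(array, grad)`` pairs for the optimizer.
"""

from __future__ import annotations

import numpy as np

from .functional import col2im, im2col


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    """Glorot uniform initialization: U(-a, a) with a = sqrt(6/(fan_in+fan_out))."""
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape).astype(np.float32)


def bilinear_kernel(k: int) -> np.ndarray:
    """k x k bilinear interpolation filter (FCN upsampling initializer)."""
    factor = (k + 1) // 2
    center = factor - 1 if k % 2 == 1 else factor - 0.5
    og = np.ogrid[:k, :k]
    filt = (1 - abs(og[0] - center) / factor) * (1 - abs(og[1] - center) / factor)
    return filt.astype(np.float32)


class Layer:
    trainable = True

    def parameters(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Conv2d(Layer):
    """2-D convolution, square kernel, symmetric zero padding."""

    def __init__(self, c_in, c_out, k, stride=1, pad=None, rng=None, init="xavier"):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        fan_out = c_out * k * k
        if init == "xavier":
            self.W = xavier_uniform((c_out, c_in, k, k), fan_in, fan_out, rng)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad)
        self._cache = (x.shape, cols)
        wmat = self.W.reshape(self.c_out, -1)
        y = np.einsum("oc,ncp->nop", wmat, cols, optimize=True)
        y += self.b[None, :, None]
        return y.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dy):
        x_shape, cols = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, -1)
        self.dW[...] = np.einsum("nop,ncp->oc", dyf, cols, optimize=True).reshape(self.W.shape)
        self.db[...] = dyf.sum(axis=(0, 2))
        wmat = self.W.reshape(self.c_out, -1)
        dcols = np.einsum("oc,nop->ncp", wmat, dyf, optimize=True)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transpose convolution (learnable upsampling).

    Implemented as the exact adjoint of a strided convolution: the forward
    pass scatter-adds weighted columns onto the upsampled grid (col2im), so
    all matrix products run at the coarse-grid size. Output size is
    ``(H-1)*stride + k - 2*pad``; with ``k = 2*stride`` and
    ``pad = stride//2`` this upsamples exactly by ``stride``, the FCN
    convention.
    """

    def __init__(self, c_in, c_out, k, stride, rng=None, init="bilinear", bias=False):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - stride) // 2
        self.W = np.zeros((c_in, c_out, k, k), dtype=np.float32)
        if init == "bilinear":
            filt = bilinear_kernel(k)
            for i in range(min(c_in, c_out)):
                self.W[i, i] = filt
        elif init == "xavier":
            rng = rng or np.random.default_rng(0)
            self.W = xavier_uniform((c_in, c_out, k, k), c_in * k * k, c_out * k * k, rng)
        self.use_bias = bias
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        ps = [(self.W, self.dW)]
        if self.use_bias:
            ps.append((self.b, self.db))
        return ps

    def _out_shape(self, n, h, w):
        s, k, p = self.stride, self.k, self.pad
        return (n, self.c_out, (h - 1) * s + k - 2 * p, (w - 1) * s + k - 2 * p)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        self._cache = (x.shape, xf)
        wmat = self.W.reshape(self.c_in, -1)  # (c_in, c_out*k*k)
        cols = np.einsum("cq,ncp->nqp", wmat, xf, optimize=True)
        y = col2im(cols, self._out_shape(n, h, w), self.k, self.stride, self.pad)
        if self.use_bias:
            y += self.b[None, :, None, None]
        return y

    def backward(self, dy):
        x_shape, xf = self._cache
        n, c, h, w = x_shape
        cols, _, _ = im2col(dy, self.k, self.stride, self.pad)  # (n, c_out*k*k, h*w)
        self.dW[...] = np.einsum(
            "ncp,nqp->cq", xf, cols, optimize=True
        ).reshape(self.W.shape)
        if self.use_bias:
            self.db[...] = dy.sum(axis=(0, 2, 3))
        wmat = self.W.reshape(self.c_in, -1)
        dx = np.einsum("cq,nqp->ncp", wmat, cols, optimize=True)
        return dx.reshape(x_shape).astype(dy.dtype)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dy * g
        # standard batchnorm backward (training statistics)
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return inv[None, :, None, None] * (t1 - t2)


class ReLU(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (ties go to the first maximum)."""

    trainable = False

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        return (
            out.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class GlobalAvgPool2d(Layer):
    """Spatial averaging of a feature map to one value per channel."""

    trainable = False

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(dy.dtype).copy()


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = xavier_uniform((n_out, n_in), n_in, n_out, rng)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
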