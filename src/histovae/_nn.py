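"""Minimal NHWC neural-network layer stack with manual backpropagation.

Only the pieces the encoder/decoder and the patch classifier need:
``Dense``, stride-2 ``Conv2D`` and ``ConvTranspose2D`` with TensorFlow-style
"same" padding, inverted ``Dropout``, a no-op ``MaxPool2D`` kept for layer
bookkeeping, and an ``Adam`` optimiser.  Everything is float32 and fully
deterministic given the RNGs handed in.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "InputLayer",
    "Dense",
    "Conv2D",
    "ConvTranspose2D",
    "Flatten",
    "Reshape",
    "Dropout",
    "MaxPool2D",
    "Sequential",
    "Adam",
    "glorot_uniform",
]

_F32 = np.float32


def glorot_uniform(shape, fan_in, fan_out, rng):
    """Glorot/Xavier uniform initialiser, the Keras default."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


def _apply_activation(a, activation):
    if activation is None:
        return a
    if activation == "relu":
        return np.maximum(a, 0.0)
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-a))
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(dout, out, activation):
    """Gradient through the activation, using the cached *output*."""
    if activation is None:
        return dout
    if activation == "relu":
        return dout * (out > 0)
    if activation == "sigmoid":
        return dout * out * (1.0 - out)
    raise ValueError(f"unknown activation {activation!r}")


def _same_pad(size, kernel, stride):
    """TensorFlow 'same' padding: output ceil(size/stride), extra on the end."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    beg = total // 2
    return out, beg, total - beg


def _im2col(xp, kernel, stride, oh, ow):
    """(N, Hp, Wp, C) padded input -> (N*oh*ow, kernel*kernel*C) patch matrix."""
    n, _, _, c = xp.shape
    cols = np.empty((n, oh, ow, kernel * kernel, c), dtype=xp.dtype)
    for i in range(kernel):
        for j in range(kernel):
            cols[:, :, :, i * kernel + j, :] = xp[
                :, i : i + oh * stride : stride, j : j + ow * stride : stride, :
            ]
    return cols.reshape(n * oh * ow, kernel * kernel * c)


def _col2im(cols, padded_shape, kernel, stride, oh, ow):
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the grid."""
    n, _, _, c = padded_shape
    xp = np.zeros(padded_shape, dtype=cols.dtype)
    cols = cols.reshape(n, oh, ow, kernel * kernel, c)
    for i in range(kernel):
        for j in range(kernel):
            xp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += cols[
                :, :, :, i * kernel + j, :
            ]
    return xp


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class InputLayer(Layer):
    """Identity placeholder so architectures can be counted as printed."""

    def __init__(self, shape=None):
        super().__init__()
        self.shape = shape

    def forward(self, x, training=False):
        if self.shape is not None and tuple(x.shape[1:]) != tuple(self.shape):
            raise ValueError(f"expected input shape {self.shape}, got {x.shape[1:]}")
        return x

    def backward(self, dout):
        return dout


class Dense(Layer):
    def __init__(self, n_in, n_out, activation=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.activation = activation
        self.w = glorot_uniform((self.n_in, self.n_out), self.n_in, self.n_out, rng)
        self.b = np.zeros(self.n_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        if x.shape[-1] != self.n_in:
            raise ValueError(f"Dense expected width {self.n_in}, got {x.shape[-1]}")
        self._x = x
        out = _apply_activation(x @ self.w + self.b, self.activation)
        self._out = out
        return out

    def backward(self, dout):
        da = _activation_grad(dout, self._out, self.activation)
        self.grads[0][...] = self._x.T @ da
        self.grads[1][...] = da.sum(axis=0)
        return da @ self.w.T


class Conv2D(Layer):
    """3x3-style convolution, NHWC, 'same' padding, arbitrary stride."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, activation=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride = int(kernel), int(stride)
        self.activation = activation
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.w = glorot_uniform((fan_in, self.c_out), fan_in, fan_out, rng)
        self.b = np.zeros(self.c_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2D expected {self.c_in} channels, got {c}")
        k, s = self.kernel, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(xp, k, s, oh, ow)
        a = cols @ self.w + self.b
        out = _apply_activation(a, self.activation)
        self._cache = (cols, xp.shape, (pt, pb, pl, pr), (n, oh, ow))
        self._out = out
        return out.reshape(n, oh, ow, self.c_out)

    def backward(self, dout):
        cols, padded_shape, (pt, pb, pl, pr), (n, oh, ow) = self._cache
        da = _activation_grad(dout.reshape(-1, self.c_out), self._out, self.activation)
        self.grads[0][...] = cols.T @ da
        self.grads[1][...] = da.sum(axis=0)
        dxp = _col2im(da @ self.w.T, padded_shape, self.kernel, self.stride, oh, ow)
        _, hp, wp, _ = padded_shape
        return dxp[:, pt : hp - pb, pl : wp - pr, :]


class ConvTranspose2D(Layer):
    """Transposed convolution: the exact adjoint of a 'same' strided Conv2D.

    Output spatial size is input size x stride, matching Keras
    ``Conv2DTranspose(..., strides=s, padding="same")``.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, activation=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride = int(kernel), int(stride)
        self.activation = activation
        # stored in the layout of the adjoint convolution: (k*k*c_out, c_in)
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.w = glorot_uniform((kernel * kernel * self.c_out, self.c_in), fan_in, fan_out, rng)
        self.b = np.zeros(self.c_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"ConvTranspose2D expected {self.c_in} channels, got {c}")
        k, s = self.kernel, self.stride
        ho, wo = h * s, w * s
        # padding of the adjoint conv mapping (ho, wo) -> (h, w)
        oh, pt, pb = _same_pad(ho, k, s)
        ow, pl, pr = _same_pad(wo, k, s)
        assert (oh, ow) == (h, w)
        x_flat = x.reshape(n * h * w, self.c_in)
        padded_shape = (n, ho + pt + pb, wo + pl + pr, self.c_out)
        yp = _col2im(x_flat @ self.w.T, padded_shape, k, s, h, w)
        y = yp[:, pt : pt + ho, pl : pl + wo, :] + self.b
        out = _apply_activation(y.reshape(-1, self.c_out), self.activation)
        self._cache = (x_flat, (n, h, w), (pt, pb, pl, pr), (ho, wo))
        self._out = out
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dout):
        x_flat, (n, h, w), (pt, pb, pl, pr), (ho, wo) = self._cache
        dy = _activation_grad(dout.reshape(-1, self.c_out), self._out, self.activation)
        dy = dy.reshape(n, ho, wo, self.c_out)
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        dyp = np.pad(dy, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(dyp, self.kernel, self.stride, h, w)
        self.grads[0][...] = cols.T @ x_flat
        return (cols @ self.w).reshape(n, h, w, self.c_in)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target_shape):
        super().__init__()
        self.target_shape = tuple(target_shape)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target_shape)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; inert (identity) outside training."""

    def __init__(self, rate):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2D(Layer):
    """Pooling with pool size (1, 1) only — an identity kept so the printed
    layer enumeration is preserved; spatial reduction comes from conv strides."""

    def __init__(self, pool_size=(1, 1)):
        super().__init__()
        if tuple(pool_size) != (1, 1):
            raise NotImplementedError("only the (1, 1) no-op pool is supported")
        self.pool_size = (1, 1)

    def forward(self, x, training=False):
        return x

    def backward(self, dout):
        return dout


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def set_dropout_rng(self, rng):
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng


class Adam:
    """Adam with Keras defaults (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params, learning_rate, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.learning_rate = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.learning_rate * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
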