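"""Layers with forward/backward passes.

Conventions: activations are float64 arrays with the batch on axis 0;
image tensors are (B, H, W, F).  Each layer exposes ``params`` and
``grads`` (parallel lists), ``forward(x, training)`` and ``backward(dout)``
returning the gradient with respect to its input.  Weight initialization
is He-normal (fan-in), suited to ReLU networks.
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted for numerical stability."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer: y = x W + b."""

    def __init__(self, in_features, out_features, rng):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class Conv2D(Layer):
    """2-D convolution over (B, H, W, Cin) with small filters.

    ``padding='same'`` preserves the spatial shape (zero padding);
    ``padding='valid'`` shrinks it by kernel-1.
    """

    def __init__(self, in_channels, out_channels, kernel, rng, padding="same"):
        super().__init__()
        kh, kw = kernel if isinstance(kernel, tuple) else (kernel, kernel)
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.kh, self.kw, self.padding = kh, kw, padding
        fan_in = kh * kw * in_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0, 0, 0)
        # 'same' with stride 1: total pad = k - 1, extra on the trailing side
        pt = (self.kh - 1) // 2
        pb = self.kh - 1 - pt
        pl = (self.kw - 1) // 2
        pr = self.kw - 1 - pl
        return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))), (pt, pb, pl, pr)

    def forward(self, x, training=False):
        B, H, W, C = x.shape
        if self.padding == "valid" and (H < self.kh or W < self.kw):
            raise ValueError(
                f"input {H}x{W} smaller than filter {self.kh}x{self.kw}"
            )
        xp, self._pads = self._pad(x)
        self._in_shape = x.shape
        self._xp_shape = xp.shape
        # patches[b, h, w, c, i, j] = xp[b, h+i, w+j, c]
        patches = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        self._patches = patches
        return np.einsum("bhwcij,ijco->bhwo", patches, self.W, optimize=True) + self.b

    def backward(self, dout):
        self.dW += np.einsum("bhwcij,bhwo->ijco", self._patches, dout, optimize=True)
        self.db += dout.sum(axis=(0, 1, 2))
        B, Hp, Wp, C = self._xp_shape
        Ho, Wo = dout.shape[1], dout.shape[2]
        dxp = np.zeros(self._xp_shape)
        # scatter dpatches back: dxp[b, h+i, w+j, c] += dout[b,h,w,o] W[i,j,c,o]
        dpatch = np.einsum("bhwo,ijco->bhwijc", dout, self.W, optimize=True)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + Ho, j : j + Wo, :] += dpatch[:, :, :, i, j, :]
        pt, pb, pl, pr = self._pads
        H, W = self._in_shape[1], self._in_shape[2]
        return dxp[:, pt : pt + H, pl : pl + W, :]


class LocallyConnected2D(Layer):
    """Convolution-like layer whose 1x1 filters are NOT shared across
    spatial positions: every (h, w) location has its own weight matrix and
    bias.  Parameter count is therefore positions x (in x out + out), a
    factor H*W more than the tied-weight 1x1 convolution."""

    def __init__(self, height, width, in_channels, out_channels, rng):
        super().__init__()
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / in_channels),
            size=(height, width, in_channels, out_channels),
        )
        self.b = np.zeros((height, width, out_channels))
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, training=False):
        if x.shape[1:3] != self.W.shape[:2]:
            raise ValueError(
                f"input spatial shape {x.shape[1:3]} does not match "
                f"layer shape {self.W.shape[:2]}"
            )
        self._x = x
        return np.einsum("bhwi,hwio->bhwo", x, self.W, optimize=True) + self.b

    def backward(self, dout):
        self.dW += np.einsum("bhwi,bhwo->hwio", self._x, dout, optimize=True)
        self.db += dout.sum(axis=0)
        return np.einsum("bhwo,hwio->bhwi", dout, self.W, optimize=True)


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial) axes per feature.

    Training uses batch statistics and maintains exponential running
    averages (momentum 0.9); inference uses the running statistics.
    """

    def __init__(self, num_features, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(num_features)
        self.beta = np.zeros(num_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._m = np.prod([x.shape[a] for a in axes])
        else:
            mean, var = self.running_mean, self.running_var
        self._training = training
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.dgamma += (dout * self._xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        dxhat = dout * self.gamma
        if not self._training:
            return dxhat * self._invstd
        m = self._m
        return (self._invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference.  The drop rate is mutable
    so the pre-train -> fine-tune rate switch reuses the same graph."""

    def __init__(self, rate, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential(Layer):
    """A chain of layers applied in order."""

    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)
        for l in self.layers:
            self.params.extend(l.params)
            self.grads.extend(l.grads)

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def set_dropout_rate(self, rate):
        for l in self.layers:
            if isinstance(l, Dropout):
                l.rate = rate
            elif isinstance(l, Sequential):
                l.set_dropout_rate(rate)
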