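"""Minimal layer objects with explicit forward/backward passes.

Each layer stores its parameters and, after ``backward``, the matching
gradients.  There is no autograd graph: composite networks chain layer
calls by hand, which keeps the execution order (and hence determinism)
fully explicit.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Layer:
    """Base class; layers without parameters inherit the empty containers."""

    def params(self):
        return []

    def grads(self):
        return []

    def buffers(self):
        return []


class Conv2d(Layer):
    """Stride-1 convolution with optional zero padding and dilation."""

    def __init__(self, c_in, c_out, k, pad=0, dilation=1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        # He initialisation, suited to the ReLU blocks these convs sit in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.pad = pad
        self.dilation = dilation
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=True):
        y = F.conv2d(x, self.w, self.b, pad=self.pad, dilation=self.dilation)
        if train:
            self._cache = x
        return y

    def backward(self, gy):
        x = self._cache
        gx, gw, gb = F.conv2d_backward(gy, x, self.w, self.pad, self.dilation)
        self.gw += gw
        self.gb += gb
        return gx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with affine parameters.

    Training mode normalises by the batch statistics over (B, H, W) and
    updates exponential running averages; evaluation mode uses the running
    averages, so dense inference and patch evaluation agree exactly.
    """

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        c = x.shape[1]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, gy):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.ggamma += (gy * xhat).sum(axis=(0, 2, 3))
        self.gbeta += gy.sum(axis=(0, 2, 3))
        dxhat = gy * self.gamma[:, None, None]
        # standard batch-norm input gradient (batch statistics)
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        gx = (inv[:, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return gx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x, train=True):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy):
        return gy * self._mask


class MaxPool2(Layer):
    def forward(self, x, train=True):
        y, xr = F.maxpool2(x)
        if train:
            self._cache = (xr, y)
        return y

    def backward(self, gy):
        xr, y = self._cache
        return F.maxpool2_backward(gy, xr, y)


class Upsample2(Layer):
    def forward(self, x, train=True):
        return F.upsample2(x)

    def backward(self, gy):
        return F.upsample2_backward(gy)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]


def zero_grads(module: Layer):
    for g in module.grads():
        g[...] = 0.0
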