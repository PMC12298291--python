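"""Neural-network layers on top of the autodiff engine.

Weight initialisation is explicit: every layer draws from the
``numpy.random.Generator`` handed to its constructor, so a single seed
reproduces a model bit-for-bit.
"""
from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, conv2d, deform_conv2d, silu, sqrt)

DTYPE = np.float32


class Module:
    """Minimal module base: parameter discovery, train/eval flag,
    state-dict (de)serialisation."""

    def __init__(self):
        self.training = True

    # recursive discovery over instance attributes
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({"buf:" + k: v.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in d.items():
            if k.startswith("buf:"):
                bufs[k[4:]][...] = v
            else:
                params[k].data[...] = v

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(DTYPE),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, padding=None,
                 bias=True, zero_init=False):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = c_in * k * k
        if zero_init:
            self.weight = Tensor(np.zeros((c_out, c_in, k, k), DTYPE),
                                 requires_grad=True)
        else:
            self.weight = _kaiming(rng, (c_out, c_in, k, k), fan_in)
        self.bias = (Tensor(np.zeros(c_out, DTYPE), requires_grad=True)
                     if bias else None)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalisation composed from autodiff primitives; keeps running
    statistics for eval mode."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, c, 1, 1), DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), DTYPE), requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1), DTYPE)
        self.running_var = np.ones((1, c, 1, 1), DTYPE)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data).astype(DTYPE)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class ConvBNAct(Module):
    """Conv → BatchNorm → SiLU, the standard YOLO building cell."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1):
        super().__init__()
        self.conv = Conv2d(rng, c_in, c_out, k=k, stride=stride, bias=False)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return silu(self.bn(self.conv(x)))


class DeformableConv2d(Module):
    """3x3 deformable convolution whose per-position offsets are predicted by
    a zero-initialised plain convolution, so training starts as an ordinary
    convolution."""

    def __init__(self, rng, c_in, c_out, k=3):
        super().__init__()
        self.k = k
        self.offset_conv = Conv2d(rng, c_in, 2 * k * k, k=k, zero_init=True)
        fan_in = c_in * k * k
        self.weight = _kaiming(rng, (c_out, c_in, k, k), fan_in)
        self.bias = Tensor(np.zeros(c_out, DTYPE), requires_grad=True)

    def forward(self, x, offsets=None):
        if offsets is None:
            offsets = self.offset_conv(x)
        return deform_conv2d(x, offsets, self.weight, self.bias,
                             padding=self.k // 2)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
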