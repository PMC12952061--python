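"""Trainable layer wrappers over the autodiff primitives (NCHW layout)."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "DeformConv2d", "BatchNorm2d", "Linear", "Dropout"]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        for name, value in self.__dict__.items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
        for mod in self.modules():
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor) and value.requires_grad:
                    yield value

    def named_state(self):
        """Flat name -> array mapping of every parameter and buffer."""
        out = {}

        def collect(mod, prefix):
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor):
                    out[prefix + name] = value.data
                elif isinstance(value, np.ndarray):
                    out[prefix + name] = value
                elif isinstance(value, Module):
                    collect(value, f"{prefix}{name}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            collect(item, f"{prefix}{name}.{i}.")

        collect(self, "")
        return out

    def load_state(self, state: dict):
        def assign(mod, prefix):
            for name, value in mod.__dict__.items():
                key = prefix + name
                if isinstance(value, Tensor):
                    value.data = np.array(state[key], dtype=np.float64).reshape(value.data.shape)
                elif isinstance(value, np.ndarray):
                    mod.__dict__[name] = np.array(state[key], dtype=np.float64).reshape(value.shape)
                elif isinstance(value, Module):
                    assign(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            assign(item, f"{key}.{i}.")

        assign(self, "")

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k, stride: int = 1, padding=0,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = (k, k) if isinstance(k, int) else k
        self.stride, self.padding, self.groups = stride, padding, groups
        self.weight = _he_init(rng, (cout, cin // groups, kh, kw), (cin // groups) * kh * kw)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class DeformConv2d(Module):
    """Deformable convolution with its parallel offset-generating 3x3 conv.

    The offset generator is a plain convolution with ``2*K*K*offset_groups``
    output channels, initialized to zero so that the layer starts out exactly
    equal to a standard convolution and the offsets are learned end-to-end.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, padding: int = 1,
                 groups: int = 1, offset_groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.groups, self.offset_groups, self.k = groups, offset_groups, k
        self.weight = _he_init(rng, (cout, cin // groups, k, k), (cin // groups) * k * k)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        # padding chosen so the offset field covers exactly the output grid
        self.offset_gen = Conv2d(cin, 2 * k * k * offset_groups, 3, stride=stride,
                                 padding=padding + (3 - k) // 2, bias=True, rng=rng)
        # zero init: training starts from an ordinary convolution
        self.offset_gen.weight.data[...] = 0.0
        self.offset_gen.bias.data[...] = 0.0

    def offsets(self, x: Tensor) -> Tensor:
        return self.offset_gen(x)

    def __call__(self, x: Tensor) -> Tensor:
        off = self.offset_gen(x)
        return ad.deform_conv2d(x, self.weight, self.bias, off, stride=self.stride,
                                padding=self.padding, groups=self.groups,
                                offset_groups=self.offset_groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return self.gamma * xhat + self.beta


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (cin, cout), cin)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Needs an explicit rng."""

    def __init__(self, p: float = 0.3):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, rng: np.random.Generator):
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
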