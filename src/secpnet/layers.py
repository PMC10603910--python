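"""Layer modules over the autodiff core: parameter registration, train/eval
mode, state dicts, and He-style initialisation."""

from __future__ import annotations

import hashlib

import numpy as np

from .autodiff import (
    Parameter,
    Tensor,
    batchnorm2d,
    conv2d,
    linear,
    relu,
)

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ConvBlock",
    "parameter_hash",
]


class Module:
    """Base class: child modules and parameters are discovered by attribute
    scan, supporting nested name paths like ``enc0.block1.conv.w``."""

    def __init__(self):
        self.training = True

    # -- discovery ----------------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- modes --------------------------------------------------------------
    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def requires_grad_(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    # -- serialisation ------------------------------------------------------
    def _named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value._named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{prefix}{name}{i}.")
        for bname in getattr(self, "_buffers", ()):
            yield prefix + bname, getattr(self, bname)

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state, strict=True):
        own_params = dict(self.named_parameters())
        own_bufs = dict(self._named_buffers())
        missing = (set(own_params) | set(own_bufs)) - set(state)
        if strict and missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for name, arr in state.items():
            if name in own_params:
                tgt = own_params[name].data
            elif name in own_bufs:
                tgt = own_bufs[name]
            elif strict:
                raise KeyError(f"unexpected key in state dict: {name}")
            else:
                continue
            if tgt.shape != np.shape(arr):
                raise ValueError(
                    f"shape mismatch for {name}: {tgt.shape} vs {np.shape(arr)}"
                )
            tgt[...] = arr
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter_hash(module: Module) -> str:
    """SHA-256 over all parameters and buffers in name order; used to assert
    freeze contracts during staged training."""
    h = hashlib.sha256()
    state = module.state_dict()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name]).tobytes())
    return h.hexdigest()


class Conv2d(Module):
    """Same-padding stride-1 convolution with He-normal initialisation."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, bias=True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.b = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Linear(Module):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.w = Parameter(rng.normal(0.0, std, (out_features, in_features)))
        self.b = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.w, self.b)


class ConvBlock(Module):
    """3x3 conv -> (batch norm) -> ReLU, the elementary encoder/decoder unit."""

    def __init__(self, in_channels, out_channels, rng, batch_norm=True):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng, bias=not batch_norm)
        self.bn = BatchNorm2d(out_channels) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return relu(x)
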