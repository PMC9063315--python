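"""Layer abstractions over the autodiff primitives.

Modules hold named :class:`Parameter` tensors and buffers (running
statistics), recurse through attributes for collection/serialization, and
carry a train/eval flag that batch normalization respects. Weight
initialization draws from a package-global generator reset via
:func:`manual_seed`, so model construction is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, as_tensor

__all__ = [
    "manual_seed",
    "Parameter",
    "Module",
    "Sequential",
    "Identity",
    "ReLU",
    "Sigmoid",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "MaxPool2d",
]

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the global weight-initialization generator."""
    global _RNG
    _RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad


class Module:
    def __init__(self):
        self.training = True

    # -- recursion ------------------------------------------------------------

    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for _, child in self.children():
            yield from child.modules()

    # -- mode / grad housekeeping ---------------------------------------------

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization --------------------------------------------------------

    def state_dict(self) -> dict:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: v.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(d)
        extra = set(d) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != d[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {d[k].shape}")
            p.data[...] = d[k]
        for k, b in bufs.items():
            b[...] = d[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = list(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return as_tensor(x).relu()


class Sigmoid(Module):
    def forward(self, x):
        return as_tensor(x).sigmoid()


class Conv2d(Module):
    """2-D convolution with He (fan-out) weight initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        k = kernel_size
        std = np.sqrt(2.0 / (out_ch * k * k))
        self.weight = Parameter(_RNG.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def children(self):
        return iter(())

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution; defaults double the spatial size (3x3, s2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3,
                 stride: int = 2, padding: int = 1, output_padding: int = 1,
                 bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        k = kernel_size
        std = np.sqrt(2.0 / (out_ch * k * k))
        self.weight = Parameter(_RNG.normal(0.0, std, size=(in_ch, out_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def children(self):
        return iter(())

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self.padding = padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)
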