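"""Neural-network layers built on the autograd core.

Conventions follow the common deep-learning toolkits: NCHW feature maps,
``Module`` objects holding named :class:`Parameter` leaves, recursive
``train``/``eval`` mode switching, and flat ``state_dict`` serialization.
Convolution weights use He-normal initialization; layers marked
``zero_init`` start at exactly zero so that residual branches are the
identity at initialization.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module", "Identity", "Linear", "Conv2d", "BatchNorm", "Sequential",
    "ReLU", "Sigmoid",
]


class Module:
    def __init__(self):
        self.training = True

    # parameter / submodule discovery ------------------------------------
    # attributes whose name starts with "_" are not traversed, so modules
    # can hold references to shared submodules without re-owning them
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Parameter):
                yield (prefix + name, value)
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # persistence ---------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Module):
                yield from value._named_buffers(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{prefix}{name}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield (prefix + name, value)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=np.float32).reshape(params[name].shape)
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name!r}")
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 groups: int = 1, zero_init: bool = False):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        w = np.zeros(shape) if zero_init else rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm(Module):
    """Batch normalization over (N,) or (N, H, W) statistics per channel.

    Works for both 2-d inputs (N, C) and 4-d feature maps (N, C, H, W).
    Running statistics are used in eval mode and carried across training
    phases, since the encoder is shared between them.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.update_stats = True

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 4:
            axes, shape = (0, 2, 3), (1, -1, 1, 1)
        else:
            axes, shape = (0,), (1, -1)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            if self.update_stats:
                m = self.momentum
                self.running_mean += m * (mean.data.reshape(-1) - self.running_mean)
                self.running_var += m * (var.data.reshape(-1) - self.running_var)
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class frozen_stats:
    """Context: run batch norm on batch statistics without touching the
    running estimates.  Used for auxiliary forward passes (destroyed or
    generated images) so inference statistics reflect real images only."""

    def __init__(self, *modules: Module):
        self._bns = [m for root in modules for m in root.modules()
                     if isinstance(m, BatchNorm)]

    def __enter__(self):
        self._saved = [bn.update_stats for bn in self._bns]
        for bn in self._bns:
            bn.update_stats = False
        return self

    def __exit__(self, *exc):
        for bn, saved in zip(self._bns, self._saved):
            bn.update_stats = saved
        return False


class Sequential(Module):
    def __init__(self, *blocks: Module):
        super().__init__()
        self.blocks = list(blocks)

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x
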