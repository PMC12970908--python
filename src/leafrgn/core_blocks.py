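"""Reusable building blocks of the encoder/decoder.

The encoder is assembled from four kinds of blocks:

* ``scale`` — a residual feature-extraction block whose branch is a grouped
  3x3 convolution, a channel shuffle to mix information across groups, and a
  1x1 convolution (pre-activation order: norm -> ReLU -> conv).
* ``SENet`` — squeeze-and-excitation channel attention: global average pool,
  bottleneck MLP, sigmoid gate, per-channel rescaling.
* ``downsample`` — stride-2 average pooling followed by a grouped 3x3
  convolution that doubles the channel count (plus a channel shuffle).
* ``scale_fc`` — the fully connected analogue of ``scale`` applied to
  pooled feature vectors.

The final convolution/linear layer of every residual branch is
zero-initialized, so each block is exactly the identity at initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm, Conv2d, Linear, Module, Tensor


@dataclass(frozen=True)
class FeatureMapSpec:
    """Shape of a square feature map at some stage of the encoder."""

    height: int
    width: int
    channels: int

    def __post_init__(self):
        if min(self.height, self.width, self.channels) <= 0:
            raise ValueError("all dimensions must be strictly positive")
        if self.height != self.width:
            raise ValueError("encoder feature maps are square")


@dataclass(frozen=True)
class BlockConfig:
    """Shared block hyper-parameters.

    groups: number of groups in grouped 3x3 convolutions.
    se_reduction: bottleneck ratio of the squeeze-and-excitation gate.
    stage_widths: channel counts of the stem and each stage; must double.
    """

    groups: int = 4
    se_reduction: int = 16
    stage_widths: tuple = (16, 32, 64, 128, 256)

    def __post_init__(self):
        for a, b in zip(self.stage_widths, self.stage_widths[1:]):
            if b != 2 * a:
                raise ValueError("stage widths must strictly double")


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Rearrange channels by the group-transpose permutation.

    Channels are viewed as a (groups, C/groups) grid, transposed and
    flattened, so that information produced by separate convolution groups
    is interleaved. ``groups=1`` is the identity.
    """
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels ({c}) not divisible by groups ({groups})")
    return (x.reshape(n, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The permutation pi with output[c] = input[pi[c]] of channel_shuffle."""
    return np.arange(channels).reshape(groups, -1).T.reshape(-1)


class SEAttention(Module):
    """Squeeze-and-excitation channel gate; preserves the input shape."""

    def __init__(self, channels: int, se_reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels < se_reduction:
            raise ValueError(
                f"channels ({channels}) must be >= se_reduction ({se_reduction})")
        hidden = max(1, channels // se_reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        squeeze = x.mean(axis=(2, 3))                     # global average pool
        gate = self.fc2(self.fc1(squeeze).relu()).sigmoid()
        return x * gate.reshape(n, c, 1, 1)


class ScaleBlock(Module):
    """Residual block: x + conv1x1(shuffle(gconv3x3(relu(bn(x)))))."""

    def __init__(self, channels: int, groups: int, rng: np.random.Generator):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels ({channels}) not divisible by groups ({groups})")
        self.bn1 = BatchNorm(channels)
        self.gconv = Conv2d(channels, channels, 3, rng, padding=1, groups=groups)
        self.bn2 = BatchNorm(channels)
        self.proj = Conv2d(channels, channels, 1, rng, zero_init=True)
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        h = self.gconv(self.bn1(x).relu())
        h = channel_shuffle(h, self.groups)
        h = self.proj(self.bn2(h).relu())
        return x + h


class DownsampleBlock(Module):
    """Halve the spatial side, double the channels.

    Average pooling with stride 2 reduces the map quickly; the grouped 3x3
    convolution (followed by a channel shuffle) doubles the channel count.
    """

    def __init__(self, in_channels: int, groups: int, rng: np.random.Generator):
        super().__init__()
        self.bn = BatchNorm(in_channels)
        self.conv = Conv2d(in_channels, 2 * in_channels, 3, rng, padding=1, groups=groups)
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        side = x.shape[2]
        if side % 2:
            raise ValueError(f"spatial side ({side}) must be even to downsample")
        h = x.avg_pool2d(2)
        h = self.conv(self.bn(h).relu())
        return channel_shuffle(h, self.groups)


class ScaleFC(Module):
    """Residual fully connected block on feature vectors: x + branch(x)."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.bn = BatchNorm(width)
        self.fc1 = Linear(width, width, rng)
        self.fc2 = Linear(width, width, rng, zero_init=True)
        self.width = width

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.width:
            raise ValueError(f"expected vectors of length {self.width}, got {x.shape[-1]}")
        return x + self.fc2(self.fc1(self.bn(x)).relu())
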