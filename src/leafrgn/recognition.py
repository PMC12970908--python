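"""The recognition model: encoder with channel attention, latent head and
classifier.

The encoder maps a normalized square RGB image to a diagonal-Gaussian
latent (a mean vector and a log-variance vector, both of the latent
dimension).  During training the classifier consumes a reparameterized
sample ``z = mu + sigma * eps``; at inference the sample is replaced by
``mu`` exactly, so repeated predictions are identical.

With the default configuration (input 128x128x3, stem width 16, four
stages) the stage shapes are::

    conv      128x128x3  -> 128x128x16
    stage s   halves the side, doubles the channels
    final     8x8x256 -> global mean -> 256 -> scale_fc -> two FC heads

A "tiny" configuration (side 32, stem width 8, three stages, latent 64) is
provided for fast experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_blocks import (BlockConfig, DownsampleBlock, ScaleBlock, ScaleFC,
                          SEAttention)
from .nn import Conv2d, Identity, Linear, Module, Tensor


@dataclass(frozen=True)
class LatentGaussian:
    """Diagonal Gaussian over the latent space: per-sample mu and log-var."""

    mu: Tensor
    log_var: Tensor

    def __post_init__(self):
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have equal shapes")


@dataclass(frozen=True)
class ClassPrediction:
    probs: np.ndarray          # (n, C), rows sum to 1
    label: np.ndarray          # (n,) argmax indices


@dataclass(frozen=True)
class EncoderConfig:
    input_side: int = 128
    input_channels: int = 3
    stem_width: int = 16
    num_stages: int = 4
    num_classes: int = 38
    groups: int = 4
    se_reduction: int = 16

    @property
    def latent_dim(self) -> int:
        return self.stem_width * 2 ** self.num_stages

    @property
    def stage_widths(self) -> tuple:
        return tuple(self.stem_width * 2 ** i for i in range(self.num_stages + 1))

    def __post_init__(self):
        if self.input_side % 2 ** self.num_stages:
            raise ValueError("input side must be divisible by 2**num_stages")

    @property
    def block_config(self) -> BlockConfig:
        return BlockConfig(self.groups, self.se_reduction, self.stage_widths)


def tiny_config(num_classes: int = 4) -> EncoderConfig:
    """32x32 input, stem width 8, three stages, latent dimension 64."""
    return EncoderConfig(input_side=32, stem_width=8, num_stages=3,
                         num_classes=num_classes, se_reduction=8)


class Encoder(Module):
    """Image -> LatentGaussian, with a recordable per-layer forward trace."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 use_attention: bool = True):
        super().__init__()
        self.cfg = cfg
        g, r = cfg.groups, cfg.se_reduction
        self.stem = Conv2d(cfg.input_channels, cfg.stem_width, 3, rng, padding=1)
        self.stages = []
        for w in cfg.stage_widths[:-1]:
            self.stages.append(ScaleBlock(w, g, rng))
            self.stages.append(SEAttention(w, r, rng) if use_attention else Identity())
            self.stages.append(DownsampleBlock(w, g, rng))
        final = cfg.stage_widths[-1]
        self.final_scale = ScaleBlock(final, g, rng)
        self.final_se = SEAttention(final, r, rng) if use_attention else Identity()
        self.scale_fc = ScaleFC(final, rng)
        self.fc_mu = Linear(final, final, rng)
        self.fc_log_var = Linear(final, final, rng)

    def _layer_sequence(self):
        yield "conv", self.stem
        n = self.cfg.num_stages
        for i in range(n):
            yield f"scale-{i + 1}", self.stages[3 * i]
            yield f"SENet-{i + 1}", self.stages[3 * i + 1]
            yield f"downsample-{i + 1}", self.stages[3 * i + 2]
        yield "scale", self.final_scale
        yield "SENet", self.final_se

    def features(self, x: Tensor, trace: list | None = None) -> Tensor:
        """The pooled trunk feature (input to the mu / log-var heads)."""
        cfg = self.cfg
        expected = (cfg.input_channels, cfg.input_side, cfg.input_side)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(f"expected input of shape (n, {expected}), got {x.shape}")
        for name, layer in self._layer_sequence():
            x = layer(x)
            if trace is not None:
                trace.append((name, x.shape[1:]))
        x = x.mean(axis=(2, 3))                       # reduce_mean
        if trace is not None:
            trace.append(("reduce_mean", x.shape[1:]))
        x = self.scale_fc(x)
        if trace is not None:
            trace.append(("scale_fc", x.shape[1:]))
        return x

    def forward(self, x: Tensor, trace: list | None = None) -> LatentGaussian:
        h = self.features(x, trace)
        mu = self.fc_mu(h)
        log_var = self.fc_log_var(h)
        if trace is not None:
            trace.append(("FC", mu.shape[1:]))
        return LatentGaussian(mu=mu, log_var=log_var)


def reparameterize(lg: LatentGaussian, mode: str = "train",
                   rng: np.random.Generator | None = None) -> Tensor:
    """Sample z = mu + exp(log_var / 2) * eps in train mode; z = mu at inference."""
    if mode == "inference":
        return lg.mu
    if mode != "train":
        raise ValueError(f"mode must be 'train' or 'inference', got {mode!r}")
    if rng is None:
        raise ValueError("train-mode reparameterization needs a random generator")
    eps = rng.standard_normal(lg.mu.shape).astype(np.float32)
    return lg.mu + (lg.log_var * 0.5).exp() * Tensor(eps)


class Classifier(Module):
    """Latent vector -> class probabilities: scale_fc -> FC -> softmax."""

    def __init__(self, latent_dim: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        self.scale_fc = ScaleFC(latent_dim, rng)
        self.fc = Linear(latent_dim, num_classes, rng)

    def logits(self, z: Tensor) -> Tensor:
        return self.fc(self.scale_fc(z))

    def forward(self, z: Tensor) -> ClassPrediction:
        probs = self.logits(z).softmax(axis=-1)
        return ClassPrediction(probs=probs, label=probs.argmax(axis=-1))


class RecognitionModel(Module):
    """Inference-time model: encoder -> mu -> classifier. No sampling noise."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | int = 0,
                 use_attention: bool = True):
        super().__init__()
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng, use_attention=use_attention)
        self.classifier = Classifier(cfg.latent_dim, cfg.num_classes, rng)

    def forward(self, x: Tensor) -> ClassPrediction:
        lg = self.encoder(x)
        return self.classifier(reparameterize(lg, mode="inference"))

    def predict(self, images: np.ndarray) -> ClassPrediction:
        """Classify a batch of channels-last images in [0, 1]."""
        was_training = self.training
        self.eval()
        x = Tensor(np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32))
        pred = self.forward(x)
        if was_training:
            self.train()
        return pred
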