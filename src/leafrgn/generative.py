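"""Generative and discriminative satellites attached to the encoder during
training: the VAE decoder, the generation network that restores destroyed
images, the real/fake discriminator head, the region-alignment head, and
their losses.  None of these participate at inference time.

The decoder maps the latent vector through a fully connected layer to a
2x2 seed map and doubles the side with nearest-neighbour upsampling + 3x3
convolution until the output side is reached (2 * 2**6 = 128 for the full
configuration), halving channels down to a floor of 32, then projects to 3
channels with a sigmoid so reconstructions live in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_blocks import ScaleBlock, ScaleFC
from .nn import BatchNorm, Conv2d, Linear, Module, Tensor
from .recognition import Encoder, LatentGaussian, reparameterize


@dataclass(frozen=True)
class DecoderConfig:
    latent_dim: int = 256
    seed_side: int = 2
    seed_channels: int = 1024
    output_side: int = 128
    output_channels: int = 3
    min_width: int = 32
    groups: int = 4

    def __post_init__(self):
        n = self.num_upsample_stages
        if self.seed_side * 2 ** n != self.output_side:
            raise ValueError("output side must be seed side times a power of two")

    @property
    def fc_width(self) -> int:
        return self.seed_side * self.seed_side * self.seed_channels

    @property
    def num_upsample_stages(self) -> int:
        return int(round(math.log2(self.output_side / self.seed_side)))


def tiny_decoder_config() -> DecoderConfig:
    """Companion of the tiny encoder: latent 64, seed 2x2x256, output 32."""
    return DecoderConfig(latent_dim=64, seed_channels=256, output_side=32)


class Decoder(Module):
    """Latent vector -> reconstructed image (NCHW, values in [0, 1])."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.fc = Linear(cfg.latent_dim, cfg.fc_width, rng)
        widths = [cfg.seed_channels]
        for _ in range(cfg.num_upsample_stages):
            widths.append(max(cfg.min_width, widths[-1] // 2))
        self.up_convs = []
        self.up_bns = []
        for w_in, w_out in zip(widths, widths[1:]):
            self.up_convs.append(Conv2d(w_in, w_out, 3, rng, padding=1))
            self.up_bns.append(BatchNorm(w_out))
        self.scale = ScaleBlock(widths[-1], cfg.groups, rng)
        self.out_conv = Conv2d(widths[-1], cfg.output_channels, 3, rng, padding=1)

    def forward(self, z: Tensor) -> Tensor:
        cfg = self.cfg
        if z.shape[-1] != cfg.latent_dim:
            raise ValueError(f"expected latents of length {cfg.latent_dim}, got {z.shape[-1]}")
        h = self.fc(z).reshape(z.shape[0], cfg.seed_channels, cfg.seed_side, cfg.seed_side)
        for conv, bn in zip(self.up_convs, self.up_bns):
            h = bn(conv(h.upsample2x())).relu()
        h = self.scale(h)
        return self.out_conv(h).sigmoid()


def kl_divergence(lg: LatentGaussian) -> Tensor:
    """KL(q(z|x) || N(0, I)), summed over latent dims, averaged over batch."""
    per_dim = -0.5 * (1.0 + lg.log_var - lg.mu ** 2 - lg.log_var.exp())
    return per_dim.sum(axis=-1).mean()


def vae_loss(x: Tensor, x_hat: Tensor, lg: LatentGaussian, beta: float = 1.0):
    """(reconstruction MSE, KL term, total = recon + beta * KL)."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    recon = ((x - x_hat) ** 2).mean()
    kl = kl_divergence(lg)
    return recon, kl, recon + beta * kl


class GenerationNetwork(Module):
    """Restores a destroyed image: shared encoder -> independent decoder head.

    The encoder (with its attention blocks) is shared with the recognition
    model, so gradients from the restoration task reach the classifier's
    features; the image-producing head has the decoder topology but its own
    weights.
    """

    def __init__(self, encoder: Encoder, decoder_cfg: DecoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self._encoder = [encoder]          # list: shared, not re-registered
        self.head = Decoder(decoder_cfg, rng)

    @property
    def encoder(self) -> Encoder:
        return self._encoder[0]

    def forward(self, destroyed: Tensor) -> Tensor:
        lg = self.encoder(destroyed)
        return self.head(reparameterize(lg, mode="inference"))


class Discriminator(Module):
    """Real/fake head on the shared encoder's pooled features.

    A residual fully connected block followed by a 2-unit linear layer;
    index 1 is the "real" class, index 0 "fake".
    """

    def __init__(self, encoder: Encoder, rng: np.random.Generator):
        super().__init__()
        self._encoder = [encoder]
        latent = encoder.cfg.latent_dim
        self.scale_fc = ScaleFC(latent, rng)
        self.fc = Linear(latent, 2, rng)

    @property
    def encoder(self) -> Encoder:
        return self._encoder[0]

    def forward(self, image: Tensor, detach_features: bool = False) -> Tensor:
        h = self.encoder.features(image)
        if detach_features:
            h = h.detach()
        return self.fc(self.scale_fc(h))


class AlignmentHead(Module):
    """Predicts each grid slot's original normalized (row, col) coordinates."""

    def __init__(self, encoder: Encoder, N: int, rng: np.random.Generator):
        super().__init__()
        self._encoder = [encoder]
        latent = encoder.cfg.latent_dim
        self.scale_fc = ScaleFC(latent, rng)
        self.fc = Linear(latent, 2 * N * N, rng)
        self.N = N

    @property
    def encoder(self) -> Encoder:
        return self._encoder[0]

    def forward(self, destroyed: Tensor) -> Tensor:
        h = self.encoder.features(destroyed)
        coords = self.fc(self.scale_fc(h)).sigmoid()
        return coords.reshape(destroyed.shape[0], self.N, self.N, 2)


REAL, FAKE = 1, 0


def adversarial_losses(real_scores: Tensor, fake_scores: Tensor):
    """(d_loss, g_loss) from two-class cross-entropy.

    d_loss is the mean of the per-sample cross-entropies of real images
    against the real label and fakes against the fake label; g_loss is the
    non-saturating generator objective (fakes scored against the real
    label).  At indifference (all probabilities 0.5) the per-sample d_loss
    is ln 2.
    """
    n_real = real_scores.shape[0]
    n_fake = fake_scores.shape[0]
    d_real = real_scores.cross_entropy(np.full(n_real, REAL, dtype=np.int64))
    d_fake = fake_scores.cross_entropy(np.full(n_fake, FAKE, dtype=np.int64))
    d_loss = 0.5 * (d_real + d_fake)
    g_loss = fake_scores.cross_entropy(np.full(n_fake, REAL, dtype=np.int64))
    return d_loss, g_loss
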