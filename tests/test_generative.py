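"""Tests of the decoder, VAE losses, generator, discriminator and
adversarial objectives."""

import numpy as np
import pytest

from leafrgn.generative import (AlignmentHead, Decoder, DecoderConfig,
                                Discriminator, GenerationNetwork,
                                adversarial_losses, kl_divergence,
                                tiny_decoder_config, vae_loss)
from leafrgn.nn import Tensor
from leafrgn.recognition import Encoder, LatentGaussian, tiny_config


@pytest.fixture(scope="module")
def tiny_encoder():
    return Encoder(tiny_config(4), np.random.default_rng(1))


class TestDecoder:
    def test_full_size_shape_and_range(self, rng):
        cfg = DecoderConfig()
        assert cfg.fc_width == 4096
        assert cfg.num_upsample_stages == 6      # 2 * 2**6 = 128
        dec = Decoder(cfg, np.random.default_rng(0))
        dec.eval()
        out = dec(Tensor(rng.normal(size=(1, 256)).astype("f4")))
        assert out.shape == (1, 3, 128, 128)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_tiny_shape_and_determinism(self, rng):
        dec = Decoder(tiny_decoder_config(), np.random.default_rng(0))
        dec.eval()
        z = Tensor(rng.normal(size=(2, 64)).astype("f4"))
        out1, out2 = dec(z), dec(z)
        assert out1.shape == (2, 3, 32, 32)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_wrong_latent_length(self, rng):
        dec = Decoder(tiny_decoder_config(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="latents"):
            dec(Tensor(rng.normal(size=(1, 32)).astype("f4")))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            DecoderConfig(output_side=96)

    def test_encoder_decoder_shape_duality(self, tiny_encoder, rng):
        """decode(mu(x)) has x's shape."""
        tiny_encoder.eval()
        dec = Decoder(tiny_decoder_config(), np.random.default_rng(0))
        dec.eval()
        x = Tensor(rng.uniform(size=(2, 3, 32, 32)).astype("f4"))
        out = dec(tiny_encoder(x).mu)
        assert out.shape == x.shape


class TestVaeLoss:
    def test_kl_closed_forms(self):
        zero = LatentGaussian(mu=Tensor(np.zeros((1, 1), dtype="f4")),
                              log_var=Tensor(np.zeros((1, 1), dtype="f4")))
        assert float(kl_divergence(zero).data) == pytest.approx(0.0, abs=1e-7)
        unit_mean = LatentGaussian(mu=Tensor(np.ones((1, 1), dtype="f4")),
                                   log_var=Tensor(np.zeros((1, 1), dtype="f4")))
        assert float(kl_divergence(unit_mean).data) == pytest.approx(0.5, rel=1e-6)

    def test_kl_invariant_under_latent_permutation(self, rng):
        mu = rng.normal(size=(3, 8)).astype("f4")
        lv = rng.normal(size=(3, 8)).astype("f4")
        perm = rng.permutation(8)
        a = kl_divergence(LatentGaussian(Tensor(mu), Tensor(lv)))
        b = kl_divergence(LatentGaussian(Tensor(mu[:, perm]), Tensor(lv[:, perm])))
        assert float(a.data) == pytest.approx(float(b.data), rel=1e-6)

    def test_perfect_reconstruction_and_total(self, rng):
        x = Tensor(rng.uniform(size=(2, 3, 8, 8)).astype("f4"))
        lg = LatentGaussian(mu=Tensor(rng.normal(size=(2, 4)).astype("f4")),
                            log_var=Tensor(np.zeros((2, 4), dtype="f4")))
        recon, kl, total = vae_loss(x, x, lg, beta=0.5)
        assert float(recon.data) == 0.0
        assert float(total.data) == pytest.approx(0.5 * float(kl.data), rel=1e-6)
        assert float(kl.data) >= 0.0

    def test_recon_invariant_under_shared_pixel_permutation(self, rng):
        x = rng.uniform(size=(1, 3, 4, 4)).astype("f4")
        y = rng.uniform(size=(1, 3, 4, 4)).astype("f4")
        lg = LatentGaussian(mu=Tensor(np.zeros((1, 2), dtype="f4")),
                            log_var=Tensor(np.zeros((1, 2), dtype="f4")))
        perm = rng.permutation(16)
        xp = x.reshape(1, 3, 16)[:, :, perm].reshape(1, 3, 4, 4)
        yp = y.reshape(1, 3, 16)[:, :, perm].reshape(1, 3, 4, 4)
        r1, _, _ = vae_loss(Tensor(x), Tensor(y), lg)
        r2, _, _ = vae_loss(Tensor(xp), Tensor(yp), lg)
        assert float(r1.data) == pytest.approx(float(r2.data), rel=1e-6)

    def test_shape_mismatch(self, rng):
        lg = LatentGaussian(mu=Tensor(np.zeros((1, 2), dtype="f4")),
                            log_var=Tensor(np.zeros((1, 2), dtype="f4")))
        with pytest.raises(ValueError, match="mismatch"):
            vae_loss(Tensor(np.zeros((1, 3, 4, 4), dtype="f4")),
                     Tensor(np.zeros((1, 3, 8, 8), dtype="f4")), lg)


class TestGenerationNetwork:
    def test_restores_image_shape_deterministically(self, tiny_encoder, rng):
        gen = GenerationNetwork(tiny_encoder, tiny_decoder_config(),
                                np.random.default_rng(2))
        gen.eval()
        tiny_encoder.eval()
        x = Tensor(rng.uniform(size=(2, 3, 32, 32)).astype("f4"))
        out1, out2 = gen(x), gen(x)
        assert out1.shape == (2, 3, 32, 32)
        assert out1.data.min() >= 0.0 and out1.data.max() <= 1.0
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_gradient_reaches_shared_encoder(self, tiny_encoder, rng):
        gen = GenerationNetwork(tiny_encoder, tiny_decoder_config(),
                                np.random.default_rng(2))
        x = Tensor(rng.uniform(size=(1, 3, 32, 32)).astype("f4"))
        loss = (gen(x) ** 2).mean()
        for p in tiny_encoder.parameters():
            p.grad = None
        loss.backward()
        assert tiny_encoder.stem.weight.grad is not None

    def test_head_parameters_are_private(self, tiny_encoder):
        gen = GenerationNetwork(tiny_encoder, tiny_decoder_config(),
                                np.random.default_rng(2))
        encoder_ids = {id(p) for p in tiny_encoder.parameters()}
        assert all(id(p) not in encoder_ids for p in gen.parameters())


class TestDiscriminator:
    def test_two_scores_summing_softmax(self, tiny_encoder, rng):
        disc = Discriminator(tiny_encoder, np.random.default_rng(3))
        disc.eval()
        tiny_encoder.eval()
        scores = disc(Tensor(rng.uniform(size=(3, 3, 32, 32)).astype("f4")))
        assert scores.shape == (3, 2)
        np.testing.assert_allclose(scores.softmax(-1).sum(axis=1), 1.0, atol=1e-6)
        scores2 = disc(Tensor(scores.data * 0 + 0.5) if False else
                       Tensor(rng.uniform(size=(3, 3, 32, 32)).astype("f4")))
        assert scores2.shape == (3, 2)

    def test_detached_features_block_encoder_gradients(self, tiny_encoder, rng):
        disc = Discriminator(tiny_encoder, np.random.default_rng(3))
        x = Tensor(rng.uniform(size=(2, 3, 32, 32)).astype("f4"))
        for p in tiny_encoder.parameters():
            p.grad = None
        loss = (disc(x, detach_features=True) ** 2).mean()
        loss.backward()
        assert tiny_encoder.stem.weight.grad is None
        assert disc.fc.weight.grad is not None


class TestAdversarialLosses:
    def _scores(self, p_real):
        # logits whose softmax gives (1 - p_real, p_real)
        logit = np.log(p_real / (1 - p_real))
        return Tensor(np.array([[0.0, logit]], dtype="f4"))

    def test_perfect_separation_drives_d_loss_to_zero(self):
        d_loss, _ = adversarial_losses(self._scores(1 - 1e-7), self._scores(1e-7))
        assert float(d_loss.data) < 1e-4

    def test_fooled_discriminator_drives_g_loss_to_zero(self):
        _, g_loss = adversarial_losses(self._scores(0.5), self._scores(1 - 1e-7))
        assert float(g_loss.data) < 1e-4

    def test_indifference_gives_ln2(self):
        d_loss, g_loss = adversarial_losses(self._scores(0.5), self._scores(0.5))
        assert float(d_loss.data) == pytest.approx(np.log(2), rel=1e-5)
        assert float(g_loss.data) == pytest.approx(np.log(2), rel=1e-5)

    def test_losses_non_negative(self, rng):
        real = Tensor(rng.normal(size=(5, 2)).astype("f4"))
        fake = Tensor(rng.normal(size=(5, 2)).astype("f4"))
        d_loss, g_loss = adversarial_losses(real, fake)
        assert float(d_loss.data) >= 0.0 and float(g_loss.data) >= 0.0


def test_alignment_head_output_geometry(tiny_encoder, rng):
    head = AlignmentHead(tiny_encoder, N=8, rng=np.random.default_rng(4))
    head.eval()
    tiny_encoder.eval()
    out = head(Tensor(rng.uniform(size=(2, 3, 32, 32)).astype("f4")))
    assert out.shape == (2, 8, 8, 2)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
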