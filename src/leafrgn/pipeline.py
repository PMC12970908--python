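"""Three-phase training scheme.

1. VAE phase: encoder + decoder trained on the whole pool (labels ignored),
   so unlabeled images contribute to representation learning.
2. RGN phase: supervised training on the labeled pool.  Each step draws a
   minibatch, destroys half of it with the region confusion mechanism, and
   combines a classification loss on the originals, an adversarial loss
   (originals real, restored-from-destroyed fake), a region-alignment loss
   on the destroyed images, and optionally the VAE reconstruction/KL terms.
   A validation pass runs every ``validate_every_images`` training images
   and the best-accuracy checkpoint is retained.
3. Export: the recognition branch (encoder + attention + classifier) is
   extracted as a standalone inference model; all generative satellites are
   dropped.

Training uses momentum SGD throughout and is bit-reproducible for a fixed
seed on a single device.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import rcm
from .generative import (AlignmentHead, Decoder, DecoderConfig, Discriminator,
                         GenerationNetwork, adversarial_losses, vae_loss)
from .nn import SGD, Module, Tensor, frozen_stats
from .recognition import (Classifier, Encoder, EncoderConfig, RecognitionModel,
                          reparameterize)

__all__ = ["TrainConfig", "TrainLog", "RGNModel", "train_vae_phase",
           "train_rgn_phase", "evaluate_accuracy", "export_inference",
           "ablation_suite", "save_model", "load_model"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 10
    validate_every_images: int = 4096
    loss_weights: dict = field(default_factory=lambda: {
        "cls": 1.0, "recon": 1.0, "kl": 1.0, "adv": 1.0, "align": 1.0})
    N: int = 8
    k: int = 2
    seed: int = 0
    beta: float = 1.0
    destroyed_fraction: float = 0.5
    classify_destroyed: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.validate_every_images % self.batch_size:
            raise ValueError("validate_every_images must be a multiple of batch_size")
        if any(w < 0 for w in self.loss_weights.values()):
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainLog:
    steps: list = field(default_factory=list)          # per-step loss dicts
    validations: list = field(default_factory=list)    # (step, images_seen, accuracy)
    best_accuracy: float = -1.0
    best_step: int | None = None

    def record_validation(self, step: int, images_seen: int, accuracy: float) -> bool:
        """Append a validation point; True if this is a new (strict) best."""
        self.validations.append((step, images_seen, accuracy))
        if accuracy > self.best_accuracy:       # ties keep the earlier checkpoint
            self.best_accuracy = accuracy
            self.best_step = step
            return True
        return False


class RGNModel(Module):
    """The full training-time model: recognition branch plus satellites."""

    def __init__(self, cfg: EncoderConfig, N: int = 8, seed: int = 0,
                 use_attention: bool = True):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.N = N
        self.encoder = Encoder(cfg, rng, use_attention=use_attention)
        self.classifier = Classifier(cfg.latent_dim, cfg.num_classes, rng)
        dec_cfg = DecoderConfig(latent_dim=cfg.latent_dim,
                                seed_channels=4 * cfg.latent_dim,
                                output_side=cfg.input_side,
                                output_channels=cfg.input_channels,
                                groups=cfg.groups)
        self.decoder = Decoder(dec_cfg, rng)
        self.generator = GenerationNetwork(self.encoder, dec_cfg, rng)
        self.discriminator = Discriminator(self.encoder, rng)
        self.align_head = AlignmentHead(self.encoder, N, rng)

    # parameter groups ----------------------------------------------------
    def recognition_parameters(self):
        return self.encoder.parameters() + self.classifier.parameters()

    def main_parameters(self):
        """Everything except the discriminator head (updated on its own step)."""
        return (self.recognition_parameters() + self.decoder.parameters()
                + self.generator.parameters() + self.align_head.parameters())

    def discriminator_parameters(self):
        return self.discriminator.parameters()

    def predict(self, images: np.ndarray):
        """Inference: encoder -> mu -> classifier, channels-last input."""
        was_training = self.training
        self.eval()
        lg = self.encoder(_to_nchw(images))
        pred = self.classifier(reparameterize(lg, mode="inference"))
        if was_training:
            self.train()
        return pred


def _to_nchw(images: np.ndarray) -> Tensor:
    return Tensor(np.ascontiguousarray(
        np.asarray(images, dtype=np.float32).transpose(0, 3, 1, 2)))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_vae_phase(images: np.ndarray, cfg: TrainConfig, model: RGNModel,
                    epochs: int | None = None) -> TrainLog:
    """Unsupervised VAE training of encoder + decoder on the whole pool."""
    if len(images) == 0:
        raise ValueError("empty image pool")
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    params = model.encoder.parameters() + model.decoder.parameters()
    opt = SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)
    log = TrainLog()
    model.train()
    step = 0
    for _ in range(epochs):
        for idx in _batches(len(images), cfg.batch_size, rng):
            x = _to_nchw(images[idx])
            lg = model.encoder(x)
            z = reparameterize(lg, mode="train", rng=rng)
            x_hat = model.decoder(z)
            recon, kl, total = vae_loss(x, x_hat, lg, beta=cfg.beta)
            opt.zero_grad()
            total.backward()
            opt.step()
            log.steps.append({"step": step, "recon": float(recon.data),
                              "kl": float(kl.data), "total": float(total.data)})
            step += 1
    return log


def evaluate_accuracy(model, images: np.ndarray, labels: np.ndarray,
                      batch_size: int = 32) -> float:
    correct = 0
    for start in range(0, len(images), batch_size):
        pred = model.predict(images[start:start + batch_size])
        correct += int((pred.label == labels[start:start + batch_size]).sum())
    return correct / len(images)


def _destroy_batch(x: np.ndarray, N: int, k: int, rng: np.random.Generator):
    """Destroy each image with its own permutation; returns (images, targets)."""
    destroyed = np.empty_like(x)
    targets = np.empty((len(x), N, N, 2), dtype=np.float32)
    for i in range(len(x)):
        perm = rcm.make_permutation(N, k, rng)
        destroyed[i] = rcm.destroy(x[i], perm)
        targets[i] = rcm.alignment_targets(perm)
    return destroyed, targets


def train_rgn_phase(train_images: np.ndarray, train_labels: np.ndarray,
                    val_images: np.ndarray, val_labels: np.ndarray,
                    cfg: TrainConfig, model: RGNModel,
                    epochs: int | None = None) -> TrainLog:
    """Supervised phase with destruction-generation-discrimination."""
    if len(train_images) == 0:
        raise ValueError("empty labeled training set")
    if len(val_images) == 0:
        raise ValueError("missing validation set")
    epochs = cfg.epochs if epochs is None else epochs
    w = cfg.loss_weights
    use_rcm = w.get("adv", 0) > 0 or w.get("align", 0) > 0 or cfg.classify_destroyed
    rng = np.random.default_rng(cfg.seed + 1)
    opt_main = SGD(model.main_parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    opt_disc = SGD(model.discriminator_parameters(), lr=cfg.learning_rate,
                   momentum=cfg.momentum)
    log = TrainLog()
    best_state = None
    step = 0
    images_seen = 0
    next_validation = cfg.validate_every_images
    model.train()
    for _ in range(epochs):
        for idx in _batches(len(train_images), cfg.batch_size, rng):
            x_np = train_images[idx]
            y = train_labels[idx]
            x = _to_nchw(x_np)
            entry = {"step": step}

            destroyed = None
            if use_rcm:
                n_destroy = max(1, int(round(cfg.destroyed_fraction * len(idx))))
                d_np, targets = _destroy_batch(x_np[:n_destroy], cfg.N, cfg.k, rng)
                destroyed = _to_nchw(d_np)

            # discriminator step: originals real, restored fakes fake;
            # encoder features detached so only the head moves
            generated = None
            if w.get("adv", 0) > 0:
                # encoder running stats must reflect real images only, so
                # auxiliary passes run on batch statistics without updating
                with frozen_stats(model.encoder):
                    generated = model.generator(destroyed)
                    real_scores = model.discriminator(x, detach_features=True)
                    fake_scores = model.discriminator(
                        Tensor(generated.data), detach_features=True)
                d_loss, _ = adversarial_losses(real_scores, fake_scores)
                opt_disc.zero_grad()
                opt_main.zero_grad()
                d_loss.backward()
                opt_disc.step()
                entry["d_loss"] = float(d_loss.data)

            # main step: classification + generation-side losses
            opt_main.zero_grad()
            opt_disc.zero_grad()
            lg = model.encoder(x)
            z = reparameterize(lg, mode="train", rng=rng)
            total = None

            def add(term, weight):
                nonlocal total
                term = weight * term
                total = term if total is None else total + term

            cls_loss = model.classifier.logits(z).cross_entropy(y)
            entry["cls"] = float(cls_loss.data)
            add(cls_loss, w.get("cls", 1.0))

            if cfg.classify_destroyed and destroyed is not None:
                with frozen_stats(model.encoder):
                    lg_d = model.encoder(destroyed)
                z_d = reparameterize(lg_d, mode="train", rng=rng)
                cls_d = model.classifier.logits(z_d).cross_entropy(y[:destroyed.shape[0]])
                entry["cls_destroyed"] = float(cls_d.data)
                add(cls_d, w.get("cls", 1.0))

            if w.get("recon", 0) > 0 or w.get("kl", 0) > 0:
                x_hat = model.decoder(z)
                recon, kl, _ = vae_loss(x, x_hat, lg, beta=cfg.beta)
                entry["recon"] = float(recon.data)
                entry["kl"] = float(kl.data)
                add(recon, w.get("recon", 0.0))
                add(kl, w.get("kl", 0.0))

            if w.get("adv", 0) > 0:
                # non-saturating generator objective: fakes scored as real
                with frozen_stats(model.encoder):
                    fake_scores = model.discriminator(generated)
                g_loss = fake_scores.cross_entropy(
                    np.ones(fake_scores.shape[0], dtype=np.int64))
                entry["g_loss"] = float(g_loss.data)
                add(g_loss, w.get("adv", 0.0))

            if w.get("align", 0) > 0 and destroyed is not None:
                with frozen_stats(model.encoder):
                    coords = model.align_head(destroyed)
                align = (coords - Tensor(targets)).abs().mean()
                entry["align"] = float(align.data)
                add(align, w.get("align", 0.0))

            total.backward()
            opt_main.step()
            entry["total"] = float(total.data)
            log.steps.append(entry)
            step += 1
            images_seen += len(idx)

            if images_seen >= next_validation:
                next_validation += cfg.validate_every_images
                acc = evaluate_accuracy(model, val_images, val_labels, cfg.batch_size)
                model.train()
                if log.record_validation(step, images_seen, acc):
                    best_state = copy.deepcopy(model.state_dict())

    # final validation so short runs still retain a checkpoint
    acc = evaluate_accuracy(model, val_images, val_labels, cfg.batch_size)
    model.train()
    if log.record_validation(step, images_seen, acc):
        best_state = copy.deepcopy(model.state_dict())
    if best_state is not None:
        model.load_state_dict(best_state)
    return log


def export_inference(model: RGNModel, use_attention: bool = True) -> RecognitionModel:
    """Extract the recognition-only model (encoder + attention + classifier)."""
    out = RecognitionModel(model.cfg, rng=0, use_attention=use_attention)
    out.encoder.load_state_dict(model.encoder.state_dict())
    out.classifier.load_state_dict(model.classifier.state_dict())
    out.eval()
    return out


# ---------------------------------------------------------------------------
# serialization: npz parameter archive with a JSON metadata header
# ---------------------------------------------------------------------------

def save_model(path, model: Module, metadata: dict | None = None):
    meta = dict(metadata or {})
    if hasattr(model, "cfg"):
        cfg = model.cfg
        meta.setdefault("encoder_config", {
            "input_side": cfg.input_side, "input_channels": cfg.input_channels,
            "stem_width": cfg.stem_width, "num_stages": cfg.num_stages,
            "num_classes": cfg.num_classes, "groups": cfg.groups,
            "se_reduction": cfg.se_reduction})
    meta.setdefault("model_type", type(model).__name__)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.asarray(json.dumps(meta)), **state)
    return Path(path if str(path).endswith(".npz") else f"{path}.npz")


def load_model(path) -> RecognitionModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    cfg = EncoderConfig(**meta["encoder_config"])
    model = RecognitionModel(cfg, rng=0,
                             use_attention=meta.get("use_attention", True))
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# ablation suite
# ---------------------------------------------------------------------------

ABLATION_CONFIGS = {
    "i": {"attention": False, "vae": False, "rgn": False},
    "i+a": {"attention": True, "vae": False, "rgn": False},
    "i+a+V": {"attention": True, "vae": True, "rgn": False},
    "i+a+d+r": {"attention": True, "vae": False, "rgn": True},
    "i+a+V+d+r": {"attention": True, "vae": True, "rgn": True},
}


def ablation_suite(train_images, train_labels, all_images, val_images, val_labels,
                   test_images, test_labels, enc_cfg: EncoderConfig,
                   cfg: TrainConfig, vae_epochs: int | None = None,
                   configs: list | None = None) -> list[dict]:
    """Train the five module combinations and report accuracy and macro F1."""
    from .metrics import confusion_and_accuracy, macro_f1

    chosen = {name: ABLATION_CONFIGS[name]
              for name in (configs or ABLATION_CONFIGS)}
    rows = []
    for name, flags in chosen.items():
        run_cfg = copy.deepcopy(cfg)
        if not flags["rgn"]:
            run_cfg.loss_weights.update({"adv": 0.0, "align": 0.0})
        if not flags["vae"]:
            run_cfg.loss_weights.update({"recon": 0.0, "kl": 0.0})
        model = RGNModel(enc_cfg, N=run_cfg.N, seed=run_cfg.seed,
                         use_attention=flags["attention"])
        if flags["vae"]:
            train_vae_phase(all_images, run_cfg, model, epochs=vae_epochs)
        train_rgn_phase(train_images, train_labels, val_images, val_labels,
                        run_cfg, model)
        pred_labels = []
        for start in range(0, len(test_images), run_cfg.batch_size):
            pred_labels.extend(model.predict(
                test_images[start:start + run_cfg.batch_size]).label)
        cm, acc = confusion_and_accuracy(test_labels, np.asarray(pred_labels),
                                         enc_cfg.num_classes)
        _, _, f1 = macro_f1(cm)
        rows.append({"config": name, "accuracy": acc, "macro_f1": f1})
    return rows
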