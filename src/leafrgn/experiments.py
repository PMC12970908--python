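"""Scaled-down end-to-end experiments on synthetic leaf images.

The full-scale study (tens of thousands of images, a 128x128 encoder,
ten-epoch phases) is not reproducible at desk scale, so these experiments
exercise the complete three-phase pipeline on the tiny configuration:
4 synthetic classes x 100 images at side 32, stem width 8, latent 64.
They are used by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .data_io import SampleRecord, SplitSpec, split_dataset, synth_generate
from .metrics import confusion_and_accuracy, macro_f1
from .pipeline import (RGNModel, TrainConfig, ablation_suite,
                       export_inference, train_rgn_phase, train_vae_phase)
from .recognition import tiny_config

SIDE = 32
N_PER_CLASS = 100


def make_synthetic_splits(seed: int, n_per_class: int = N_PER_CLASS,
                          side: int = SIDE):
    """4-class synthetic pools split 6:2:2 per class; arrays, not paths."""
    images, labels, names, _ = synth_generate(n_per_class, seed=seed, side=side)
    records = [SampleRecord(image=i, label=int(y)) for i, y in enumerate(labels)]
    split = split_dataset(records, SplitSpec(seed=seed))

    def take(recs):
        idx = np.asarray([r.image for r in recs], dtype=np.int64)
        return images[idx], labels[idx]

    return take(split.train), take(split.validation), take(split.test), names


def default_train_config(seed: int) -> TrainConfig:
    return TrainConfig(seed=seed)


def run_scaled_down_experiment(seed: int = 0, epochs: int = 10,
                               n_per_class: int = N_PER_CLASS) -> dict:
    """Phase-1 VAE then phase-2 RGN training on the tiny configuration.

    Returns the phase-1 reconstruction-loss trajectory (first/last epoch
    means), the retained model's validation accuracy, and held-out test
    accuracy / macro F1 of the exported recognition-only model.
    """
    (train_x, train_y), (val_x, val_y), (test_x, test_y), names = \
        make_synthetic_splits(seed, n_per_class=n_per_class)
    cfg = default_train_config(seed)
    cfg.epochs = epochs
    model = RGNModel(tiny_config(len(names)), N=cfg.N, seed=seed)

    vae_log = train_vae_phase(train_x, cfg, model)
    steps_per_epoch = max(1, len(vae_log.steps) // epochs)
    recon = [s["recon"] for s in vae_log.steps]
    recon_first = float(np.mean(recon[:steps_per_epoch]))
    recon_last = float(np.mean(recon[-steps_per_epoch:]))

    rgn_log = train_rgn_phase(train_x, train_y, val_x, val_y, cfg, model)

    inference = export_inference(model)
    preds = []
    for start in range(0, len(test_x), cfg.batch_size):
        preds.extend(inference.predict(test_x[start:start + cfg.batch_size]).label)
    cm, test_acc = confusion_and_accuracy(test_y, np.asarray(preds), len(names))
    _, _, f1 = macro_f1(cm)
    return {
        "n_train": len(train_x), "n_val": len(val_x), "n_test": len(test_x),
        "recon_first_epoch": recon_first, "recon_last_epoch": recon_last,
        "best_val_accuracy": rgn_log.best_accuracy,
        "test_accuracy": float(test_acc), "test_macro_f1": float(f1),
        "chance_accuracy": 1.0 / len(names),
    }


def run_ablation_report(seeds=(0, 1, 2, 3, 4), epochs: int = 10,
                        n_per_class: int = 40,
                        configs=("i", "i+a+V+d+r")) -> dict:
    """Median test accuracy of selected module configurations over seeds.

    Defaults compare the plain recognition network against the full model.
    A reduced problem size keeps the seed-replicated sweep tractable; the
    comparison is reported, not asserted, since at this scale the
    synthetic task is easy enough that configurations often tie.
    """
    per_seed = []
    for seed in seeds:
        (tr_x, tr_y), (va_x, va_y), (te_x, te_y), names = \
            make_synthetic_splits(seed, n_per_class=n_per_class)
        cfg = default_train_config(seed)
        cfg.epochs = epochs
        rows = ablation_suite(tr_x, tr_y, tr_x, va_x, va_y, te_x, te_y,
                              tiny_config(len(names)), cfg,
                              configs=list(configs))
        per_seed.append({r["config"]: r["accuracy"] for r in rows})
    medians = {name: float(np.median([run[name] for run in per_seed]))
               for name in per_seed[0]}
    return {"per_seed": per_seed, "median": medians}
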