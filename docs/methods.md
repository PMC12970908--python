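# Methods

## Model

The recognition model is a variational encoder/classifier. An input image
x ∈ [0,1]^(S×S×3) (S = 128 for the full configuration) passes through a
3×3 convolutional stem and `num_stages` stages, each consisting of a
*scale* block, an SE attention block and a *downsample* block. A final
scale + SE pair, global average pooling, a residual fully connected block
(*scale_fc*) and two parallel linear heads produce μ and log σ², each of
the latent dimension d (d equals the final stage width: 256 at full size,
64 in the tiny configuration). The classifier is scale_fc → linear →
softmax over C classes.

* **scale block**: `x + conv1×1(shuffle_g(gconv3×3(relu(bn(x)))))` with
  g = 4 groups. The pre-activation order keeps the zero-branch identity
  property exact; the channel shuffle mixes information across groups.
* **SE attention**: per-channel sigmoid gate from globally pooled features
  through a bottleneck of ratio r (default 16; 8 in the tiny configuration
  because the first stage has only 8 channels). Gates lie in (0,1), so the
  block is contractive elementwise.
* **downsample**: stride-2 average pooling then a grouped 3×3 convolution
  doubling the channel count, followed by a channel shuffle. Each stage
  halves the side and doubles the channels.
* **Initialization**: He-normal for convolutions and linear layers; the
  final layer of every residual branch starts at zero, so each residual
  block is the identity at initialization, which stabilizes the
  multi-phase schedule.

Training samples z = μ + exp(log σ²/2) ⊙ ε and classifies z — the sampling
noise acts as a regularizer. Inference uses μ exactly; the variance head
is computed but unused, and repeated predictions are bit-identical.

## Training phases

**Phase 1 (VAE).** Encoder + decoder are trained on the full image pool,
labels ignored, with loss `MSE(x, x̂) + β·KL`, where KL is summed over
latent dimensions and averaged over the batch, and β defaults to 1. The
decoder maps z through a linear layer to a 2×2 seed map (1024 channels at
full size; 4·d in general) and doubles the side with nearest-neighbour
upsampling + 3×3 convolution per stage (channels halving to a floor of
32), ending in a scale block and a 3×3 projection to 3 channels with a
sigmoid. Nearest-neighbour + convolution was chosen over transposed
convolution to avoid checkerboard artifacts.

**Phase 2 (destruction–generation–discrimination).** Per minibatch of
labeled images:

1. Half the batch (rounded, at least one image) gets a destroyed twin via
   the region confusion mechanism, each with its own permutation.
2. *Discriminator step*: the discriminator head (scale_fc → FC(2) on the
   shared encoder's pooled features) scores originals as real and
   generator restorations of the destroyed twins as fake; its head is
   updated alone on the two-class cross-entropy, with encoder features
   detached.
3. *Main step*: one momentum-SGD update of everything except the
   discriminator head on
   `w_cls·CE + w_recon·MSE + w_kl·KL + w_adv·CE(D(G(destroyed)), real) +
   w_align·MAE(alignment)`.
   All weights default to 1. The generator objective is the non-saturating
   form. The alignment head predicts, for each of the N×N grid slots of
   the destroyed image, the normalized original-centre coordinates
   ((i + 0.5)/N convention) of the region now occupying it; its loss is
   the mean absolute error over the 2N² coordinates.

A validation pass runs every 4096 training images (and once at the end of
the phase, so short runs still retain a checkpoint); the state with the
highest validation accuracy is retained, ties keeping the earlier one.

**Export.** Only encoder + attention + classifier parameters are written;
the exported model predicts bit-identically to the full model's inference
branch. The parameter archive is an `.npz` with a JSON metadata header
(configuration, class names, phase).

### Batch-normalization statistics

Batch norm runs on batch statistics during training and on running
estimates at inference, with running statistics carried across phases
(the phases share the encoder). One subtlety matters: destroyed and
generated images pass through the shared encoder during phase 2, and
letting those passes update the running estimates biases them away from
real-image statistics — enough to collapse held-out accuracy while the
training loss looks healthy. Auxiliary passes therefore run under a
`frozen_stats` context: batch statistics are used, running estimates are
not touched. Only the recognition path over original images updates them.

## Region confusion mechanism

For an N×N grid (N = 8, so 16-pixel regions at S = 128), each row j draws
q_{j,i} = i + r_i with r_i ~ U(−k, k) continuous (k = 2) and permutes its
columns by argsort(q_j); after all rows, each column of the row-shuffled
grid is permuted the same way. Sorting a ramp perturbed by at most ±k
moves no element more than 2k positions, so regions stay local. Row and
column indices are interpreted over the full range 1..N (excluding border
regions would leave them unshuffled for no stated reason). Ties — possible
only with a discrete generator — break by original index (stable sort).
The stored permutation is exactly invertible; `destroy` conserves the
multiset of region blocks, and `alignment_targets` exposes both
conventions (origin-of-slot, the default, and its inverse).

## Data handling

Splits use round-half-up arithmetic: for ratios (r₁, …, r_m) over n
records, every component after the first receives ⌊rᵢ·n + 0.5⌋ records
and the first the remainder; the labeled fraction f marks ⌊f·n + 0.5⌋
training records as labeled. This convention reproduces all published
cell counts it is tested against (e.g. 54,303 → 32,581/10,861/10,861 at
6:2:2; 32,581 at 50% → 16,291/16,290; 558 → 391/167 at 7:3). Splitting is
per-class by default (stratified) with a global mode available; both are
bit-stable under a fixed seed. Augmentation triples a pool with the
horizontal mirror and the 180° rotation of each image, ordered
(original, mirror, rotation) per input; it is applied before the 7:3
detection split, which risks leakage between augmented twins — the
alternative order is available via the library. Preprocessing decodes to
RGB, resizes bilinearly to the target side and scales to [0,1]; no
mean/std normalization, since the decoder reconstructs [0,1] images.

Detection rates use truncate-then-complement: the false-recognition rate
is 100·misidentified/total truncated to two decimals, the correct rate
its exact complement to 100. Truncation is the default because it makes
the headline pair (4.93/95.07 from 12/243) self-consistent; a rounding
flag covers the other convention. Zero-denominator metrics return 0 with
a warning so batch evaluation never aborts. Multi-class F1 is reported as
the macro average.

## Synthetic data generator

Each image is a textured soil background (brown base + smoothed
common-mode noise), a green leaf ellipse with vein-like texture, and
class-specific lesion disks constrained to the leaf. The default four
classes are healthy (zero lesions), rust_spot (small dark-red disks,
6–12), yellow_blight (large yellow patches, 3–7) and gray_mold (many
small pale-gray specks, 10–20). Lesion colours are chromatically distant
from both leaf green and soil brown, so the classes are separable by
local colour statistics — a property the test suite verifies with an
independent pixel-count threshold classifier (>90% healthy/diseased
accuracy). Generation is fully deterministic per seed.

What the generator does *not* emulate: illumination changes, occlusion,
leaf shape variety, disease progression stages, camera noise and
class-imbalance — so passing tests demonstrate that the pipeline learns
separable local lesion statistics, not field robustness.

## Scaled-down study conditions

The end-to-end experiment uses 4 classes × 100 images at side 32, the
tiny configuration (stem width 8, three stages, latent 64), a 6:2:2
per-class split (240/80/80), all training images labeled, and the
published optimization settings (batch 32, lr 0.001, momentum 0.9, 10
epochs per phase, validation cadence 4096 images). It asserts that the
phase-1 reconstruction loss falls epoch-over-epoch and that held-out
accuracy exceeds 60% against a 25% chance level. The seed-replicated
ablation (plain network vs full model, median over 5 seeds) runs at a
further reduced size (25–40 images per class, 6–10 epochs) and is reported,
not asserted: at this scale the synthetic task is easy enough for the
plain classifier that the ranking is noisy, and with every training image
labeled the VAE phase has no unlabeled pool to exploit — its benefit is a
semi-supervision effect by design.

## Numerical notes and limitations

* The network stack runs on a compact reverse-mode autodiff core
  (`leafrgn.nn`) over numpy: im2col convolution (grouped), non-overlapping
  average pooling, nearest-neighbour upsampling, batch norm, fused
  softmax cross-entropy. Gradients are verified against central finite
  differences in the test suite.
* All tensors are float32; KL and cross-entropy use numerically stable
  forms (log-variance parameterization, log-sum-exp).
* Single-device, single-threaded training only; no mixed precision, no
  learning-rate schedule (constant 0.001), one discriminator step per
  generator step.
* `predict` probabilities are uncalibrated; no test-time augmentation.
* The detection model itself (Mask R-CNN stage) is out of scope; the
  package consumes its count tables and can export the encoder as a
  backbone parameter archive.
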