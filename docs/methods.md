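# Methods

## Problem and model

The target task is voxelwise binary segmentation of the mandible in 3D
CBCT/CT volumes whose bone boundaries are corrupted by metal streak
artifacts.  The method is a two-stage cascade Ŷ = F₂(F₁(X, θ₁), X, θ₂),
decomposing a hard segmentation problem into an easier localization problem
followed by a refinement problem (a curriculum-style decomposition):

1. **Coarse stage F₁** — a 3D SegUNet maps a normalized sub-volume to a
   same-size probability map.  Training samples random sub-volumes
   (default 64×128×128; any size divisible by 2^depth works); with
   probability `positive_fraction` (default 0.5) a window is forced to
   cover a randomly chosen foreground voxel, otherwise it is uniform over
   all valid positions — the uniform windows act as hard negative mining.
   Whole-volume inference tiles the scan with a clamped-stride sliding
   window (stride = patch − overlap, last window clamped to the boundary,
   default overlap (8, 16, 16) voxels) and fuses overlapping predictions by
   the arithmetic mean, a symmetric and order-independent rule.
2. **Fine stage F₂** — a 2D SegUNet applied recurrently along the axial
   axis in ascending slice order.  Step t receives the fixed 3-channel
   stack (image slice xₜ, coarse probability slice ŷ₁ₜ, previous
   prediction ŷ₂ₜ₋₁).  The recurrence is initialized with an all-zeros
   previous slice (a coarse-slice initialization is available via
   `CascadeModel.init_prev="coarse"`).  The coarse channel is the *soft*
   fused probability, not a binarized mask, and during training the
   previous-prediction channel also stays soft so that gradients can flow
   through the recurrence; binarization (threshold 0.5, ties to foreground)
   happens once, at the end of inference, optionally followed by
   largest-26-connected-component post-processing.

## Architecture

Each SegUNet block is (conv → batch norm → ReLU) twice with same-padding
kernels of 3 per axis.  Encoder widths start at `base_filters` (32 at full
scale) and double per level; each level ends in a 2× max-pool that records
its argmax indices.  The decoder mirrors the encoder: max-unpooling places
values at the recorded argmax positions (SegNet-style index transfer), the
same-level encoder feature map is then concatenated channelwise (U-Net-style
skip), and the block's convolutions halve the width.  The head is a 1×1(×1)
convolution with a numerically clipped sigmoid, so outputs are strictly
inside (0, 1).  Convolutions are Kaiming-initialized (fan-in, seedable);
batch norm starts at γ=1, β=0 with running statistics (momentum 0.1,
eps 1e-5) used at evaluation time.

The entire network stack — convolution via shift-and-stack im2col, batch
norm, pooling/unpooling, the recurrence, and Adam — is implemented in numpy
with hand-written forward and backward passes.  The backward pass is seeded
by the closed-form loss gradient below and is verified in the test suite
against central finite differences and symbolic differentiation, and the
pooling/unpooling index contract is asserted exactly.

## Objective

L = ω₁·L_BCE + ω₂·L_Dice with ω₁ = ω₂ = 0.5.  L_BCE is the voxel-mean
binary cross-entropy with probabilities clipped to [1e−7, 1−1e−7] (finite
loss at saturation); L_Dice = 1 − (2Σyŷ + s)/(Σy + Σŷ + s) with smoothing
s = 1e−6 in numerator and denominator, which makes the empty/empty case a
perfect score.  The analytic per-voxel gradient, with N voxels,
I = Σyŷ and D = Σy + Σŷ + s, is

    ∂L/∂ŷⱼ = −(ω₁/N)(yⱼ/ŷⱼ − (1−yⱼ)/(1−ŷⱼ)) − ω₂(2yⱼD − (2I+s))/D².

Batch reduction is the mean over items; across recurrent steps the
per-step losses Lₜ are applied individually (see below).

## Training

Both stages train separately with Adam at learning rate 1e−4 (β = 0.9/0.999,
eps 1e−8).  The coarse stage draws `batch_size` sub-volumes per case per
epoch.  The fine stage uses truncated backpropagation through time in the
per-step form: each slice loss Lₜ is backpropagated through the last
`bptt_window` (default 4) recurrent steps — the window t−w+1…t is
re-unrolled from the stored soft predictions, the entry state is treated as
a constant (gradient truncation), and one optimizer update is applied per
slice.  With `bptt_window=1` this reduces exactly to per-slice training
with a detached previous mask.  Teacher forcing (ground-truth previous
slice, which collapses the window to 1) is available as a config switch but
is off by default, so the network trains on its own recurrent inputs — the
same distribution it sees at inference.

## Preprocessing

Raw intensities are truncated to [−1000, 2000] and linearly rescaled to
[0, 1]; one rule for all cases, applied to stored values as-is (CBCT-like
data is not HU-calibrated first).  Volumes are indexed (slice, row, col)
with spacing (dz, dy, dx) in mm; NIfTI files are transposed on read/write
accordingly.  Volumes smaller than the inference patch are symmetrically
zero-padded and un-padded afterwards; for training they are rejected.

## Metrics

Dice = 2|A∩B|/(|A|+|B|) (1 for two empty masks).  Surface distances use
boundary voxels — foreground voxels with ≥1 background 6-neighbour, volume
edge counting as background — as points at voxel centres in mm, so
anisotropic spacing is exact.  ASD is the symmetrized mean
nearest-neighbour distance; HD the symmetrized maximum; 95HD uses the
nearest-rank rule (rank ⌈p·|A|⌉ of the ascending nearest-neighbour
distances) per direction before the symmetrizing max, which is unambiguous
for small point sets and is mirrored by the brute-force oracles in the
tests.  When exactly one mask is empty the distances are undefined and
reported as NaN sentinels with a warning, keeping batch tables finite.

## Phantom generator

The generator emulates the features of artifact-polluted maxillofacial
scans that drive the method's design, not radiometric physics:

- geometry: a horseshoe-shaped body arch (partial annulus with a posterior
  gap), two ascending rami, condylar knobs — parameterized as fractions of
  the volume shape so one default set scales across grid sizes;
- intensities: soft tissue ≈ 0, bone ≈ 1200, metallic tooth voxels at 3000,
  deliberately above the 2000 clip ceiling so they saturate after
  normalization like real fillings and braces (noise sd 80, a realistic
  CT-like noise level);
- artifacts: from every metal voxel, 8 in-plane rays at random angles with
  alternating ±600 offsets and linear falloff — creating the bright/dark
  streaks and false edges that corrupt real scans.  Streaks are 2D rays,
  not cone-beam physics; their role is to perturb edges, not to model
  scatter.  Artifacts and noise corrupt only the image; the label is the
  clean anatomy, with metal voxels labelled foreground (teeth belong to
  the jaw).

What passing on phantoms does **not** show: robustness to anatomical shape
variation, to true beam-hardening/scatter physics, to inter-observer label
noise, or to HU calibration differences between scanners.  The phantom
study validates the machinery (losses, gradients, recurrence, tiling,
metrics) and the cascade's qualitative behaviour, not clinical accuracy.

## Desk-scale study conditions

The reference study (`c2fseg.experiments.run_scaled_study`, also run by
`scripts/acceptance.py`) uses 20 training + 5 held-out phantoms at
32×64×64, a coarse net with base_filters 4 and depth 2 trained 30 epochs on
16×32×32 patches, and a fine net trained 15 epochs — a configuration chosen
so a complete two-stage run finishes in minutes on one CPU core while
preserving every structural element of the method.  Per-case phantom seeds
are base+index, so cohorts extend without reshuffling.  Training and
inference are bit-reproducible for a fixed seed in single-threaded
execution.

## Numerical choices and edge cases

- Sliding-window fusion error on uncovered voxels (never silently zero).
- Threshold ties (probability exactly 0.5) map to foreground.
- Largest-component ties keep the component whose first voxel is earliest
  in z-major scan order.
- Sigmoid logits are clipped at ±36 so probabilities stay strictly inside
  (0, 1) in float64, which the analytic loss gradient requires.
- Checkpoints are single `.npz` files with the network config embedded as
  JSON, so a checkpoint is self-describing.

## Known limitations

- Single-item (batch of 1) network execution: batch statistics in batch
  norm reduce over the spatial axes only.
- One sweep direction (ascending slices) in the fine stage; no
  bidirectional averaging.
- No joint end-to-end training of the two stages (they are trained
  separately by design), no data augmentation beyond window sampling, and
  no GPU path — the numpy core is meant for correctness and desk-scale
  experiments, not production throughput.
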