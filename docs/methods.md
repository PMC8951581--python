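# Methods

## Problem and scope

`uqseg` implements an uncertainty-quantification-and-exploitation
framework for 3-D multimodal brain-tumor segmentation with BraTS-style
labels (0 background, 1 necrotic/non-enhancing core, 2 peritumoral
edema, 4 enhancing tumor) and the three nested evaluation regions
ET = {4}, TC = {1, 4}, WT = {1, 2, 4}. The pipeline has two stages:

1. **Baseline with Monte-Carlo dropout.** A 3-D encoder–decoder
   segmentation network carries a dropout layer (rate 0.10) after every
   hidden convolution. At inference the dropout stays active and the
   input is forwarded T = 7 times, producing a stack of per-voxel
   softmax samples `p_t(c)`.
2. **Uncertainty attention.** Four voxel-wise uncertainty maps are
   computed from the stack, concatenated into a 4-channel block, and fed
   to a second-stage network in which an uncertainty attention module
   (UAM) refines the running feature map after every fifth convolution.

## Uncertainty measures

With `p̄(c) = (1/T) Σ_t p_t(c)` the across-sample mean, per voxel:

- aleatoric: `(1/T) Σ_t Σ_c p_t(c)(1 − p_t(c))` — within-sample spread,
  irreducible data noise;
- epistemic: `(1/T) Σ_t Σ_c (p_t(c) − p̄(c))²` — across-sample variance,
  model uncertainty;
- predictive entropy: `−Σ_c p̄(c) ln p̄(c)`;
- mutual information (BALD): `H(p̄) − (1/T) Σ_t H(p_t)`, clamped at 0
  from below (non-negative by Jensen's inequality up to float rounding).

Normalisation: the aleatoric and epistemic sums carry a `1/T` factor so
the values estimate the expectations they approximate and do not grow
with the number of samples; `normalize_by_t=False` yields the plain sum
over samples. Natural logarithms are used throughout (a base change
only rescales the maps, and the block is rescaled anyway, below).
`p ln p` is stabilised by clamping probabilities to `[1e-12, 1]`.
Epistemic uncertainty and mutual information are defined against the
across-sample mean `p̄`; with a single sample (T = 1) both are zero by
construction and the functions return zeros with a warning.

The four maps are stacked channel-wise in the fixed order (aleatoric,
epistemic, entropy, mutual information) and each channel is min–max
rescaled to [0, 1] by default, so the attention module sees scale-free
inputs regardless of measure magnitudes; a constant channel carries no
spatial information and maps to zero.

## The uncertainty attention module

For a feature map `F` (C channels) and the uncertainty block `U`:

    A(F, U) = σ( f₃ₓ₃( [ f₃ₓ₃(U_resized); AvgPool(F); MaxPool(F) ] ) )
    O(F, U) = F ⊗ A ⊕ F

`U` is trilinearly resized per channel to `F`'s grid (endpoint-aligned,
so constants stay constant and linear ramps resize exactly); the pools
run across the channel axis, producing two single-channel maps; both
convolutions are 3×3×3 with bias and zero padding 1; σ is the logistic
sigmoid, so attention values are strictly inside (0, 1). The
U-reduction convolution is channel-preserving (4 → 4), so the fusion
convolution sees 6 channels; one site therefore owns
4·27·4 + 4 + 6·27 + 1 = 599 parameters. The additive skip in `O` keeps
an identity component in ∂O/∂F (verified by finite differences), and
`O` has `F`'s shape, so a site can be inserted at any depth.

Sites are inserted after every fifth convolution counted in forward
order, classifier head included: the default network has 10
convolutions, hence 2 sites, the second gating the pre-softmax logits.
Convolutions are 3-D because the model segments volumes; the module
also accepts any channel count, so a 2-D-slice network would work
unchanged apart from the kernels.

## Network

The baseline is a configuration-driven encoder–decoder, not a
reimplementation of any fixed published topology (the framework is
architecture-agnostic): a stem convolution, `depth` encoder stages
(2× average pooling, then two 3×3×3 convolutions doubling the channel
width), a mirrored decoder with nearest-neighbour upsampling and skip
concatenation, and a 1×1×1 softmax head. Leaky ReLU (slope 0.01, so no
unit can die) and dropout follow every hidden convolution; an optional
non-affine instance normalisation (`norm="instance"`) is off by
default because per-volume statistics differ between training crops
and full-volume inference. The head emits raw, undropped logits
(dropping the logits themselves would inject argmax-flipping noise
that standard MC-dropout practice avoids). For attention-site
placement only convolutions are counted — normalisation and dropout
layers are not. Weights are He-initialised from a seeded
generator, so identical configurations give bit-identical networks.
Default width/depth: 16 base channels, 2 stages (≈ 347 k parameters);
the attention overhead of 2·599 parameters is ≈ 0.35 %.

The final label map is the argmax over classes of the across-sample
mean probability (ties toward the lower class index, i.e. background),
mapped through class-index → label-code (0,1,2,3 → 0,1,2,4).
Mean-then-argmax rather than per-sample voting keeps the prediction
consistent with the `p̄` used by the uncertainty measures.

The tensor backend (`uqseg.nn`) is a small reverse-mode autodiff engine
on numpy float32 arrays with numba-jitted convolution inner loops (and
a pure-numpy fallback); all operation gradients are finite-difference
checked in the test suite.

## Training

Soft Dice loss: per foreground class c,
`1 − (2 Σ p_c g_c + ε) / (Σ p_c² + Σ g_c² + ε)` with soft probabilities
`p`, one-hot targets `g`, ε = 1e-5 in numerator and denominator (an
empty class therefore contributes ≈ 0 rather than NaN), averaged
without weights over the three foreground classes. Optimiser: Adam
with coefficients (0.5, 0.999), L2 weight decay 1e-5, constant learning
rate 1e-3, batch size 8, 200 epochs at full scale; no learning-rate
schedule.

Augmentation per sample: one random crop (96³ at full scale);
independent per-axis flips at p = 0.5; one rotation uniform in ±10°
about a randomly chosen principal axis — linear interpolation for image
and uncertainty block, nearest neighbour for labels so no interpolated
label codes can appear; per-channel intensity shift uniform in ±0.1 and
per-channel scale uniform in [0.9, 1.1] applied to image channels only.
All spatial operations are applied identically to image, labels and
uncertainty block.

Stage 2 uses a frozen stage-1 baseline: uncertainty blocks are computed
once per full volume (T = 7) and cached keyed by weight hash, then
cropped/transformed in lockstep with the image during training. Test
volumes get their blocks from the same frozen baseline — no ground
truth is involved in producing them. Freezing keeps stage 2
reproducible and the blocks cacheable; the stage-2 network is trained
from scratch with its own attention parameters.

## Synthetic phantoms

Real multicentre MRI is deliberately out of the loop; the phantom
module generates what the pipeline needs structurally: 4 co-registered
contrasts (t1, t1ce, t2, flair) with nested spherical tumor subregions
per focus — edema shell (2) ⊃ enhancing rim (4) ⊃ necrotic center (1) —
and class-mean intensities reproducing the diagnostic contrast
orderings (enhancing tumor hyperintense in t1ce, edema hyperintense in
flair, necrotic core hypointense in t1ce). Defaults: 64³ isotropic
grid, one focus with whole-tumor radius uniform in [6, 12] voxels, TC
radius 0.6 of WT, enhancing rim the outer half of TC, parenchyma mean
1.0 everywhere, lesion means 2.0 in the defining contrast / 1.2
off-contrast / 0.4 for necrotic core in t1ce, i.i.d. Gaussian noise
σ = 0.15 per channel. Spheres (optionally ellipsoidally jittered) make
geometric oracles computable — the discrete-sphere voxel count checks
the generator. The phantoms have no bias fields, partial-volume
effects, anatomy, or registration artifacts, so passing tests show the
framework's mechanics and its uncertainty→error relationship, not
clinical-grade segmentation performance.

## Desk-scale study

`uqseg.experiments.desk_scale_experiment` runs the full two-stage
protocol at a size one CPU finishes in minutes: 40 training / 10 test
phantoms on 64³ grids, a 4-base-channel depth-2 network (22 128
parameters, 2 attention sites), 24³ training crops, 30 epochs, T = 7,
10 % dropout, full-volume evaluation. Volumes are z-scored per channel
(the standard load-time normalisation) before training and evaluation.
Because a 24³ crop of a 64³ volume often misses a small lesion
entirely (unlike a 96³ crop of a brain-filling 240³ scan), training
crops are forced to contain tumor voxels with probability 0.5
(`tumor_crop_prob`; 0 restores plain uniform cropping).

A small fraction of weight inits produce degenerate runs, in two
observable modes: the final-epoch *training* loss plateaus above 0.65
(converged runs end around 0.3–0.5), or one minority class floods the
background — its predicted soft mass exceeding ten times its target
mass while the mean loss looks fine. Either condition triggers a
restart from a fresh init (at most twice); flooded runs are abandoned
a third of the way through training since the collapse is established
early. A class that is merely under-predicted (tiny necrotic cores
are genuinely hard at 150 optimiser steps) does not trigger restarts.
The rule reads training statistics only — never test data — and
applies identically to both stages, so the baseline-vs-attention
comparison is like for like.

Reported outcomes: mean region Dice per model, voxel-wise
error–uncertainty ROC AUCs (does the uncertainty map rank mispredicted
voxels above correct ones; 0.5 = uninformative), and the attention
parameter overhead. `scripts/acceptance.py` reruns this study (2
replicates by default) plus the formula-oracle and closed-form checks,
and writes all measured numbers as JSON.

## Numerical conventions and edge cases

- Dice score on regions: both masks empty → 1.0 (correctly predicted
  absence, common BraTS practice); exactly one empty → 0.0.
- Error–uncertainty AUC undefined (all voxels correct or all wrong) →
  NaN sentinel, excluded from case averages.
- Z-score normalisation on load runs per channel over nonzero voxels;
  all-zero or constant channels pass through unchanged.
- Label code 3 (or any unknown code) is rejected with the offending
  value and voxel count, never remapped.
- FLOP accounting counts 2 operations per convolution
  multiply-accumulate at a stated input shape; parameter counts are
  exact sums over learnable tensors.
- Sliding-window inference (50 % overlap, probability mean-blending) is
  available for volumes exceeding the training crop; the desk-scale
  study evaluates full volumes in a single pass since the network is
  fully convolutional.

## Known limitations

- The numpy/numba backend is CPU-only and desk-scale; full BraTS-scale
  training (240×240×155, 200 epochs) is out of reach by design.
- Phantom realism is deliberately minimal (see above); absolute Dice
  values on phantoms do not transfer to clinical data.
- Mutual-information and epistemic maps discriminate errors only once
  the model is trained well enough that its errors concentrate at
  decision boundaries; early in training, confident systematic errors
  carry low disagreement.
- Whether the T Monte-Carlo passes share or redraw dropout masks per
  layer is an open choice; independent masks per pass (standard MC
  dropout) are used.
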