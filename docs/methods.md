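# Methods

`octseg` reimplements a complete desk-scale pipeline for segmenting the
three neovascular AMD lesion classes — intra-retinal fluid (IRF, label 1),
sub-retinal fluid (SRF, label 2) and pigment-epithelium detachment (PED,
label 3) — in 2D SD-OCT B-scans, and validates every stage on synthetic
phantoms with known ground truth.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not show.

## Synthetic B-scan phantoms (`octseg.phantom`)

Real SD-OCT training data of this kind is clinical and private, so the
package ships a generator that emulates the *data regime* rather than OCT
physics:

* **Geometry.**  Three layer lines per scan — ILM above RPE above Bruch's
  membrane (BM) — built from a low-order polynomial plus smooth sinusoidal
  perturbations and a foveal dip, in fractions of image size so the same
  code yields 512x496 scans and 64x64 miniatures.  The invariant
  `ilm < rpe <= bm` holds at every column.
* **Lesions.**  IRF: hyporeflective elliptical blobs strictly between ILM
  and RPE.  SRF: fluid pockets immediately above the RPE line.  PED: domes
  where the RPE line detaches from BM; the pocket between lifted RPE and BM
  is the PED region.  The blob model is a stand-in for real lesion shape
  statistics, which are not publicly characterised.
* **Speckle.**  Pixel intensity = layered reflectivity template x
  multiplicative gamma noise with mean 1 (`speckle_shape` k = 4 by default,
  i.e. speckle contrast 1/sqrt(k) = 0.5, a typical OCT value).
* **Volume sampling.**  49 B-scans per volume of which 5 are drawn without
  replacement with Gaussian weight centred on the middle slice
  (`slice_sigma` = 6 slices); realised as Gumbel-top-k so that the sigma->0
  limit degenerates cleanly to the 5 centre-nearest slices.
* **Class presence.**  Scans with no lesion are rejected and resampled
  (the study population contains lesion-bearing scans only).  Because that
  conditioning inflates raw Bernoulli rates, the generator solves the fixed
  point `q_c = p_c * P(>=1 lesion)` so the *emitted* per-class frequencies
  converge to `class_probs` = (0.47, 0.37, 0.84) for (IRF, SRF, PED) — the
  relative class frequencies of the study dataset.
* **Axial resolution** defaults to 3.87 um/pixel (Spectralis-typical).
  For miniature phantoms it is scaled by the depth ratio (e.g. 30 um/pixel
  at 64 px) so that the 390-um ROI offset remains anatomically meaningful.

What passing tests on phantoms show: the pipeline's plumbing, losses,
metrics, splitting and optimisation behave correctly, and the models can
learn lesion geometry from intensity contrast.  What they do not show:
performance on real OCT texture, vendor artefacts, annotation noise, or
clinically realistic lesion morphology.

## Preprocessing (`octseg.preprocess`)

Fixed order: BM polynomial fit -> ROI masking -> CLAHE -> shear
registration -> resize -> (train-time) rotation augmentation.

* **BM fit**: least squares, degree 2 by default (configurable); missing
  candidates are ignored.
* **ROI**: rows between the ILM (upper) and BM + round(390 um / axial
  resolution) (lower, clamped to the image); everything outside is zeroed.
  Columns whose bounds invert after clamping are flagged degenerate and
  zero-filled.
* **CLAHE** is implemented in the integer-LUT dialect so results are
  bit-comparable: per-tile 256-bin histograms, clip threshold
  `max(1, round(clip_limit * tile_area / n_bins))`, uniform excess
  redistribution (remainder to the first bins — a stated tie rule), LUT
  `round(cdf * 255 / tile_area)`, bilinear blending between the four
  nearest tile centres with clamping at the borders.  Defaults: 8x8 grid,
  clip limit 1.  With one tile and unbounded clip this reduces exactly to
  global histogram equalisation.
* **Registration**: a vertical shear (pivot at the left RPE endpoint)
  levels the two RPE endpoints, then a global vertical translation places
  that row at `round(0.65 * depth)`.  Images are resampled linearly, masks
  with nearest-neighbour, vacated pixels zero-filled.  The pivot choice is
  immaterial — any pivot yields the same post-state after the translation.
  When no pre-segmented RPE line exists the fitted BM endpoints act as the
  proxy.
* **Resize**: bilinear for images, nearest for masks (value set {0..3} is
  preserved exactly); default target 224.
* **Augmentation**: with probability 0.5 both image and mask are rotated
  by one shared angle, uniform in ±20 degrees.

CLAHE runs after ROI zero-filling (the chain's stated order); tile
histograms near the ROI boundary therefore include the zeroed background.

## Architectures (`octseg.models`)

All three networks map `1 x S x S -> 4 x S x S` logits and are implemented
as pure-numpy functional layers differentiated with HIPS `autograd`
(reverse-mode AD over numpy); convolutions are slice-gathers feeding one
BLAS matmul.

* **2D Swin-UNETR.**  Encoder: 2x2 patch embedding to `feature_size`
  channels (24 default, 48 for the large variant), four shifted-window
  transformer stages with depths [2,2,6,2] and heads [3,6,12,24], window
  7x7, MLP ratio 4, learned relative-position bias, patch merging after
  every stage (width doubles, resolution halves; patch footprint
  2-4-8-16-32 px, so a 224 input bottoms out at 7x7 tokens).  Token grids
  not divisible by the window are zero-padded; the attention mask treats
  padding as a separate region so real tokens never attend into it.
  Decoder: five stages of residual blocks (two 3x3 convolutions + instance
  normalisation, 1x1-projected shortcut on width change) on the skips,
  2x transposed-convolution upsampling, concatenation, residual fusion; a
  1x1 convolution emits logits.  Dropout paths are kept at their default
  rate 0.  `input_size >= 64` is required: a 1x1 bottleneck would be
  annihilated by instance normalisation.
* **U-Net**: the classic 5-level design, widths 64..1024, two 3x3
  convolutions + ReLU per level, max-pool down, transposed-conv up with
  skip concatenation.  This configuration counts 31.0 M parameters.
* **U-Net3+**: same encoder; each decoder stage aggregates all five scales
  (max-pooled encoder maps, bilinearly upsampled coarser decoder maps and
  bottleneck), each through its own 3x3 convolution with 64 kernels
  (+BN+ReLU), concatenated to 320 channels and fused by a 3x3 convolution
  with 320 kernels + BN + ReLU.  Deep supervision heads exist but are off
  by default — the training loss makes no provision for auxiliary outputs.

**Capacity accounting.**  `count_parameters` enumerates actual tensors;
each module also reports an analytic count and analytic MACs
(k^2*Cin*Cout*Ho*Wo for convolutions, token x channel products for
projections, the two window-attention matrix products; normalisations,
activations and pooling excluded).  Computed constants at 224x224:

| model | parameters | MACs |
|---|---|---|
| Swin-UNETR-24 | 6.76 M | 3.8 G |
| Swin-UNETR-48 | 26.9 M | 14.6 G |
| U-Net | 31.0 M | 36.8 G |
| U-Net3+ | 27.0 M | 151.2 G |

Two published figures for these models are internally inconsistent with
each other and with this family of architectures: a 6.3 M count for the
feature-size-24 model cannot coexist with a 27 M count for the
feature-size-48 model, because doubling the feature size scales every
component at most quadratically (measured ratio 3.98); the 6.76 M count
reproduces the 27 M figure exactly.  Similarly, U-Net3+'s MACs exceed the
U-Net's by ~4x, not by an order of magnitude — the order-of-magnitude gap
holds against the Swin models (~40x).  Both discrepancies are reported as
computed, not adjusted.

## Training (`octseg.training`)

* **Loss**: `0.5 * CE + 0.5 * (1 - soft Dice)`.  Soft Dice uses softmax
  probabilities against the one-hot target, summed per image and class,
  averaged over all four classes including background, with eps = 1e-5
  smoothing in numerator and denominator — so a perfectly predicted scan
  (including correctly absent classes) reaches loss 0.
* **Optimiser**: SGD with momentum and weight decay (applied to all
  parameters).  The learning rate follows a triangular cyclic schedule
  between `lr_base` and `lr_max` (half-cycle = 10 epochs by default; the
  cycle period is a package choice, not a reported value); momentum cycles
  inversely between `momentum_max` and `momentum_base`.
* **Early stopping**: strict improvement of the validation loss, patience
  6 epochs, maximum 50; the best-validation-loss checkpoint is retained.
  No minimum-delta threshold is applied (strict `<`).
* **3-stage manual search** (`run_hpt`): stage 1 sweeps six LR ranges
  (base = max/10, plus a constant-LR control at 5e-3.5); stage 2 the four
  momentum ranges [.80,.90], [.80,.95], [.85,.97], [.85,.99]; stage 3
  weight decay 1e-6..1e-2; each stage fixes the previous winner.  Each
  configuration is scored by the class-weighted mean validation Dice at
  its best-validation-loss epoch.  Early in training the weighted Dice can
  be undefined (the skip rule removes every record when a model predicts
  only background); such configurations rank below any scored one, with
  validation loss as the tie-break.

## Evaluation (`octseg.evaluation`)

Image-wise protocol: one-vs-rest confusion counts per image and class;
Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP).  For each class, images with an empty reference *or* an empty
prediction are skipped (this also silently removes pure-false-positive and
pure-false-negative images — a property of the protocol that is preserved
verbatim and applied to all three metrics uniformly).  Per-class means are
then combined with weights proportional to the number of evaluated images
in which the class is present in the reference — computed on the evaluated
split, and recorded in the report.  A class with no usable record is
reported missing (NaN), never zero.

Lesion size analysis: per class, reference-area quartile boundaries over
the evaluated records; boundaries are right-inclusive (ties go to the
lower bin); per-bin mean/SD/median/quartiles of Dice.

## Splitting (`octseg.splits`)

Patient-level, stratified by the seven lesion-combination groups.  Each
patient's stratum is the modal group of their scans (ties towards the
globally rarest group).  Patients of each group are spread over the k=5
outer folds within one of the balanced share; residual ties go to the
globally smallest fold, so fold sizes stay balanced too.  The inner split
is a single stratified train/validation partition with `val_fraction`
0.2 (a documented default; largest-remainder allocation hits the exact
validation count).  No patient appears in more than one of
train/validation/test within a fold.

## Scaled-down experiments and problem sizes

The test suite exercises real learning at miniature scale, chosen so the
whole suite runs on one CPU:

* Overfit sanity: feature-size-8 Swin-UNETR on 8 phantom images (64x64),
  30 epochs, training loss must at least halve.
* Held-out learning: 40 patients x 5 slices of 64x64 phantoms through the
  full chain (ROI, CLAHE, registration at native 64), patient-stratified
  5-fold split, feature-size-8 Swin-UNETR (heads [2,4,8,16], 0.77 M
  parameters), 16 epochs with the cyclic schedule (LR 5e-3..5e-2, momentum
  0.80..0.95, weight decay 1e-4).  The batch size is 8 rather than the
  comparison protocol's 16: at this miniature scale the binding constraint
  is the number of optimiser steps, not device memory, and halving the
  batch doubles the updates per epoch at identical compute cost — the
  model escapes the all-background minimum around step ~150 and reaches a
  validation weighted Dice of 0.77 at the 16-epoch cap (0.82 held-out when
  run to 20 epochs).  At this budget the model masters
  only PED — the largest-area class; IRF and SRF predictions are still
  empty, so the skip-empty weighting rests on PED alone.  This mirrors, in
  miniature, the size-performance effect seen on real data (larger lesions
  are easier), and is the main caveat on what the phantom experiments
  demonstrate.

## Degenerate inputs and numerical choices

float32 throughout; attention masks use an additive -1e4 fill;
`sigma = 0` slice sampling is handled deterministically; all-background
scans are rejected at generation and refused by `assign_group`; ROI
columns that invert after clamping are zero-filled; masks are always
resampled nearest-neighbour so label values never interpolate; seeds
derive from a single `SeedSequence` root and stay below 2^31.
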