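# Methods

## Problem and pipeline

Many clinical datasets are small numeric tables — the reference schema
here is the PIMA diabetes collection: 768 records of eight bounded
measurements (pregnancies, glucose, blood pressure, skin thickness,
insulin, BMI, pedigree function, age) with a binary outcome. Convolutional
image models cannot consume such rows directly. `tabraster` converts each
record into a small grayscale image so that standard 2-D convolutional
backbones, image augmentation, and CNN-feature + SVM hybrids all become
applicable to tabular data.

The pipeline is:

1. **ReliefF weighting** of the raw features;
2. **min–max normalization** of each feature to [0, 1];
3. **rasterization**: each record becomes a 120×120 grayscale image in
   which every feature owns one rectangular cell, cell area ordered by
   ReliefF importance and cell brightness equal to value × 255;
4. **affine augmentation** (reflection, rotation, scale, translation),
   quintupling the image set;
5. one of three classification approaches: (1) fine-tuned residual
   networks of depth 18 and 50; (2) their fused 512 + 2048 = 2560-dim
   penultimate features classified by kernel SVMs; (3) the ReliefF top-500
   of the fused features classified by kernel SVMs.

## ReliefF

For a visited sample R with k nearest hits H (same class) and k nearest
misses M (other class), each feature weight is updated by
`mean diff(A, R, M)/m − mean diff(A, R, H)/m`, with
`diff(A, I1, I2) = |value(A,I1) − value(A,I2)| / (max(A) − min(A))` and
neighbors found by Manhattan distance over the same diff terms. At k = 1
this is exactly the classical single-hit/miss Relief update; the k-average
form is the standard generalization and k defaults to 10. Weights are in
[−1, 1] by construction; a constant feature gets weight exactly 0.

Choices that the method statement leaves open, decided here:

- **Visits m**: every sample once in row order (`m="all"`), deterministic;
  seeded random subsampling is available and is what the deep-feature stage
  uses at scale.
- **Diff denominators**: declared feature bounds when the table carries
  them, observed per-column min/max otherwise (deep features have no
  declared bounds).
- **Ties**: neighbor ties broken by ascending sample index; ranking ties by
  ascending feature index.
- **Binary-class form only** — both uses in the pipeline are binary; the
  prior-weighted multi-class extension is out of scope.

## Layout geometry

The published design fixes only the constraints — 120×120 canvas, one cell
per feature, larger cells for more important features, asymmetric
arrangement — not the coordinates. The deterministic reconstruction used
here is a guillotine treemap: visit features in ranking order; slice a
strip off the longer side of the remaining rectangle (ties cut vertically),
with thickness `round(extent × mass / remaining mass)` clamped so every
remaining feature keeps ≥ 1 px; the last feature absorbs the remainder.
Masses default to ranks (p, p−1, …, 1) rather than raw weights because
ReliefF weights can be negative; proportional-to-shifted-weight masses are
accepted as an argument. The partition is exact (every pixel owned by
exactly one cell), areas deviate from exact mass proportionality by at most
max(width, height) pixels, and the cell set is asymmetric under the
horizontal mirror for p ≥ 2 and under both mirrors for p ≥ 3 (at p ≤ 2 a
single edge-to-edge cut makes one mirror symmetry unavoidable; p = 1 is a
full-canvas cell). Cell coordinates are exported in the manifest so an
alternative geometry can be dropped in.

Intensities use round-half-up (`floor(255·x + 0.5)`), making 0.5 map to
128; with ≥ 1 px cells this keeps rasterization injective at the 1/255
resolution level.

## Augmentation

One output per technique per original (plus the original), hence exactly
5× the count and per-class counts. Ranges: rotation ±30°, scale 0.9–1.1,
translation ±10 px per axis (drawn as integers, which keeps the shift
exact under bilinear interpolation), reflection = left-right flip (the
axis is not specified by the source protocol; left-right is the
convention chosen here). Off-canvas regions are zero-filled; interpolation
is bilinear with a round-half-up cast to 8 bits. Because resampling plus
rounding can move a pixel mean by a fraction of a grey level, the
"rotation/translation never gain intensity" property is asserted with a
0.5-intensity slack.

## Backbones

The depth-18 and depth-50 residual networks are implemented in-package as
plain numpy (im2col convolutions, batch normalization, max/global-average
pooling, hand-derived backprop verified against finite differences in the
test suite). The stock classifier is replaced by two fully connected
output layers (hidden width 64 by default, recorded in checkpoints) and a
softmax; the deep-feature tap is the globally pooled penultimate vector —
512 dimensions at depth 18, 2048 at depth 50, independent of input
resolution.

Training is SGD with momentum 0.9 (the momentum coefficient is not fixed
by the protocol; 0.9 is the conventional default), batch 32, 5 epochs,
initial learning rate 0.001, drop factor 0.1 every 20 epochs (so the rate
never drops inside a default run). Grayscale images are bilinearly resized
to 224×224 and replicated to three channels; intensity scaling is
pixel/255 by default, with pretrained-stem channel statistics available
for use with a locally supplied weights file. Pretrained initialization is
never downloaded: `pretrained=True` requires an `.npz` checkpoint path.

## SVM stage

Features are z-scored with training-set statistics inside the fitted
pipeline. Kernels: linear; quadratic/cubic = polynomial of degree 2/3 with
unit scale and offset 1; Gaussian with kernel width sqrt(p) (gamma = 1/p).
Box constraint C = 1. These presets mirror the common classification-
toolbox defaults the protocol implies; all are exposed as arguments. The
six reported statistics are accuracy (×100), specificity, precision,
sensitivity, F1 and MCC; a zero denominator yields NaN plus a flag in
`MetricsReport.undefined` rather than a silent 0.

## Split order and leakage

The reference protocol augments first and then splits 80/20, which can
place augmented siblings of one source record on both sides of the split
and inflate test metrics. The default reproduces that order; every report
names the active mode, and `split_after_augmentation=False` switches to
the leakage-safe order (split originals, augment training images only,
test on original images). The feature re-selection of approach 3 is
computed on training rows only by default (`selection_on="all"` reproduces
a whole-set selection).

## Synthetic data

The generator draws class-conditional Gaussians per feature: class 0
centered at the bound midpoints, class 1 shifted by effect_size × sd on an
informative subset, all values clipped to the declared bounds. Defaults
are the reference study conditions where stated — 500 negative / 268
positive records, the eight PIMA features and their published ranges —
plus choices a practitioner would call realistic where nothing is stated:
informative subset {glucose, BMI, age, pregnancies} (the clinically
strongest PIMA predictors), effect size 1.0 (moderate separation), noise
sd = range/6 so ±3 sd spans each feature's range. The generator does not
reproduce the real data's inter-feature correlations, zero-inflation
(insulin, skin thickness) or skewness, so passing tests demonstrate
pipeline correctness and recovery behavior, not clinical performance on
real records. Results on the real PIMA table require the user-supplied CSV
via `replicate_pima`, which is explicitly non-gating: without pretrained
weights, accuracies are not expected to match the published reference
numbers it displays alongside.

## Problem sizes in tests and the acceptance script

Dataset bookkeeping runs at full scale (768 → 3840 images at 120×120).
Deep-learning checks run at reduced scale as a deliberate design choice:
gradient checks on small tensors in float64; the capacity (overfit) check
on 16 images at 32×32 input; the end-to-end approach-3 acceptance run uses
the full 3840 augmented images at 32×32 backbone input with 2 fine-tuning
epochs and ReliefF visits subsampled to 256 rows. The global average pool
makes feature dimensions (512/2048/2560) independent of input resolution,
so the dimension contract is checked at the full 224×224 input.

## Known limitations

- No pretrained initialization offline, so replication of the published
  accuracy table is approximate by construction.
- The numpy backbones are single-threaded CPU code: full-resolution
  fine-tuning of the 3840-image set is possible but slow; the scale knobs
  (`backbone_input_size`, epochs) exist for exactly this reason.
- Missing values are rejected, not imputed; the protocol performs no
  imputation.
- Binary outcomes only, throughout.
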