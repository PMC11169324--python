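# Methods

This note documents the models and procedures implemented in `camval`, the
choices made where the design was genuinely open, and what the synthetic
experiments can and cannot show.

## Problem setting

A binary classifier is trained on 2D montages of stacked grayscale
cross-sectional images (the motivating application is postmortem-CT
drowning diagnosis). The question asked here is not how accurate the
classifier is but whether its *saliency maps* — per-pixel attributions of
the decision — coincide with the regions human annotators mark as the
medically relevant findings. The pipeline therefore couples four parts:
a synthetic data generator with exact ground truth, a classifier, a
gradient-free saliency method, and a consistency/statistics layer.

## Phantom generator

Real postmortem CT is not redistributable, so the generator emulates the
decision-relevant structure of two-class chest data on an 8-bit [0, 255]
scale: a mid-gray body ellipse (~100-120), two dark elliptical lung fields
(base intensity drawn per case from 45-62, tapering toward the stack ends),
and Gaussian noise (sd 4).

Positive (drowning-like) cases carry three bright finding types, merged
into a single truth mask because the downstream evaluation is binary:

| feature | geometry | defaults (fraction of image side) |
|---|---|---|
| consolidation | blurred disks inside a lung, non-touching | 1-3 blobs, radius 0.04-0.08, intensity 120-200 |
| airway fluid | filled disk at the tracheal position, only above the carina (upper half of the stack) | radius 0.035-0.06, intensity 140-200 |
| pleural effusion | crescent along the dorsal lung boundary | thickness 0.04-0.08, intensity 120-180 |

Each instance spans a contiguous run of slices (6-14 of 30) so findings are
coherent through the stack. Negative cases contain zero positive-feature
pixels but show *dry-airway distractors* — sharp bright rings with dark
lumina at the tracheal position and optionally inside the lungs. Sharp
ring edges are exactly the kind of structure a CNN latches onto, so the
distractors keep the saliency assessment from being trivial. Blobs are
placed by rejection sampling with a separation margin; if no position
exists after bounded retries a placement error names the feature.

Everything is a pure function of (config, label, case seed): fixed seeds
give bit-identical volumes.

Simulated annotators replace the human annotation workflow. A profile has
an `area_scale` (target annotated area relative to truth, realized by
thresholding the Euclidean distance transform so the target is hit to
within tie-groups of the distance values), a boundary jitter (smooth
Gaussian random field of a given pixel sd added to the signed distance
before re-thresholding), a per-component omission probability, and an
optional probability of leaving an image empty (empty annotations are
allowed; how often real annotations were empty is not known, so it is a
free parameter defaulting to 0). The default panel has four annotators:
three with `area_scale` 1.0 and one systematic under-annotator at 0.6,
reproducing the interobserver pattern in which one annotator's total
annotated area is significantly smaller than the others'.

## Montages

`select_slices` picks `count` indices at a fixed interval from an offset;
`build_montage` tiles them into one image (vertical = consecutive slices
stacked down a column; horizontal = across a row). Coordinates are
row-major, 0-based, origin top-left throughout — a single stated
convention, because mask/saliency misalignment is the main failure mode of
this kind of artifact. The mapping is exactly invertible and
`project_mask` uses the identical geometry, so montage-level masks conserve
per-slice areas. Montage intensities are min-max normalized to [0, 1] per
montage before entering the model (constant images map to zeros); how the
original study normalized is not stated, and [0, 1] inputs are what
Score-CAM's input-masking step assumes.

Desk-scale defaults: 48-px slices, 30 slices per case, 6 slices at
interval 5 in a 3×2 grid (144×96 montages). Training uses one montage per
case (offset 0); test cases contribute five montages (offsets 0-4), so 30
positive test cases yield 150 annotated images — the same annotated-image
count as the motivating study (25 cases × 6 images). The exact slice count
per montage in the original work is not stated; all of this is config.

## Classifier

Backbone presets are desk-scale stand-ins, not replicas: `tiny` (default)
is three conv(3×3)/BatchNorm/ReLU/maxpool blocks with 8/16/32 channels;
`alexnet_like` widens them; `vgg16_like` uses two convs per block. A
56M-parameter replica is deliberately out of scope. All backbones end in
the same head: global average pooling → FC(h1) → FC(h2) → 2-way softmax.
Two stabilizers address a failure mode specific to small GAP-headed conv
nets on nearly homogeneous images — a long chance-level plateau before the
loss collapses, whose length varies wildly with the random init: (i) the
first layer standardizes each input image to zero mean and unit variance,
and (ii) batch normalization follows every convolution (batch statistics
during training, running averages at inference). With both in place the
plateau disappears and training-loss descent starts in epoch 1 across
seeds. Layer inits are additionally rescaled on a calibration batch to
unit output variance (an LSUV-style step), and as a belt-and-braces
measure a fit whose best validation loss never leaves chance level is
deterministically re-initialized and retrained (at most twice, off by
config); with batch normalization in place this path is not normally
taken.

Training: binary cross-entropy (as 2-class softmax cross-entropy), Adam,
and the legacy additive inverse-time learning-rate decay
`lr_t = lr/(1 + decay·t)` (the stated "decay rate" is ambiguous between an
lr schedule and weight decay; the schedule matches the classic Keras Adam
`decay` semantics contemporary with the referenced models, and L2 weight
decay is available by flag). Early stopping monitors a validation split
held out from the training cases (15%, stratified, seeded — the original
split is train/test only, but early stopping needs a validation set) and
stops once validation loss has not decreased for `patience` epochs,
restoring the best-validation weights.

Two named presets: `paper` (lr 1e-5, decay 1e-6, patience 10) preserves
the published schedule for full-scale networks; the desk default raises lr
to 1e-2 with patience 10, batch 16 and at most 20 epochs, which the
batch-normalized tiny backbone on 48-px phantoms needs to converge within
~10-15 epochs. The implementation is NumPy (im2col convolutions, analytic
backward passes verified against numerical gradients), float32,
single-threaded and bit-reproducible per seed.

Evaluation reports AUC (rank-based), accuracy, sensitivity and specificity
at threshold 0.5 on the positive-class probability (the original threshold
is unstated; 0.5 is the convention), each as the mean over 2000 seeded
case-level bootstrap resamples with percentile 95% CIs. Degenerate
resamples without both classes are redrawn. Evaluation is per montage by
default; per-case aggregation is a caller-side mean over a case's montage
scores.

## Score-CAM and binarization

For the chosen conv layer (default: the last block's ReLU output, the CAM
convention), each channel activation is bilinearly upsampled to input
size, min-max normalized (constant channels → zeros), and multiplied into
the input; the increase of the target-class softmax score over the
all-zero baseline input is softmaxed across channels into weights α_k, and
the map is ReLU(Σ α_k · upsampled activation), min-max normalized. The
target class is the image's true class (predicted-class mode is a flag).
Bilinear upsampling is the CAM-family convention; nearest-neighbor is
available for exact oracle tests. Normalization is per image.

`S_o` is the support of the map above an activation floor (default 0: any
nonzero attention counts — this reproduces the characteristic
|S_o| ≫ |S_h| area relationship; the binarization rule for "original maps"
had to be chosen here). `S_h` applies Otsu's threshold on a 256-bin
histogram over [0, 1] (classic formulation, bin count configurable);
a constant map has no Otsu split and yields an empty, flagged mask.
`S_h ⊆ S_o` holds by construction at the default floor.

## Consistency metrics

IoU, SC = |S∩G|/|S|, GC = |S∩G|/|G|. Conventions: both masks empty →
IoU 1 (agreement on absence); exactly one empty → IoU 0; SC/GC undefined
on empty denominators, carried as missing and excluded from medians with a
logged count — imputing zeros would bias the summary tables. IoU ≥ 0.5 is
"consistent" (boundary inclusive, the detection-benchmark convention).
The algebraic identity IoU = SC·GC/(SC+GC−SC·GC) holds wherever defined
and is used as a cross-check oracle in the tests. Summaries are
per-annotator medians with IQRs plus pooled overall medians, per model and
variant; medians are taken over images (the annotated image is the unit).

The area-ratio analysis reports median and range of |S|/|G|, and
`max_achievable_iou(r) = min(r, 1/r)` gives the IoU ceiling imposed by
area mismatch alone — attained exactly when the smaller mask nests in the
larger, symmetric in r ↔ 1/r. At the empirically observed ratios 2.92 and
0.82 the ceilings are ≈0.342 and 0.82: saliency-vs-annotation IoU cannot
approach 1 regardless of content.

## Statistics

Kruskal-Wallis H (mid-ranks, tie correction, chi-square p) and pairwise
Dunn z tests from pooled ranks with tie correction; p values are two-sided
and uncorrected by default (raw p values are what the motivating analysis
reports), with Holm and Bonferroni behind a flag. Using Dunn's z as a
standalone two-group test is unconventional (it is normally a post-hoc
procedure) but implemented as stated; with two groups H = z² so the two
decisions are monotonically related. The annotation-area analysis uses the
area of each annotation map as the variability index, flags annotators
whose areas are significantly below every other annotator's, and never
excludes them. Bootstrap CIs are seeded percentile intervals.

## Numerical and degenerate-input choices

- Otsu threshold = upper edge of the argmax bin; mask rule is strictly
  greater-than. First maximum wins on ties.
- Min-max normalization of a constant array returns zeros everywhere
  (montage, channel and saliency normalization alike).
- Distance-transform area targeting hits the requested pixel count exactly
  up to ties in the distance values (±a few pixels on typical masks).
- Polygon rasterization sets a pixel iff its center (col+0.5, row+0.5) is
  inside under the even-odd rule; vertices outside the image are clipped
  with a warning. An all-touched mode exists behind a flag.
- Seeds: every stochastic component derives its generator from explicit
  integer seeds via `SeedSequence`; manifests record all of them, and the
  manifest alone reproduces a run.

## Problem sizes

The shipped experiment sizes are chosen so the full suite runs on a single
CPU core: 130+130 cases (100 train / 30 test per class), 48-px slices,
tiny backbone, 150 annotated test images, 2000 bootstrap resamples, and
ten seeded replicate runs for the stochastic classifier property. These
are the package's desk-scale study conditions, fixed once; larger
configurations are plain config changes.

## What passing tests do and do not show

The phantom is deliberately easy to classify (bright, geometrically simple
findings; AUC ≈ 1 for the tiny CNN), has exact ground truth, and its
annotator panel is a parametric caricature of interobserver behaviour.
Passing the suite therefore demonstrates that the *measurement machinery*
is correct — metrics match brute-force oracles, Score-CAM matches its
closed form, thresholds match exhaustive search, statistics are calibrated
under the null — and that the pipeline reproduces the qualitative
phenomena (|S_o| ≫ |S_h|, area-ratio IoU ceilings, detection of a
systematic under-annotator). It does **not** show that any real classifier
is valid or invalid: real CT has anatomy, pathology continua and scanner
physics the phantom does not model, and real annotator disagreement is not
reducible to three parameters. Conclusions about a real system require
running the same machinery on that system's data.

## Known limitations

- No DICOM/Hounsfield physics, no 3D anatomical atlas, no postmortem
  change modelling; phantom intensities are stylized.
- The NumPy CNN is CPU-only and desk-scale; it is not meant to train
  ImageNet-class backbones.
- Dunn's test without correction inflates pairwise type-I error when used
  as an omnibus screen; corrections are available but off by default to
  match the reported analysis style.
- `S_o` at floor 0 counts every nonzero attention pixel; with bilinear
  upsampling this tends to cover most of the image for diffuse maps, which
  is faithful to the "original map" notion but makes S_o-IoU pessimistic.
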