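# Methods

## Problem and model

Facial complexion classification assigns one of five TCM-derived categories
(dark, red, pallid, sallow, normal; ordinal codes 1-5) to a frontal face
photograph.  All three pipelines share the same front end: a 68-point
landmark set in the iBUG convention (jaw 1-17, brows 18-27, nose 28-36,
eyes 37-48, mouth 49-68; 1-based in files, 0-based in memory) is converted
into six rectangular ROIs.  Only the chin construction follows a published
recipe — the bounding box of keypoints 9, 56, 58 and 60.  The other five
boxes are this package's documented conventions (see `complexion.roi`),
chosen to be deterministic, anatomically plausible and mirror-symmetric;
they are conventions, not reconstructions of any particular clinical
segmentation.  Boxes are 0-based and half-open, clipped to the frame, and
only a clip to zero area is an error: the forehead necessarily extrapolates
above the brow landmarks (the 68-point scheme has no forehead points), so
mild out-of-frame extrapolation must be tolerated.

## Backbones

`complexion.nn` is a self-contained numpy CNN engine: plain/grouped
convolutions (im2col + einsum), batch normalisation with running
statistics, SiLU/ReLU/sigmoid, squeeze-and-excitation gates, residual
blocks, max/global-average pooling, linear heads, softmax cross-entropy and
SGD with momentum and L2 weight decay.  Every layer implements an explicit
backward pass (verified against numeric differentiation in the test suite),
so the same engine trains models and runs inference.

Three architectures are registered:

* `efficientnet_b0` — stem conv (3->32, stride 2), the canonical seven
  MBConv stages (expansion 1 or 6, kernels 3/5, SE squeeze =
  block-input/4), head conv to 1280, global pooling.  With its 1000-class
  head it counts 5,288,548 trainable parameters (5.3 M at one decimal);
  the pooled feature is 1280-d regardless of batch size or input-channel
  adaptation.
* `resnet50` — the standard bottleneck residual network; 25,557,032
  parameters with its head.  Note 25.557 M rounds to 25.6 at one decimal;
  the conventional "25.5 M" figure is a truncation, and the package reports
  the truncated convention for this architecture only.
* `tiny` — three stride-2 conv-BN-ReLU blocks to a 64-d pooled feature.
  Fine-tuning a full EfficientNet for tens of epochs is not needed to
  validate pipeline mechanics, so all learned tests and the acceptance
  script train this backbone.

No pretrained weights ship with the package (builds are offline);
`pretrained=True` falls back to seeded random initialisation and nothing
downstream depends on pretrained values.  Four-channel adaptation widens
the first convolution, seeding the added channel with the mean of the RGB
kernels (`init="mean"`) or zeros (`init="zero"`, which provably leaves the
RGB response unchanged); both modes exist because it is genuinely open
which one a fine-tuning setup should use.

Inputs are scaled to [0, 1] and standardised with the usual natural-image
channel statistics; the grayscale channel uses the mean of the RGB
statistics.  Feature extraction runs in eval mode (running BN statistics),
which is what makes embeddings batch-size invariant.

## Training protocol

Defaults follow the study protocol: SGD, learning rate 0.01, momentum 0.9,
weight decay 1e-4, batch size 16, 50 epochs, 224 px inputs, cross-entropy
(the objective is not named in the source protocol; cross-entropy is the
field default).  Backbone and head are optimised jointly.  A shared
backbone (the default; per-ROI backbones are available via
`shared_backbone=False`) caches only its most recent forward pass, so
during backpropagation each earlier ROI branch is re-forwarded before its
gradient is applied — a compute/memory trade that keeps the engine simple.
Training is deterministic for a fixed seed under single-threaded
execution.

Desk-scale settings used throughout the tests and the acceptance script:
`tiny` backbone, 32 px inputs, 15 epochs (6 for stacking base learners),
250 training / 60 held-out samples.  These sizes are the package's choice
of a minimal configuration at which the recovery experiments are already
saturated.

## Splicing transform

Median target sizes are computed per ROI and per dimension (height and
width separately; even counts take the mean of the middle two, rounded half
up).  This preserves "same aspect ratio" only approximately — a known
deviation risk, accepted for determinism.  The composite shape rule
(`w = floor(sqrt P)`, `h = ceil(P/w)`, zero padding, row-major flattening)
is one consistent choice fixed so that an exact inverse exists; the
per-sample `SpliceRecord` stores everything `unsplice` needs.  Pixel
conservation (the non-pad composite multiset equals the resized-crop
multiset) and pad-cell isolation are tested invariants.

## Stacking

Meta features are hard ordinal codes (1-5), not probabilities, matching the
source procedure's wording; probability features would be a one-line
extension but are not the default.  Scaling is min-max to [0, 1] followed
by z-score — two verbs, two steps, in that order, either one can be
disabled.  The z-score uses the sample standard deviation (ddof = 1), the
convention under which the column (1, 3, 5) maps to (-1, 0, 1).  Constant
columns map to zero.  The scaler is always fitted on training rows only and
re-fitted inside every cross-validation fold.

Out-of-fold meta tables are the default: base models are re-trained per
stratified fold so a sample's row never comes from a model that saw it.
The in-sample variant (`out_of_fold=False`), in which trained base models
re-predict their own training images, is retained because it mirrors the
source procedure, but it leaks and should not be used for reported
accuracies.

Seven meta-learners are provided (KNN, decision tree, random forest,
multinomial logistic regression as `linear1`, ridge regression on the codes
with rounding to the nearest valid code as `linear2`, SVM, XGBoost), all
with library-default hyperparameters and fixed seeds; the two linear
variants are stand-ins for an underspecified "linear regression"
classifier.  Cross-validation is stratified k-fold (default 10) reporting
fold accuracies, mean and sd (ddof = 1).

## Evaluation

Per-class P/R/F1 follow the standard confusion-matrix definitions.  0/0
cells are reported as NaN and excluded from the unweighted macro averages
rather than coerced to zero; with small fixtures an absent class would
otherwise drag the macro down artificially.  The paired t-test is the
closed form `t = mean(d) / (sd(d)/sqrt(n))` with ddof = 1 and two-sided p
from the t distribution (n-1 df); identical nonzero differences are a
degenerate-variance error rather than an infinite statistic.  Paired
Cohen's d is `mean(d)/sd(d)` with the conventional large-effect flag at
d > 0.8.  ROI correlation is plain Pearson r on raw code columns, reported
in [-1, 1]; an `absolute()` view exists for heatmaps drawn on a 0-1 scale,
since a correlation coefficient itself cannot "range from 0 to 1".
Constant columns yield undefined (NaN) entries.  ROI importances are the
boosting model's gain importances normalised to sum to one.

## Synthetic generator

`complexion.synthetic` renders schematic faces: flat background, skin-tone
ellipse, then each ROI box filled with a per-class, per-ROI palette mean
plus i.i.d. Gaussian pixel noise (sd 8 by default), at 256 px (desk scale;
crops are resized before use anyway).  Landmarks come from a canonical
frontal template scaled to the frame with Gaussian jitter (sd 1.5 px) and
clipping; the template's six ROI boxes are pairwise disjoint, so painted
colours do not bleed between regions.  Class identity is carried purely by
ROI-local colour shifts — full strength in nose, forehead and cheeks, one
quarter strength in chin and philtrum (those two regions share similar
colour characteristics in clinical practice).  Palette means are rounded to
integers so zero-noise renders equal the palette exactly.  The default
composition is 131/134/168/160/128 (721 samples).  Everything is a pure
function of (config, seed): same seed, byte-identical files.

What the generator does **not** emulate: texture, gloss, illumination
gradients, pose, occlusion, landmark-detector noise, inter-patient anatomy
and class overlap.  Passing recovery tests therefore demonstrates that the
pipelines correctly extract, route and combine region-local colour signal —
the mechanism they were designed around — not that clinical accuracy would
reach any particular level.  The `separation` dial of `default_palette`
scales all class shifts toward a common tone; at zero all classifiers drop
to chance (1/5), which the test suite verifies along with monotone accuracy
in separation.

## Numerical choices and degenerate inputs

* float32 throughout the engine; BN eps 1e-5, running-stat momentum 0.1.
* Bilinear resizing (Pillow) for crops and composites.
* Round-half-up (`floor(x + 0.5)`) wherever a midpoint rule is needed
  (stratified split sizes, median sizing), for platform-independent
  determinism.
* Stratified splitting is the default (the printed class ratio survives the
  split); flipped copies inherit the original's split so a flip pair can
  never straddle train and test.
* Degenerate inputs fail loudly: unknown labels/ROIs/architectures list the
  valid names, empty manifests and single-class training sets are errors,
  zero-area ROI boxes name the offending ROI, and landmark validation
  returns a full failure report instead of raising on the first problem.

## Known limitations

* Five of six ROI constructions are package conventions; absolute box
  agreement with any clinical pipeline is not claimed.
* The engine is CPU/numpy: fine for the tiny backbone and for inference
  through B0, but not a practical substrate for 50-epoch B0 fine-tuning.
* `linear2` (rounded ridge) is an interpretation, as is the exact splice
  output-shape rule; both are documented where defined.
* Synthetic recovery accuracies are ceiling-level by design and are not
  comparable to accuracies obtainable on clinical photographs.
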