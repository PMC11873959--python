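# Methods

This note documents the models, the synthetic benchmark, the numerical
choices and the known limitations of `longchange`, in the spirit of a
package methods appendix. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The comparison model

**Architecture.** Both images of a within-subject pair pass through one
shared feature extractor: four convolutional blocks, each a same-padding
stride-1 convolution (default kernel 3), per-channel batch normalization,
leaky ReLU (slope 0.01) and a non-overlapping /2 pooling layer. Default
channel widths are (8, 16, 32, 32); with these defaults a 3D extractor
sits at the ~10⁵-parameter scale, deliberately lightweight so volumes fit
desk-scale hardware. Average pooling is the default for comparison models;
the single-image regression baseline defaults to max pooling, where it
performs better. The final pooled activation grid — input size divided by
16 per axis, e.g. 64 px → 4×4, 128³ voxels → 8×8×8 — is flattened into the
feature vector and retained for localization.

**Head.** The flattened features (plus optional metadata covariates,
concatenated per branch) are differenced and scored by a single linear
layer *without* a bias term: `r = wᵀ(φ₁ − φ₂)`. Reflexivity, antisymmetry
and additive transitivity of `r` then hold for any weights, trained or
not, because `r` is linear in the branch difference; the test suite
asserts them to within float32 rounding (tolerance 10⁻⁴ × max |r|, several
orders looser than the observed violations).

**Tasks and losses.** `ordering` trains binary cross-entropy on σ(r)
against the label "presented order is chronological"; `interval` and
`score` train squared error of `r` against the presented-order time or
target difference. Each unordered pair enters each epoch once with a
freshly randomized presentation orientation, keeping labels balanced in
expectation while halving cost relative to emitting both orders; because
the head is antisymmetric the two orientations are informationally
redundant, and a `both_orders` flag provides exact balance where wanted.

**Optimization.** Adam with standard defaults (β = 0.9/0.999, ε = 10⁻⁸, no
weight decay) at learning rate 10⁻³. Early stopping halts training after
`patience` (default 10) consecutive epochs without a new best validation
loss; minimum validation loss selects the restored weights (ties →
earliest epoch), while validation AUC/R² is logged alongside for
inspection. Batch-norm statistics are shared across branches (both images
of a batch run as one forward pass); all inference uses running statistics
and is therefore deterministic per image and independent of batch
composition. An optional curriculum for hard regression problems starts
with pairs separated by more than a threshold (e.g. 50 time units),
decaying linearly to zero by one step every 2 epochs across a 10-epoch
warmup; an epoch left empty by the filter relaxes the threshold one step
with a warning.

**Input normalization.** Per-image min–max rescaling to [0, 1]; robust
across modalities and intensity drifts. Constant images map to zero.

**Single-image baseline (SIRB).** The same extractor family feeds a linear
head *with* a bias that predicts the target (e.g. age) from one image;
pair change is the difference of the two predictions. Metadata, when
present, is concatenated to the features before the output head.

## Localization

Because features are flattened rather than globally pooled, channel-level
Grad-CAM importance collapses to an element-wise rule. For the chosen
branch, the gradient of the presigmoid score `r` with respect to that
branch's final activation grid (the other branch fixed) is multiplied
element-wise with the activations, summed over channels, then rectified —
ReLU after the channel sum, matching the original Grad-CAM placement; with
the linear head this gradient is exactly ±`w` reshaped to the grid. The
coarse map is upsampled bi/trilinearly for overlays; nearest-neighbour
(exact block) upsampling is used wherever peak indicators are counted.
Peak ties break to the lowest linear index. Maps are normalized to [0, 1]
only for overlay rendering, never before averaging peak indicators.

**Orientation convention.** Quantitative localization uses each subject's
maximum-interval pair presented chronologically (first-to-last scan) with
the map read on the later image's branch. The rectified map keeps
contributions aligned with *increasing* r; under chronological
presentation those are the regions carrying evidence that the second image
is later — i.e. where change has accumulated. On a reversed pair the same
rectification would instead surface "evidence of earliness" (absence
regions), which is well-defined but not the change map a reader wants.

**Explainability gating.** Each case carries
`τ = 1 − (y − ŷ)²/(y − ȳ)²`, with `ȳ` the training-set target mean — a
per-sample analogue of R², and an Efron-style pseudo-score for the binary
task (there `ŷ = σ(r)`). `τ` is undefined when `y = ȳ`; such cases return
NaN and are excluded from gated outputs. Population peak maps use one pair
per subject (the maximum |Δt| pair), keep cases with τ > 0.7, place a 1 at
each coarse-grid peak, block-upsample and average.

**Oracle for validation.** Tests validate Grad-CAM peaks against an
occlusion-sensitivity oracle: slide a mean-filled patch over the image and
record |Δr|. Mean filling (not zeros) is required because a zeroed patch
would shift the per-image minimum and perturb the global normalization.
The oracle localizes at patch resolution with one cell of smear — a coarse
cell's receptive field (~46 px at 64-px inputs) extends well past its
aligned 16-px block — so the oracle's region is defined as the argmax
patch plus its 8-neighbourhood, and agreement means the Grad-CAM peak
falls inside it.

## Statistical evaluation

- **AUC**: tie-aware rank statistic (Mann–Whitney, half credit for ties);
  a constant scorer on balanced labels yields exactly 0.5, the naive
  baseline for ordering. Percentile bootstrap CI from 1,000 resamples of
  the test set with replacement; single-class resamples are redrawn.
  Percentile (not BCa) intervals match the plain resampling design.
- **Regression**: RMSE/MAE/R² against the always-zero baseline, which is
  the target mean when pair orientations are randomized symmetrically.
- **Correlation**: Pearson r between truth and prediction on
  chronologically ordered pairs only (the antisymmetric score makes
  reversed pairs redundant and their inclusion would inflate r); for the
  ordering task the presigmoid logit is the prediction. p-values below
  1e−16 are printed as "<1e−16".
- **Mixed model**: changes anchored at each subject's first timepoint are
  zero at t = 0 by construction, so the model has no intercepts:
  `change = (β + γ·group + b_subject)·t + ε`, `b ~ N(0, σ_b²)`, fitted by
  maximum likelihood (statsmodels MixedLM; BFGS with a Powell fallback).
  The random-slope LRT compares against a no-random-effect OLS fit and
  uses the boundary-corrected null `0.5·χ²₀ + 0.5·χ²₁`, since σ_b² is
  tested on the edge of its parameter space. The group LRT compares ML
  fits with and without the group×time term (both retaining the random
  slope), referred to χ²₁. Fewer than 3 subjects is an error;
  non-convergence is flagged on the result.

## The synthetic benchmark

The generator emulates the *structure* of longitudinal imaging studies
while staying fully controlled:

- **Change process.** Each subject draws a rate from
  N(mean + group·effect, sd) (default mean 1.0 px per frame, sd 0.15,
  clipped away from zero); the state `rate · t` drives a centred bright
  disk's radius (base radius = image_size/8). A `division` variant doubles
  a blob count at integer state thresholds, emulating cleavage-stage
  development. States are strictly increasing whenever the rate is
  positive, so ordering is learnable in principle and the true rate is
  recoverable from noiseless renders by measuring the object.
- **Confound process.** Optionally, a disjoint corner square shrinks at a
  rate common to all subjects — a pure function of time. In the
  metadata-controlled setting the target y is the subject-specific disk
  state while metadata supplies (t, sex·t) per timepoint; their in-model
  difference hands the network the interval directly, so only the
  disk region carries signal beyond the covariates. Geometry is validated
  at configuration time: an object that could outgrow the field of view,
  or overlap the confound region, raises a sizing error.
- **Nuisance.** Per frame, independent of the frame index: rotation
  (uniform, default ±5°), translation (default ±2 px), multiplicative
  intensity drift (default ±5%) and additive Gaussian noise (default
  sd 0.02). Carrying no ordering information, these must be ignored by a
  correct model and are used to check that nuisance draws are uncorrelated
  with time.
- **I/O.** 2D frames are written as 32-bit float TIFF (lossless — 8-bit
  PNG would quantise the [0, 1] intensities), 3D volumes as NIfTI-1 with
  an identity affine, plus a CSV manifest (subject, time, path, target,
  group, `meta_*` columns) and a JSON ground-truth sidecar. Cohorts are
  bit-identical for identical config + seed; a partial write is rolled
  back before the error propagates.

**What the benchmark does not emulate**: photorealistic texture,
deformable anatomy, irregular visit schedules, missing data, or label
noise. Passing tests demonstrate that the machinery is correct and that
the method recovers known signal under controlled nuisance — not that any
particular clinical effect size is detectable in real data.

## Desk-scale study sizes

All shipped experiments are sized for a single CPU. The ordering
experiment uses a 100-subject cohort (60/20/20 subject-wise split at the
standard 0.6/0.2/0.2 fractions), 12 frames per subject at 64×64, with a
per-subject cap of 16 training pairs and at most 10 epochs; interval and
score experiments use 60- and 40-subject cohorts with caps of 12 pairs.
The mixed-model calibration study simulates 24-subject cohorts (12 per
arm, 6 timepoints) with β = 1.0, γ = 0.4, σ_b = 0.2, σ_ε = 0.5 over 200
replicates; recovery checks use 60 subjects with tighter noise
(σ_b = 0.15, σ_ε = 0.3), where one standard error on γ is well inside a
20% relative band.

## Known limitations

- Images within a run must share a grid; 3D volumes are assumed
  co-registered by the user. Registration, skull stripping and other
  modality-specific preprocessing are out of scope.
- The saliency map inherits the coarse grid's resolution (1/16 of input
  per axis) and, like any rectified gradient map, shows positive
  contributions to `r` only; it is gated by τ precisely because it is
  meaningless when the prediction is poor.
- Training is single-device and the engine favours clarity over
  throughput; large 3D cohorts will be slow compared to GPU frameworks.
- The mixed model assumes linear subject trajectories; strongly nonlinear
  change (e.g. non-monotonic clinical scores) is captured by the network's
  pair scores but not by the slope analysis layered on them.
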