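# Methods

## Synthetic stimuli

The generator renders schematic luminance "faces" on an RGB canvas
(reference size 562 × 762 px; width, height): a soft-edged head ellipse
with a mild vertical shading gradient and a skin tint, plus localized
features at fixed fractional positions — eye rectangles centered at
(0.345, 0.40) and (0.655, 0.40) of the canvas, nose at (0.50, 0.565),
mouth at (0.50, 0.715).  Feature rectangles are sized so the default
162 × 63 occlusion box (specified on the reference canvas and rescaled
proportionally to any working canvas) fully covers the feature it is
centered on.

The two class prototypes share the layout and differ in feature
appearance.  The class-diagnostic signal is deliberately concentrated in
the eye region: the Caucasian-like prototype carries wide, high-contrast
dark eye bars (amplitude 0.55), the Asian-like prototype narrow faint
ones (0.10) plus a slightly stronger nose ridge (0.11 vs. 0.06); the
mouth differs only marginally (0.21 vs. 0.20) and each prototype carries
a small opposite-signed blue tint inside the eye boxes.  This eye-heavy
placement mirrors where human observers concentrate when judging face
ethnicity and is what gives the occlusion experiment its contrast: hiding
the eyes removes nearly all class evidence, hiding the mouth removes
almost none.  Per-seed wobble (±6% on amplitudes, plus faint pixel
texture) makes different seeds produce visibly different prototype pairs
while keeping the layout fixed.

Morphing is pixel-wise linear: the image at morph coordinate t is
(1 − t)·A + t·B, with 21 evenly spaced levels on [0, 1] by default, so
endpoint images equal the prototypes exactly and the morph coordinate is
the x-axis of every psychometric plot.  What the generator does **not**
emulate: photorealistic texture, geometric (warp-based) morphing,
identity variation within a class, or any ethnicity-specific appearance
statistics.  Passing tests therefore demonstrate the correctness and
internal consistency of the measurement pipeline, not that any
conclusion transfers to photographs of real faces.

Training corpora are balanced by construction (n per class, identical
counts in the train and validation splits) and jitter each prototype with
an integer translation (±3 px), a geometric rescale (0.97–1.03, center
crop/pad), and additive Gaussian noise (SD 0.05), clipped to [0, 1].

Simulated observers draw individual PSEs from a normal distribution with
the benchmark mean (0.362) and standard deviation sem·√n (sem = 0.012,
n = 30), so the sample's expected standard error equals the published
SEM.  Two-alternative forced-choice sessions are Bernoulli draws from a
logistic curve at the observer's PSE (default slope 10, a mid-range
steepness on the unit morph axis), 21 levels × 20 repetitions = 420
trials per observer.

## Stimulus disruptions

Grayscale uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114) and
replicates the luminance plane to three channels; already-gray input is
returned unchanged, making the operation exactly idempotent.

Luminance equalization matches the first two luminance moments across a
stimulus set — each image is affinely rescaled so its luminance mean and
SD equal the across-set averages — preserving within-image rank order.
This is a deliberate minimal reading of histogram-equalization toolboxes
used for face stimuli: matching mean and SD only is exactly testable and
is all the downstream analysis relies on.  Outputs are clipped to [0, 1]
with the clipped-pixel count reported; zero-variance inputs are set to
the target mean and flagged.

Coordinates are 0-based, x right, y down; rectangles are half-open
integer boxes [x0, x1) × [y0, y1).  Occlusion boxes (default 162 × 63;
small 90 × 35; large 216 × 84) are centered on feature centers — the
published protocol specifies sizes but not coordinates, and centering is
the placement that guarantees "covers the named feature".  "Both eyes"
places one box per eye (two 162 × 63 boxes); a merged bounding box is
available behind a flag since the published phrasing does not
disambiguate.  Masks set pixels to exact 0 and are applied **after**
luminance equalization, mirroring the published order (test sets
equalized first, masks added per condition).  Masking and visibility are
exact complements: `occluded + visible_only == original` pixel-wise.

Resolution rescaling is bilinear; layout rectangles scale by
(target/source) independently per axis with rounding to the nearest
pixel, so a 162 × 63 box on 562 × 762 becomes 65 × 19 at 224 × 224.

## The reference classifier

Because the analysis only needs class scores, named stage activations,
and gradients of a class score with respect to those activations, the
reference model is a deliberately small numpy CNN: five blocks of
(3 × 3 same-padding convolution, ReLU, 2 × 2 max pool) with channel
widths (8, 12, 16, 16, 16), global average pooling, and a 2-way linear
head.  Pool outputs are the five probe stages; the GAP head makes the
classical CAM construction applicable at the final stage.  Convolution is
im2col-based; all backward passes are hand-written and are verified
against central finite differences of the class score (relative error
< 1e-4 in tests, observed ~1e-8).  Weights use kaiming-normal fan-in
initialization; inputs in [0, 1] are centered to [−1, 1] before the first
block — without centering, the all-positive input correlates first-layer
gradients and short training runs stall at chance on some seeds.

Training is softmax cross-entropy with Adam.  The full-scale default
configuration is batch 32, learning rate 5e-5, 60 epochs; the desk-scale
configuration used by every run in this repository is batch 16, learning
rate 1e-2, 5 epochs (the tiny network needs the larger step to converge
inside 100 gradient steps).  Augmentation is a random crop to 90–100% of
the frame resized back, plus a fair-coin horizontal flip; at 48 × 48 the
eye bars are only ~3 px tall, and more aggressive crops (e.g. to 80%)
destroy the positional regularity a 5-epoch run needs.  The checkpoint
with the highest validation accuracy is kept, ties broken toward the
earlier epoch.  The optimizer and loss are this package's choices
(recorded in the configuration, hence swappable); the published protocol
names neither.  The seven published large architectures appear only as a
stage-name registry for adapting user-supplied weights; no pretrained
weights ship and nothing in the tests depends on them.

Experiments run on a quarter-scale canvas (140 × 190) with a 48 × 48
network input; the box geometry stays anchored to the reference canvas
and rescales proportionally.  Corpus size 200 per class (80/20 split).
These sizes give training runs of ~15 s and full three-experiment runs of
~30 s while leaving every geometric relation of the full-scale design
intact; the full 562 × 762 arithmetic is exercised directly in the
stimulus-module tests.

## Psychometric analysis

Model response curves are deterministic softmax probabilities of the
Asian class, one per level ("transformed predicted probability" is read
as exactly this, with no further transform).  Observer curves collapse
Bernoulli trials to per-level proportions.  Both are fitted by least
squares with the 2-parameter logistic; lapse parameters are omitted
because they are not identifiable at 21 × 20 trials.  The fitter tries
several curve-fit starts (0.5-crossing interpolation for the PSE, both
slope magnitudes) and falls back to a coarse grid for pathological
curves, so a decreasing or out-of-range best fit is still found and then
rejected by the gate rather than erroring.

The validity gate reports a PSE only when the curve is non-degenerate,
rising (β > 0), adequately fit (R² ≥ 0.5), and crosses 0.5 inside the
morph axis (PSE ∈ [0, 1] — the "large bias" discard).  Thresholds are
configuration values with these defaults; the published discard rule is
qualitative, and these are the weakest quantitative criteria that
reproduce its observed pattern.

t tests are one-sample and two-tailed against the human group (df = 29)
at α = 0.05.  Bonferroni families follow the published tables: the
color/grayscale experiment corrects over all attempted comparisons
(family 14 at full scale = 7 networks × 2 conditions), the occlusion
experiment over valid comparisons only (family 22 = its non-discarded
rows).  Both policies are selectable per experiment; feeding the printed
t values through this exact path reproduces every finite printed
corrected p to within 0.001, which is how the family sizes were pinned
down.  The printed t values imply the original test used unrounded human
statistics (mean ≈ 0.3618, SEM ≈ 0.0117), so checks against printed rows
use a 0.05 tolerance on t while p values are compared at 0.001.

## Activation maps and attention metrics

The canonical GAP-head CAM (class-specific head weights w^c_k) is the
primary form; a literal self-weighting variant (channel weights equal to
each channel's own spatial mean) exists behind a flag for fidelity
experiments but cannot produce class-discriminative maps.  Gradients are
taken on the pre-softmax class score.  Grad-CAM and LayerCAM carry the
outer ReLU; LayerCAM additionally clips gradients element-wise before
weighting, which is what keeps it informative at early high-resolution
stages — at the final 1 × 1 stage both reduce to scalars and the
normalized map is degenerate (flagged constant).  Stage maps are
bilinearly upsampled to input resolution and min–max normalized; maps are
invariant to positive rescaling of the gradients after normalization.

Attention metrics quantify a map's allocation over the known layout:
per-feature overlap (map mass inside the feature box / total mass),
map-weighted centroid, and left–right asymmetry
(left-half mass − right-half mass)/total ∈ [−1, 1], with all-zero maps
flagged undefined.  The asymmetry metric is this package's own
operationalization of lateral-bias claims; no published value is asserted
for it.  The "dominant feature" used by the end-to-end checks pools the
two eye boxes and takes the argmax overlap of the **Caucasian-class**
LayerCAM at stage 2 on the level-0 (Caucasian-prototype) image: the
evidence for that class is dark localized eye bars, so its map is
spatially concentrated, whereas the Asian-class evidence is feature
*absence* and its maps are diffuse.

## Numerical and procedural choices

- All randomness flows from one root seed through named sub-seed streams
  (data, training, observers), keeping every derived seed below 2^31;
  reports are bitwise reproducible (CSV byte equality is asserted in
  tests).
- Mirror-equivariance of the map formulas is exact in exact arithmetic;
  tests compare at 1e-12 because summing over a reversed axis changes
  floating-point association order.
- Monte-Carlo checks are scaled to keep the suite fast: parameter
  recovery uses 200 simulated observers (bias |mean error| ≤ 0.005, MAE
  ≤ 0.02 at 21 × 20 trials), the SEM ~ 1/√n scaling law is verified on
  the observer generator over n ∈ {10, 30, 90} × 200 replicates, and the
  trial simulator is checked against its generating curve at 500
  repetitions per level.
- The 30-observer group-recovery check ("group mean within 2 SEM of the
  generating mean") is by construction a ~95% event over seeds; the test
  fixes a seed, and the acceptance script reports the recovered values at
  whatever seed it is given rather than asserting the interval.

## Known limitations

- The human benchmark constants are exogenous: nothing here validates
  0.362/0.012, and PSE magnitudes measured on schematic stimuli have no
  calibrated relation to those measured on photographic morphs.  The
  desk-scale CNN's PSE (~0.5–0.65 depending on seed) accordingly differs
  from the human mean by tens of SEMs, and the headline published
  finding — a particular large architecture being statistically
  indistinguishable from humans — is out of reach without those
  architectures and their training corpus; this package reproduces the
  qualitative disruption signature instead (valid clean curve, collapse
  under dominant-feature occlusion, collapse under feature-only input).
- The equalization step matches two moments, not full histograms or
  amplitude spectra.
- Single-image (not batched) evaluation dominates pipeline runtime; the
  reference CNN is not intended to be fast, only transparent.
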