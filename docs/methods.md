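# Methods

## The problem and the model

`seedpoint` counts and localizes seeds in RGB images of individual plants
using only dot annotations — one (x, y) coordinate per seed — instead of
bounding boxes or density maps. The network is a point-to-point design: a
fully convolutional trunk produces a feature map on a stride-8 grid; every
grid cell carries K candidate ("reference") points; a regression branch
predicts a pixel offset per candidate and a classification branch predicts a
confidence in [0, 1]. The final prediction is the set of decoded points
`reference + offset` whose confidence clears a threshold, optionally
followed by fixed-radius duplicate merging.

Training assigns candidates to ground-truth dots by exact minimum-cost
one-to-one (Hungarian) assignment with cost

    cost(i, j) = ||p_i − g_j||₂ − τ · s_i

where `p_i` is the decoded candidate, `g_j` a ground-truth dot and `s_i` the
candidate's confidence. Matched candidates are positives for a weighted
binary cross-entropy; the regression loss is the mean squared Euclidean
distance over matched pairs; the total is `L_cls + λ · L_reg`. Matching
requires labels, so it exists only in the training path.

### Feature extraction and fusion

The trunk is a VGG-16-layout backbone (blocks of 2, 2, 3, 3, 3 stride-1
3×3 convolutions with ceil-mode 2×2 max pooling after blocks 1–4). The last
convolution of each block is tapped, giving low-level maps at strides 1 and
2 and high-level maps at strides 4, 8 and 16. Widths (64, 128, 256, 512,
512) scale by a `width_multiplier` (floored at 8 channels) so a tiny
CPU-trainable variant exists; 1.0 reproduces the standard widths.

Fusion applies, per tapped map and per configuration flags:

- **MSMR** (multi-scale, multi-reception-field): parallel 3×3 atrous
  branches at dilation rates 1, 3, 5, 7 (a rate-d branch spans
  3 + 2(d−1) pixels, so 3/7/11/15), concatenated and projected back to the
  input width by a 1×1 convolution. Branches and projection are linear; the
  nonlinearity follows the block, so a single-rate block with an identity
  projection is exactly one plain convolution — a property the tests use as
  an oracle.
- **Spatial attention** on low-level maps: channel-wise mean and max maps,
  concatenated, one 7×7 convolution, sigmoid; the input is multiplied by
  the resulting [0, 1] gate. The statistics map is replicate-padded so a
  spatially constant input yields a constant gate (zero padding would break
  that symmetry at borders).
- **Channel attention** on high-level maps: squeeze-and-excitation — global
  average pooling, a bottleneck of ratio 16 (floor 1), sigmoid per-channel
  weights in [0, 1].

Each selected map is projected to `fused_channels` by a 1×1 convolution,
bilinearly resampled to the stride-8 grid (half-pixel-center convention)
and summed. With the original-image residual enabled, the normalized input
image is resampled to the same grid, passed through a 1×1 projection and
added — the network then literally learns a residual on top of the raw
image. The fused map's spatial size depends only on the input size and the
fusion stride, never on the flags.

Seven presets form the ablation ladder: `p2pnet` (high-level features only,
no postprocessing), `update1` (same, with postprocessing), `update2` (+
low-level), `update3` (+ MSMR), `update4` (spatially attended low-level in
place of plain), `update5` (+ original image), `update6` (+ channel
attention on high-level). In `update4`–`update6` the attended low-level maps
replace the plain ones rather than being added alongside.

### Postprocessing

A k-d tree links every pair of predictions within a merge radius; connected
components of that graph each collapse to one point at the score-weighted
centroid, carrying the component's maximum score. This is transitive:
chained components merge into one point. Radius 0 is special-cased to the
identity (a literal "distance ≤ 0" rule would still fuse exactly coincident
points). The k-d tree is an accelerator only — tests assert exact agreement
with an O(n²) pairwise-linking implementation. The default radius is half
the configured nominal seed diameter, so merging collapses duplicates while
staying below typical seed spacing.

### Evaluation

Counting: per-image absolute error and its mean (MAE), plus R² taken as the
squared Pearson correlation between predicted and true counts (identical to
regression R² for a fitted line, which is how such scatter plots are
usually summarized). R² is reported as NaN with a warning for fewer than
two images or zero variance. Localization precision/recall/F1 at a distance
threshold (one-to-one Hungarian matching on distance) is an auxiliary
metric for synthetic experiments only.

## Implementation notes

The network, reverse-mode automatic differentiation, convolution / pooling /
bilinear-resampling kernels and the Adam optimizer are implemented directly
on NumPy (`seedpoint._nn`), in float32, NCHW, batch size 1. Convolutions
are stride-1 tap-loop matmuls (spatial reduction happens only in ceil-mode
pooling, which preserves the `ceil(H / stride)` contract for odd sizes).
Analytic gradients of every op are verified against central differences in
the test suite. Classification trains on logits through a numerically
stable weighted binary cross-entropy. scipy provides the Hungarian solver
(`linear_sum_assignment`), k-d tree and distance matrices; Pillow reads and
writes images.

Numerical/design choices where the design was genuinely open:

- **Initialization**: He-normal from a seeded generator; there is no
  pretrained backbone initialization in this package. Runs are bit-for-bit
  reproducible given the config and seed on one device.
- **Loss constants**: τ = 0.5, λ = 2e-4, negative-class weight 0.5 in the
  weighted-mean BCE (normalized by the sum of weights, so the all-equal
  case reduces to the plain mean). All configurable.
- **Heads**: K = 4 candidates per cell on a 2×2 sub-grid inside the cell
  (K = 1 is the cell center; non-square K falls on the cell diagonal);
  two 3×3 convolutions plus a 1×1 output convolution per branch; inference
  score threshold 0.5.
- **Decoding**: decoded points may leave the image during training
  (matching handles them); they are clipped to the image only at export.
  Output is sorted by descending score with ties broken by (y, x).
- **Optimizer**: Adam, learning rate 1e-4 for fusion and heads and 1e-5
  for the backbone, batch size 1 (the simplest correct choice with
  variable-size images). Divergence (non-finite loss or proposals) aborts
  with the offending epoch/step and image named.

## The synthetic data generator

The generator emulates the statistical hazards of field imagery — not its
appearance. Each image contains: a textured background (low-frequency
mottling, grain, and a few stem-like streaks); annotated seeds rendered as
anti-aliased shaded ellipses in the central zone; and unannotated
*distractor* seeds in the left/right margin strips, standing in for
neighboring plants that appear in pixels but never in labels. Defaults:
256×256 images, 20–80 seeds per image, seed radius 6 ± 1.5 px across images
(a per-image "accession" size factor giving roughly a two-fold diameter
range, the variation the MSMR block targets) plus 0.8 px per-seed noise,
overlap level 0.3 (the fraction of seeds placed within one diameter of an
earlier seed), distractor rate 0.15 per annotated seed, and background
texture 0.5.

Blobs are rasterized in z-order: later blobs overdraw earlier ones, and a
label map records per-pixel ownership. A seed is annotated only when at
least 10 % of its area survives overdrawing (the one-tenth-visible
annotation policy); occluded-below-threshold seeds remain in the per-image
metadata, so tests can verify count conservation exactly. Distractors draw
from random streams independent of the seed streams, so changing the
distractor rate changes pixels but never the annotations. Seeds that cannot
be placed within the rejection-sampling budget are dropped and the count
recorded truthfully.

What the generator does *not* model: photorealistic plant structure, pods,
leaves and self-shading, lighting variation, perspective, or front/back
view-pair consistency. Passing tests therefore demonstrate that the
architecture, objective, postprocessing and evaluation machinery are
correct and that the model can learn the counting task under controlled
hazards — not field-level accuracy on real plants, which depends on real
data and full-width GPU training.

## Problem sizes used in tests and the acceptance script

The shipped experiments use the tiny variant: width multiplier 0.125
(8–64 channels), 32 fused channels, K = 4, 30 training and 10 held-out
synthetic 128×128 images with 8–30 seeds each, 50 epochs at batch size 1 —
a configuration chosen so the full train-and-evaluate cycle completes in a
few minutes on one CPU core while still showing clear learning: the final
training loss falls below half its initial value and held-out MAE beats the
predict-zero baseline by more than 2×. The duplicate-merging experiment
decodes at a permissive threshold (0.25), where the raw output over-counts
(~1.6× truth); fixed-radius merging at the default radius reduces MAE —
the qualitative direction the postprocessing stage exists for.

## Known limitations

- No pretrained weights and no GPU path: full-width training at field
  image sizes is out of practical reach of this NumPy implementation.
- Batch size is fixed at 1; there is no data augmentation enabled by
  default (flips/crops would be straightforward additions).
- The merge radius is a single global parameter; images mixing very
  different seed scales would benefit from a per-image radius.
- R² on small synthetic held-out sets is noisy and is not asserted by the
  test suite; MAE is the primary metric.
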