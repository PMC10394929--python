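# Methods

## Problem and pipeline

A single wheat ear photographed from one side shows its grains in two
staggered columns along the rachis. The package estimates grain number per
spike from such photographs in three stages: per-pixel grain/background
segmentation, separation-and-counting of the segmented grains, and a
whole-spike count rule (Method I: double one side; Method II: sum both
sides). The chief difficulty is *adhesion*: neighboring grains touch in the
image, so segmented grains merge into blobs and a naive component count is
biased low.

## Segmentation network

The network is a four-stage high-resolution architecture. A stem of two
stride-2 3×3 convolutions (64 channels) brings the input to 1/4 resolution;
a stage of four bottleneck blocks widens it to 256 channels; three further
stages run 2, 3 and 4 parallel branches (1, 4 and 3 modules respectively, 4
residual blocks per branch per module) whose widths double as resolution
halves — 32/64/128/256 for the w32 variant, 18/36/72/144 for w18. Each
module ends with full cross-resolution fusion (1×1 projection + bilinear
upsampling toward higher resolution; chains of stride-2 3×3 convolutions
toward lower). The representation head bilinearly upsamples all branches to
the top resolution, concatenates them (480 channels for w32, 270 for w18),
fuses with a 1×1 convolution + batch norm + rectifier, classifies with a 1×1
convolution, and upsamples the logits to the input size (bilinear,
align-corners false throughout). Convolutions are bias-free except in the
head; batch normalization uses momentum 0.1 and eps 1e-5.

Instantiated for 2 classes the w32 network has 29,538,338 learnable scalars;
with the 21-class classifier head that the publicly distributed pretrained
configuration ships, the total is 29,547,477 (29.547 M). Both numbers are
verified against an independent closed-form layer enumeration in the test
suite; `scripts/acceptance.py` reports the published-configuration count.

### Attention gates

With `cbam_enabled`, CBAM gates are placed where the head resamples: one on
each lower-resolution branch immediately before its upsampling, plus one on
the concatenated representation before the fusion convolution. A gate first
weights channels with `sigmoid(MLP(avgpool) + MLP(maxpool))` — a shared
bias-free two-layer perceptron with reduction ratio r = 16 and a rectifier
between the layers — then weights positions with a 7×7 convolution over the
stacked channel-wise (max, mean) planes. Channel attention is always applied
first. This standard configuration adds 39,944 parameters to the w32 head;
the attention mechanism's parameter cost is not separately calibrated
against any external total, and the per-gate counts are asserted exactly in
the tests.

Because no deep-learning framework is assumed, the network runs on
`spikecount.nn`, a reverse-mode autodiff engine over numpy arrays
(im2col convolution, batch norm with train/eval statistics, bilinear
resampling with exact adjoints, softmax cross-entropy). Every operation's
gradient is checked against central finite differences at 1e-7 relative
tolerance in the test suite.

## Training schedule

Transfer-style two-phase training: epochs [init, 50) freeze the backbone
(only head parameters are optimized; batch 16), epochs [50, 300) train all
parameters (batch 8). The optimizer — Adam (lr 5e-4, weight decay 0) or SGD
(lr 4e-3, momentum 0.9, weight decay 1e-4) — is re-created at the boundary
because the parameter groups change. The loss is mean per-pixel softmax
cross-entropy over the two classes. The test partition doubles as the
validation set; this mirrors the original protocol but is methodologically
weak (model selection and evaluation share data), so both training and
validation mIoU are logged per epoch and the caveat is noted here. Training
is bit-deterministic given (seed, config): weight initialization, shuffling
and all kernels are seeded numpy operations.

Batch-norm running statistics are buffers, not parameters; the frozen-phase
guarantee ("backbone bit-identical") covers learnable parameters, while
running statistics continue to track activations in both phases.

## Counting model

Stages, with defaults: luma grayscale (0.299 R + 0.587 G + 0.114 B) →
binarize at threshold 120 (strictly greater-than; a pixel exactly at 120 is
background) → one erosion with a 3×3 square element → exact Euclidean
distance transform to the nearest zero pixel → divide by the image maximum
(identically-zero maps pass through) → re-binarize at α = 0.4 → opening with
a 3×3 square → count external contours with enclosed (shoelace) area ≥ 10 px
at the 480×480 working scale. Holes are filled before contour extraction so
only external boundaries count.

α is the one consequential free parameter: a blob of two grains whose neck
distance-value is below α of the image's peak distance is split. α = 0.4 was
fixed once by a small grid on the synthetic suite (the generator's neck
geometry, below) and is exposed on the CLI. The distance metric is
Euclidean; erosion/opening elements and the minimum area are exposed as
`CountingParams`. The pipeline thresholds the normalized distance map
directly; no explicit skeletonization step is performed between the distance
transform and re-binarization.

Measured behaviour on the generator (100 ears/level, defaults): side counts
are exact up to adhesion ≈ 0.3; naive component counting is already wrong
from adhesion 0.15. At adhesion 0.4 the necks widen past the α cut and
undercounting begins (≈ 3.7% mean relative error). The acceptance suite
asserts exactness at adhesion 0 and ≤ 5% Method II MRE at adhesion ≤ 0.25.

## Synthetic ears

One sample emulates one photographed ear side at 480×480: ellipse grains
(major axis 18–30 px, minor 10–16 px, ±5° orientation jitter) in two columns
offset ±(max minor/2 + 3) px from a straw-colored rachis band, the right
column staggered by about half a step. Within a column, consecutive centers
are spaced `a_i + a_j + g − adhesion·(minor + g)` (semi-majors `a`, base gap
g = 3 px): adhesion 0 leaves a 3 px margin (disjoint components — verified
by labeling), and growing adhesion produces interpenetration with
progressively wider necks, which is precisely the failure mode the counting
model must resolve. Grain counts per side default to 16–24. Backgrounds:
"field" is low-frequency green-brown noise (so its luma stays below the 120
threshold), "white" is 240±σ paper; grains get radial dome shading, a
lateral illumination ramp (±10 intensity), and Gaussian pixel noise (σ = 3).
All randomness derives from one master seed via counter-based per-sample
seeds.

What the generator does *not* emulate: awns, glumes, specular highlights,
perspective, defocus, inter-ear occlusion, or the correlation between the
two sides of a real spike (sides are drawn independently, so Method I is
pessimistically scored on synthetic pairs — see the README example). Passing
tests therefore demonstrate the counting model's separation mechanics and
the training loop's contracts, not field-condition segmentation accuracy.

## Data pipeline choices

- Polygon annotations rasterize by exact point-in-polygon tests of pixel
  centers (pixel (r, c) center at (c+0.5, r+0.5)); overlapping polygons
  union.
- Resizing to the square working size is a direct anisotropic resize
  (bilinear for images, nearest-neighbor for masks so labels stay in {0,1});
  no padding, since the counting stage is scale-tolerant.
- Augmentation applies each transform independently (not composed): 90/180/
  270° rotations, horizontal/vertical flips, and a 5×5 Gaussian blur on the
  image only, with σ = 0.3·((k−1)/2 − 1) + 0.8.
- Splits (9:1 and k-fold) shuffle ids with a seeded generator and operate on
  ear identity, so augmented variants never straddle partitions.
  Stratification by variety/treatment is accepted as an option but off by
  default.

## Evaluation conventions

- mPA and mIoU average over the actual classes (2), background included. A
  class absent from both masks yields NaN and is excluded from means rather
  than counted as zero.
- R² uses the standard total-sum-of-squares denominator Σ(x_i − x̄)²; the
  relative-error percentage is applied exactly once in MRE. R² is undefined
  (NaN) for constant truth.
- The paired t-test is two-sided with n−1 degrees of freedom and refuses
  zero-variance differences; fold summaries report mean ± sample standard
  deviation (ddof = 1, absent for a single value).
- TN is stored in the confusion matrix for completeness; no reported score
  uses it.

## Numerical and scale choices

- Argmax ties in mask prediction break toward the lower class index
  (background).
- Grad-CAM targets the head's fused feature map (the final convolutional
  output before the classifier); the class score is the spatial sum of that
  class's logits, channel weights are spatial means of its gradient, and the
  rectified weighted sum is min-max normalized after upsampling.
- Quantitative tests run on reduced problem sizes chosen as adequate for
  their property: 112-px ears with 4–6 large grains for training tests, a
  width-8 network (full four-branch topology, one module per stage) for the
  overfit contract, 100 ears per adhesion level for count recovery, and the
  full-width w32/w18 networks for parameter accounting only.
- Full-network horizontal-flip equivariance is not a property of this
  architecture (stride-2 downsampling on even grids samples a
  mirror-asymmetric lattice); the equivariance smoke test covers the
  stride-1 residual and upsampling paths, and flip invariance is asserted
  exactly where it truly holds — on the counting pipeline.

## Known limitations

- Evaluation-mode outputs of an *untrained* network are extreme because
  batch-norm running statistics are still at their initialization; this is
  inherent to batch norm and irrelevant after a few training steps.
- The numpy engine is single-threaded apart from BLAS and is intended for
  reduced-scale experiments; full-resolution w32 training is out of its
  scope, though full-resolution inference works.
- Method I's synthetic-data scores understate its field accuracy (see the
  generator's independence caveat above).
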