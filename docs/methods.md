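# Methods

## Problem and approach

Given one 3D point cloud per tree (terrestrial laser scanning, meters,
z vertical), the package predicts the tree's species. The cloud is reduced
to ten 2D grayscale views and classified with a small CNN; this trades some
3D information for the speed and maturity of 2D image classification, and
multi-view rendering recovers part of what a single projection would lose.

## Rendering model

Each tree is subsampled once to 6,000 points (uniform, without
replacement, seeded; smaller clouds are used whole with a warning) and
rendered at ten azimuths, 360°/10 = 36° apart starting at 0°, rotating
about the vertical axis through the cloud's xy-centroid.

A view is an orthographic projection along y onto the x–z plane:

- The x–z bounding box is fitted inside the 150 × 100 px raster with a 5%
  margin, preserving aspect ratio. Absolute tree size is therefore *not*
  encoded in pixels — only adult trees of broadly comparable stature
  should be mixed in one study.
- Each point is a filled disc of radius 1 px (the full 3×3
  neighbourhood), the smallest marker that keeps 6,000 points visible at
  this resolution. Configurable.
- Gray level is a linear map of the point's y-coordinate (viewing depth)
  over the *per-view* min–max depth range: nearest → 0, farthest → 200.
  The ceiling of 200 keeps the farthest markers distinguishable from the
  white (255) background. A degenerate depth range renders everything at
  the near gray.
- Overlapping discs resolve to the nearer (darker) point. Because the
  depth→gray map is monotone, painter's order far→near is exactly a
  per-pixel minimum over covering discs, which is how the fast renderer
  implements it; a brute-force per-pixel rasterizer in the test suite must
  agree bit-for-bit.
- Row 0 is the top of the tree (z increases upward).

Rendering is bit-reproducible from the seed: pixel values depend only on
the subsample and the geometry, never on iteration order.

## Splitting and balancing

`grouped_split` assigns whole trees to train or test, per species
(default 20% test, round-half-away-from-zero, at least one test tree;
explicit per-species test-tree counts are supported to reproduce a given
design exactly). Augmentation runs strictly after the split and draws only
from training trees, so the test pool is bit-identical before and after
balancing — this is asserted, not assumed.

The balancing policy: a species whose base image pool (views × total tree
count) is below 1,000 images receives exactly 400 augmented training
images; others are untouched. Both numbers are configurable
(`AugmentConfig.minority_threshold_images`, `n_aug_per_minority`). The
threshold is a strict inequality: a species at exactly 1,000 images is not
augmented.

Each augmented image applies, in order: random tilts about x and y
(uniform, ≤ 10°, so the tree still stands upright), a free z-rotation, a
fresh render, then image-space perturbations — integer shift up to 5% of
each dimension (background fill), additive Gaussian pixel noise (σ = 5
gray levels), unsharp-mask sharpening (amount 0.5, σ = 1 px blur), and a
multiplicative contrast change about mid-gray (factor in [0.8, 1.2]).
The magnitudes are deliberately conservative so augmented images remain
plausible renders; with every magnitude at zero the output equals the
plain 0° view bit-for-bit, which pins the transform order. Augmented
images carry view indices ≥ 1000 and an `augmented` flag for provenance.

## Classifier

Input 150 × 100 × 1, pixels scaled to [0, 1]. Layers: conv 3×3 ×8 (ReLU)
→ maxpool 2×2 → conv ×16 → maxpool → conv ×32 → maxpool → dropout 0.3 →
conv ×64 → maxpool → flatten (9 × 6 × 64 = 3,456) → dense 128 (ReLU) →
dropout 0.5 → dense n_classes (softmax). 467,783 trainable parameters for
seven classes, verified in tests against independent shape arithmetic.

Convolutions use "same" padding and stride 1. Pooling uses stride 2: a
stride-1 pooling variant is exposed (`pool_stride=1`) but not default,
since it would not shrink the feature maps — the stated purpose of the
pooling stages — and makes the flatten layer enormous.

Training: categorical cross-entropy, Adam (lr 10⁻³), batch size 32,
default 50 epochs, seeded shuffling and dropout; a NaN loss aborts with
diagnostics. Defaults for epochs/batch/lr are package choices, exposed in
`CNNConfig`. The engine itself (`_nn.py`) is a compact NumPy
implementation — im2col convolution, mask-based max-pool gradients,
inverted dropout, Adam with bias correction — with its gradients exercised
by overfitting and descent tests.

Inference: softmax probabilities per image; hard label = argmax (ties to
the lowest class index). `per_tree_evaluate` averages a tree's view
probabilities before the argmax. Default reporting is per-image, matching
the granularity of test-image pools; per-tree scoring is an explicit
alternative.

## Evaluation

Confusion matrices are true × predicted counts with row normalization by
true-class support (diagonal = per-class recall), printed as decimals read
row-wise (×100 = percent). Overall accuracy is trace/total, which equals
the support-weighted mean of the diagonal — asserted as an algebraic
identity in tests. Counting is delegated to scikit-learn; an independent
hand-written tally loop serves as the test oracle.

## Synthetic trees

`synthetic_trees` generates labeled clouds from two archetypes plus an
intermediate: a tapered trunk (noisy circular cross-sections), branch
segments (regular five-branch whorls for the conifer, irregular upswept
branches otherwise), and a crown envelope — narrow cone
(crown width/height 0.25, crown base at 20% of height) for the conifer,
wide ellipsoid (0.6, base at 45%) for the broadleaf, broad cone (0.45,
base 35%) for the intermediate. Per-tree jitter: height drawn from the
archetype range, crown width ×U(0.92, 1.08), branch counts and angles from
their ranges. Defaults: 20,000 points per tree, 2 cm coordinate noise.

Trunk point heights follow z ~ H·u⁴ (density-gradient exponent g = 3),
mimicking the strong ground-ward density bias of real TLS clouds where
every scan position sees the lower stem: with default parameters the
lowest 30% of points span only ≈ 20% of tree height, so cutting 30% of
points for point-sample preparation removes far less than 30% of height
(≥ 75% of height is retained — both directions are tested).

What the generator does **not** emulate: leaves and fine branching, bark
structure, occlusion and anisotropic density of multi-scan setups, stray
points, species-specific allometry beyond the crown envelope. Passing
synthetic-recovery tests therefore demonstrates that the pipeline's
mechanics (rendering, splitting, balancing, training, scoring) work and
that archetype-level shape differences are learnable — not that real
seven-species accuracy is achieved; that requires real scan data.

## Problem sizes used in the automated checks

- Renderer oracle: 50 random clouds of ≤ 200 points, bit-exact agreement.
- Split hygiene: 1,000 random grouped splits, zero leakage.
- Synthetic recovery: 3 archetypes × 30 trees, 20% grouped hold-out,
  default CNN trained 6 epochs (training accuracy saturates by epoch 4 on
  this data), per-image test accuracy ≥ 0.90.
- Balancing direction: 40 majority vs. 5 minority trees, three seeds,
  6 epochs; mean minority recall with balancing ≥ without.
- Bookkeeping: the full 690-tree design, counted from actually rendered
  images in `scripts/acceptance.py` (8,000-point clouds there, so the
  6,000-point subsampling path is still exercised).

## Numerical and design notes

- Pixel coordinates use `np.rint` (round-half-to-even); disc membership is
  dx² + dz² ≤ (r + 0.5)², giving the full 3×3 at r = 1.
- Depth ties across coincident pixels are harmless: equal depth maps to
  equal gray, so min-gray and painter's order agree.
- `subsample` with n ≥ cloud size returns the cloud unchanged (warning
  below n); sampling with replacement would fabricate duplicate markers.
- Trimming the lowest 30% of points breaks z-ties by input order
  (stable argsort) and keeps the survivors in input order.
- Whether base views should use per-view or global depth ranges, and
  whether the ten views are evenly spaced, are open choices; per-view
  min–max and even spacing are the defaults, both configurable.
- Label order everywhere is the sorted species list.

## Known limitations

- Per-tree frame fitting discards absolute size; mixing juveniles and
  adults will confuse the classifier by design.
- The NumPy training loop is single-threaded and CPU-bound; at the
  reference design's scale (≈ 8,000 images, 50 epochs) training takes
  hours, not minutes. The architecture is small enough that this is
  usable, but large studies would want a GPU-backed engine behind the same
  `cnn_classifier` interface.
- The point-set preparation stops at sample generation; no point-set
  network is included.
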