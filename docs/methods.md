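# Methods

This note records the modeling assumptions, default parameters and
numerical choices behind `edlseg`, and what the synthetic experiments do
and do not establish.

## Evidential model

Each voxel `i` carries a Dirichlet distribution `Dir(alpha_i)` over its
class-probability vector; the network head emits non-negative evidence
`e_ij` through a ReLU, and `alpha_ij = (e_ij + 1)^2` by default.  The
squared map is the default because it lets a bounded head activation reach
large Dirichlet parameters (confident opinions); the classical linear map
`alpha = e + 1` is available via `parameterization="linear"` for
comparison.  Both guarantee `alpha >= 1`: every class keeps one
pseudo-count, so zero evidence encodes total ignorance (uniform Dirichlet,
normalized predictive entropy 1).

Entropies use the natural logarithm throughout.  The normalized
predictive entropy divides by `log K`, which cancels the base; the
unnormalized predictive entropy is therefore reported in nats.  Exact
zeros in `p log p` are masked to contribute 0 (no epsilon inside the
logarithm, which would bias exactly-one-hot outputs); an epsilon of 1e-12
only guards values merely close to zero from producing NaN.

Arrays are channel-first (class axis before spatial axes), 0-based.

## Losses

Closed-form Bayes risks under `Dir(alpha)`: marginal likelihood
(`log S - log alpha_c`), cross-entropy (`psi(S) - psi(alpha_c)`), and MSE
(`(y-p)^2 + p(1-p)/(S+1)` summed over classes).  Digamma/log-gamma come
from scipy/autograd special functions; nothing is hand-expanded.

The region-based Dice risk follows the ratio-of-expectations form: the
expectation is pushed through numerator and denominator separately, so
each class term is `2 sum_i y p / sum_i (y^2 + p^2 + Var)` with
`Var = p(1-p)/(S+1)`.  This is the operational definition the theorems
and training use; `mc_bayes_risk(..., "sdice")` estimates the expectation
of the ratio by Monte Carlo so the approximation gap can be *measured*
rather than hidden.

Numerical choices:

- **Smoothing 1e-5** is added to each class term's numerator and
  denominator to guard classes absent from both label and prediction
  (0/0).  It perturbs the two-voxel worked example by under 1e-4.  The
  theorem sweep runs with smoothing 0 — for `alpha >= 1` every
  denominator is strictly positive, and the structural properties concern
  the exact loss.
- **Class weights** for the weighted variant are
  `max(1 - foreground/background, 1e-3)`, computed per training sample
  from its ground truth.  The raw formula goes non-positive when a class's
  foreground reaches its background; the clamp preserves the positivity
  the loss properties require.  A class with zero background voxels is
  rejected.
- **The region** over which the Dice sums run is one sample (all voxels of
  one image); mini-batches reduce by the mean over samples.  The default
  recipe uses batch size 1, where the distinction is moot.
- **Annealing** is indexed by epoch: `lambda(n) = 0.1 min(1, n/ramp)^2`,
  zero at epoch 0, capped at 0.1.  The canonical ramp is 100 epochs; the
  desk-scale default scales it to 25 for 50-epoch runs (the full ramp is
  one config field away).

## Loss properties and their verification

`check_theorems` sweeps four structural claims over
`alpha in {1, 1.5, 2, 4, 8, 16, 64}^K`, `K in {2,3,4}`, voxel sets up to
size 4 with several context configurations, using central finite
differences with relative step 1e-3 (and grid sweeps at the `alpha = 1`
boundary, where one-sided differences apply):

1. the soft-Dice denominator term `y^2 + p^2` strictly dominates the
   variance term at every point — data fit outranks variance reduction;
2. the region loss strictly decreases as correct-class evidence grows;
3. the region loss decreases when evidence is removed jointly from all
   wrong classes of a voxel;
4. the KL regularizer grows in each wrong-class parameter.

Properties 1–3 hold with zero violations on the full grid.  Property 4
holds for binary segmentation (K = 2, the default per-region regime) and
on every point with at most one inflated wrong-class parameter, but it is
**not true in general for K >= 3**: the derivative of
`KL(Dir(alpha~) || Dir(1))` in a wrong coordinate `a_w` is
`(a_w - 1) psi'(a_w) - (S - K) psi'(S)`, which turns negative once
*another* wrong-class parameter is large (e.g. `KL(Dir(1, 64, b))`
decreases from 5.69 at `b = 1` to 4.42 at `b = 16`).  Intuitively, adding
mass to a second wrong class makes the opinion less concentrated and so
*closer* to the uniform prior.  `check_theorems` reports these grid
points honestly instead of masking them; the practically relevant binary
case is clean.

All losses are written with `autograd.numpy`, so training gradients are
exact autodiff, and the test suite verifies them against central finite
differences (1e-4 relative) at random interior points.

## Uncertainty and evaluation metrics

- **ECE**: confidence is `1 - u`; voxels outside the brain mask are
  excluded so the huge trivially-confident background cannot mask
  miscalibration.  Default 10 equal-width bins, half-open `[lo, hi)` with
  the top bin closed; the per-bin confidence is the empirical mean of
  member confidences (not the bin midpoint).
- **sUEO** compares the continuous uncertainty map directly with the
  binary error map (XOR of prediction and ground truth); no threshold is
  tuned.  The degenerate no-error/no-uncertainty case returns 0 with a
  flag, since the ratio cannot express a perfect outcome.
- **Confidence-filtered curves**: 101 evenly spaced thresholds on [0, 1];
  a voxel is retained when `1 - u >= tau` (the inclusive boundary keeps
  `tau = 0` retaining everything exactly).  Dice over an empty retained
  set carries the last non-empty value forward; Dice of two empty masks
  is 1.  FTP/FTN ratios measure the fraction of baseline true
  positives/negatives removed by filtering; when a baseline count is
  zero, the curve is identically 0 and flagged.  The brain mask, when
  supplied, restricts all counts, consistently with ECE.  AUCs are
  trapezoidal; BraS is the mean of `AUC_Dice`, `1 - AUC_FTP` and
  `1 - AUC_FTN`.
- `evaluate_case` evaluates foreground classes of exclusive one-hot
  labels (argmax predictions, shared uncertainty map) and averages them;
  overlapping nested regions are evaluated per region with K = 2 models.

## Synthetic phantoms

A phantom is an ellipsoidal "brain" containing three nested irregular
blobs (whole lesion ⊇ core ⊇ enhancing focus), rendered into four
channels that weight the regions differently — a cartoon of multi-modal
MRI contrasts.  Gaussian noise (sd 0.08 by default) is added everywhere,
including outside the brain, so the background is realistically non-flat;
channels are then min-max normalized to [0, 1].  Default size 96x96,
40-case collections split 0.6/0.2/0.2.  Generation is a pure function of
(parameters, seed); manifests record recipes and array checksums and
suffice to regenerate a dataset bit-exactly.

Corruption operators and their canonical strengths: Gaussian blur
sigma 1.5 (reflective boundaries), additive Gaussian noise variance 1.5,
gamma correction gamma 5 applied to min-max-scaled intensities.  Noise is
added *after* normalization, so variance 1.5 against a unit intensity
range is a severe corruption by construction.  Corruptions never touch
labels or brain masks.

What the phantoms do not emulate: MRI physics (bias fields, k-space
artifacts), anatomical texture, inter-scanner variability, or
BraTS-scale volumes.  Passing the synthetic suite demonstrates the
correctness and internal consistency of the losses, uncertainty maps and
metrics — not clinical segmentation performance.

## Network and training defaults

The trainable vehicle is a three-level 2D U-Net in pure numpy (two 3x3
conv + ReLU blocks per level, widths 8/16/32, average-pool down,
nearest-neighbour up with skip concatenation, 1x1 ReLU evidence head,
~30k parameters) with hand-written matmul-based backpropagation and Adam
(lr 3e-4, batch size 1).  The loss framework is architecture-agnostic;
this is simply the smallest network that segments the phantoms well at
interactive speed (~70 s per 50-epoch run on one CPU).  Per-region binary
training (K = 2) is the default; multi-class K = 4 is a config flag.
Seeding covers parameter initialization, data order and noise; runs are
bit-reproducible on a fixed platform, though exact floats may differ
across BLAS builds.

Default experiment sizes, chosen as the package's desk scale: 40 phantoms
of 96x96, 50 epochs, KL ramp 25; the Monte-Carlo oracle uses 100 000
draws; the robustness check repeats training over 5 seeds.

## Known limitations

- Under the severe noise (variance 1.5) and gamma (gamma 5) corruptions
  the small desk-scale model collapses (test Dice near 0) — it is trained
  on clean data only, with no augmentation, unlike a full-scale clinical
  pipeline.  The blur corruption is the informative desk-scale probe: Dice
  degrades moderately while sUEO improves, showing the uncertainty map
  locating the induced errors.
- The KL regularizer's coordinate monotonicity caveat for K >= 3 above.
- Uncertainty is total (predictive entropy); no epistemic/aleatoric
  decomposition is attempted.
- 3D phantoms and volumes are supported by the field/metric/synthetic
  layers, but the bundled network is 2D.
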