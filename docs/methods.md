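# Methods

## Model

Registration estimates a pair of cubic B-spline free-form deformations
(T_AB, T_BA) between a floating image A and a reference image B by
minimizing

    J(T_AB, T_BA) = 1/2 ( d_AB + d_BA ) + lambda/2 ( iic_AB + iic_BA ).

The distance terms are directed alpha-AMD distances: images are treated as
spatial fuzzy sets (intensity = membership), and for a fuzzy point p with
height h the bidirectional alpha-cut distance is

    d_alpha(p, S) = int_0^h d(p, aS) da + int_0^{1-h} d(p, a S-bar) da,

the average over cut levels of the Euclidean distance from p to the
thresholded object (below the point's height) or to the thresholded
complement (above it).  d_AB is the weighted mean of d_alpha over sampled
fuzzy points of A, transformed by T_AB, restricted to those landing inside
B's mask.  The measure combines intensity and spatial information and
needs no intensity interpolation: sampled points keep their source
membership as height.

Cubic B-splines are not closed under inversion, so symmetry is promoted
softly: iic_AB is the weighted mean of ||T_BA(T_AB(x)) - x||^2 / 2 over
the same sample domain.  Because the distance term is non-squared while
the penalty is squared, the distance dominates J for small residuals and
the penalty takes over for large ones.

## Monte Carlo distance estimation

The exact integral requires a distance map per intensity level.  Instead,
N_alpha cut levels are sampled per iteration and each level's point-to-cut
distance is found by branch-and-bound search over an augmented max-KD-tree
(one tree for the image, one for its complement, rebuilt per pyramid
level).  Each node of the implicit, array-stored tree holds the maximum
membership of its sub-rectangle, so sub-trees empty after cutting are
pruned; a per-corner geometric lower bound prunes sub-trees that cannot
improve the current best distances.  All levels are searched in one
traversal.  Distances start at, and saturate at, a cap d_max (a schedule
fraction of the image diagonal); empty cuts therefore contribute d_max.

Search acceleration: the lower bound can be relaxed by a factor beta >= 1
beyond a threshold d_t, trading exactness of far (hence less relevant)
distances for fewer node visits.  Bounds below d_t are never relaxed, so
near distances stay exact.  Defaults in the shipped schedules: beta = 1.2,
d_t in grid units of the level.

Cut levels come from a golden-ratio Kronecker sequence with a random
offset per iteration — stratified (low variance) yet uniform in
expectation, so the estimator is unbiased for the truncated integral; the
levels are shared by all points of one iteration, which is cheaper and
reduces between-point variance (a deliberate interpretation: the
alternative of per-point levels changes only the noise structure).
Level 0 is excluded; its cut is the whole domain and contributes zero.

Sub-spel evaluation computes the per-corner mean distances at the 2^n grid
corners around a query point and interpolates multilinearly.  The spatial
gradient used by the optimizer is the discrete gradient at the corner-cell
*mid-point* — robust at saddle points of the interpolation surface, where
the exact derivative can vanish.  The estimator also exposes
`gradient_mode="interp"`, the exact derivative of the interpolated
surface, which is what a finite-difference check of J must be compared
against (the mid-point stencil is a deliberate, documented deviation from
that exact derivative; at cell mid-points the two coincide).  Points whose
corner cell is not fully inside the grid are out-of-domain and are masked
by the caller.

Two implementations of the tree build and search exist: a recursive
pure-Python reference, and batched numba kernels with explicit stacks used
by the registration loop.  The tests assert bit-identical distances.

## Sampling

Per iteration each direction draws `fraction * #spels` source spels, with
replacement, from the mixture m * p_grad + (1 - m) * p_uniform: with
probability m a draw follows the normalized Gaussian gradient magnitude of
the image (scale sigma_GM, reflect boundaries, values under t_GM zeroed;
if everything is zeroed the draw falls back to uniform), otherwise a
quasi-uniform Kronecker point.  The gradient map depends only on the
image, so it is cached per pyramid level.  t_GM defaults to 0 (the
schedule tables give no value).  The uniform stream is quasi-random with a
random start index per iteration; a plain RNG stream is available for
ablation.

## Optimization

Heavy-ball SGDM: v <- mu v - eta * g_i / (gamma_i + eps), Phi += v, with
fresh velocity at each stage and eps = 0.01.  gamma_i sums the parameter's
influence over the kept sample points — its basis-weight mass, plus the
lambda-weighted influence through the composed round-trip transforms
(whose spatial Jacobian is evaluated analytically from the derivative
basis functions).  Dividing by gamma makes the update magnitude
independent of how many points landed in the parameter's support and of
uniform weight rescaling, which decouples the step-size from grid
coarseness.  The gradient fed to this ratio is the raw weighted sum; the
objective report also carries the true (mean-normalized) gradient of J,
which is what the finite-difference tests verify.  Both transforms are
updated in the same iteration from one objective evaluation.

The AW-IIC chain rule needs the outer field's spatial Jacobian; the cubic
B-spline Jacobian has a closed form (derivative basis functions), which we
use exactly — both in the gradient and in gamma.

## Pipeline

Preprocessing: robust normalization to [0, 1] clipping at the q and
(100 - q) percentiles (constant images map to zero), optional histogram
equalization (256 bins in the 3-D preset).  Pyramids: Gaussian smoothing
with the level's sigma followed by block-mean downsampling by the level's
factor; masks downsample by majority vote; spacing scales accordingly.
Both choices (kernel and mask policy) are explicit decisions — the
downsampling kernel is otherwise unconstrained.

Transforms live in physical coordinates (spel centers at index * spacing),
so a field estimated on a coarse level applies unchanged on finer levels.
The control mesh covers the image extent with spacing extent/(c - 3) and
origin one spacing before the image origin, which makes the FFD index
arithmetic valid for every in-image point.  Between stages the pair is
refitted to the finer mesh by linear least squares on a dense sample grid
(>= 4 samples per new knot span); the schedules use non-dyadic count
progressions, for which closed-form subdivision does not apply.  Nested
(dyadic) refits are exact to ~1e-12; non-nested refits carry a small
approximation residual.

A plain coarse grid search over rotations and translations (scored by the
directed distance at 4x downsampling, with a 40% mask-overlap floor) is
provided for rigid initialization of separately acquired image pairs.

Shipped schedule presets: `retinal` (synthetically deformed fundus
images), `fire` (separately acquired fundus pairs), `brain3d`
(inter-subject MR volumes) — these reproduce the published configurations
verbatim and target full-scale data — plus `phantom`, a desk-scale
3-level schedule for the 128 x 128 recovery experiment below.

## Synthetic data

`make_vessel_phantom` emulates the thin-structure statistics of fundus
vessel networks without any download: branching random-walk tubes 1-6 px
wide with radial intensity falloff, slow contrast modulation along each
branch, and a smooth textured background; the mask is the tube support and
branches are added until it covers at least 4% of the domain.  The
along-branch modulation matters: with constant-intensity tubes the
tangential component of a deformation is unobservable (an aperture
problem), which real vessel images do not exhibit.

`make_retinal_pair` implements the full benchmark construction for real
fundus inputs: grayscale conversion, rolling-ball background removal
(radius 20 px; grayscale morphological opening by default, exact rolling
ball behind a flag), 350 px padding, then a coarse-to-fine stack of random
B-spline warps with 7/14/24/48 control points per dimension and uniform
per-parameter perturbations of (-250, 250)/(-50, 50)/(-25, 25)/(-15, 15)
px, composed with the coarse warp outermost (the construction order is
otherwise unspecified; we read the per-level counts as per-dimension).
The mask is deformed by the same warp with nearest-neighbor sampling.
Landmark grids carry ground-truth correspondences, so registration error
is measurable as mean endpoint error without annotation.

What the generator does not emulate: acquisition noise models, optic-disc
and macula structures, illumination fields beyond a smooth bias, and
inter-subject anatomy — passing the recovery experiment shows the method
recovers known smooth warps of thin-structure images, not performance on
any clinical task.

## Desk-scale experiment sizes

The recovery experiment registers ten 128 x 128 phantoms warped by known
three-level B-spline stacks (6/10/16 control points, rescaled to a 10 px
maximum displacement) with the `phantom` preset, and repeats the runs with
lambda = 0 for the inverse-inconsistency ablation.  These sizes keep the
whole suite in the minutes range while exercising every stage of the
pipeline; the full-scale presets are shipped but not exercised by tests.

## Numerical choices

- Rectangle splitting: widest physical axis, argmax_k s_k (R_k - 1), ties
  to the lowest axis; the left child takes ceil(R_k/2) so search and build
  traverse identical rectangles.  Child visit order follows the first
  corner (all corners share one cell, so the heuristic is shared).
- Pruning uses the conjunction over all corners; leaves evaluate all
  corners (no per-corner early exit).
- The B-spline support test uses a 1e-9 relative tolerance so boundary
  points produced by exact arithmetic on the support edge stay inside.
- Gradient-correctness checks filter sample points whose transformed
  position falls within 0.1 cells of an interpolation-cell boundary:
  central differences require differentiability, and J is piecewise
  smooth with kinks at cell crossings and at the d_max cap.
- Least-squares refits solve the normal equations with a sparse LU; the
  collocation matrix has full rank at >= 4 samples per span.
- Degenerate inputs: constant images normalize to zero and make the
  gradient-weight map degenerate (uniform fallback); empty masks raise a
  no-overlap error; splitting a leaf rectangle is a contract violation.

## Known limitations

- Mono-modal by construction: the distance assumes similar intensities
  for corresponding structures; normalization and histogram equalization
  are the only contrast harmonization provided.
- The stochastic estimator has an accuracy floor of a few tenths of a
  spel under the desk-scale settings (N_alpha = 7, unit grids, linearly
  resampled floating images): the optimum of the sampled objective sits
  slightly off the true warp, and the finest estimation mesh cannot
  represent a composed warp stack exactly.  Intersection-over-union of
  1-6 px wide masks is extremely sensitive at that scale — a mean error
  of 0.3 px costs roughly 0.15-0.25 Jaccard on thin structures — so
  recovered-mask overlap saturates around 0.8 even when the endpoint
  error has dropped by an order of magnitude (the acceptance script
  reports both quantities).  The sensitivity is geometric: for a tube of
  width w, a boundary pixel flips under a sub-pixel misalignment e with
  probability of order e, so the intersection-over-union loses on the
  order of 2e/w per unit length.  On full-scale images, where structures
  are tens of pixels wide, the same absolute accuracy costs almost no
  overlap.
- No diffeomorphism guarantee: the penalty discourages, but does not
  forbid, folding.
- The rigid initializer is a plain grid search: adequate for coarse
  pre-alignment at small angle ranges, not a full global registration.
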