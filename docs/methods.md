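# Methods

## The learning-curve model

Test Dice as a function of training+validation set size `x` is modelled by
the exponential-plateau law

    D(x) = D_max − (D_max − D_0) · e^(−k·x)

with three parameters: the asymptotic maximum Dice `D_max`, the minimum Dice
`D_0` (the value the curve takes at `x = 0`; in practice the performance at
the smallest observed size anchors it), and the rate constant `k` (per
image).  The model assumes diminishing returns — each additional image
closes a constant *fraction* of the remaining gap to `D_max` — which is the
empirical shape of segmentation learning curves once the architecture and
preprocessing are fixed.  It does not model double descent, curriculum
effects, or distribution shift between the training pool and the test set.

The **plateau point** is the smallest integer size at which the curve is
within a tolerance `tol` (default 0.01 Dice) of `D_max`.  Because
`D_max − D(x) = (D_max − D_0)·e^(−kx)` is strictly decreasing, it has the
closed form

    x_plateau = max(1, ⌈ ln((D_max − D_0)/tol) / k ⌉),

with `x_plateau = 1` when the total rise is already within tolerance.  The
ceiling is used because image counts are whole numbers; the tests verify the
closed form against brute-force integer scans.

### Fitting

Parameters are estimated by nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) with box constraints
`0 ≤ D_0 ≤ 1`, `0 ≤ D_max ≤ 1`, `k ∈ [1e−6, 1]`.  Dice is bounded, so an
unconstrained fit could extrapolate past 1; constraining is the safer
default.  The joint ordering `D_0 ≤ D_max` is not a box constraint; it is
checked after the fit, and a violation (a decreasing curve, not a learning
curve under this model) clears the `converged` flag rather than being
silently clipped.

Initialisation is deterministic and seed-free: `D_max⁰` is the best observed
Dice (clipped to 1), `D_0⁰` the Dice at the smallest size, and `k⁰` the
negated slope of an ordinary regression of `ln(D_max⁰ + 1e−3 − dice)` on
`x` — for data of the expected shape this starts the optimiser inside the
right basin.  Optimiser tolerances are tightened to 1e−12 so that noiseless
curves refit to their generating parameters at the 1e−6 level.

Degenerate inputs: fewer than three distinct sizes is an error (three free
parameters); identical Dice everywhere returns the flat fit
`D_max = D_0` with `plateau_x = 1` and a `flat_curve` flag, bypassing the
optimiser.

By default only ensemble-level observations enter the fit; `use="all_points"`
includes individual fold observations, unweighted.  Mixing them changes the
effective weighting of each size, which is why both modes are explicit.

### Extrapolation and stability

If `x_plateau` exceeds the largest observed size, the fit is flagged
`extrapolated`: the estimate then rests entirely on the assumed functional
form and deserves less confidence.  Complementing this, the stability
analysis refits after progressively removing all observations at the largest
remaining size (`max_drops` times, default 2) and reports the largest
|ΔD_max| between successive fits.  The default instability threshold is a
gap of 0.02 Dice: successive estimates that agree within ~0.01 indicate a
curve that has genuinely settled, while jumps of ~0.05 indicate the plateau
is still being dragged upward by the newest data.  The threshold is a
configurable heuristic, not a statistical test.

### Volume-quartile curves

`quartile_curve_analysis` ranks test cases by reference structure volume
(ties broken deterministically by case id), splits them into four near-equal
groups, and fits a separate learning curve to the mean Dice per size within
each quartile.  Small structures are harder to segment, so the lowest
quartile typically plateaus lower and later than the cohort curve; this
makes the analysis sensitive to exactly the cases that drag cohort means
down.

## Agreement metrics

For each case and label the toolkit reports Dice, Jaccard, TPR, symmetric
mean surface distance, and physical volumes.  Voxel counts (TP/FP/FN) are
exact; Dice = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN) (the identity
J = D/(2−D) is asserted in tests), TPR = TP/(TP+FN).

Conventions for empty masks are explicit and flagged in the output rather
than silently applied: both masks empty → Dice = Jaccard = 1 (perfect
agreement on absence); reference empty → TPR = 1; either mask empty → MSD is
*missing* (serialised as an empty CSV cell), never a sentinel value, and
cohort summaries report the exclusion count.  A sentinel such as "assign a
huge distance" would let a single missed structure dominate a cohort mean in
an arbitrary way.

Surface distance choices (several defensible definitions exist; these are
fixed and the directed components are exposed so alternatives can be
reconstructed):

- **Boundary**: mask voxels with at least one face-adjacent (6-connectivity)
  neighbour outside the mask; the grid edge counts as outside.
- **Distance**: Euclidean between voxel centres, per-axis scaled by the voxel
  spacing (anisotropic grids are handled exactly; MSD scales linearly under
  uniform spacing scaling, volumes cubically — both property-tested).
- **Symmetrisation**: arithmetic mean of the two directed mean
  nearest-boundary distances (not Hausdorff, not median).

Volumes are voxel count × voxel volume, reported in mL.

A documented limitation: volumes are compared on identical grids only
(same shape, spacing within 1e−6 relative).  Header affine rotations/flips
beyond the zooms are ignored — the metrics are orientation-invariant, and
refusing mismatched grids is safer than attempting resampling, which is out
of scope.  NIfTI files storing labels as floats are accepted only when every
value is within 1e−6 of an integer.

## Majority-vote ensembling

The ensemble label at a voxel is the most frequent label across the K fold
predictions.  With five voters over three labels, 2-2-1 ties occur; the
default rule picks the numerically lowest tied label (with the
background/kidney/tumor = 0/1/2 map, this prefers background — the
conservative choice), and a `background_wins` variant prefers the background
label in any tie it participates in (these coincide when background is the
smallest label value).  Both rules are deterministic and order-independent;
permutation invariance, unanimity, and idempotence are property-tested, and
all 3⁵ vote combinations are checked against an enumeration oracle.  Voting
is over hard labels only, not probabilities.

## Agreement statistics

- Volume regression: OLS of predicted on reference volume; R² is the squared
  Pearson correlation.
- Bland–Altman: per-case percent difference 100·(pred − ref)/denominator;
  bias = mean, SD = sample SD (ddof 1), limits of agreement bias ± 1.96·SD.
  The denominator is the reference volume by default — interpretable as
  relative error against ground truth — with the classical mean-of-pair
  denominator behind a flag.  Zero-denominator cases are excluded and listed.
- Paired comparisons: two-sided paired Student's t-tests of per-case Dice
  between consecutive dataset sizes, star-coded *** p ≤ 0.001, ** p ≤ 0.01,
  * p ≤ 0.05.  No multiple-testing correction is applied across the
  adjacent-size family; the report says so.  Degenerate inputs are flagged:
  identical vectors give t = 0, p = 1; a constant nonzero difference gives a
  sign-correct infinite t with p = 0.

## Synthetic data

The generators produce label volumes only — every downstream operation
consumes labels, so intensity realism would add nothing.

- **Phantom**: two kidney ellipsoids plus a tumor sphere on a 64×64×32
  isotropic 1 mm grid by default (~6 mL of kidney per side, ~0.9 mL tumor);
  tumor label takes precedence where the sphere carves into parenchyma.
  Geometry is validated to fit the grid.
- **Degradation**: `boundary_flip` removes `f` label voxels near the boundary
  and adds `f` nearby background voxels, with
  `f = round(n·(1 − target))` so the Dice against the original is exactly
  `(n − f)/n` up to rounding; flips are sampled from a boundary band holding
  at least 4·f candidates, so different seeds produce largely independent
  error patterns — which is what lets majority voting of simulated folds
  beat the individual folds.  `erode`/`dilate` step morphologically until
  the measured Dice is nearest the target; `delete_component` empties the
  structure (Dice 0), emulating a model that misses a tumor entirely.
  Discrete flips cannot hit arbitrary real targets, so achieved Dice within
  ±0.05 of the target is accepted and anything worse is an error reporting
  the achieved value.  Degradation never touches voxels of other labels.
- **Learning curves**: per fold, dice = clip(D(x) + ε, 0, 1) with
  ε ~ N(0, noise_sd); the ensemble observation per size is the fold mean.
  Defaults (sizes 50–300 step 50, 5 folds, noise SD 0.02, generating curve
  0.40 → 0.85 at k = 0.02) mirror a realistic tumor-segmentation experiment
  design.  The additive truncated-Gaussian fold noise is the simplest model
  consistent with observed fold scatter; it does not model the heavy left
  tail that hard outlier cases produce in real cohorts, nor correlations
  between folds sharing training cases.  Passing tests therefore demonstrate
  correctness of the machinery and recoverability under well-behaved noise,
  not robustness to pathological real-world cohorts.

All generators are byte-deterministic under a fixed seed (per-fold seeds are
spawned from a `SeedSequence`).

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small problems:
8³ volumes for oracle-equivalence checks (brute-force triple-loop and
exhaustive nearest-boundary oracles stay exact and fast there), the 64×64×32
phantom for pipeline checks, 200 replicates for the noisy-recovery suite,
and 1000 random parameter triples for the plateau closed-form identity.
These sizes make every check exact or tightly toleranced (1e−9 mm for MSD
against the exhaustive oracle, 1e−6 for noiseless parameter recovery,
1e−12 for the Jaccard–Dice identity) while the whole suite completes in
seconds.  The algorithms themselves are vectorised (distance queries via
cKDTree, voting via label-count stacks) and scale to clinical-resolution
volumes.

## Known limitations

- No affine-aware registration or resampling: grids must match.
- Learning-curve families other than the exponential plateau (power laws)
  are not fitted; a visibly different curve shape will show up as high RSS,
  not as an automatic model comparison.
- No bootstrap confidence intervals on the plateau point; the dropout
  stability analysis is the provided robustness check.
- The tie rule in majority voting is a documented convention; frameworks may
  resolve ties differently, which matters only for exactly tied voxels.
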