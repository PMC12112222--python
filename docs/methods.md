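# Methods

## The model

`enmkit` fits a presence-background maximum-entropy model: the landscape
is a finite set of grid cells, the species' use of it is a probability
distribution over those cells, and the fitted distribution is the Gibbs
form `P(x) ∝ exp(β·f(x))` whose feature expectations match the presence
sample, subject to an L1 budget. Equivalently, `β` minimizes

    obj(β) = −mean_presence(β·f) + log mean_background(e^{β·f})
             + Σ_j rm·s_j·|β_j|

which is convex; the null model (`β = 0`) has objective 0, so the
regularized training gain `−obj(β̂)` is non-negative and measures the
improvement over a uniform landscape.

Assumptions worth stating explicitly:

* presences are an unbiased sample of the species' use of environment
  (violations can be emulated with the generator's bias field);
* the background sample (10,000 cells drawn uniformly from the valid
  mask, without replacement, presences not added) represents the available
  environment;
* all rasters share one WGS84 geographic grid — there is no reprojection;
* projection to novel climates clamps features to their training range
  (the standard MaxEnt extrapolation rule), so responses flatten rather
  than extrapolate beyond the training envelope.

### Features and regularization

Feature classes L/Q/P/H/T are built per layer (products per layer pair),
min-max scaled so background values lie in [0, 1]. Hinge and threshold
knots sit at background quantiles, 50 per layer by default. Per-feature
penalty weights are `base(class, m) · max(sd_j, 10⁻³) / √m` with `m` the
presence count, `sd_j` the presence-sample SD of the scaled feature, and
`base` the published class-specific default tables (linear 1.0→0.05 as m
grows 10→100, quadratic 1.3→0.05, product 2.6→0.05, threshold 2.0→1.0,
hinge constant 0.5). The SD floor keeps near-constant features penalized
rather than free. The regularization multiplier `rm` scales every weight.

### Logistic output

The raw distribution is normalized to sum to one over the background; the
logistic value is `q/(1+q)` with `q = raw·e^H` and `H` the entropy of the
fitted background distribution. This is the classical logistic transform
with implied prevalence 0.5: a featureless model scores exactly 0.5
everywhere. Cloglog output is not provided.

## Fitting: numerical choices

Greedy coordinate descent on the penalized objective: each outer pass
computes the exact gradient over the background, ranks coordinates by
their KKT violation, and applies per-coordinate proximal Newton steps
(curvature from the background variance of the feature) with backtracking
on the true objective. Defaults: at most 5000 coordinate updates,
convergence declared when the largest KKT violation falls below 1e−5.
Warm starts are used along the RM path during tuning (high RM → low).
Each accepted step's objective improvement is recorded against the updated
feature; percent contribution credits those improvements to the owning
variable (products split evenly between their two layers) and normalizes
to 100. Degenerate designs (all features constant on the background) are
refused rather than fitted.

The fit agrees with an independent L-BFGS-B solution of the same objective
(β split into positive and negative parts) to 1e−4 on small designs; this
cross-check is part of the test suite.

## Tuning

56 candidates: FC ∈ {L, LQ, H, LQH, LQP, LQHP, LQHPT} × RM ∈ {0.5, …,
4.0}. Spatial cross-validation uses the two-level checkerboard: bit A from
coarse-block parity (block = agg1·agg2 cells, default 10×2), bit B from
fine-block parity (agg1 cells), group = 2A+B+1, deterministic from the
grid origin. If a presence group comes out empty the aggregation falls
back through halved factors to plain cell parity. Per candidate we report
mean train/test AUC over the four folds, their mean difference (an
overfitting diagnostic), and the mean 10th-percentile omission rate
(threshold excludes the ⌈0.1·n⌉ lowest training-presence predictions;
rate = test presences strictly below it). AICc uses the full-data fit:
raw standardized over all valid landscape cells, `k` = nonzero
coefficients, undefined when `k ≥ n−1`. Selection takes delta AICc = 0;
exact ties resolve to fewer parameters, then smaller RM (parsimony).
CV folds reuse the full-background feature scaling; penalty weights are
recomputed from each fold's training presences.

## Thresholding, grading, areas

MTSPS is the prediction value (candidates = observed values, smallest on
ties) maximizing sensitivity of held-out presences plus specificity of the
background. Grade bounds are MTSPS multiples (1×, 2×, 3×, capped at 1) in
half-open intervals with the boundary belonging to the higher class; the
familiar 0.22/0.44/0.66 scheme is the MTSPS = 0.22 case. Binarization for
change analysis is strict (`HSI > MTSPS` is suitable; equality is not —
"suitable" means exceeding the threshold). Areas are spherical:
`(cellsize·111.19493 km)²·cos(lat)` per cell, Earth radius 6371.0088 km;
the same sphere serves the haversine distances and centroid bearings. No
ellipsoid: the quantities reported (areas to 0.01×10⁴ km², distances to
0.01 km) do not resolve the difference.

Change maps code absent/expansion/stable/contraction as 0/−1/1/2; the
accounting identity `area_future = area_current + gain − loss` holds
exactly by construction. Periods 20 years apart ("2050s" → "2070s") give
centroid speeds as distance/20; migration between scenarios is assumed
unrestricted (no dispersal constraint). Compass labels use eight
45°-sectors centered on the cardinal and intercardinal bearings.

## Occurrences

Cleaning drops unparseable and out-of-range coordinates, collapses exact
duplicate coordinates (no rounding first), and optionally drops records on
masked cells; every drop is counted in the cleaning report. Thinning is
greedy at a minimum great-circle spacing (default 2.5 km): records are
visited in a seed-shuffled order and kept iff at least `min_km` from every
already-kept record, so the result's pairwise minimum distance is
guaranteed and re-thinning is a no-op. The shuffle removes file-order
bias; the spacing is a parameter because one-per-cell thinning at the grid
resolution (~4.6 km ground size at 2.5 arc-min) is an equally defensible
reading — pass `min_km=4.6` for that behavior.

## Variable screening

Pairwise Pearson correlation over all jointly valid landscape cells
(optionally a seeded subsample; landscape-wide is more stable than
presence-only sampling). Pairs with |r| ≥ 0.8 are resolved iteratively —
largest |r| first, dropping the member with the lower percent contribution
from a baseline (default-settings LQHPT, RM 1) fit — until all surviving
pairs are below the threshold. A user-supplied priority list (biological
significance) overrides the contribution comparison where it covers both
members; exact ties drop the later name in the matrix's canonical order so
the kept set is order-invariant. Zero-variance layers are flagged,
treated as uncorrelated, and warned about.

## The synthetic study system

The generator exists so the whole pipeline has a known answer. It
emulates: spatial autocorrelation (Gaussian random fields smoothed to a
chosen correlation length — default 8 cells), inter-layer collinearity
(a mixing matrix; the default stack has one pair at r ≈ 0.85 to exercise
screening), a deterministic latitudinal temperature gradient (−1 unit per
degree, colder northward), a truth surface from stated linear/quadratic
responses (interior thermal optimum, positive precipitation response),
presences sampled proportionally to truth (200 by default, one per cell),
and a "future" scenario that warms the temperature layer by +0.5 units —
translating the suitable band ~0.5° poleward.

It does not emulate: GCM physics or realistic bioclimatic covariance
structure, non-stationary responses, observation error in coordinates,
dispersal limits, or biotic interactions. Passing tests therefore show
that the estimators recover what they are defined to recover under clean
presence-only sampling on an autocorrelated, collinear landscape — not
that any real-data analysis is correct.

Default sizes (5 layers, 120×120 cells at 2.5 arc-min, 200 presences,
10,000 background, seed 42) were chosen as the smallest system on which
hinge-rich models are non-trivial, spatial partitioning has all four
groups populated, and the full 56-candidate grid search completes in a
few minutes on one CPU; the cross-validated recovery correlation with the
truth exceeds 0.9 there with margin.

## Known limitations

* One grid, one CRS: no reprojection or resampling; inputs must be
  co-registered upstream.
* The bootstrap replicate convention (resample with replacement, then
  75/25 split) is one of two defensible readings; the order is isolated in
  the pipeline and easy to swap.
* Percent contribution is path-dependent (as in MaxEnt itself): it is
  reproducible given a seed but not an estimand; permutation importance is
  the stabler measure and both are reported.
* AICc for penalized likelihoods counts nonzero coefficients as `k`, the
  common convention, which understates effective complexity at small RM.
* The Java MaxEnt `.lambdas` format is not read or written; models
  serialize to a self-contained JSON document instead.
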