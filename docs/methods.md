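# Methods

## Model

The mapper embeds `p` features as latent points on the unit square by
Bayesian metric multidimensional scaling.  Observed feature distances
(Euclidean distances between feature columns over the samples, linearly
rescaled so the largest is 1) are modelled as truncated-normal perturbations
of the latent planar distances:

    d_jk ~ N(δ_jk, σ²) I(d_jk > 0),   δ_jk = ‖s_j − s_k‖,
    s_j ~ U([0,1]²),                   σ² ~ IG(a, b),  a > 2, b > 0.

The distance rescaling is a package choice: raw column distances grow like
√n and would be incommensurate with δ ∈ [0, √2]; a single multiplicative
factor preserves the geometry the method relies on.  The truncation penalty
−Σ log Φ(δ_jk/σ) is kept in the location updates; the σ² Gibbs step uses the
large-q inverse-gamma approximation IG(q/2 + a, ½Σ(d−δ)² + b), which drops
that penalty — accurate once q = p(p−1)/2 is more than a few dozen.

### Sampler

One sweep = a Metropolis update of every location (isotropic Gaussian
proposal, reflected at the unit-square boundary so the uniform support is
exact and the proposal stays symmetric) followed by one σ² draw.  Defaults:
`a = 3`, `b = 1` (weakly informative, prior mean σ² = 0.5 on rescaled
distances), `n_iter = 2000` sweeps with `burn_in = 1000`, `proposal_sd =
0.05`, thinning 10.  All randomness flows through one seeded generator, so
maps are bit-reproducible.  Because the locations are identifiable only up
to rigid motions, convergence is monitored on the induced distances and σ²
(both in the trace).

### Point estimate

The posterior mode is the point estimate.  A finite chain's best *visited*
state wanders on the flat plateau around the mode (its induced distances
move by ~0.04 even after tens of thousands of sweeps on a 3-point toy), so
the fit polishes the best visited state with L-BFGS-B — analytic gradient,
locations box-constrained to the square, σ² on the log scale — and keeps the
result only when it improves the log posterior (`polish=False` restores the
raw proxy).  Retained posterior draws are available as alternative maps for
augmentation (`posterior_draw_maps`).

## Grid assignment and hill climbing

The square is tessellated into the smallest square grid holding all
features, side `⌈√p⌉` (672 features → 26 × 26).  Each feature takes the
pixel containing its location; a collision moves the later feature (label
order) to the nearest free pixel by increasing Chebyshev ring, ties broken
row-then-column — deterministic and local.

Hill climbing minimizes `Σ_{j<k} |pixdist_jk − δ̂_jk|`, with pixel distances
measured between pixel centres and divided by the grid side so they share
the unit-square scale of δ̂ (the distances induced by the estimated
locations; ablation paths that skip the Bayesian step use the observed
rescaled distances instead).  Sweeps visit pixels in row-major order; the
feature at each occupied pixel tries all eight Moore-neighbour exchanges
(occupied neighbour → swap, empty → move) and takes the best strictly
improving one.  Strict improvement guarantees termination; the default cap
is 50 sweeps, and terminal states are 1-swap local optima (verified by
exhaustive enumeration in the tests for p ≤ 9).  Single greedy exchanges are
used rather than multi-feature permutations of the 3 × 3 patch; the
patch-permutation variant would be a possible extension.

## Initializers

The default initial embedding is classical (Torgerson) MDS — deterministic,
exact when the distances are planar-realizable — rescaled into the unit
square by a similarity transform (both axes share one scale factor, so the
shape is preserved; per-axis scaling would distort distances).  Ablation
alternatives: isomap on the precomputed distances, locally linear embedding
(run on full-rank MDS coordinates, since LLE needs points rather than
distances), Laplacian eigenmaps on a k-nearest-neighbour graph, and uniform
random locations.  Non-MDS initializers skip the Bayesian refinement, so
they isolate the contribution of each stage.

## Rendering and baseline mappers

Rendering is lossless: a mapped pixel carries the sample's feature value
exactly, empty pixels a configurable null value (default 0 — neutral for
ReLU convolutions), and `image_to_vector` inverts it bit-exactly.  The
random baseline assigns features to pixels uniformly (seeded); the PCA
baseline places each feature at its loading pair on the first two principal
components of the samples-by-features matrix (the construction of per-feature
PCA coordinates is ambiguous in general; the loading reading is implemented
and stated here).  Images serialize to a numeric archive (exact; used for
training) and optionally to 16-bit grayscale PNG (quantized to 1/65535;
inspection only).

## Synthetic benchmark generator

`simulate_dataset(N, P, gamma, spurious_frac, seed)` draws each sample's
features from a zero-mean Gaussian process on the feature index with
covariance `Σ_ij = γ^|i−j|` (exact multivariate normal via Cholesky — fine
for P up to a few thousand).  A fraction `spurious_frac` of features
(rounded) receives exactly zero weight; remaining weights are standard
normal resampled away from zero (their magnitude is irrelevant after target
normalization).  Targets are `y = Xw` min-max normalized to [0, 1]; no noise
is added by default (a `noise_sd` option exists).  Features are min-max
normalized for rendering.  Defaults γ = 0.7 and 20% spurious features.

What the generator emulates: index-local correlation (so a good map has
genuine neighbourhood structure to recover) and irrelevant features the
method must tolerate without explicit selection.  What it does not emulate:
heavy-tailed or zero-inflated marginals of real descriptor data, nonlinear
response surfaces, or measurement noise on the response.  In particular the
target is *exactly linear with randomly signed weights*, so adjacent
(correlated) pixels of a distance-preserving map carry unrelated target
contributions — a regime that favours full-rank models (a dense network
fits it almost perfectly) and gives convolutional weight sharing little to
exploit.  Passing tests on this generator therefore validate the mapping
and training machinery, not a universal predictive advantage of mapped CNNs
over alternatives at these problem sizes.

## CNN engine

A self-contained numpy implementation: valid-padding strided convolution via
im2col, batch normalization (running statistics, momentum 0.9), ReLU,
inverted dropout parameterized by the *retain* probability, dense layers, a
linear or sigmoid head, and Adam.  Gradients are verified against central
finite differences in the tests.  Inference uses running batch-norm
statistics with dropout disabled, so predictions are batch-size independent.

Reference architectures (declarative `ArchitectureSpec`s):

* regressor: two conv layers of 64 7×7 kernels with stride 2 and valid
  borders, each + batch norm + ReLU; dense 256 and 64 (+BN+ReLU); dropout
  retain 0.7; linear output.  On a 26 × 26 input the first conv yields
  10 × 10; on inputs too small for the stack the builder raises, naming the
  layer.
* classifier: conv 16 7×7, 32 7×7, 64 3×3 (stride 1), dense 256/64, sigmoid.
* hybrid: two arms (60 5×5 s1, 72 6×6 s2, then 72 5×5 — stride 2 on the
  cell-line arm, stride 1 on the drug arm), concatenated, dense 305/175,
  dropout retain 0.7, linear.

Training defaults: Adam `lr = 1e-4`, batch 128, early stopping on validation
loss with patience 20 and best-weight restore (the stopping rule is a
package choice).  The regressor text implies two identical conv layers; that
reading is implemented.  The desk-scale benchmark (`refined.pipeline`) uses
a compact variant that fits 10 × 10 images — conv 32 7×7 s1 + 64 3×3 s1,
dense 64/16, dropout retain 0.7 — trained 200 epochs at `lr = 3e-3`; both
the optimized-map and random-map arms always share the identical
architecture, budget and training seeds, so their comparison is paired.

## Evaluation statistics

* NRMSE, NMAE: error of the model over the error of the intercept-only
  predictor (1 = no better than the mean).  NMAE for y=(0,1,2), ŷ=(0,1,1)
  is 0.5 (Σ|y−ŷ| = 1 over Σ|y−ȳ| = 2).
* Bias: two non-equivalent readings are exposed and never silently merged —
  the literal vector angle θ = ∠(y, y−ŷ) (default; bias = tan θ, 0 for a
  zero residual by convention) and the OLS slope of residuals on
  observations with θ = arctan(slope).
* Gap statistics: per bootstrap replicate the test pairs are resampled and
  a null model predicts by sampling the training responses; each pooled
  metric distribution (model + null) is summarized by 1-D k-means with k=2,
  centroids initialized at the extremes, ≤100 Lloyd iterations; the
  centroid difference is the gap.  Default 10,000 replicates, reducible for
  desk-scale runs.
* Robustness: fraction of replicates where one model strictly beats another
  (lower NRMSE/bias, higher PCC).  Bootstrap inputs are put in a canonical
  sort order first, so results are invariant to the order test samples
  arrive in.
* Intervals: percentile bootstrap for regression metrics; binomial
  proportion CI in its normal-approximation form (Wilson optional).
* McNemar: exact binomial on the discordant pairs when they number < 25,
  chi-square with continuity correction otherwise; p = 1 (flagged) when the
  models never disagree.
* BC1 bias correction: OLS of residuals on observations on a fitting set;
  applied to new predictions the correction uses ŷ as the regressor (y is
  unknown at test time), which provably shrinks a linear residual slope β
  toward β² rather than zero; `use_observed=True` applies the exact
  correction where y is available.
* Stacking: NNLS of validation responses on the validation prediction
  matrix.  Predictions use the raw NNLS coefficients (this guarantees the
  stack is at least as good as the best single model on the validation
  set); sum-normalized weights are also returned for interpretation.

## Numerical choices and degenerate inputs

Constant feature columns normalize to zero rather than aborting; zero
residual vectors report bias 0; classification metrics with empty
denominators are NaN-flagged per field rather than fatal; k-means on a
degenerate (constant) pooled distribution returns equal centroids; the
truncation term uses `log_ndtr` for stability; coincident locations in the
mode polish are guarded against zero division; collision resolution and
hill climbing break ties deterministically (row-then-column), so every map
is reproducible from its seed.

## Problem sizes

Tests and the benchmark command run at desk scale by configuration, not by
code changes: the Bayesian sampler uses 600 sweeps (300 burn-in) for
100-feature problems, the CNN benchmark uses N = 1000 samples on 10 × 10
images, and bootstrap statistics accept reduced replicate counts.  All of
these are public configuration knobs whose defaults match the larger values
stated above.

## Known limitations

A 2-D embedding cannot represent the full geometry of weakly correlated
high-dimensional features: on the GP benchmark the achievable correlation
between any planar embedding's distances and the observed distances
plateaus near 0.55, and the pixel map inherits that ceiling relative to the
*observed* distances (it tracks the *estimated* planar distances at
r ≈ 0.9+).  Hill climbing is a local optimizer; global assignment solvers
are out of scope.  Images are single-channel and unsmoothed.  The CNN engine
targets small images on CPUs; it is not a general deep-learning framework.
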