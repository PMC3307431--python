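# Methods

## Model and estimation

Classifier accuracy as a function of training-set size is modelled as
`Y(x) = 1 − a − b·x^c` with `a ∈ [0, 1)`, `b ≥ 0`, `c ∈ [−1, 0)`. The
parameter box reflects the behaviour of saturating learning curves: the
asymptote `1 − a` is the best accuracy the feature set and classifier
can reach; `c` governs how quickly the curve flattens. For optimisation
the open endpoints are made numerically safe (`c ∈ [−1, −1e−8]`,
`a ∈ [0, 1 − 1e−8]`); a fit that lands on a bound is still reported, but
a model with `b = 0` or `c ≥ 0` cannot be inverted and raises a
degenerate-model error.

Estimation minimises the weighted sum of squared residuals
`Σ_j w_j (y_j − f(x_j))²` with `w_j = j/m`. The weight denominator `m`
defaults to the number of fitting points, since in a live annotation
project only the fitting partition exists; because least squares is
invariant to a common rescaling of the weights, this choice affects
nothing but the printed objective (asserted to 1e−10 in the tests). The
optimiser is scipy's bounded trust-region-reflective least-squares
solver with an analytic Jacobian, run from a deterministic three-start
ladder: a heuristic start (`a0 = max(0, 1 − y_last − 0.01)`,
`c0 = −0.5`, `b0` solved from the last point) plus variants with
`c0 = −0.2` and `−0.8`. The best objective wins; ties keep the first
start. Multistart guards against the shallow ridge in `(b, c)` that the
model exhibits when the fitted range of `x` spans less than a decade;
on noiseless curves the global optimum is recovered to ~1e−14, and a
dense-grid-plus-polish oracle agrees with the optimiser on noisy
fixtures to 1e−6.

Fits require at least 5 points — below that the three-parameter model is
effectively unidentified and recommendations would be noise.

## Uncertainty

The parameter covariance is the Gauss–Newton estimate
`Cov(β̂) = σ̂² (JᵀWJ)⁻¹`, with `σ̂²` the weighted residual sum of squares
over `n − 3` degrees of freedom and `J` the model Jacobian at the
estimate. This is the covariance that nls-family software reports and is
exact in the linearised model; the full-Hessian variant is deliberately
not implemented. Pointwise confidence intervals for predicted accuracy
use the delta method, `Var(ŷ(x)) = g(x)ᵀ Cov(β̂) g(x)` with `g` the
gradient of the model in `(a, b, c)`, and a Student-t quantile with
`n − 3` degrees of freedom — with as few as 5 fitting points, a normal
quantile would be noticeably anticonservative. A singular `JᵀWJ` falls
back to the pseudoinverse and marks the band with a wide-band warning
instead of raising. The upper bound is clipped at 1.0 for presentation
(accuracy cannot exceed 1); coverage experiments disable the clip.

The delta-method variance assumes the noise variance at point `j` is
proportional to `1/w_j`. On the `x_j = k·j` schedule the weights `j/m`
are exactly inversely proportional to a noise variance that decays as
`1/x` — the decay produced when each curve point is the mean of many
repeated train/test runs (binomial error shrinking with training size).
Under that matched regime the empirical coverage of the 95% band at a
2× extrapolation horizon is 95–98% over 500 replicates (n = 10 fitting
points, noise 0.01). Under mismatched noise the band can be optimistic;
this is a property of the method, not corrected here.

## Learning-curve construction

Curves are built on the schedule `x_j = m0 + (j−1)·k`, default
`m0 = k = 16`. The classifier is a linear-kernel SVM with complexity
constant 1 and tolerance 1e−3, no feature normalisation; any classifier
exposing `fit`, `predict` and a signed `decision_function` can be
substituted via the `classifier_factory` hook. A training batch that
happens to contain a single class trains a constant predictor rather
than aborting the repetition. Accuracy is measured on a fixed held-out
test set; repetitions re-draw the sampling order, not the train/test
split. Per-point standard deviations over repetitions are attached to
the curve for variability reporting.

Sampler details that were genuinely open design choices:

* **First batch** of every strategy (including the active ones) is drawn
  uniformly at random — an untrained model has no margin to sample.
* **DIV aggregation**: a candidate's diversity is its *minimum* cosine
  distance to the union of the training set and the candidates already
  picked this batch (greedy max-min). Min is the stricter
  anti-redundancy reading; mean aggregation is available via
  `diversity_aggregate="mean"`.
* **CMB fusion**: the margin and diversity criteria are combined by
  shortlist-then-diversify — the `3k` candidates nearest the hyperplane
  are shortlisted, then `k` of them are picked by greedy diversity. The
  shortlist factor is configurable. This is one standard hybrid; other
  fusions (score averaging, alternation) would satisfy the same
  interface.
* All ties resolve to the lowest pool index, making every sampler
  bit-reproducible under a fixed seed.

## Evaluation protocol

A curve `Ω` is split at a threshold size `x_s` into the fitting
partition `Ω_t` (`x ≤ x_s`) and validation partition `Ω_v` (`x > x_s`).
Extrapolations are scored on `Ω_v` by MAE and RMSE (root of the mean of
squares; RMSE ≥ MAE always, by the power-mean inequality — asserted on
every grid cell). Sweeping `|Ω_t|` from 5 to a per-curve cap produces a
tidy results grid; with 8 curves capped at 62 points and 4 at 30, the
sweep contains exactly 568 cells. Weighted and un-weighted fits are
compared cell-by-cell with a one-sided paired t-test (alternative:
baseline error exceeds weighted error). Degenerate inputs are reported,
not raised: identical error vectors give p = 1 with a zero-variance
flag; constant nonzero differences give an unbounded statistic, reported
as p = 0 with the same flag. Cells whose fit failed are dropped pairwise
with a logged count.

## Synthetic data

`simulate_learning_curve` draws `y_j = clip(f(x_j) + ε_j, 0, 1)` with
`ε_j ~ N(0, sd_j)`; `sd_j` is constant or, in the "decreasing" profile,
`noise_sd · sqrt(x_1/x_j)` (so `noise_sd` is the first point's sd). The
decreasing profile emulates curve points that are averages over many
repeated runs; the constant profile is kept for robustness checks.
Clipping events are counted and reported; the specs used in tests keep
them at zero. `simulate_dataset` produces Gaussian blobs (separation
parameter from pure noise to fully separable), a waveform-like task —
21 continuous features formed as `u·h_i + (1−u)·h_j` from three
triangular basis waves of height 6 plus unit Gaussian noise, labelled
wave-1 vs the rest — and a sparse-binary text-like task with
class-dependent word-firing rates. These generators reproduce the
*shape* regimes the method must handle (separable vs overlapping,
dense vs sparse features); they do not emulate clinical-text realism
(vocabulary, negation, label noise), so passing tests demonstrate
correct behaviour of the method, not performance on any particular real
corpus.

## Simulation-study design choices

* **Parameter recovery** (200 curves, 20 points, noise 0.005): uses the
  decreasing-noise profile, matching the repetition-averaged curves the
  method is designed for. On the 16..320 schedule the exponent `c` is
  only weakly identified; with constant noise its median absolute error
  roughly doubles and can exceed 0.05 — a genuine identifiability limit
  of three-parameter power laws on short, narrow-range curves, not an
  optimiser artifact (noiseless recovery is exact to ~1e−14).
* **Weighted-vs-baseline comparison** (200 independent curves, 60
  points, fit on the first 30): one cell per curve keeps the t-test's
  independence assumption honest (cells sharing a curve share validation
  noise). The weighted fit's advantage here is estimator efficiency
  under the matched decreasing-noise regime; it needs a moderately sized
  fitting partition (≳10 points) to express itself. At 5–9 points
  neither estimator is well identified and the comparison is dominated
  by fit instability. On real curves the weighted method's advantage at
  small partitions has an additional source this generator deliberately
  omits: empirical curves deviate from the asymptotic power law at very
  small training sizes, which penalises a fit that trusts early points
  equally.
* Problem sizes throughout (hundreds of fits, 500-replicate coverage
  runs, datasets of a few thousand instances) are chosen so the full
  suite completes in a few minutes on a single core while keeping
  Monte-Carlo error well below the margins being asserted.

## Known limitations

* The inverse power law is the only curve family; exponential or
  logarithmic saturation models are out of scope.
* Confidence bands are first-order (delta method) and can undercover
  when extrapolating far beyond the fitted range or when the noise
  regime is mismatched; bootstrap or profile-likelihood intervals are
  not provided.
* Sample-size recommendations inherit all model error: when the fitted
  asymptote is below the requested target the recommendation is
  reported as infeasible rather than extrapolated.
* The CMB fusion rule is one reasonable interpretation of a
  margin-plus-diversity hybrid; results for CMB depend on it.
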