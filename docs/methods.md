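# Methods

## Model and fitting procedure

The estimator is component-wise (model-based) gradient boosting with
linear base learners.  Data are n i.i.d. pairs (x⁽ⁱ⁾, y⁽ⁱ⁾) with
x ∈ ℝᵖ; the additive predictor f(x) = β₀ + Σ_j h_j(x_j) is built by
functional gradient descent on an empirical loss ρ.  Starting from the
loss-minimising constant f⁽⁰⁾ ≡ c, iteration m computes the negative
gradient u⁽ⁱ⁾ = −∂ρ/∂f at the current fit, fits h_j(x) = b_j·x to u by
least squares separately for each covariate, selects the component with
the smallest residual sum of squares (equivalently the largest
⟨x_j, u⟩²/⟨x_j, x_j⟩) and updates f by ν·h_{j*}.  The final coefficient
vector is the column-wise accumulation of ν·b over the path, so a
variable has a nonzero coefficient iff it was ever selected.

Assumptions and conventions:

- **Losses.**  Gaussian: ρ = (y − f)²/2, u = y − f, offset = ȳ.
  Binomial with y ∈ {0, 1}: ρ = log(1 + e^f) − y·f on the logit scale,
  u = y − expit(f), offset = logit(ȳ).  The {−1, +1}/half-logit
  parametrisation used by some boosting software is equivalent up to a
  scaling of f and leaves the selection order unchanged; we use the
  0/1 form for a cleaner contract.  An all-0 or all-1 binomial response
  is rejected (infinite offset).
- **Centring.**  Covariates are mean-centred once before fitting; no
  variance scaling.  The centres are stored on the results object and
  re-applied at prediction time, so the reported intercept on the
  original scale is offset − centres·coef.  Base learners carry no
  per-learner intercept; centring absorbs the drift.
- **Tie-breaking.**  Equal selection scores resolve to the smallest
  column index (deterministic and testable).  Exact ties have measure
  zero for continuous data.
- **Degenerate columns.**  Zero-variance columns admit no least-squares
  base learner (0/0); they are excluded from the candidate set rather
  than raising, because permuted copies of constant columns would
  otherwise poison the probing augmentation.
- **Learning rate.**  ν = 0.1 throughout, the conventional "small
  enough" default; the closed-form p = 1 path
  coef_m = β_OLS(1 − (1 − ν)^m) and the OLS limit on full-rank data are
  enforced by tests at 1e−10 / 1e−6.
- **Stopping callbacks** are consulted *before* an update is applied:
  a fired stop leaves the offending iteration out of the model.  This
  is what makes the probing rule exact ("stop when a shadow *would be*
  selected").

## Probing (shadow variables)

Each covariate gets exactly one shadow: an independent uniform random
permutation of its own column (column-wise, not a joint row
permutation), which preserves the marginal distribution exactly while
breaking any link to the response.  Boosting runs on the 2p-column
design and stops before applying the first shadow update; the distinct
original variables in the retained path, in first-selection order, are
returned.  Under a global null the first selected column is a shadow
with probability ½ by exchangeability — a Monte-Carlo test asserts
this.  A safety cap of m_max = 10p iterations guarantees termination
when no shadow is ever competitive; hitting the cap is logged and the
capped model returned.  Rerunning with a different seed may change the
result slightly (the permutations are stochastic); only seed control is
provided, no aggregation across reruns.

## Stability selection

B subsamples of size ⌊n/2⌋ are drawn without replacement (B = 100 by
default; the benchmark uses B = 50 to halve runtime at an acceptable
Monte-Carlo cost).  Each fit stops once q distinct variables entered
the path or after m_cap = 1000 iterations (a capped fit contributes its
partial set and is logged); "selected" is membership in the path,
regardless of coefficient size.  Selection frequencies are exact
rationals with denominator B; the stable set keeps variables with
π̂_j ≥ π_thr.  The per-family error rate bound
E(V) ≤ q²/((2π_thr − 1)p) ties the three hyperparameters together:
exactly two are user-supplied and the third is derived assuming
equality, with q rounded *down* so the realised bound never exceeds a
requested PFER (the rounding direction is our choice; it is the
conservative one).  Single-class subsamples under the binomial loss are
redrawn with a retry limit.  Complementary-pairs subsampling and the
tighter exchangeability-based bounds are out of scope.

## Bootstrap CV stopping

The baseline rule: 25 bootstrap resamples (n-out-of-n with
replacement), the path fitted to m_max = 1000 on the in-bag rows, mean
loss evaluated on the out-of-bag rows at every iteration by replaying
the stored path incrementally (no refit per grid point).  m_opt is the
smallest minimiser of the averaged curve (ties → sparser model), and
the full-data path truncated at m_opt yields the selection.  Resamples
with an empty out-of-bag set or a single in-bag class are redrawn.
m_max = 1000 is a configurable default; the risk curves in the
benchmark scenarios flatten well before it.

## Synthetic benchmark

The generator emulates a high-dimensional binary-outcome study:
X ~ N(0, Σ) with Σ_ij = 0.9^|i−j| sampled exactly via the AR(1)
recursion x_j = ρx_{j−1} + √(1−ρ²)z_j (O(np), no Cholesky), p_inf
support positions drawn uniformly without replacement, nonzero
coefficients from U(−1, 1) — redrawn fresh, values *and* positions, in
every replicate so the correlation pattern among informative variables
varies — and y ~ Bernoulli(expit(Xβ)).  Single-class responses are
redrawn.  The full grid is n ∈ {100, 500} × p ∈ {100, 500, 1000} ×
p_inf ∈ {5, 20} (12 scenarios); FDR of an empty selection is defined
as 0.  Per-replicate RNG streams are spawned from the root seed keyed
by (scenario, replicate, method), so any record is reproducible in
isolation and replicates could be run in parallel.

What the generator does **not** emulate: heavy-tailed or discrete
covariates, batch effects, missing data, and effect sizes bounded away
from zero — U(−1, 1) draws can be arbitrarily tiny, so "informative"
variables near β = 0 are genuinely unidentifiable and a TPR of 1 is not
attainable in expectation.  Passing benchmark tests therefore show
correct relative behaviour of the selection rules under this model, not
performance guarantees on real expression data.  A `beta_floor` option
(resample |β| < floor) exists for easy test fixtures only and is off by
default.

## Benchmark sizes used in tests and the acceptance script

The distribution-level claims are checked on a reduced grid chosen as a
reasonable Monte-Carlo compromise: the four p = 100 scenarios with 20
replicates each for the CV-greediness comparison (median CV FDR above
50 % in the majority of scenarios; probing's mean FDR below CV's in
every scenario), and 50 replicates of (n = 500, p = 100, p_inf = 5)
with B = 50 for empirical PFER control at target 1 with π_thr = 0.9,
q = ⌊√(1·0.8·100)⌋ = 8 (realised bound 0.8).  Observed values are well
inside the bounds (e.g. mean false-positive counts ≈ 0.1).

## Known limitations

- Linear base learners only; no smooth/spline, tree or random-effect
  components, no multinomial or survival losses.
- Probing v1 stops at the *first* shadow; allowing k > 0 shadow hits
  before stopping is a possible extension, as is combining probing with
  stability selection.
- The PFER bound assumes nothing about exchangeability; tighter bounds
  exist but are not implemented.
- Coefficients returned by probing are strongly regularised (early
  stopping) and are meant for selection, not prediction.
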