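# Methods

## Model and sampler

The core model is Gaussian linear regression with a per-predictor binary
inclusion indicator and a point-mass spike-and-slab prior: included
coefficients get an unconditional `N(0, τ²)` slab with `τ² = 10` — the slab
is deliberately *not* scaled by `σ²`, so the prior is fixed on the
standardized-predictor metric — excluded coefficients are exact zeros, the
prior inclusion probability is `π = .5` per predictor (scalar or
per-predictor vector), the intercept has a flat prior, and the residual
precision `1/σ²` has a `Gamma(shape .01, rate .01)` prior.

Sampling is a systematic-scan Gibbs sweep. For `j = 1..p` the pair
`(δ_j, β_j)` is updated jointly from its conditional given the partial
residual `r = y − β₀ − X₋ⱼβ₋ⱼ`: with `v_j = 1/(x_j'x_j/σ² + 1/τ²)` and
`m_j = v_j x_j'r / σ²`, the indicator is Bernoulli with odds
`π R_j / (1 − π)`, `R_j = √(v_j/τ²) · exp(m_j²/2v_j)` (computed on the
log-odds scale), and `β_j ~ N(m_j, v_j)` if included, else 0. Because `y`
is centered and the columns of `X` are centered, the intercept conditional
is `N(0, σ²/n)` and drops out of every coefficient update. `σ²` is updated
from `1/σ² ~ Gamma(a + n/2, b + RSS/2)` with RSS from the current fit.
This collapsed update samples the same posterior as the
"indicator-times-coefficient" parameterization in which `y = Σ δ_j x_j β_j`
with `β_j ~ N(0, τ²)` independent of `δ_j`; we verified the two agree on
the full benchmark grid.

Implementation notes:

* The sweep is compiled with numba. All random variates (uniforms, normals,
  gamma) are pre-drawn from one seeded `numpy` Generator, so a run is
  bit-identical given `(data, prior, config)` and the kernel is pure
  arithmetic. The running `X'X β` product is refreshed every 1,000
  iterations to cap floating-point drift.
* Initialization: all indicators on, `β` at the ridge solution with penalty
  1e-6, `σ²` at that fit's residual variance — a high-likelihood start that
  shortens warm-up. Defaults are 20,000 draws with 5,000 discarded.
* Update order is the fixed scan `1..p`; a random-scan option exists but is
  off by default for reproducibility. No convergence diagnostics are
  computed by default; chain length is the user's control.
* `SsvsConfig(fix_sigma2=...)` holds `σ²` fixed. This exists for exact
  cross-checks: with `σ²` fixed and `p ≤ 3` the posterior over models is
  computable by enumerating all `2^p` Gaussian marginal likelihoods, and
  the test suite requires the chain MIPs to match that enumeration within
  Monte-Carlo error. It also makes the `π → 1` limit testable against the
  conjugate ridge-like closed form.
* The median model uses a strict threshold (`MIP > .5`); an exact tie
  excludes the predictor. `avg_b = MIP × avg_b_nonzero` holds exactly over
  the draws; `avg_b_nonzero` is NaN for a predictor never included.

### Response scaling in the benchmark

`run_ssvs` takes a centered (not rescaled) outcome, so applied results are
reported in outcome units — this is what the `analyze` command does. The
*benchmark pipeline*, however, scales the response to unit variance before
sampling and back-transforms the model-averaged estimates afterwards,
treating response scaling as part of the SSVS method. Two reasons: the
fixed `τ² = 10` slab is only meaningful on a scale-free metric, and the
benchmark's published behavior (small-effect power ≈ 39% at n = 100, mean
model size ≈ 7.5) is arithmetically consistent only with a unit-variance
response — with the outcome left on its raw scale (variance ≈ 9.1 under
the generator) the same sampler selects small effects ~15 points more
often and null effects ~3× less often than with the scaled response, and
neither power figure matches. Reference implementations of SSVS for
continuous outcomes standardize the response internally for the same
reason.

## Lasso-family comparators

Penalties follow the coordinate-descent convention
`(1/2n)‖y − Xβ‖² + λ‖β‖₁`, with `λ_max = max_j |x_j'y|/n` and a 100-point
log-spaced grid down to `10⁻³ λ_max`. Paths are computed by scikit-learn's
`lasso_path`/`enet_path` (tol 1e-10); KKT conditions of the returned
solutions are verified independently in the tests.

* **Cross-validation.** One seeded fold assignment (sizes differing by at
  most one) is shared by every CV-tuned method on a dataset, so method
  differences are not fold noise. Predictors are standardized once on the
  full sample (a known, slight source of CV optimism, accepted for
  simplicity); within each training fold `X` and `y` are re-centered so
  the fold intercept is honestly estimated. `select_min` takes the
  error-minimizing penalty (largest on ties); `select_1se` the largest
  penalty within one standard error (across folds) of that minimum.
* **lasso(BIC).** Candidate supports are the distinct nonzero patterns on
  the path between the CV-min and 1SE penalties; each is refit by OLS and
  scored with `BIC = n ln(RSS/n) + k ln n`, `k` counting coefficients plus
  intercept (`σ²` is constant across candidates and omitted — rank order
  unchanged); ties favor the smaller support; candidates with `k−1 ≥ n`
  are skipped with a warning.
* **Adaptive lasso.** OLS initial estimator (requires `n > p`; a singular
  design raises with a pointer to ridge initialization), weights
  `w_j = 1/|β̂_j|^γ` with `γ = 1`, solved by rescaling columns and running
  an ordinary lasso. The penalty is chosen by the **one-standard-error
  rule by default**: the widely used CV-lasso tooling extracts the 1SE
  solution by default, and the benchmark's published adaptive-lasso
  behavior (false inclusion 7.7%/2.8% at n = 100/400, small-effect power
  72%/100%) matches 1SE tuning closely while CV-min tuning produces ~3×
  the false-inclusion rate. `rule="min"` restores CV-min, under which
  `γ = 0` reduces exactly to lasso(min).
* **Elastic net.** `α` (the l1 fraction) on the grid `.1, .2, …, 1`, each
  with its own λ grid, jointly tuned by CV-min on the shared folds. A grid
  without a positive `α` is rejected (pure ridge never selects).

## Synthetic-data generator

The generator emulates the benchmark's study conditions: `p = 50`
multivariate-normal predictors in blocks of five with exchangeable
within-block correlation `ρ ∈ {0, .4, .8}` and zero between-block
correlation; ten true raw coefficients `(1.5, .9, .9, .3, .3)×2` placed
either in the leading positions (`independent`, `clustered`) or one per
block (`mixed`); outcome `y = Xβ + ε` with `σ² = 1`; `n ∈ {100, 400}`.
Under independence `Var(Y) = β'β + 1 = 9.1`, so the raw effects correspond
to standardized coefficients ≈ .5/.3/.1; under clustered-with-correlation
conditions `β'Σβ` grows and the standardized effects shrink. Replication
`r` of a condition uses seed `base_seed + r`, and the predictor matrix is
redrawn every replication. The generator produces exactly Gaussian,
homoscedastic, linearly related data — real psychological data are none of
these, so passing benchmarks here speak to selection behavior under the
stated model, not to robustness against misspecification, measurement
error, or missingness.

## Evaluation

Per replication each method reports a selected support (nonzero
coefficients; `MIP > .5` for SSVS), coefficient estimates (model-averaged,
zeros included, for SSVS), and — for methods with a natural threshold
family — per-predictor selection scores: the MIP for SSVS and, for the
lasso, the largest penalty at which each predictor enters the path
(normalized by `λ_max`; predictors never entering score 0). ROC curves
sweep the distinct scores (ties share a point, endpoints appended), and
AUC is the trapezoidal area, computed per replication and averaged; it
equals the Mann–Whitney concordance statistic, which the tests verify by
direct pair counting. Inclusion rates pool (predictor × replication) cells
by effect class. Bias is benchmarked against the raw generating
coefficients (0/.3/.9/1.5) — valid because predictors are standardized and
the outcome unscaled — with relative bias undefined for the null class and
95% spread taken as empirical 2.5/97.5 percentiles. Failed replications
are logged, dropped, and counted, never imputed. Aggregation is invariant
to replication order.

## Scales used in the shipped checks

The packaged acceptance runs use 100–200 replications per condition and
6,000 draws / 1,000 warm-up chains (the defaults remain 20,000/5,000);
rates estimated this way carry binomial Monte-Carlo error of roughly 1–4
percentage points depending on how many predictors a class pools. At
these scales the reproduced quantities sit well inside those bands, with
one open gap documented below.

## Known limitations

* The peak SSVS false-inclusion rate under high within-block correlation
  reproduces in *location* (n = 100, ρ = .8, mixed effects) but not in
  magnitude: an exact-posterior sampler of the stated model yields ~1–3%
  null inclusion there, not the published ~6.6%. The published SSVS null
  rates exceed the exact posterior's by a roughly uniform ~2.5 points in
  every condition, a pattern consistent with estimator noise or an
  implementation artifact in the original software rather than with any
  legitimate prior or scaling variant (we checked both samplers, both
  response scalings, and chain lengths); we do not emulate it.
* Our BIC-refit comparator nearly collapses onto the 1SE support
  (false inclusion ~14%/7% at n = 100/400); published values (~24%/20%)
  suggest the original selection step scored candidates by their
  *penalized* RSS. The textbook OLS-refit BIC is kept.
* Applied-mode missing data are handled by listwise deletion only, with a
  logged count — the same acknowledged limitation as the workflow the
  package reproduces.
* Binary or multilevel outcomes, grouped-predictor selection,
  `p ≥ n` designs for the adaptive lasso, Bayesian lasso / ridge /
  elastic-net priors, and post-selection inference are out of scope.
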