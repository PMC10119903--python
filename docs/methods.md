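# Methods

## Model and assumptions

We observe `(T_i, Y_i, X*_i, Z_i)` for `i = 1..n`: a binary treatment, an
outcome (continuous or binary), surrogates of error-prone covariates and
error-free covariates.  The estimand is the average treatment effect
`τ0 = E[Y(1)] − E[Y(0)]` under:

* **consistency** — `Y = T·Y(1) + (1−T)·Y(0)`;
* **no unmeasured confounders** — `{Y(1), Y(0)} ⫫ T | W`, where
  `W = (X, Z)` collects all pre-treatment covariates;
* **sparsity** — only a subvector `W_I` of `W` predicts `T`; the
  propensity score is `π = P(T=1 | W_I)`;
* **positivity** — `0 < π < 1` for every subject;
* **classical additive error** — `X* = X + e`, `e ~ N(0, Σe)` independent
  of `(T, X, Z, Y(0), Y(1))` (non-differential).  Σe must be supplied:
  known, estimated from replicate measurements, or posited through a
  reliability ratio (sensitivity analysis).

The treatment model is parametric, `π = g(γ0 + γx'X + γz'Z)` with a
logistic, probit or complementary log-log link, and the ATE estimator is
the stabilized IPW contrast (ratio of weighted sums), which is invariant to
rescaling the weights and markedly more stable than the simple-mean form
when some propensities are extreme.  The unstabilized form is available and
the two coincide exactly when the fitted propensity is constant.

## Why SIMEX, and the pseudo-error convention

Plugging `X*` into the treatment model attenuates coefficients and biases
the weights.  SIMEX attacks this empirically: adding *extra* error
`√ψ·e_ik` makes the cumulative error variance `(1+ψ)Σe`, so the trend of
the estimate in ψ, fitted on the grid `C = {0, 0.25, …, 2}` (M = 9 points)
and extrapolated to `ψ = −1`, approximates the error-free estimate.  The
√ψ scaling is essential: under a linear-in-ψ perturbation the variance at
`ψ = −1` would not vanish and the extrapolation would not remove the
error.  A `psi_scaling="linear"` switch preserves the literal alternative
for comparison.  Defaults `K = 500`, `ψ_max = 2` follow the simulation
protocol; the benchmark harness uses `K = 50` (see *Problem sizes* below).

The pseudo-errors `e_ik` are a deterministic function of the seed and the
indices `(i, k)` only.  Step 5 regenerates exactly the same draws from the
grid seed, as the procedure requires: the τ-level curve must be computed on
the same pseudo-data as the coefficient-level curve.

Extrapolant families: `linear` and `quadratic` are exact least-squares
polynomials in ψ; `rational_linear` fits `a + b/(c+ψ)` by
Levenberg–Marquardt, initialized at the exact solution through three
spread grid points.  The rational-linear family is exact for the classical
linear-model attenuation curve `β·σx²/(σx² + (1+ψ)σe²)` (a property the
tests verify to 1e-8).  If the fitted pole `−c` falls inside `[−1, ψ_max]`
the code falls back to quadratic with a warning.  Constant trajectories
short-circuit to the constant for every family.

## Treatment-model solver

Fisher scoring from a zero start with step-halving on the Bernoulli
log-likelihood; convergence when `‖score‖∞ < 1e-8`, at most 100
iterations.  Probabilities are clipped to `(1e-10, 1 − 1e-10)` so the
cloglog/probit score weights stay finite; the clip is far outside the range
that affects estimates at realistic linear predictors.  Coefficients larger
than 100 in magnitude (on standardized covariates) trigger a separation
warning and are capped.  Non-converged fits inside the SIMEX loop are
dropped from the K-average (error if a whole ψ level fails, warning beyond
10% drops).  Covariate standardization is provided as an explicit
preprocessing step (`standardize`); the synthetic generator produces
standardized covariates by construction.

## Selection step: loss scaling, BIC, and a sign correction

The penalized loss is `ℓP(γ) = ½(γ−γ̃)'Vₙ(γ−γ̃) + n·Σ_{j≥1} p'λ(|γ̃ⱼ|)|γⱼ|`
with `BIC(λ) = 2ℓ(γ̂(λ)) + 2(log n)·df_λ`.  Two deliberate choices:

* **Signs.**  Subtracting the penalty from the loss, or negating the BIC's
  fit term, is degenerate under minimization; the implemented signs are the
  standard ones and reproduce the intended behavior (shrinkage; BIC trading
  fit against sparsity).
* **Scaling of Vₙ.**  The asymptotic theory requires `Vₙ/n → V` positive
  definite, so the *user-facing* weight matrix is `V` with `Vₙ = n·V`,
  default `V = I`.  With a literally O(1) Vₙ the BIC's `2(log n)·df` term
  would dominate any fit term and the criterion would always pick the empty
  model; with `Vₙ = n·I` the fit term is `n·‖γ̂−γ̃‖²`, the usual n:log(n)
  balance, and the `V = I` minimizer is the closed-form soft-threshold
  `γ̂ⱼ = sign(γ̃ⱼ)(|γ̃ⱼ| − p'λ(|γ̃ⱼ|))₊`.

SCAD uses shape `a = 3.7`; its derivative weight is λ below λ, decays
linearly on `(λ, aλ)` and is zero beyond, which leaves large pilot
coefficients untouched (near-unbiasedness) while thresholding small ones.
For general positive-definite V the minimizer is computed by cyclic
coordinate descent (tolerance 1e-9), verified against the closed form at
`V = I` to 1e-8 and against a derivative-free optimizer on random
instances.

The λ grid is 50 log-spaced values spanning `[1e-4, 1] × max|γ̃ⱼ|`
(from shrink-nothing to shrink-everything); BIC ties break toward the
larger λ, i.e. the sparser model.  `|γ̂ⱼ| < 1e-10` counts as excluded for
df and `#S`; df includes the (always active) intercept.  Must-include
covariates get penalty weight 0; alternatively `forced_ate` adds them after
selection with their unpenalized pilot coefficients.

## ATE step and inference

Step 5 reuses the shrunken selected coefficients as-is (no post-selection
refit; `refit=True` re-runs the unpenalized SIMEX pipeline on the selected
submodel).  No propensity truncation is applied by default — the stabilized
estimator is the intended guard — and fitted propensities outside
`(0.01, 0.99)` raise a `PositivityWarning` rather than an error.

The asymptotic variance of τ̂ requires the true extrapolation function and
closed-form derivative expressions that a working extrapolant cannot
provide honestly; inference instead uses a nonparametric bootstrap over
subjects (default `B = 200`), re-running all five steps per resample with
fresh pseudo-errors, with normal-approximation CIs and p-values.  More than
20% failed resamples is an error.

## Synthetic designs: what they emulate, and a caveat

`SimulationDesign` reproduces the benchmark generator: `(X, Z) ~ N(0, Σw)`
with unit-variance AR(0.5) blocks and cross-covariances `0.4^(2+|j−k|)`
(read as a power — the multiplicative reading yields an indefinite matrix);
`n = 400`, `px = pz = 15`; treatment coefficients
`γ0 = 1, γx = γz = (1₄, −1₄, 0₇)`; outcome coefficients
`βx = βz = (1₈, 0₇)`; a linear-Gaussian outcome (true ATE exactly 1) or a
logistic-binary outcome (true ATE by Monte-Carlo integration, N = 5000
default); diagonal error covariance `σe²·I` with `σe² ∈ {0.15, 0.5, 0.75}`.

The generator emulates correlated continuous confounders with homoscedastic
non-differential error.  It does **not** emulate non-normal or discrete
covariates, differential or heteroscedastic error, or model
misspecification of the treatment link — passing tests therefore say
nothing about those regimes.

**Caveat — the default design is an extreme-propensity regime.**  With the
default coefficients the treatment linear predictor has variance ≈ 30, so
most propensities lie near 0 or 1 (about 7% below 1e-3) and the n = 400
logistic fit is close to separation.  Consequences, all visible in the
benchmark output: per-component coefficient noise of order 0.5–1 (L1 losses
of order 10, selection that can only partially discard noise covariates)
and τ̂ sampling SD of order 2–4.  The *qualitative* behavior is as expected
— `#FN ≈ 0`, bias magnitudes ordered true-X < proposed < full < naive, the
proposed correction reducing the naive bias — but the absolute coefficient
losses and τ̂ SDs are orders of magnitude larger than they would be in a
moderate-overlap design at this n.  Users wanting a well-posed testbed
should scale down `gamma_x`/`gamma_z` (the unit and property tests use such
tame configurations); the benchmark defaults are kept as the fixed
reference conditions.  Relatedly, the reported signal-to-noise of the
surrogates equals `1/σe⁴`, consistent with σe being a standard deviation,
but `σe²` is implemented as a variance throughout.

## Problem sizes and numerical defaults

The replicate harness (`run_benchmark`) and `scripts/acceptance.py` use the
reduced-scale profile: 100 replicates, `K = 50`, the 9-point ψ grid and
quadratic extrapolation (≈ 1–2 minutes on one CPU); the full-scale profile
(`reps = 500`, `K = 500`) is a parameter change away.  Benchmark coverage
rates are reported only when `bootstrap_B > 0`, since bootstrap CIs inside
the replicate loop multiply the cost by B; CR% is NaN otherwise.
Per-replicate seeds are spawned from one master seed, so results are
independent of execution order and bit-reproducible.

## Known limitations

* Only likelihood scores are implemented for the treatment model (not
  general unbiased estimating functions), and only the three named links.
* Discrete error-prone covariates (misclassification) are out of scope.
* The working extrapolant is an approximation; the estimator is exactly
  consistent only when the true extrapolation function lies in the chosen
  family, and results can be sensitive to that choice (compare families via
  the `extrapolant` parameter).
* No doubly robust augmentation: a misspecified treatment model biases τ̂.
* The efficient weight-matrix choice `V = Σ̃⁻¹` (inverse covariance of the
  pilot) is accepted as input but not estimated internally.
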