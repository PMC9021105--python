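# Methods

## Model and assumptions

The package implements an area-level Poisson mixed model in which a block
of covariates is observed with known sampling error.  For domains
d = 1..D:

- `y_d | p_d ~ Poisson(ν_d p_d)` with known size parameter `ν_d` (the
  domain sample size in survey applications);
- `log p_d = x̃_d β + φ v_d`, `v_d ~ N(0,1)` i.i.d.;
- the true covariates split into an error-free block `x̃_{0,d} = x_{0,d}`
  and an error-prone block `x̃_{1,d} = x_{1,d} + u_d`,
  `u_d ~ N(0, Σ_d)` with known per-domain covariance `Σ_d`.

All inference is conditional on the observed `x_d = (x_{0,d}, x_{1,d})`,
so the latent exponent is `x_d β + u_d' β₁ + φ v_d` with
`(u_d, v_d)` independent normal.  Key assumptions: the error covariances
are known (in practice: design-based estimates from the covariate survey,
treated as fixed), the two surveys are independent (no error covariance
between `y_d` and `x_{1,d}`), and errors and random effects are normal.
The sign of φ is not identified; the nonnegative representative is
reported.

## Marginal moments and the moment system

The exponent is normal with mean `x_d β` and variance
`q_d + φ²`, `q_d = β₁' Σ_d β₁`, hence by the lognormal
moment-generating function

```
E[y_d]  = ν_d exp(x_d β + q_d/2 + φ²/2)
E[y_d²] = E[y_d] + ν_d² exp(2 x_d β + 2 q_d + 2 φ²)
```

Both forms are verified in the test suite against brute-force Monte-Carlo
simulation of the three-stage model (3-standard-error criterion, up to
10⁶ draws).  θ = (β, φ) solves the p+1 equations matching
`Σ E[y_d] x_dk` to `Σ y_d x_dk` (k = 1..p) and `Σ E[y_d²]` to `Σ y_d²`.

Numerical choices for the Newton–Raphson solver:

- The system depends on φ only through φ², so the iteration runs on
  ψ = φ² unconstrained.  This keeps the last Jacobian column bounded away
  from zero at the boundary (in (β, φ) coordinates it is proportional to
  φ), removes the need for a starting-value floor, and gives
  underdispersed samples a well-defined solution with ψ̂ < 0, reported as
  φ̂ = 0.  Such samples occur regularly inside bootstrap loops.
- Start values: β from the Poisson log-linear fit with offset `log ν`
  (damped IRLS, which is the φ = 0, Σ = 0 moment system), ψ⁽⁰⁾ = 0.01.
- Convergence: max-norm of the equation vector below
  `tol · max(1, ‖M̂‖∞)` with tol = 1e-8 — relative, because the moment
  sums scale with D·ν and an absolute criterion would not be attainable in
  double precision for large problems.  Default cap 100 iterations; a full
  step that does not reduce the residual is halved up to 10 times; failure
  is flagged, never silently returned.
- All exponent evaluations that enter ratios (the EBP integrands) are
  max-shifted per domain (log-sum-exp); the moment forms are assembled on
  the log scale before a single exponentiation.

## Prediction

The best predictor of `p_d` is `E[p_d | y_d, x_d]`, a ratio of integrals
over `(u_d, v_d)`.  The EBP plugs in θ̂ and evaluates both integrals by
antithetic Monte Carlo: L draws `(u, v)` per domain plus their negations,
averaged on the log scale; the exponent uses the error-prone coefficient
block only (`u' β̂₁`), matching the single-model formulation.  A
Monte-Carlo standard error is reported from the variance of the
antithetic pair means via the delta method for a ratio; with Σ_d = 0 and
φ̂ = 0 the integrands are constant and the EBP collapses exactly to the
synthetic predictor `exp(x_d β̂)`.  Default L = 500 (1000 evaluation
points per domain), which puts the MC error well below the sampling
uncertainty at benchmark scales; the suite cross-checks the q₁ = 1 case
against two-dimensional Gauss–Hermite quadrature.

The Poisson-mixed baseline (no measurement error) is fitted by
Laplace-approximate ML: the integrand in `v` is strictly log-concave
(−h''(v) = φ²μ + 1 > 0), the per-domain mode is found by 1-D Newton, and
the outer optimization (BFGS) uses the exact gradient of the Laplace
objective obtained by implicit differentiation through the mode.  Its EBP
is a ratio of one-dimensional integrals, evaluated with 25-node
Gauss–Hermite quadrature by default (deterministic; node-count stability
is tested), antithetic MC optionally.

## Uncertainty estimation

- **Predictor MSE**: parametric bootstrap.  Per replicate, new latents and
  counts are drawn from the fitted model, the model is refitted by the
  method of moments, the EBP recomputed, and the squared deviation taken
  against the *latent* bootstrap truth `μ_d^(b)` (recorded before Poisson
  noise).  Defaults B = 300; comparing MSE estimates *between* domains
  reliably needs B ≥ 600 (a warning is issued below 100).  Rare refit
  failures are skipped, with a 10% failure ceiling.  The estimator has
  O(D⁻¹) bias and is validated for level, not unbiasedness; no double
  bootstrap is provided.
- **Parameter covariance**: variant A bootstraps only the sample-moment
  vector and applies the Taylor sandwich `H⁻¹ var(M̂) H⁻ᵀ`; it is computed
  in (β, ψ) coordinates, where the Jacobian stays invertible even at
  φ̂ = 0, and mapped to (β, φ) by the delta method with a boundary-safe
  effective φ (var(φ̂) ≈ sd(ψ̂)/4 at the boundary).  Variant B refits every
  bootstrap sample and returns the empirical covariance of the refitted
  parameters.  Both are available; they agree at benchmark scales and are
  tested against each other and against the GLM Fisher-information limit.
- **Significance**: per-parameter t intervals
  `θ̂_k ± t_{D−p,1−α/2} sd(θ̂_k)`; a parameter is significant when zero
  falls outside its interval.
- Every stochastic routine takes an explicit seed; bootstrap replicate b
  and simulation replicate i use child seeds derived deterministically
  from (seed, index) through numpy `SeedSequence` spawn keys, so any
  replicate is reproducible in isolation.  Within one EBP call the draws
  come from a single seeded stream indexed by (domain, ℓ); domains remain
  mutually independent.

## Synthetic benchmark: what it emulates

`ScenarioConfig` reproduces the benchmark's data-generating process: D ∈
{50, 75, 100, 125}, ν = 300, β = (−4, 0.5, 0.5, −0.5, −0.5), φ = 0.3;
four error-prone covariates drawn once per scenario from U(1.0, 1.4) and
held fixed over replicates, as are the per-domain error scales drawn from
U(0.05, 0.15); `(u, v, y)` are redrawn each replicate.  Two aspects of the
error-covariance law required a decision:

- **Error scale.**  The benchmark description presents the U(0.05, 0.15)
  draws as variances, but the results it reports (the sign and size of the
  φ biases of both fitters, the baseline's MSE rows, the prediction RRMSE
  level) are reproduced only when the draws are standard deviations
  (variances 0.0025–0.0225).  The generator therefore defaults to
  `diag_form="sd"`; the literal variance reading remains available.
- **Off-diagonals.**  The printed form `σ_jk = ρ_jk σ_j² σ_k²`
  (a product of variances) is implemented as stated.  The conventional
  alternative ρ_jk σ_j σ_k is selectable but infeasible with the stated
  constants: the implied correlation matrix (0.5 between covariate 1 and
  the others, −0.3 among covariates 2–4) has a negative eigenvalue, so no
  valid covariance exists and the generator rejects every draw.

The baseline Poisson-mixed fit in the harness omits the exposure offset —
the comparator convention of the original benchmark, visible in its
intercept summaries, whose bias equals log ν — so its intercept estimates
β₀ + log ν while slopes and φ are unaffected (ν is constant).
Applications should use `fit_pm`'s default offset.

What passing the benchmark tests shows — and does not show.  The DGP is
Berkson-like (observed covariates fixed, truth = observed + error), uses
normal errors with *known* covariances, a constant ν, and a nearly
collinear design (covariates confined to a 0.4-wide interval), under
which the regression block, the intercept in particular, is weakly
identified and summaries conditional on the single fixed design draw vary
by a factor of ~2 across draws.  Real data bring estimated (noisy) Σ_d,
non-normal errors, and informative designs; none of these are exercised
here.

Performance summaries follow the benchmark's definitions: per-domain
RMSE/RRMSE/ABIAS/RABIAS against the latent `μ_d` of each replicate,
aggregated as unweighted domain means; PoEP is the percentage of domains
where a method's RMSE is strictly below the competitor's.  For the MSE
study, the reported absolute bias compares the replicate-averaged
bootstrap estimate with the Monte-Carlo MSE (the level comparison);
per-replicate deviations are dominated by the sampling spread of φ̂
(correlation ≈ 0.85 between φ̂ and the bootstrap MSE level) and are not a
meaningful summary of the estimator's calibration.

## Known limitations

- The method-of-moments system is exactly identified and unweighted; for
  the regression block it is comparable to, not better than, the
  Laplace-ML baseline in efficiency under these study conditions.  Its φ̂
  carries a negative finite-sample bias at D = 50 (≈ −0.13 at φ = 0.3)
  that shrinks with D; that bias propagates into the EBP's shrinkage
  weight and is the dominant cost of prediction accuracy relative to
  prediction with known parameters.
- Problem sizes used by the shipped experiments: parameter and prediction
  studies at 500 replicates (L = 500), the nested bootstrap study at
  100 replicates × 100 bootstrap samples with L = 200 — chosen to make
  the full benchmark reproducible in minutes on one core while keeping
  Monte-Carlo error well inside the comparison tolerances.
- Unit-level modeling, non-normal error laws, error covariance between
  target and covariate surveys, prediction intervals, and double-bootstrap
  bias correction are out of scope.
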