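# Methods

This note records the statistical model implemented by `covfun`, the
defaults and numerical choices, what the synthetic-data lab does and does
not emulate, and the design decisions that were genuinely open.

## Model and estimators

Let x ∈ ℝᵖ be a response vector and U a covariate vector with q continuous
and r categorical components. The object of interest is the conditional
covariance function Σ(u) = Cov(x | U = u). Because the comparison theory
operates on standardized responses (each column mean 0, variance 1 within
a group), Σ(u) is in effect a conditional *correlation* structure; the
estimator does not force unit diagonals, so we keep calling it a
covariance.

The mean function m(u) = E[x | U = u] is estimated by local polynomial
smoothing. The local constant (Nadaraya–Watson) estimator is available; by
default we use the local linear estimator, which reproduces affine trends
exactly for any bandwidth and has smaller boundary bias. For q > 1 the fit
solves the kernel-weighted least-squares problem with design [1, U − u];
for q = 1 this reduces to the classical s₀, s₁, s₂ moment formulas, which
is also how the vectorized implementation computes it.

The covariance estimator is the kernel-weighted average of residual outer
products,

    Σ̂(u) = Σᵢ wᵢ(u) (xᵢ − m̂(Uᵢ))(xᵢ − m̂(Uᵢ))′ / Σᵢ wᵢ(u),

where the residual at observation i uses the mean fit at that
observation's *own* covariates. The weight is a product kernel over
continuous dimensions, wᵢ(u) = ∏ⱼ K_hj(U_ij − u_j), times an
Aitchison–Aitken factor per categorical covariate: λ for a matching level,
(1 − λ)/(k − 1) otherwise. Σ̂(u) is symmetric positive semi-definite by
construction. A local linear covariance estimator would not be; extending
it through a modified Cholesky decomposition is known to work but is out
of scope here.

Two deliberate conventions, both of which matter downstream:

* the mean fits used for residuals are full-sample fits, not leave-one-out
  fits, including inside the covariance cross-validation criterion (the
  criterion varies only the covariance bandwidth);
* the mean estimator with categorical covariates targets each
  observation's own factor level, so at λ = 1 both the mean and covariance
  estimates coincide exactly with running the continuous-only estimator on
  the per-level subsample (this stratification equivalence is asserted to
  1e-12 in the tests).

## Bandwidths

All bandwidths are in covariate units.

* **Mean bandwidth** (`mean_h`): selected by leave-one-out mean squared
  prediction error summed over the p responses, on a default grid of 25
  log-spaced multiples (0.05–2) of each covariate's standard deviation.
  Ties go to the smallest bandwidth. Inside the simulation harness a
  Silverman-type rule of thumb, 1.06 · sd(U) · n^(−1/5), is the default
  instead: the designs have zero mean functions, every mean fit is
  consistent there, and the rule keeps repeated studies cheap.
* **Covariance bandwidth** (`h`, one per continuous covariate): selected
  by the leave-one-out Gaussian log-likelihood criterion
  CV(h) = (1/n) Σᵢ [ rᵢ′ Σ̂₍₋ᵢ₎(Uᵢ)⁻¹ rᵢ + log |Σ̂₍₋ᵢ₎(Uᵢ)| ]. Candidates
  whose leave-one-out estimate anywhere has condition number above 1e12
  (or a nonpositive determinant, or an empty neighborhood) score +∞. The
  criterion is O(n²p²) per candidate; an optional `subsample` argument
  evaluates it on every k-th observation for large n (off by default). An
  optional jitter ε·I (default off, ε caller-chosen) is applied only
  inside the criterion's inverse, never to reported estimates.
* **Categorical weight λ**: not cross-validated; default λ = 1
  (stratification), the setting used in the motivating analyses. Values in
  [1/k, 1] are accepted.

The cross-validated covariance bandwidth is not always the best bandwidth
for *testing*: oversmoothing protects the parametric tests' type-I error,
undersmoothing raises power when the groups differ near the covariate
boundary. The study harness therefore sweeps an explicit bandwidth grid
rather than trusting CV, and the CV choice is used where a single
bandwidth is needed (eigenvalue-accuracy studies, the `analyze` workflow).

## Comparison tests

For groups of sizes n₀, n₁ with estimates S₀(u), S₁(u), all tests use the
combined matrix Z(u) = (n₀S₀ + n₁S₁)⁻¹ n₁S₁, computed as a symmetric
generalized eigenproblem after Cholesky-whitening the denominator — the
spectrum is then real and confined to [0, 1] up to roundoff (clipped at
tolerance 1e-8; a non-PD denominator raises). Under H₀ with equal sizes
every eigenvalue is 1/2. The explicit inverse is formed only for the
returned Z matrix itself, never for the spectrum.

* **Tracy–Widom.** t = (logit λ₁ − μ)/σ with
  sin²(γ/2) = (min(p, n₁) − ½)/(n₀+n₁−1),
  sin²(φ/2) = (max(p, n₁) − ½)/(n₀+n₁−1), μ = 2 log tan((γ+φ)/2) and
  σ³ = 16/[(n₀+n₁−1)² sin²(γ+φ) sin γ sin φ]. The squared-total exponent
  in σ³ was confirmed by null simulation: with 2000 null replicates
  (p = 2, n₀ = n₁ = 500) the statistic passes a KS test against TW₁,
  whereas the alternative first-power reading is grossly miscalibrated.
  The TW₁ CDF uses the Chiani moment-matched shifted-gamma approximation
  (shape 46.446, scale 0.18605, shift 9.84801); its 95% point matches
  published TW₁ tables to about 1e-4. p-values are one-sided upper tail.
  The group sizes entering μ, σ are the raw n₀, n₁ even though the kernel
  weighting makes the effective sample size smaller; an ESS-based variant
  was considered and deliberately not made default, since the raw-n form
  is what the calibration studies characterize.
* **Forkman's bootstrap.** Statistic λ₁/Σₖλₖ. Each of B iterations draws
  fresh N(0,1) matrices of shapes (n₀, p), (n₁, p), forms plain sample
  covariances (columns centered, divisor n) and recomputes the statistic.
* **Permutation.** Mean functions are fitted once on the original data;
  the pooled mean-adjusted residuals have their group labels permuted, and
  both conditional covariances are re-estimated at u with the original
  bandwidths (recomputing bandwidths per permutation would be correct in
  principle but is computationally prohibitive). The observed statistic is
  computed from the same residual-based covariances as the permuted
  replicates, for exchangeability. A permutation leaving a pseudo-group
  with negligible kernel weight at u is redrawn, at most 10·B times.

Resampling p-values use strict ">" and divisor B, hence live on the 1/B
lattice and can be exactly 0; an `add_one` option switches to
(1 + #)/(B + 1). No multiplicity adjustment is applied across a
significance trace. Resampling seeds derive per-iteration substreams from
the user seed via `numpy.random.SeedSequence`, so any iteration is
reproducible in isolation.

## Synthetic-data lab

`simulate_group_1d(n, θ, seed)` draws U ~ Uniform(−1, 1) and bivariate
normal responses with unit variances and correlation θ·U, via the
closed-form 2×2 Cholesky factor (x₂ = ρz₁ + √(1−ρ²)z₂).
`simulate_group_2d` uses two independent Uniform(0, 1) covariates and
correlation θ·(U₁ − U₂). With group parameters θ₁, θ₂ the true combined
matrix has closed-form eigenvalues (the two correlation matrices commute):
r(1±θ₂u)/(1±θ₁u + r(1±θ₂u)) with size ratio r — a flat 1/2 when θ₁ = θ₂
and r = 1, which is the package's analytic acceptance identity.

The harness defaults mirror the published study conditions: n = 1000 per
group with 100 repetitions for type-I error and power (an n = 500 preset
is also provided, since both sizes appear in the source descriptions of
the same study), and n = 5000 with 50 repetitions for eigenvalue accuracy.
Scaled-down presets (`ci`: n = 500, 25 reps; `accuracy-ci`: n = 1000,
10 reps) are labeled as such in outputs. Per-repetition seeds come from a
counter-based stream (`SeedSequence(seed, spawn_key=(rep,))`).

What the lab does *not* emulate about real data: responses here are
exactly Gaussian with exactly unit variances and a correlation exactly
linear in the covariate; covariates are uniform with no boundary
clustering; there are no outliers, truncated values, missing data or
measurement error; and p = 2. Passing the calibration and power tests
therefore shows the machinery is correct and well calibrated under the
stated model — it does not certify behavior under heavy tails or strong
skew, which is why the CSV workflow offers a log transform and why the
Tracy–Widom route in particular should be interpreted cautiously when its
Gaussianity conditions are doubtful.

## Numerical choices and degenerate inputs

* Kernel families: Gaussian (default; unbounded support cannot produce an
  empty interior neighborhood) and Epanechnikov.
* Degeneracy threshold: a point where the total kernel weight is below
  n·1e-12 raises an extrapolation error rather than returning NaN —
  estimates outside the data range are not meaningful. Curve/trace
  evaluation records such points as flagged rows instead of aborting.
* Local linear rank check: the diagonally rescaled local Gram matrix must
  have condition number ≤ 1e12, else a degenerate-neighborhood error.
* CV tie-break: the smallest bandwidth attaining the minimum (stable sort),
  so duplicate grid entries cannot change the answer.
* As h → ∞ the local constant estimator tends to the column means
  everywhere; the local linear estimator tends to the *global OLS line*,
  which equals the column means exactly at the covariate mean. Tests
  assert the limit in that exact form.
* The consistency check of the covariance estimator (n = 5000, truth
  0.25 at u = 0.5) uses h = 0.15: a consistency statement needs a small
  bandwidth at large n, and at h = 0.3 the residual boundary-smoothing
  bias (~0.02) is already comparable to the Monte-Carlo error.
* Eigenvalues are reported in descending order; the trace identity
  tr Z = Σλ holds to 1e-10 and is tested.

## Test problem sizes

The statistically heavy checks run at reduced but meaningful scale, chosen
as the smallest sizes at which the assertions are comfortably outside
Monte-Carlo noise: permutation type-I calibration at n = 500/group,
B = 199, 100 replicates against the exact binomial 95% band; power
ordering at n = 500, h = 0.5, 50 replicates (h below the type-I setting,
since a smaller bandwidth favors power); Tracy–Widom null KS at 500
replicates; eigenvalue accuracy at n = 1000, 10 replicates with
CV-selected bandwidths. The full published-scale designs remain available
through the `paper` presets and the CLI.

## Known limitations

* Nadaraya–Watson covariance estimates are boundary-biased; significance
  traces near the covariate range limits should be read with caution.
* The CV criterion optimizes each group's likelihood separately, not the
  two-group testing problem; bandwidth choice for testing is an open
  problem and the harness exposes it as a sweep.
* q > 3 continuous covariates are impractical (curse of dimensionality);
  no additive-model extension is provided.
* Only two groups are compared; means are assumed exchangeable after the
  local fit (no mean-difference test is included).
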