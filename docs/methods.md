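# Methods

## Model

For twin *j* (= 1, 2) of pair *i*, with age as the time scale:

- Marker: `y_ijk = M_ij(t_k) + ε_ijk`, `M_ij(t) = β₀ + β₁t + b_ij0 (+ b_ij1 t) + u_i`,
  with `b_ij ~ N(0, Σ_b)` per subject, pair effect `u_i ~ N(0, σ_u²)`,
  `ε_ijk ~ N(0, σ_e²)` mutually independent.
- Hazard: `h_ij(t|v_i) = λρ t^{ρ−1} v_i exp{γ'x_ij + α M_ij(t)}` with pair
  frailty `v_i ~ Gamma(mean 1, variance θ)`; the two event times are
  conditionally independent given `v_i` (and `u_i` when the marker is
  treated as endogenous).
- Observation: subject `ij` enrolls at age `t_ij0` and is observed only if
  its exit age (event or censoring) exceeds `t_ij0` — left truncation.
  Only complete pairs are analyzed; the likelihood conditions on *both*
  members surviving to their entry ages.

### Pair marginal likelihood with delayed entry

Conditional on `v`, each subject contributes a standard PH likelihood with a
piecewise-constant (or calibrated) marker value per at-risk interval.
Conditioning a gamma prior on both twins surviving to entry leaves the
frailty gamma with shape `1/θ` and rate `1/θ + B`, where
`B = Σ_j H₀(t_ij0) exp(γ'x_ij + α z_ij0)` and `z_ij0` is the marker value in
force at entry.  With `d` events in the pair and `A` the summed at-risk
cumulative hazard, the marginal log-likelihood of a pair is

```
Σ_events log[h₀(t) e^{γ'x+αz}] + log Γ(1/θ + d) − log Γ(1/θ)
  + (1/θ) log(1/θ + B) − (1/θ + d) log(1/θ + B + A).
```

`B = 0` gives the naive fit (population frailty at entry; at-risk intervals
still start at entry, so risk sets are correct — this isolates the
frailty-update correction).  A flag `exposure_from_zero` additionally
extends exposure back to age 0 for the alternative reading of "ignoring
delayed entry".  As θ → 0 the expression converges to the independence
Weibull PH log-likelihood; the implementation switches to that analytic
branch below θ = 1e−6 and floors θ at 1e−8 during optimization.

### Estimators

- **LOCF** carries each observed marker value forward to the next
  observation (final interval ends at the exit age).  Valid when the marker
  is near-constant between observations and measurement error is small;
  attenuates α otherwise.
- **ORC** fits the twin mixed model once to all marker data (ML, exact
  pair-blocked Gaussian marginal likelihood with the fixed effects profiled
  out by GLS) and replaces the marker by the BLUP prediction
  `M̂_ij(t) = β̂₀ + β̂₁t + b̂_ij0 (+ b̂_ij1 t) + û_i` at the start of each
  interval of a dense age grid.
- **RRC** refits the mixed model at each event age on the risk set
  (subjects with entry ≤ t ≤ exit) using only observations taken by then,
  and predicts from the refit at the latest event age not after each
  interval start.  Structure falls back stepwise when a risk set cannot
  identify it (random slope → subject intercept → fixed slope), and risk
  sets with fewer than 10 pairs reuse the nearest earlier refit; fallbacks
  are logged per time point.  A subject absent from the selected refit uses
  the nearest refit containing it, else the fixed line.
- **Two-stage JM** freezes the stage-1 fixed effects and *subject-level*
  BLUPs, then maximizes a joint likelihood in α, θ, λ, ρ, σ_u², σ_e² in
  which the pair effect `u` enters both the marker residuals and the hazard
  exponent.  The frailty integral is closed-form (as above, with the entry
  marker value `Ĝ_ij(t_ij0) + u`); only the integral over `u` is numerical.
  The full joint likelihood over all five random effects per pair is out of
  scope as computationally impractical; the two-stage fit is the supported
  compromise.

### Numerical integration over the pair effect

The prior `N(0, σ_u²)` times the longitudinal residual likelihood is exactly
Gaussian in `u`, with per-pair posterior variance
`τ² = (1/σ_u² + n/σ_e²)⁻¹` and mean `μ = τ² Σr/σ_e²`.  That Gaussian factor
is absorbed analytically (its marginal constant is the pair's Gaussian
likelihood with covariance `σ_e²I + σ_u²J`), and Gauss–Hermite quadrature
(default 20 nodes) centered at `(μ, τ)` integrates only the smooth survival
factor.  Plain σ_u-scaled nodes were rejected: the marker data concentrate
the u-posterior at SD `σ_e/√n ≪ σ_u`, which σ_u-scaled nodes resolve poorly.
The centered rule agrees with adaptive quadrature to ~1e−8 per pair, is
continuous at σ_u² → 0 (all nodes collapse to 0), and doubling the node
count moves fitted α̂ by < 1e−6 on reference data.

Cumulative hazards with a linear marker exponent,
`∫ λρ s^{ρ−1} e^{as} ds`, use 40-node Gauss–Legendre quadrature (exact
λt^ρ when a = 0; for ρ < 1 the endpoint singularity is removed by the
substitution q = s^ρ).

## Simulation engine

The generator reproduces a twin study design: per pair draw `v, u, b_i1,
b_i2`; per subject invert `−log w = H(t | M_ij(·), v)` for the event time
(vectorized bisection on the monotone cumulative hazard, bracket width
< 1e−14; a scalar Brent/adaptive-quadrature solver is exposed for
verification); censor by `C ~ U[0, 15]`; draw the entry age (0 with
probability 0.5, else `U(0, 5)`); drop subjects with exit ≤ entry; keep
complete pairs.  Marker observations lie on either a dense calendar grid
(gap 2, entry age prepended) or a sparse scheme (`K ~ uniform{1,…,3}`
times, first at entry, the rest uniform over the at-risk window), plus
`N(0, σ_ε²)` noise.

Defaults are the reference study conditions: `β₀ = 1, β₁ = 0.01,
σ_b = σ_u = 0.1, θ = 0.5, ρ = 2, λ = 0.001`; σ_ε varies by scenario
(0–0.6).  Each pair has its own deterministic RNG substream keyed by
(seed, pair index), so identical seeds give byte-identical datasets and
growing the cohort never reshuffles earlier pairs.

Design choices where the study design leaves room:

- **Cohort size before truncation**: the post-truncation pair counts of the
  reference design (≈1637/1584/1465 at α = 1/2/3) are consistent with 2000
  pairs entering the truncation filter, so `n_pairs = 2000` is the default;
  `calibrate_n_pairs` inverts the retention rate for other targets.
- **Sparse observation law**: the count is uniform on {1,…,max_k} and
  placements uniform over the at-risk window; only "three or fewer, not at
  regular time points" is pinned down externally, so sparse-scenario
  comparisons carry extra tolerance.
- **Entry observation**: a marker observation is always placed at the entry
  age (it supplies the entry marker value the updated frailty needs).
- **Event horizon**: solutions beyond age 200 are treated as alive at the
  horizon and then censored (numerically immaterial at these rates).

What the generator does *not* emulate: informative censoring or
visit-dependent observation, non-Gaussian measurement error,
monozygotic/dizygotic differences, incomplete pairs, or marker trajectories
beyond a subject-level linear model.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Monte-Carlo harness

`run_scenario` fits every requested method on the *same* simulated dataset
per replication (seeded as `base_seed + 1_000_003·(r+1) mod 2³¹−1`), and
reports per method × parameter: relative bias `(mean θ̂ − θ)/θ`, the SD of
the estimates, `MCSE = SD/(|θ|√R)`, MSE, and Wald 95% coverage (natural
scale for α, log scale for the positive parameters, by the delta method).
Replications whose optimizer aborts are excluded from the moments and
counted as failures; replications without a positive-definite Hessian keep
their point estimates but drop out of coverage.  Results are invariant to
execution order by construction.

## Problem sizes and runtimes

The bundled scenario files describe 1000-replication grids.  The test suite
and the reproduction script run the dense-grid LOCF scenario at 200
replications of 2000 pairs — enough for a Monte-Carlo SE of about 0.026 on
the relative bias of θ̂ — and exercise ORC/RRC/JM on cohorts of 150–600
pairs, since the risk-set refits and the joint fit dominate runtime (RRC
refits the mixed model at every event age).  One LOCF replication
(simulate + build + fit) takes ≈0.7 s on one CPU.

## Numerical choices

- Positive parameters (λ, ρ, θ, σ_u², σ_e²) are optimized on the log scale
  with L-BFGS-B; mixed-model variance parameters use Nelder–Mead on a
  log-Cholesky scale with the fixed effects profiled out.
- Standard errors: central finite-difference Hessian (step 1e−5 on the
  working scale), inverted after a Cholesky positive-definiteness check,
  delta method back to the natural scale.  A non-PD Hessian yields
  `converged = False` with `se = None`, never an exception: a noticeable
  fraction of joint-model replications lacks standard errors under heavy
  measurement error, and the harness tracks fit failures and SE failures
  separately.
- Zero-length start-stop intervals are dropped with a warning; interval
  contiguity and single-final-event structure are validated on
  construction.
- Mixed-model estimation is ML, not REML: downstream estimators plug in
  point predictions and the two-stage likelihood interpretation stays
  coherent.  Stage-1 uncertainty (β̂, Σ̂_b, BLUPs) is **not** propagated
  into stage-2 standard errors — a known limitation of the two-stage
  construction.

## Known limitations

- Complete pairs only; conditioning on one twin's entry (needed to retain
  singletons) is not implemented.
- The RRC refit grid uses event ages only; entry-age refits (useful for
  application data with strongly staggered entry) are not generated
  automatically, though `rrc_refit` accepts any age.
- Wald coverage for variance-type parameters near their boundary is
  anti-conservative, as usual.
- Joint-model standard errors understate total uncertainty (stage-1 error
  ignored).
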