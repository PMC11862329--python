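# Methods

This note records the modelling assumptions, numerical conventions and
open design choices behind `bufferscape`, in the spirit of a model
documentation page: what exactly is computed, with which defaults, and
what the synthetic test models do and do not establish about real data.

## Environmentally explicit IPMs

A model is a size mesh plus vital-rate regressions.  The mesh is regular
midpoint discretization of `[α, ω]` into `n` cells, `z_j = α + (j−½)h`,
`h = (ω−α)/n`.  Regressions are generalized linear predictors over
`{size, size², driver, driver×size}` with identity, log or logit links.
The kernel at a given environment is

* `P[i,j] = s(z_j) · N(z_i; g(z_j), σ_g) · h` — survival times the
  Gaussian growth density evaluated at the destination midpoint;
* `F[i,j] = p_repro(z_j) · offspring(z_j) · N(z_i; μ_r, σ_r) · h` —
  per-capita recruit production spread over the recruit-size density;
* `K = P + F`, exactly, elementwise.

Numerical conventions: density mass falling outside `[α, ω]` is lost
(eviction) by default; an optional flag renormalizes growth columns so
each column of `P` sums to its survival value.  A fertility component
that a model lacks contributes the identity value 1.  Models whose
survival is far from 1 and whose growth/recruit densities sit several
standard deviations inside the bounds are essentially eviction-free; the
test suite checks a ≥5σ-margin fixture integrates to 1 within 1e−6, and
that doubling the mesh changes λ₁ by <1%.

The deterministic rate λ₁ is the spectral radius, computed by power
iteration (relative tolerance 1e−10) with a full eigendecomposition
fallback for periodic/reducible matrices where the iteration cannot
settle.

## Environmental timeseries

Drivers follow a stationary AR(1): `X_{t+1} = φX_t + ε_{t+1}`,
`X_1 ~ N(0, 1/(1−φ²))` so the raw series carries no transient.  Drivers
are mutually independent, each with its own innovation stream derived
deterministically from the master seed and the driver index.

The raw series is affinely mapped to the driver's target mean and
variance with *exact sample moments* (standardize by the sample SD,
scale by √σ²): variance targeting is exact at any length, not
asymptotic, and the affine map preserves rank order and the sample lag-1
autocorrelation.  Variance manipulation is proportional:
`σ² = σ²_init · σ²_prop`.

**Measurement-window targeting.** A growth-rate estimate only measures
the post-burn-in steps, and with autocorrelated noise the sample
variance of a window drifts substantially away from the full-series
variance (the effective sample size of an AR(1) window is
`T(1−|φ|)/(1+|φ|)`, i.e. ~33 for 300 steps at φ = 0.8).  Landscape runs
and the CLI therefore fit the affine map on the post-burn-in window (and
apply it to the whole series), so the variance manipulation is exact
precisely where λ_s is measured.  Without this, the uncontrolled window
variance masquerades as a smooth autocorrelation effect in the
landscape analyses.  `generate_driver_matrix(..., moment_window=None)`
recovers full-series targeting.

## Stochastic growth rate and average size distribution

Projection renormalizes the state to total 1 each step while
accumulating exact log increments, so trajectories over thousands of
steps neither overflow nor underflow; the increments equal those of the
unnormalized matrix product.  λ_s = exp(mean of increments with index ≥
burn-in); the default burn-in is 200 of 1000 steps, and "steps 200 to
1000" is read half-open (retain indices 201..1000).  Initial structures
are uniform draws on the simplex (Dirichlet(1,…,1)), seeded.

The average size distribution (ASD) is the mean of all retained,
per-step-normalized states over many random initial structures; it sums
to 1 by construction and converges to the dominant right eigenvector
for a constant kernel.

## Stochastic elasticities of variance

For each kernel element whose post-burn-in timeseries varies, deviations
from the window mean are scaled by `1 + δ` (sample mean preserved,
variance × (1+δ)², δ = 1e−5 by default), λ*_s is recomputed on the
otherwise identical sequence, and

    E^σ²_ij = [var(a_ij,t)/λ_s] · (λ*_s − λ_s)/(δ · var(a_ij,t))
            = (λ*_s − λ_s)/(δ λ_s).

Scaling *deviations* by `1+δ` (rather than variance by `1+δ`) is what
makes the sum satisfy the small-noise relation
`ln λ_s ≈ ln λ_1 + ½∑E^σ²`; the test suite asserts this within 15% on
the reference species at quarter variance.  Conventions:

* **Window consistency.** Element means, variances and the perturbation
  itself all live on the λ_s measurement window; burn-in steps are left
  unperturbed so the finite difference carries no uncontrolled
  initial-state contribution.
* **Zero-variance elements** contribute exactly 0 (the perturbation is a
  no-op).  "Varying" means window variance > 1e−300 *and* max > min over
  the window — the second condition makes constant-series detection
  exact, since the floating mean of identical values can leave ~1e−32 of
  spurious variance.
* **Evaluation.** E = expm1(m* − m)/δ with m the mean retained log
  increment; algebraically identical to the formula above but immune to
  the catastrophic cancellation of exponentiating first at δ = 1e−5.
* **Common random numbers.** All perturbed projections (whole-kernel and
  both subkernels) run as columns of one blocked projection that shares
  the base run's kernels, initial vector and arithmetic; the result is
  deterministic given (kernels, n0).
* Perturbed values are not clamped; a sign flip (possible only for
  degenerate elements at large δ) raises a warning.

Subkernel elasticities perturb `P` (resp. `F`) element series while the
other subkernel stays fixed; `∑E_P + ∑E_F = ∑E_K` holds exactly when no
element varies in both subkernels and to first order in δ (~1e−3
relative here) otherwise.  The P−F contribution is `∑E_P − ∑E_F`.

The per-stage buffering profile is the column sums of `E^σ²`
(transitions out of, and reproduction by, stage j); its sum equals
∑E^σ².

## Structure diagnostics

* Expected buffering given structure: `Σ_j ASD_j · profile_j`.
* Scaled deviance: across all landscape cells, z-score (n−1 SD) the
  expected-buffering vector and the ∑E^σ² vector, subtract.  The result
  has mean 0, is invariant to positive affine transforms of either
  input, and needs ≥3 nonconstant cells.
* Mean buffered size: the centroid of the normalized profile over mesh
  midpoints, reported both as `(c−α)/(ω−α)` (normalized, default; 0 =
  smallest possible size, 1 = largest) and `(c−α)/ω` (literal).  The
  two coincide when α = 0, which the reference mesh uses.  Mixed-sign
  profiles can push the value outside [0, 1]; that warns, never raises.

## Landscape and variance partitioning

Default grid: 15 φ-levels on [−0.8, 0.8] × 15 σ²_prop-levels on
[0.9, 1.1] (225 cells), T = 1000, burn-in 200, δ = 1e−5, 1000 ASD
initializations.  One innovation stream per driver is drawn once and
reused across all cells (common random numbers), transformed per cell by
φ and the variance target; the initial population vector and ASD
initializations are likewise shared.  This isolates the environmental
manipulation from sampling noise, and each cell remains a single
realization (replicate averaging is not performed).  The deviance column
is filled across cells after the grid completes.  Tables round-trip
through CSV at 17 significant digits.

Partitioning fits 18 candidate models — degrees 1–3 per predictor, with
and without the linear×linear interaction — on centered predictors, with
every power column (and the interaction) re-centered to mean zero; on a
factorial grid this makes the two predictor blocks exactly orthogonal,
so block shares are independent of entry order (asserted numerically).
AIC is `n·ln(RSS/n) + 2(k+2)` with RSS floored at `n·1e−12·var(y)` to
stay finite on noiseless responses; ties break to fewer parameters, then
lower autocorrelation degree, then lower variance degree.  Shares are
sequential (Type I) sums of squares — autocorrelation powers ascending,
then variance powers, then interaction — divided by the total sum of
squares; the residual share is RSS/TSS and all shares sum to 1.  Cubic
candidates need ≥4 distinct levels per axis to be identifiable; smaller
grids raise a rank-deficiency error naming the collinear columns.

## The synthetic reference species

The reference species stands in for database-encoded plant IPMs so the
whole pipeline is testable without external data: mesh of 60 cells on
[0, 10] (α = 0 so the two MBS conventions coincide), survival low
(~0.23–0.33) and nearly size-flat, Gaussian growth converging to size
10, steep size-dependent reproduction probability (maturity near size
6), high log-linear fecundity, and a single driver (mean 0, unit
baseline variance) entering the survival logit (0.20), log fecundity
(0.14) and weakly the growth mean (0.06).  λ₁ at the mean environment is
1.003.

The coefficient pattern is deliberate: 0.20 on the survival logit times
(1−s) ≈ 0.7 matches 0.14 on the log-fecundity scale, so the environment
acts close to a common multiplicative factor on the whole kernel.  In
that regime the cost of stochasticity is governed by the variance of the
forcing rather than its temporal autocorrelation, so the landscape
exhibits the canonical pattern — ∑E^σ² negative, declining in σ²_prop,
with the variance axis explaining most of its landscape variation —
robustly across master seeds, while the weak growth-mean term keeps a
genuine structure-mediated autocorrelation channel open for the deviance
and mean-buffered-size diagnostics.  Species with strong environmental
effects on growth or survival alone have a much larger, fully real,
structure-mediated autocorrelation response; the randomized sampler's
coefficient ranges bracket the reference design rather than that regime.

What the synthetic models do not emulate: cross-driver covariance,
nonstationary or non-AR(1) (e.g. 1/f) environments, curvilinear
environment–rate reaction norms beyond link nonlinearity, demographic
stochasticity, density dependence, and the specific fitted coefficients
of any published species.  Passing tests therefore establish the
correctness and internal consistency of the machinery and the
qualitative direction of its responses, not quantitative predictions for
real populations.

## Problem sizes and determinism

The test suite and the acceptance script run scaled-down designs chosen
to keep single-CPU runs comfortable while leaving the estimators'
behavior unchanged: a 7×7 landscape at T = 500 with 200 ASD
initializations (the ASD then still averages ~6e4 retained states per
cell), and T = 4000 for the small-variance Tuljapurkar consistency
check, where the sampling noise of `ln λ_s − ln λ_1` at quarter variance
would otherwise be comparable to ∑E^σ² itself.  Every random quantity
(innovations, initial structures, ASD draws, species sampling) derives
from explicit seeds via independent child seed sequences; identical
seeds reproduce identical tables bitwise.

## Known limitations

* Single-realization landscapes inherit realization noise on the
  autocorrelation axis (the effective sample size shrinks as |φ| → 1);
  measurement-window moment targeting removes the dominant part but
  higher-moment drift remains.
* Sequential SS shares are order-invariant only across the two predictor
  blocks (guaranteed on factorial grids); within-block ordering is fixed
  by convention.
* The elasticity finite difference resolves |∑E^σ²| down to ~1e−6;
  far-smaller buffering signals would need a larger δ or longer series.
* Subkernel additivity is first-order in δ when P and F overlap in
  time-varying elements.
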