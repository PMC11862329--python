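# bufferscape

Structured demographic buffering for stochastic integral projection
models (IPMs).

Populations in variable environments pay a growth-rate cost for the
temporal variance of their demographic rates. *Demographic buffering* is
a population's capacity to limit that cost. `bufferscape` is a toolkit
for demographers and population ecologists to ask **which environmental
components (temporal autocorrelation vs. variance) drive buffering, and
through which demographic mechanisms (population structure vs. the rates
themselves)** — for any environmentally explicit, size-structured
population model.

## The model and the measures

A size-structured population is projected through a timeseries of
discretized kernels `A_t = P_t + F_t` (progression and fertility
subkernels) built from vital-rate regressions over size `z` and one or
more AR(1) environmental drivers

    X_{t+1} = φ X_t + ε_{t+1},   ε ~ N(0, 1),

rescaled to each driver's mean `μ` and variance `σ² = σ²_init · σ²_prop`
(exact sample moments; `σ²_prop` is the proportional-variance multiplier,
1 = the fitted model).  The stochastic growth rate is

    λ_s = exp( E[ ln(N_{t+1}/N_t) ] ),

estimated from post-burn-in log increments.  Buffering is measured by the
summed **stochastic elasticities of variance**: each kernel element's
timeseries `a_ij,t` has its deviations scaled by `1 + δ` (mean fixed,
variance × (1+δ)², δ = 1e−5) and

    E^σ²_ij = (λ*_s − λ_s) / (δ λ_s),    ∑E^σ² = Σ_ij E^σ²_ij ≤ 0,

which satisfies the Tuljapurkar small-noise relation
`ln λ_s ≈ ln λ_1 + ½ ∑E^σ²`.  Perturbing only `P` or only `F` elements
gives subkernel sums and the **P−F contribution** `∑E_P − ∑E_F`.
Structure diagnostics: the **expected buffering value** (the per-stage
buffering profile averaged under the average size distribution, ASD), its
z-scored **deviance** from `∑E^σ²` across a simulation landscape, and the
**mean buffered size** (elasticity-weighted size centroid on a 0–1
scale).  Landscape runs cross `φ ∈ [−0.8, 0.8]` with
`σ²_prop ∈ [0.9, 1.1]` factorially; each response is then attributed to
autocorrelation, variance, their interaction and residual by sequential
sums of squares under an AIC-selected polynomial model (degrees 1–3 per
predictor, optional interaction).

## Worked example

Write the built-in reference species (a short-lived, fast-growing,
highly fecund perennial with one environmental driver) to the JSON model
format, then measure its growth rates and buffering at the baseline
environment (`φ = 0`, `σ²_prop = 1`):

```bash
$ bufferscape synthesize-species --out model.json
$ bufferscape lambda-s --model model.json --phi 0.0 --sigma2-prop 1.0 --seed 1
{"lambda_s": 1.0007219545811143, "lambda_1": 1.0131682813158212}
$ bufferscape elasticity --model model.json --phi 0.0 --sigma2-prop 1.0 --seed 1 --out E.csv
{"lambda_s": 1.0007219545811143, "sum_E": -0.027384001138278817,
 "sum_E_P": -0.01850789876918218, "sum_E_F": -0.008876101944967725,
 "pf_contribution": -0.009631796824214457, "delta": 1e-05}
```

Reading the numbers: environmental stochasticity drags the stochastic
growth rate (`λ_s = 1.0007`) below the deterministic rate of the mean
kernel (`λ_1 = 1.0132`); the summed elasticity of variance
(`∑E^σ² = −0.0274 ≈ 2(ln λ_s − ln λ_1)`) quantifies that cost — a 1%
proportional increase in all demographic-rate variances would lower
`λ_s` by about 0.027%.  The split is `∑E_P = −0.0185` vs
`∑E_F = −0.0089`: variance in progression (survival/growth) costs this
species about twice as much as the same proportional variance in
fertility (P−F contribution −0.0096 < 0 means fertility variance is the
*less* damaging channel here).  `E.csv` holds the full 60×60 elasticity
matrix.

A full landscape plus attribution:

```bash
$ bufferscape simulate-landscape --model model.json --out landscape.csv --seed 1
$ bufferscape partition --landscape landscape.csv --response sum_E --out partition.json
```

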