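# Methods

## Model

The data are long-format concentration–time measurements: subject
`i = 1..m` contributes `n_i` strictly positive concentrations `y_ij`
at strictly positive times `t_ij` (hours) after a single dose `D_i`.
The population mean on the log scale is the fractional-polynomial
rewrite of the one-compartment absorption curve,

    E[log y_ij | b_i] = β0 + β1 t_ij^{p1} + β2 t_ij^{p2} + b_i + offset_i ,

with default powers `(p1, p2) = (1, −1)`, i.e. `β0 + β1 t + β2/t`.
This basis reproduces the rise-then-fall shape of
`c(t) = D ka/(V(ka−ke))(e^{−ke t} − e^{−ka t})` precisely when
`β1 < 0` and `β2 < 0`, which we impose as hard constraints: the curve
then has the unique interior peak `tmax = √(β2/β1)`. The powers are
user-configurable; `(1, −1)` is the default because it both matches
the constraint convention and puts the implied peak time in the
empirically sensible range for absorption data on this time scale.

Stage one (residuals), three families:

* **normal** — isotropic multivariate normal, variance `σ2` per
  coordinate, applied to the log concentrations;
* **t** — isotropic multivariate Student *t* per subject with scatter
  `σ2·I` and degrees of freedom `ν` (default 4, fixed), applied to the
  log concentrations. `σ2` is the *scatter* element, not the variance:
  for `ν > 2` the implied variance is `σ2·ν/(ν−2)`. This is documented
  rather than silently corrected.
* **gamma** — gamma GLM with log link on the *raw* concentrations,
  shape `a` (variance `mean²/a`); retained for AIC comparison with the
  gamma-GLM tradition.

Stage two: scalar random intercepts `b_i ~ N(0, σ1)` — a single
per-subject log-scale shift, chosen because exactly two variance
components (`σ1`, `σ2`) are identified in this design. The residual
scatter is isotropic (`σ2·I`): the residual correlation matrix is
modelled as diagonal with a constant element, so one scalar is
estimated.

An important structural consequence of the *multivariate* t (one
gamma-mixing variable per subject block): robustness operates at the
block level. A block containing one aberrant observation is
down-weighted as a whole; isolated single-observation outliers are
therefore only partially rejected (see Limitations).

Dose handling: by default a common dose is absorbed into `β0`; with
`dose_offset=True` the fixed-coefficient offset `log D_i` is added for
heterogeneous doses.

## Priors

Independent diffuse priors: `β_k ~ N(mean_k, 100)` with the prior mean
set at the conventional initial estimate `(0.1, −0.1, −0.1)`;
`σ1, σ2 ~ Gamma(shape 0.01, rate 0.01)` (switchable to inverse-gamma —
both conventions circulate for variance components and the sampler is
agnostic); and the stage-two `b_i ~ N(0, σ1)` terms. With variance 100
the β prior is effectively flat over the constrained region, so the
prior mean has no practical influence.

## Sampler

Component-blocked Gaussian random-walk Metropolis–Hastings with hard
constraint rejection. One sweep updates `β0, β1, β2, σ1, σ2`, then all
`b_i`; a proposal is accepted iff `u < min(1, exp(Δ log posterior))`
*and* it satisfies `β1 < 0, β2 < 0, σ1 > 0, σ2 > 0` (violations count
as rejections, never errors). The `b_i` have conditionally independent
posteriors given the other blocks, so they are proposed jointly and
accepted subject-by-subject — identical in law to a per-subject sweep.

Numerical choices:

* **Initial values** `β = (0.1, −0.1, −0.1)`, `σ1 = σ2 = 0.01`,
  `b = 0`; a non-finite posterior at initialization raises with
  guidance rather than starting a dead chain.
* **Proposal scales** start at (0.05, 0.02, 0.05, 0.005, 0.005, 0.05)
  and are adapted every 100 burn-in iterations by the multiplier
  `clip(exp(2(rate − 0.3)), 0.3, 3)` toward a 25–45% acceptance rate,
  then frozen, so the retained chain uses a fixed kernel. The paper
  trail for this model never states a proposal; these are engineering
  choices and the reported acceptance rates make them auditable.
* **Run length** defaults to 5000 iterations with 4000 burn-in;
  summaries (posterior mean and empirical 2.5/97.5 percentiles) come
  from the last 1000 retained draws. The test and acceptance runs use
  2500/2000/500 — the sampler mixes well at the canonical design size
  (120 observations) and these lengths keep a 20-replicate study under
  a minute without changing the conclusions.
* **Determinism**: all randomness flows from a single integer seed
  through numpy `SeedSequence`; identical config + seed gives
  bit-identical chains. Replicate studies derive per-replicate
  simulation and chain seeds the same way (reduced mod 2^31).
* Likelihood evaluation uses per-subject residual sufficient
  statistics updated incrementally, so one sweep costs O(total
  observations) regardless of the number of blocks.

Diagnostics: per-parameter effective sample size via Geyer's
initial-monotone-sequence autocovariance truncation, exportable trace
series, and trace/pred/ipred plots.

## Simulation harness

`SimulationDesign` reproduces the canonical study conditions: 10
subjects, 10 mg common dose, 12 sampling times
`[0.2, 0.5, 1, 2, 4, 8, 14, 22, 28, 30, 32, 36]` h. Three presets:

| preset | β_true | σ1 | σ2 | errors | outliers |
|---|---|---|---|---|---|
| 1 | (0.4, −0.04, −0.2) | 0.008 | 0.008 | normal | none |
| 2 | (0.8, −0.04, −0.2) | 0.008 | 0.008 | normal | 5% |
| 3 | (0.8, −0.04, −0.2) | 0.010 | 0.001 | t (ν=4) | 5% |

Contamination adds a fixed shift to `round(0.05·N)` log concentrations
chosen uniformly without replacement. The shift magnitude defaults to
**+1.0 on the log scale** (≈ 11 residual SDs under preset 2) with
positive sign — large, upward spikes; it is configurable. Outliers are
injected on the log scale (the model's error scale), not the
concentration scale. The generating ν for preset 3 is 4 (a
deliberately heavy tail). Truth records (generating values, drawn
`b_i`, contamination mask) travel with every simulated dataset.

What the generator does *not* emulate: assay error that grows with
concentration, below-quantification censoring, missing visits, dose
heterogeneity, or covariate effects. Passing recovery tests therefore
demonstrate correctness of the estimator under the stated generating
process, not robustness to those real-data features.

`replicate_study` runs simulate → fit → collect posterior means over
`n_reps` replicates and reports the across-replicate mean and
2.5/97.5 percentile interval per parameter — percentiles because the
interval type of a replicate table is a convention, and the empirical
one needs no normality assumption.

## Derived PK parameters

Computed from the fixed-effect population curve (`b = 0`):
`tmax = √(β2/β1)` (closed form; golden-section search to 1e-8 for
non-default powers, cross-checked against the closed form),
`cmax = exp(β0 + offset − 2√(β1β2))`. Half-life is reported in **two
labelled variants**, because no single closed form exists for a
fractional-polynomial curve and candidate definitions disagree
numerically: `t_half_terminal = log 2/(−β1)` (exponential-tail rate)
and `t_half_descent`, the post-peak time at which the curve has fallen
by half, solved by bisection to 1e-8 (bracket extended by 1000 terminal
half-lives so an early peak cannot truncate the root search). Posterior
summaries map every retained β draw through these formulas; draws where
a quantity is undefined are dropped and counted, and >50% undefined is
an error.

## Model comparison

Plug-in AIC: for each family the sampler runs on the same data and
seed, the log likelihood is evaluated at the posterior means with
`b_i` integrated out by **adaptive Gauss–Hermite quadrature** (40
nodes, re-centred per subject on the integrand mode with Laplace
scaling — exact for the normal family, verified against the closed-form
compound-symmetric marginal), and `AIC = −2 loglik + 2k`. Declared
counts: normal `k = 5`; t `k = 6` with ν grid-profiled over
{3, 4, 6, 8, 12, 20, 50} (the default; `σ2` is re-optimised per ν since
the scatter's meaning is ν-dependent) or `k = 5` with ν fixed; gamma
`k = 5` (3 fixed effects + σ1 + shape). The gamma fit is not fully
Bayesian: its chain samples β, b, σ1 with the shape held at a
moment-matched estimate (reciprocal log-residual variance from an OLS
pre-fit), and the shape entering AIC is re-profiled by maximum
likelihood at the posterior-mean β.

Because the gamma family models raw concentrations while the other two
model logs, the log-scale families' likelihoods include the
change-of-variable Jacobian `−Σ log y`, putting all three AICs on the
concentration scale; t-vs-normal differences are unaffected.

The plug-in convention (posterior means, marginalized random effects)
is one of several defensible likelihood choices under Bayesian
fitting; absolute AIC values are convention-dependent, differences
between families on the same convention are the meaningful output.

## Known limitations

* Block-level robustness: with one mixing variable per subject, the
  multivariate t down-weights whole subject vectors. Under 5%
  contamination at shift +1.0 the t fit roughly halves the intercept
  bias of the normal fit (≈ +0.03 vs ≈ +0.05 per the replicate
  studies the test suite runs) rather than eliminating it;
  per-observation t errors would reject isolated spikes more fully but
  describe a different model.
* ν is fixed (default 4) or grid-profiled for AIC; it is not sampled.
* Single-chain diagnostics only (ESS, traces); no multi-chain R-hat.
* No censoring/missing-data handling, multi-compartment structures,
  covariate submodels beyond the dose offset, or non-diagonal residual
  correlation.
* The `ka = ke` one-compartment limit is rejected, not special-cased.
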