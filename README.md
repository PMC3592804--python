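# robustpk

Robust Bayesian population pharmacokinetics with multivariate **t** errors.

## The problem

Population pharmacokinetic (PPK) studies model drug concentration–time
profiles across many subjects, separating inter-individual variability
(random effects) from residual scatter. Concentration data routinely
contain a few extreme values — assay spikes, recording errors,
atypical responses — and under the usual (log-)normal error assumption
those outliers can badly distort the estimated fixed effects and
variance components.

`robustpk` fits a generalized linear mixed model whose mean is a
log-linear *fractional polynomial* rewrite of the one-compartment
absorption model and whose residual vector per subject follows a
heavy-tailed multivariate Student *t* distribution. The package is for
pharmacometricians and biostatisticians who want a robust alternative
to normal-error PPK fits, with an explicit simulation-study harness to
quantify the robustness gain.

## The model

One-compartment kinetics, `c(t) = D·ka/(V(ka−ke))·(e^{−ke t} − e^{−ka t})`,
rises then falls in `t`. On the log scale it is approximated by

    log y_ij = β0 + β1·t_ij + β2/t_ij + b_i + ε_ij

with the sign constraints **β1 < 0, β2 < 0** (increasing absorption,
decreasing elimination). Subject intercepts are `b_i ~ N(0, σ1)`; the
per-subject error vector is either isotropic multivariate normal
(variance σ2) or multivariate *t* with scatter `σ2·I` and ν degrees of
freedom (small ν ⇒ heavy tails; ν → ∞ recovers the normal). A gamma
GLM with log link on the raw concentrations is available for model
comparison.

Inference is fully Bayesian: diffuse normal priors on β, gamma (or
inverse-gamma) priors on σ1, σ2, and a component-blocked random-walk
**Metropolis–Hastings sampler with hard constraint rejection** — a
proposal is accepted iff `u < min(1, p)` *and* it satisfies the sign
and positivity constraints. Derived population PK parameters
(`tmax = √(β2/β1)`, `cmax = exp(β0 − 2√(β1 β2))`, and two explicit
half-life variants) are mapped through the posterior draws, and error
families are compared by plug-in AIC with the random effects
integrated out by adaptive Gauss–Hermite quadrature.

## Worked example

```python
from dataclasses import replace
import robustpk as rp

# one draw from the clean 10-subject study design
data, truth = rp.simulate_dataset(replace(rp.preset_example(1), seed=42))

res = rp.PKMixedModel(data).fit(n_iter=2500, burn_in=2000,
                                summary_window=500, seed=0)
print(res.summary())
print(res.derived_pk().table.round(4))
```

Output:

```
Robust Bayesian population PK fit
==============================================
error family : t (nu=4)
powers       : (1.0, -1.0)
subjects     : 10   observations: 120
iterations   : 2500  burn-in: 2000  summary window: 500

            mean     lower     upper
beta0   0.379945  0.340597  0.413652
beta1  -0.040101 -0.041188 -0.038778
beta2  -0.204000 -0.213517 -0.193886
sigma1  0.009740  0.002989  0.039912
sigma2  0.004663  0.002814  0.007071

acceptance rates: beta0=0.26  beta1=0.31  beta2=0.30  sigma1=0.32  sigma2=0.31  b=0.30

                    mean    lower    upper
tmax              2.2553   2.1974   2.3051
cmax              1.2205   1.1801   1.2594
t_half_terminal  17.2890  16.8288  17.8745
t_half_descent   21.5637  21.0370  22.1575
```

The posterior means recover the generating values β = (0.4, −0.04,
−0.2) up to this dataset's subject-mean randomness; the intervals are
2.5/97.5 posterior percentiles over the last 500 draws. The derived
rows say the population curve peaks at ≈ 2.26 h at a concentration of
≈ 1.22, the exponential tail halves every `log 2 / (−β1)` ≈ 17.3 h, and
the curve itself first falls to half its peak ≈ 21.6 h post dose.

The same objects drive the simulation study (`rp.replicate_study`:
simulate → fit → collect posterior means, 20–100 replicates), outlier
contamination (`rp.inject_outliers`), and family comparison
(`rp.fit_and_compare(data, ["t", "normal", "gamma"])`, ranked by AIC).

A CLI wraps the pipeline:

```bash
robustpk simulate --example 2 --reps 5 --seed 7 --out sim/
robustpk fit --input sim/rep_001.csv --family t --nu 4 --derived --plot --out fit/
robustpk compare --input sim/rep_001.csv --out cmp/
```

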