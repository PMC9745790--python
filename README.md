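# nmix

Binomial **N-mixture models** for estimating the relative abundance of
unmarked species from camera-trap count data, plus the **Royle–Nichols**
model for detection–nondetection data, AIC model selection,
parametric-bootstrap goodness of fit with overdispersion (ĉ) correction, and
the camera-trap data preparation rules that feed them.

The package is aimed at field ecologists who run camera-trap grids for
species that cannot be identified individually (bears, small carnivores,
ungulates) and want model-based abundance instead of raw encounter indices.

## The model

Counts `y_it` of a focal species at site `i` on sampling occasion `t` are
modelled hierarchically:

- **State process:** latent site abundance `N_i ~ f(λ_i)` where `f` is
  Poisson, negative binomial (mean λ, variance λ + λ²/α) or zero-inflated
  Poisson (extra mass ψ at zero), with `log(λ_i) = β₀ + β·x_i`.
- **Observation process:** `y_it | N_i ~ Binomial(N_i, p_it)` with
  `logit(p_it) = α₀ + α·z_i`.

The likelihood marginalises the latent count,
`L_i = Σ_N [Π_t Binom(y_it; N, p_it)] f(N; λ_i)`, truncated at `K`
(default: max observed count + 100) and computed in log space. With
Z-standardized covariates, `exp(β₀)` is the mean site abundance at average
covariates and `logistic(α₀)` the per-occasion detection probability.
Cameras inside the same grid-cell site enter as parallel *spatial replicate*
columns. The Royle–Nichols model links binary detection histories to
abundance via `P(detection | N) = 1 − (1−r)^N`.

Model fit is judged by a parametric bootstrap of a Pearson χ² statistic
(sum-of-squares and Freeman–Tukey variants provided); the overdispersion
ratio ĉ = observed/mean(bootstrap) inflates standard errors by √ĉ when it
exceeds 1. Candidate models are ranked by AIC and inference restricted to
models within 2 ΔAIC units.

## Worked example

```python
import numpy as np
from nmix import NMixture, SimulationConfig, gof_bootstrap, rank_models, simulate_survey

# a synthetic survey shaped like a real one: 73 grid sites, 1-4 cameras
# per site, 15 three-day occasions, detection probability near 0.08
counts, covs, truth = simulate_survey(SimulationConfig(seed=11))

top = NMixture("poisson",
               state_covariates=("mixed", "human_CR", "vildist", "sal.forest"),
               det_covariates=("fruit_density",)).fit(counts, covs)
null = NMixture("poisson").fit(counts)

print(rank_models({"top": top, "null": null})[["model", "nPars", "AIC", "dAIC"]])
lam, se, ci = top.mean_site_abundance()
p, p_se = top.detection_estimate()
print(f"mean site abundance {lam:.2f} +/- {se:.2f}, CI {ci[0]:.2f}-{ci[1]:.2f}")
print(f"detection probability {p:.3f} +/- {p_se:.3f}")
g = gof_bootstrap(top, counts, covs, n_boot=200, seed=1)
print(f"GoF p = {g.p_value:.2f}, c-hat = {g.c_hat:.2f}")
```

Output:

```
  model  nPars          AIC       dAIC
0   top      7  2567.955375   0.000000
1  null      2  2633.328686  65.373311
mean site abundance 2.66 +/- 0.51, CI 1.83-3.88
detection probability 0.069 +/- 0.013
GoF p = 0.86, c-hat = 0.94
```

The covariate model wins decisively (ΔAIC 65); the mean site abundance of
2.7 bears per 12.4 km² site and detection probability of 0.07 recover the
generating truth (λ = e^0.95 ≈ 2.6, p = 0.08) within sampling error; ĉ near
1 says the Poisson model fits data simulated from a Poisson world.

The same pipeline is scriptable from the shell:

```bash
nmix simulate --seed 5 --out-dir survey/
nmix prep --events survey/events.csv --deployments survey/deployments.csv --out-dir prepped/
nmix rank --counts prepped/counts.csv --covariates survey/covariates.csv \
     --model "p(.)lambda(.)" --model "p(fruit_density)lambda(mixed+human_CR)" \
     --out-dir ranked/
nmix gof --counts prepped/counts.csv --model "p(.)lambda(.)" --n-boot 200 --seed 1 --out-dir gof/
```

`nmix prep` applies the standard camera-trap preparation rules: photographs
of the same species at the same camera count as one independent event unless
≥ 30 min apart, events are pooled into three-day occasions anchored at each
camera's activation date, and cameras are aggregated into spatial-replicate
columns per site.

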