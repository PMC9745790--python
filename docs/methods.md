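# Methods

## Model and likelihood

The package fits binomial N-mixture models to a site × (replicate, occasion)
matrix of detection counts. Latent abundance `N_i` at site `i` follows one of
three count mixtures:

- **Poisson**: `N_i ~ Pois(λ_i)`;
- **negative binomial** in the mean–dispersion parameterisation: mean `λ_i`,
  variance `λ_i + λ_i²/α` (α > 0 estimated on the log scale). This is the
  convention of the software family ecologists use for these models; other NB
  parameterisations change the meaning of the dispersion coefficient;
- **zero-inflated Poisson**: extra probability ψ of a structural zero,
  `Pr(N=0) = ψ + (1−ψ)e^{−λ}`. ψ is a scalar on the logit scale — zero
  inflation is a property of the landscape as a whole here, and covariates
  enter only through λ and p.

Each observed cell is an independent binomial thinning,
`y_it | N_i ~ Binom(N_i, p_it)`. Links: `log λ_i = x_iᵀβ`,
`logit p_it = z_iᵀα` (detection covariates are site-level, so p is constant
across a site's cells). The marginal site likelihood sums the binomial
product over `N` from `max_t y_it` (below which the binomial pmf is zero —
an exactness optimisation, not an approximation) up to a truncation bound
`K`.

**Truncation.** Default `K` = max observed count + 100, user-overridable.
The mixture's truncated mass and the effect of doubling `K` are both
testable (`truncation_mass`, and the K-doubling checks in the test suite);
with camera-trap λ of a few animals and p below 0.1, the default leaves
< 1e−8 of probability beyond `K`.

**Numerics.** All sums run through log-sum-exp; with p ≈ 0.01–0.08 direct
probability products underflow at modest counts. Because p is site-level,
the per-occasion binomial product reduces to sufficient statistics (site
total, number of surveyed cells, and a precomputed table of summed log
binomial coefficients over the latent grid), so one likelihood evaluation is
O(R·K) and a full fit takes well under a second at 73 sites. Missing cells
(camera absent or inactive) are skipped; they never contribute zeros.

The Royle–Nichols model is fitted to the binarized matrix with
`P(detection in an occasion | N) = 1 − (1−r)^N` and a Poisson abundance
mixture, intercept-only (its role here is the null-model cross-check).
Its default truncation (K = 300) sits far beyond the Poisson tail for any
plausible camera-trap λ.

## Estimation and inference

Maximisation uses BFGS from a deterministic all-zeros start (optional seeded
random restarts), tolerance 1e−8. Finite-difference gradients bottom out at
≈ √eps·|f|, so a stationary point whose gradient sits at that noise floor is
accepted as converged; one restart from the candidate optimum guards against
a noise-corrupted Hessian approximation. Non-convergence is flagged on the
fit, warned about, and propagated into the AIC table — never silent.

Standard errors come from the inverse of the numerically evaluated observed
information (central finite-difference Hessian); P values are two-sided Wald.
A singular information matrix yields undefined SEs with a warning rather
than an exception. Derived quantities use the delta method:

- mean site abundance `λ̂ = exp(β₀)` (abundance at average covariates, since
  covariates are Z-standardized), SE `λ̂·se(β₀)`, 95% CI normal on the log
  scale and back-transformed;
- detection `p̂ = logistic(α₀)`, SE `p̂(1−p̂)·se(α₀)`;
- response curves `λ(x) = exp(β₀ + β_j x)` with the joint-vcov delta interval.

For the ZIP model the reported mean site abundance is `exp(β₀)` with ψ̂
reported separately; a `(1−ψ)`-scaled expected-abundance variant is available
through the empirical-Bayes summaries but is not the headline number, keeping
the three mixtures' intercepts directly comparable.

Empirical-Bayes site abundance evaluates `P(N_i = n | y_i)` at the MLE over
`n = max(y_i)..K`; the posterior mode is the value used for site-level
abundance maps, and the mean is returned alongside.

## Model selection and goodness of fit

Models are ranked by AIC; Akaike weights are `exp(−Δ/2)` normalised over the
candidate set, and a report flag marks models within 2 ΔAIC units — the set
from which inference should be drawn. No model averaging is provided.

Absolute fit uses a parametric bootstrap: simulate from the fitted model on
the same design and missingness pattern, refit the same specification
(started from the original MLE for speed and basin consistency), and
recompute the fit statistic. The default statistic is Pearson χ² on cell
expectations `ŷ_it = λ̂_i p̂_it` (ZIP: ×(1−ψ̂)); sum-of-squared-errors and
Freeman–Tukey are provided because the choice is consequential for ĉ and
should be testable (`observed_statistics` emits all three). The bootstrap
p-value is the proportion of simulated statistics at or above the observed
one; ĉ is observed/mean(bootstrap), floored at 1 when used to inflate SEs
(standard quasi-likelihood practice — under-dispersion is not rewarded).
Every GoF result records its seed and is bit-reproducible. Residual
diagnostics return per-site mean Pearson residuals for external mapping; no
formal spatial test is computed, since judging residual maps is deliberately
left to the analyst.

## Data preparation

- **Independence filter:** within each (camera, species) stream a photo is
  retained iff it falls ≥ 30 min (inclusive) after the previously *retained*
  photo. Measuring from the last retained event makes all retained events
  pairwise ≥ 30 min apart and the filter idempotent — the strictest reading
  of the ≥ 30 min convention.
- **Occasion pooling:** fixed three-day occasions (15 by default) anchored at
  each camera's own activation date, because deployments are staggered in
  blocks in real surveys. Occasions wholly outside the active period are
  missing; partially covered occasions keep their counts but carry an effort
  flag, with a toggle (`drop_partial`) to treat them as missing instead —
  both conventions are defensible and the choice is exposed rather than
  baked in.
- **Aggregation:** cameras inside one site become replicate-major columns
  ordered by camera id; sites with fewer cameras than the site-wide maximum
  get all-missing surplus columns. Aggregation preserves the total count.
- **Covariates:** Z-scores with the sample (n−1) standard deviation, original
  means/sds retained for back-transformation. Zero-variance columns are an
  error. The collinearity screen flags pairs with |Pearson r| ≥ 0.7 and
  model construction refuses formulas containing a flagged pair.
- **CSV conventions:** `NA` is the single missing sentinel; zero always means
  surveyed-with-no-detections. The count reader auto-detects replicate-major
  (`rep<k>_occ<t>`) vs flat site × occasion layouts and records which it
  found. The covariate reader detects already-Z-scored files (|mean| and
  |sd−1| below 0.02, loose because deposited files are rounded) and flags
  rather than re-transforms them.

## Synthetic-data generator

The generator emulates the survey design this package is aimed at: 73 sites,
1–4 cameras per site drawn with probabilities (0.30, 0.45, 0.17, 0.08) so
~143 cameras cover the grid and most sites are multi-camera, 15 three-day
occasions, detection probability near 0.08 and mean site abundance near 2.6.
Default effect sizes on the link scale (abundance: intercept 0.95, mixed
forest 0.33, human capture rate 0.27, village distance 0.25, sal forest
0.21; detection: fruit-tree density 0.27) define the canonical world that
the recovery tests must re-estimate. Raw covariates are drawn Gaussian with
field-plausible means/sds (optionally correlated through a user correlation
matrix) and Z-standardized; the ZIP variant defaults to ψ = 0.3 (~30% of
sites structurally unoccupied) and the NB variant to α = 1 (strong
overdispersion). Every counted detection can be expanded into a cluster of
1–3 photos within < 30 min plus independent human photo streams, so the
filter → pool → aggregate pipeline must reproduce the generating matrix
exactly — a property asserted, not assumed.

What the generator does **not** emulate: animal movement and home-range
geometry (cells are thinned independently, so there is no spatial
autocorrelation of counts between neighbouring sites or replicates),
double-counting/false positives, temporal variation in detection within a
deployment, and seasonal drift in abundance. Passing the recovery tests
therefore shows the estimator is correct *when the model's assumptions
hold*; it cannot show robustness to closure violations or misidentification.

## Problem sizes in tests and the acceptance script

Coefficient recovery runs 200 replicate surveys at the study design in the
test suite (60 in the acceptance script); goodness-of-fit calibration runs
50 replicates at 120 bootstrap iterations (uniformity of p-values, ĉ near 1)
and 40 replicates at 80 iterations (ĉ > 1 on NB-generated data); mixture
identification uses 20 replicates at 300 sites. These sizes were chosen once
to keep a full run in the minutes range on a single CPU while leaving Monte
Carlo error well inside the asserted margins; production analyses should use
1,000 bootstrap iterations, for which the machinery is unchanged.

## Known limitations

- N-mixture mixtures are weakly identifiable at 73 sites: AIC frequently
  prefers NB on Poisson data and vice versa at this size, which is why the
  mixture-identification check is run at 300 sites and reported as a rate
  rather than asserted per-dataset.
- The NB mixture's detection probability can collapse toward zero with a
  compensating rise in λ (a known ridge in these likelihoods); fits report
  the flag honestly and the AIC table warns when a non-converged fit enters.
- Detection covariates are site-level; occasion-varying detection (e.g.
  weather) is not modelled.
- Royle–Nichols support is intercept-only by design, matching its role as a
  null-model comparator.
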