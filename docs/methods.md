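# Methods

`chondrofit` estimates effect-direction probabilities for skeletal
phenotyping measurements with Bayesian hierarchical generalized linear
models. This note records the model, the numerical machinery, the synthetic
data the test-suite relies on, and the design choices that were genuinely
open.

## Models

Two noise families cover the measurement types that occur in growth-plate
phenotyping:

**Lognormal** (positive continuous responses: bone lengths, expression-zone
lengths in µm or mm, qPCR relative quantities):

    log y_i ~ Normal(eta_i, sigma)

**Binomial-logit** (BrdU labelling counts: `labelled` out of `total` cells
scored per region per animal):

    labelled_i ~ Binomial(total_i, theta_i),   logit(theta_i) = eta_i

with the shared linear predictor

    eta_i = alpha + sum_k beta_k x_ik [+ beta_int x_i1 x_i2] + sum_f u_f[g_f(i)]

where `beta` are effects of interest (genotype, treatment; treatment coding
against the `control`/`vehicle` reference), `beta_int` an optional pairwise
interaction, and `u_f` per-level group intercepts for batch, litter, animal
or embryo. Group intercepts are *separate fixed intercepts with a broad
shared prior*, constrained to sum to zero within each factor so they remain
identifiable against `alpha`; a partial-pooling (hierarchical variance)
variant is available behind `BayesGLM(..., pooled_group_intercepts=True)`
but is not the default, because the fixed-intercept reading is the more
literal interpretation of per-group intercepts in a linear model and keeps
the posterior free of funnel geometry.

### Identifiability caveat (nested grouping factors)

A fixed intercept per *animal* (or embryo) is exactly confounded with
genotype whenever each animal carries one genotype: shifting the genotype
coefficient can be absorbed by the animal intercepts without changing any
linear predictor, even under the sum-to-zero constraint. Genotype effects
must therefore be paired with grouping factors that *cross* genotype
(litters or batches containing both genotypes). The paired limb-explant
design keeps embryo intercepts because its identified quantities — the
within-embryo treatment effect and the genotype×treatment interaction — do
not suffer from this confounding; its genotype main effect is reported but
is prior-dominated by construction.

## Priors

Priors are broad relative to the data so the posterior is dominated by the
likelihood. They are set from the data's spread on the link scale:

* lognormal, with `s = 10·sd(log y) + 1`:
  `alpha ~ Normal(mean(log y), s)`, `beta, beta_int, u ~ Normal(0, s)`,
  `sigma ~ HalfNormal(0, s)`;
* binomial-logit: `alpha ~ Normal(logit(pooled rate clipped to [0.01,0.99]), 5)`,
  `beta, beta_int, u ~ Normal(0, 5)`.

The `10·spread + 1` rule makes "much broader than the data" concrete and
auditable; the binomial scale 5 spans roughly probabilities 0.007–0.993
around the pooled rate, far wider than any observed labelling fraction. A
practical consequence of proper (rather than improper flat) priors is a
small compression of extreme effect-direction probabilities toward 0.5 at
small n — of order 0.01 near p ≈ 0.95 for the default length design — which
makes the significance rule very slightly conservative relative to the
classical one-sided tail probability.

## Inference

No probabilistic-programming framework is assumed; the posterior is sampled
by an in-package Hamiltonian Monte Carlo sampler:

* analytic gradients of the log posterior for both families (verified
  against finite differences at 1e-7 accuracy in the test suite);
* leapfrog integration with the number of steps jittered uniformly in
  {1..max_leapfrog} (default 10) to avoid resonant trajectories;
* dual-averaging step-size adaptation to a target acceptance rate
  (default 0.9);
* a **dense** mass matrix (full covariance, shrinkage-regularized) estimated
  in two successive warmup windows. The sum-to-zero intercepts induce strong
  posterior correlations with `alpha` and the effect coefficients; a
  diagonal mass leaves effective sample sizes near 1 on the explant
  interaction model, while the dense mass yields R-hat ≈ 1.000 and ESS in
  the thousands at the default budget.

Defaults: 3 chains × (1000 warmup + 2000 kept draws), matching the
convention of a few chains of a few thousand iterations. Convergence is
monitored with split Gelman–Rubin R-hat (acceptance bound **R-hat < 1.02**
for every parameter; values below 1 are floored at 1) and bulk effective
sample size (via arviz). A run violating the bound is returned *flagged*,
and the pipeline marks its probabilities provisional rather than failing.
Chains are seeded from a single `SeedSequence(seed)`: identical
(data, config, seed) gives bit-identical draws.

## Effect-direction probabilities

For the coefficient of interest, `p− = fraction of pooled posterior draws
strictly below 0` and `p+ = 1 − p−` exactly (draws exactly at 0, a
measure-zero event, count to `p+`). `p− ≥ 0.950` or `p+ ≥ 0.950`
(threshold inclusive) is labelled significant; no multiple-testing
adjustment is applied anywhere. Probabilities are reported to 3 digits;
values below the Monte Carlo resolution `1/n_draws` (or that would render
as 0.000/1.000) are reported as bounds, e.g. `< 0.001`.

Effect sizes are reported on the measurement scale: percent change
`100·(exp(beta)−1)` for lognormal coefficients, percentage-point difference
`100·(logistic(alpha+beta+u_bar) − logistic(alpha+u_bar))` (with `u_bar`
the per-draw mean group intercept) for binomial coefficients; medians with
central 90% credible intervals.

## Model checking and comparison

**Posterior predictive checks** simulate replicate datasets from the fitted
likelihood at posterior draws and compare the statistics mean, sd, min, max
and per-genotype mean (on the labelling-rate scale for counts). The tail
probability `ppc_p` = fraction of replicated statistics ≥ observed; values
in [0.05, 0.95] are flagged consistent. The statistics are a fixed,
conventional set — the original analysis does not name its statistics.

**PSIS-LOO**: approximate leave-one-out cross-validation via
Pareto-smoothed importance sampling (generalized-Pareto fit to the upper
tail of the importance ratios, using arviz's `psislw` primitive), with
pointwise elpd, its standard error, and per-observation Pareto-k
diagnostics. For n ≤ 30 with any k > 0.7 an exact refit-LOO fallback is
used automatically; a held-out group level unseen in a reduced fit is
scored at intercept 0 (the prior mean), the correct predictive treatment
for a new level under sum-to-zero coding. The interaction comparison fits
the design with and without its genotype×treatment interaction and prefers
the higher-elpd model only when `|elpd_diff| > 2·SE(diff)` (SE from the
pointwise elpd differences); otherwise the models are reported
indistinguishable. The 2·SE rule is the conventional reading — no numeric
rule is stated in the original analysis, which reports only that the
comparison was done.

## Synthetic data

Four generators emulate the study designs, with defaults mirroring the
published figure legends (sample sizes) and published effect magnitudes:

| generator | design | defaults |
|---|---|---|
| `simulate_length_study` | one radius length per animal, litters round-robin | 10 vs 8 animals, 5 litters, control geometric mean 5000 µm, multiplier 0.865 (a −13.5% effect), litter SD 0.05, σ 0.05 (log scale) |
| `simulate_brdu_study` | labelled/total per animal×region | 6 vs 4 animals, 3 litters, control rate 0.30, drop 5.4 pp, animal SD 0.15 (logit), totals 200–600 |
| `simulate_qpcr_study` | relative quantities, batch intercepts | 12 vs 10 samples, 6 batches, control RQ 0.05, fold change 0.6, batch SD 0.2, σ 0.4 |
| `simulate_explant_study` | paired vehicle/treated counts per embryo | 9 vs 8 embryos, control rate 0.25, boost +3.2 pp, genotype −2.4 pp, interaction −3.2 pp (treatment response abolished in mutants), embryo SD 0.15 |

Free choices not fixed by any published number, chosen once for realism: a
P7 radius of ~5 mm; ~5% biological coefficients of variation for lengths;
columnar-zone BrdU labelling ~30%; qPCR RQ ~0.05 against B2M with ~40–45%
total CV; 200–600 scoreable cells per region. Group effects are drawn
Normal on the link scale, matching the fitted intercept model.

What the generators do *not* emulate: section-level variation within a
region (counts enter pre-aggregated), non-normal litter effects, unequal
litter sizes, measurement error in `total`, or any spatial growth-plate
structure. A green recovery/calibration test therefore establishes that the
inference machinery is correct *for the stated generative world*, not that
the original biological data satisfy these assumptions.

In the BrdU generator the per-animal effect (`animal_sd`) is deliberately
*not* matched by a model term (see the identifiability caveat): it acts as
overdispersion, so interval coverage for the BrdU design is expected to run
slightly below nominal while point estimates stay unbiased; the calibration
and coverage acceptance checks run on the length design, whose matched
model is exact.

## Numerical choices

* Sum-to-zero constraint implemented by sampling K−1 free intercepts per
  factor; the prior applies to all K implied levels.
* `log(sigma)` and hierarchical `log(tau)` are the sampling-space
  parameters (Jacobians included); exponentials are clamped at e^300.
* Binomial likelihoods use `xlogy`, so a success probability pinned at 0
  or 1 with incompatible counts yields −inf, never an exception.
* Constant chains make R-hat/ESS undefined: they return NaN sentinels and
  the run is flagged, not crashed.
* PSIS columns that are −inf for every draw are excluded from elpd with a
  warning and flagged with k = +inf.
* Dense-mass Cholesky factorization escalates a diagonal jitter (from
  1e-10·mean variance, ×100 per retry) and falls back to the diagonal if
  the covariance estimate is not positive definite.
* The log-posterior/gradient hot path is JIT-compiled (numba) for the
  common layout (at most one group factor, fixed intercepts), with a
  bit-equivalent-in-exact-arithmetic numpy fallback used automatically when
  numba is unavailable, for multiple group factors, or for the
  partial-pooling variant; the two routes are asserted to agree in the test
  suite. ESS is computed in one batched arviz call per fit.

## Known limitations

* Fixed broad intercepts cannot estimate a genotype effect against a nested
  grouping factor (by design — see above); the partial-pooling variant can,
  but its centered parameterization can mix poorly when data per group are
  weak, and it is deliberately not the default.
* No overdispersion family (e.g. beta-binomial) is provided; the binomial
  model understates uncertainty when counts within an animal are more
  variable than binomial.
* Technical qPCR replicates are averaged on the Ct scale; non-detects are
  rejected as input errors rather than imputed, and amplification
  efficiency is fixed at 2 (a per-gene efficiency hook exists on
  `delta_ct_relative_quantity`).
* PPC replicate count and LOO draw budgets trade Monte Carlo error for
  runtime; the defaults (500 replicates, full sampler budget) suit
  desk-scale datasets of tens to hundreds of rows.
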