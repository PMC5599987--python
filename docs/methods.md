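# Methods

## Model

The analysis unit is the sextant. For sextant *i* of subject *j*
examined by rater *r*:

* latent true status `y*_ij ~ Bernoulli(p_ij)` with
  `logit(p_ij) = β0 + x_ij'β + u_j`;
* subject random intercept `u_j ~ Normal(0, σ_u²)`, capturing the strong
  within-mouth correlation of sextant outcomes;
* observed status `y_ij ~ Bernoulli(q_ij)` with
  `q_ij = Se_r p_ij + (1 − Sp_r)(1 − p_ij)`.

The mixture `q` is the exact marginal of the latent status under
non-differential misclassification, so the true statuses are never
sampled. An optional second intercept level (rater or region) nests the
subject intercepts inside examiner clusters.

Misclassification modes:

* `none` — Se = Sp = 1; the uncalibrated random-intercept logistic model.
* `fixed` — Se/Sp fixed at validation point estimates, globally or per
  rater (the default pipeline path: per-rater estimates with a pooled
  fallback for strata under 20 pairs).
* `beta` — one (Se, Sp) pair sampled with independent
  `Beta(tp+1, fn+1)` and `Beta(tn+1, fp+1)` priors built from validation
  counts, truncated to the identifiable region Se + Sp > 1. This
  propagates validation uncertainty into the odds ratios; interval
  widths can only grow relative to `fixed`.

Identifiability requires Se + Sp > 1 for every rater; configurations
violating it are rejected with an explanatory error everywhere they can
enter (generator, model spec, Rogan–Gladen correction).

## Inference

The subject intercepts are integrated out of the likelihood with
probabilists' Gauss–Hermite quadrature (default 21 nodes; records are
first collapsed to (subject, rater, covariate-pattern) binomial groups,
so one likelihood evaluation costs O(subjects × nodes)). The remaining
parameters `(β0, β, log σ_u, …)` form a low-dimensional smooth posterior
sampled with `emcee`, using differential-evolution moves (80% DEMove,
20% DESnookerMove), which mix several times faster than the default
stretch move on these correlated posteriors. Chains start in a small
ball around the posterior mode found by BFGS.

* Priors: coefficients Normal(0, 10) on the log-odds scale — diffuse
  without improper tails; `σ ~ Half-Normal(2)`. A flat coefficient prior
  (`coef_scale = inf`) is available and is used by the
  maximum-likelihood cross-checks.
* Defaults: 32 walkers × (500 burn-in + 1000 kept) steps. Walkers are
  treated as chains for split-R-hat and bulk ESS (arviz). A fit whose
  max R-hat exceeds 1.1 or min ESS falls below 400 records the failure
  in `fit.warnings` and emits a Python warning — loud, but the result is
  returned for inspection.
* The reported 95% interval is the equal-tailed posterior credible
  interval; OR interval endpoints are exactly `exp` of the log-OR
  endpoints (monotone transform), never separately estimated.
* DIC = D̄ + p_D with p_D = D̄ − D(θ̄), computed on the *marginal*
  deviance (random intercepts integrated out, misclassification mixture
  included). This differs from Gibbs-sampler conventions that condition
  on the sampled random effects; marginal DIC is the variant that is
  well defined when the intercepts are never sampled, and it is
  comparable between calibrated and uncalibrated fits on identical data.
  The deviance mean uses every 4th kept draw; the induced error is well
  under 0.5 on the scale where model differences of interest are ≥ 2.

### Independent oracles

Two cross-checks are built in and exercised by the test suite:

* `oracle.grid_posterior_2x2` re-derives the posterior for a 2×2
  exposure table (no random effect, ≤ 2 free parameters) by dense-grid
  numerical integration with its own likelihood code; MCMC posterior
  means agree within 2% of the posterior SD.
* `oracle.rogan_gladen_or` applies the closed-form correction
  `p = (p_obs + Sp − 1)/(Se + Sp − 1)` per exposure group; with flat
  priors the model's posterior mode reproduces it to optimizer
  precision.

The grid spans ±1.5 log-odds units around a Rogan–Gladen-based centre at
201² points; this covers >10 posterior SDs for interior tables. Tables
whose corrected proportions sit near 0 or 1 have heavy-tailed,
weakly-identified posteriors for which a fixed grid truncates mass — the
oracle is therefore only used (and only valid) on interior tables.

## Synthetic data generator

The generator is the forward model above plus survey plumbing, emulating
a nationwide oral-health survey: 12 raters nested two per region in 6
regions, subjects allocated round-robin to regions and raters; per
subject a scorable-sextant count of 1 + Binomial(5, 0.7) (mean 4.5,
emulating missing and edentulous sextants); subject-level covariates
drawn independently at the margins education 0.40, BMI ≥ 25 0.35,
pre-diabetes 0.16, diabetes 0.06, smoking 0.22, male 0.42, alcohol 0.32,
age Normal(46, 16) truncated at 18. Default per-rater (Se, Sp) pairs
range from (0.50, 0.55) to (0.85, 0.89), spanning positive likelihood
ratios ≈ 1.1–7.7 — the heterogeneity reported for trained raters in
community validation studies. Ordinal CPI/LA scores are drawn backwards
from the binary outcome (a mix of pocket-only, pocket-plus-attachment
and attachment-only presentations) so that scoring-rule tests have
ordinal material; the generator has no site-level or ordinal progression
model.

What passing tests therefore show: correct likelihood, correct
calibration arithmetic, near-nominal Bayesian coverage *when the model
class matches the data-generating process*. What they cannot show:
robustness to covariate correlation (off by default; a correlation
matrix can be supplied), differential misclassification (excluded by
design), or real-world deviations such as site-level error structure.

All randomness flows from one `numpy` Generator keyed by the config
seed, consumed in documented order; a fixed config is byte-reproducible.

## Numerical and design choices

* Binomial confidence intervals are exact Clopper–Pearson
  (`statsmodels`, beta-quantile route), the conservative choice for the
  small validation strata (~tens of pairs); the suite checks them
  against direct tail-inversion by bisection.
* Sextant aggregation is the site maximum; an empty sextant is a
  *missing* signal, never healthy. Outcome definitions: CPI ≥ c
  (default 3), LA ≥ 1, or the combined either-or; the combined count
  dominates each component by construction.
* Subjects with no scorable sextant are dropped (logged); partial
  dentitions contribute their scorable sextants.
* Age is kept continuous (per-year OR) and centred internally for
  sampling stability; intercept reporting absorbs the shift. AR/PAR are
  computed for binary exposures only.
* Report percentages round half-up (away from zero for negatives), full
  precision retained internally.
* AR/PAR use posterior-median ORs; posterior-draw propagation is
  available through `CalibratedFit.draws` but off by default since the
  published report format carries no intervals for them.

## Experiment sizes

The attenuation/recovery experiment in the acceptance suite runs 20
seeded replicates of 500 subjects × 6 sextants (σ_u = 0.8, Se = 0.75,
Sp = 0.80, true smoking OR 2.0) with 16 walkers × (300 burn + 500 kept)
draws — settings at which the minimum bulk ESS stays in the hundreds and
the whole experiment completes in minutes. Misclassification at this
severity destroys most of the outcome information: single-replicate
calibrated medians scatter widely (≈1.4–3.4) while centring on the
truth, which is exactly why the calibrated intervals are wide and why
coverage, not point accuracy, is the meaningful criterion.

## Known limitations

* Differential misclassification (error rates depending on exposure) is
  out of scope; the mixture assumes non-differential error.
* The full CPI ordinal scale is dichotomized before modelling; no
  ordinal-outcome model.
* The beta-prior mode samples a single pooled (Se, Sp); per-rater
  uncertainty propagation would add two parameters per rater and is not
  implemented (per-rater *fixed* values are).
* Within-subject correlation beyond the shared intercept (e.g. spatial
  adjacency of sextants) is not modelled.
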