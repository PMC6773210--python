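# Methods

## Design vocabulary and contrast coding

The design has five factors: experiment (`brightness`, `length`), condition
(`congruent`, `incongruent`, `shape_change` — the control exists only in the
brightness experiment), familiarization group (6 vs 18 syllables, a
counterbalancing factor that does not enter the models), first-test order
(between subjects) and trial type (within subjects, one observation per
level). The dependent measure is looking time in seconds per test trial,
ceiling-censored at the 60-s maximum trial length; familiarization looking
during the fixed 60-s exposure enters the regressions as a standardized
covariate.

Two contrast schemes are built once and shared by every fit:

* **Single experiment (13 terms).** Two-level factors use difference
  coding (+1/2 / −1/2), so a coefficient is the difference of the two
  marginal means. The three-level condition factor uses two
  against-reference contrasts whose codes (2/3, −1/3, −1/3 and permutation)
  invert to `mean(condition) − mean(shape_change)` with the intercept equal
  to the unweighted mean of the three condition cells. Interactions are
  elementwise products. Consequence: the two condition columns are not
  orthogonal to each other (they share the reference level); all columns
  from *different* factor families are orthogonal on balanced data.
* **Aggregate (21 terms).** The five condition × experiment cells get an
  explicit cell-code table solved from the linear functionals each
  coefficient must equal: shape-vs-magnitude (codes 0.8 on the shape cell,
  −0.2 on the four magnitude cells), congruent−incongruent and
  brightness−length (±1/2 on magnitude cells, 0 on shape rows) and their
  product (±1/4, 0 on shape rows). The intercept is the unweighted mean of
  the five cells. Trial-type and order contrasts multiply in as above.

The familiarization covariate is centered and scaled by its subject-level
sample mean and SD; the applied center/scale is recorded in the design
matrix (and in all CLI metadata) because the covariate coefficient's units
depend on it.

## Synthetic-data generator

The generator emulates exactly the structure the models assume, plus the
two features of real data collection that the models do not model
explicitly (the coder rule and the attentiveness confound):

1. subject intercept `u ~ N(0, σ_u)` on log seconds;
2. trial-level latent `log T = x'β + u + N(0, σ_e)`;
3. a two-coder measurement step on the seconds scale: two readings
   `T + N(0, coder_sd)`; if they disagree by more than 5 s a third reading
   is drawn and the closest pair is averaged;
4. clamping into (0, 60] after averaging — the trial procedure, not the
   coders, enforces the ceiling — with the censoring flag set at the limit;
5. familiarization looking = 60 s × a Beta(3, 2) attentiveness fraction
   whose underlying Gaussian is correlated 0.3 with the subject intercept.

Defaults are the study's conditions: `n_per_cell = 8` subjects per
condition × order cell (16 per condition, 48 in the brightness experiment);
β equal to the experiment's fitted log-scale coefficient vector (intercept
3.37 log-s, trial-type effect 0.33, etc.); `σ_e = 0.49` and `σ_u = 0.32`,
back-derived from the reported coefficient standard errors together with
the marginal/conditional pseudo-R² pair (0.29/0.50); `coder_sd = 3.7 s`,
chosen so that the third coder is consulted on 34% of trials — the rate the
study reports (P(|N(0, sd√2)| > 5 s) = 0.34 at sd = 3.7). Under these
defaults roughly 10–25% of trials in the high-mean cells hit the ceiling.
The Beta(3, 2) attentiveness fraction (mean 36 s of looking) and the 0.3
correlation are modelling conveniences — the source experiments report only
that attentiveness varied widely — and both are configurable.

Seeding: each subject draws from an independent substream keyed by
(cell index, slot), so enlarging the design never perturbs existing
subjects' data.

What passing simulation tests does **not** show about real data: real
looking times need not be log-normal, infant attrition/exclusion is not
modelled, coder errors need not be Gaussian or independent, and the
familiarization–attentiveness structure is stipulated, not estimated.

### The endogenous covariate

Because attentiveness is correlated with the subject intercept, the
familiarization covariate is *endogenous*: a model conditioning on it
estimates `β_cov + cov(u, fam_z)/var(fam_z)`, not `β_cov` alone.
`implied_conditional_covariate_slope` computes that projection by
large-sample Monte Carlo (≈ 0.095 log-units at the defaults), and all
parameter-recovery and coverage checks target the implied conditional
estimand. Recovery of the ML estimator is additionally run on the
estimator's own data-generating process (no ceiling, no coder noise),
since the ML models deliberately ignore censoring.

## Classical inference

* **One-way ANOVA** on per-subject familiarization looking (fixed-effects
  decomposition; partial η² = SS_effect/(SS_effect + SS_error)).
* **Mixed (split-plot) ANOVA** on raw test-trial looking times, computed
  from balanced-design mean formulas with two error strata:
  subjects-within-cells (df 42 at the study size) for between effects, and
  the trial-type × subject stratum (df 42) for within effects. The test
  suite validates the full table against an independent projection-matrix
  decomposition.
* **Estimated marginal means** average cell means with equal weights.
  The variance of any cell-mean combination with weights *c* is
  `σ_u² Σ_ab (Σ_w c)²/n + σ_e² Σ c²/n`, re-expressed in the two mean
  squares; combinations that live purely in one stratum take that stratum's
  df. Contrasts mixing strata are rejected rather than given an
  approximate df (no Satterthwaite/Kenward–Roger by design). Tukey
  adjustment uses the studentized-range distribution with the family size
  of the grid, applied within each comparison family separately; a
  two-mean family reduces to the ordinary t-test.
* **ML multilevel regression** (raw or log response): the random-intercept
  likelihood is profiled over λ = σ_u²/σ_e² (closed-form GLS given λ) and
  maximized in one dimension; statsmodels MixedLM (ML) is the test oracle.
  Coefficient df use the containment rule, observations − subjects
  (96 − 48 = 48), matching the published tables; p-values are two-sided.
  Marginal pseudo-R² = var(Xβ)/(var(Xβ) + σ_u² + σ_e²); conditional adds
  σ_u² to the numerator. The ANOVA-style summary reports type-III Wald F
  per coefficient set (consistent with sum-to-zero coding), with
  SS = q·F·σ_e² so that SS/MS/F are mutually consistent with MS_error =
  σ_e².

## Bayesian model family

Four variants: likelihood {normal on seconds, log-normal via a Gaussian
model of log seconds with the change-of-variables Jacobian} × censoring
{none, handled}. Censoring is implemented two ways:

* **latent** (default): each ceiling observation's response is an extra
  parameter constrained above the limit. The sampler is a blocked Gibbs
  scheme — exact joint Gaussian draws of (β, u) given the variances,
  truncated-normal draws of the latent responses, slice-sampling updates of
  log σ_e and log σ_u, plus an ancillarity–sufficiency interweaving move
  that re-draws σ_u under the non-centered parameterization (where it is a
  conjugate regression coefficient). The interweaving step removes the
  u ↔ σ_u coupling that otherwise throttles variance-component mixing;
  with it, bulk ESS for all reported parameters exceeds several hundred
  per thousand kept draws.
* **integrated**: ceiling rows contribute the log upper-tail probability.
  Subject intercepts are marginalized out of the target by per-subject
  Gauss–Hermite quadrature (25 nodes), and the low-dimensional marginal
  posterior (β, log σ_e, log σ_u) is explored with an affine-invariant
  ensemble sampler (emcee, differential-evolution moves). Subject
  intercepts and latent values are reconstructed afterwards by a few exact
  conditional scans per draw. Because this route shares no mechanics with
  the Gibbs engine, agreement of the two posteriors (coefficient medians
  within 0.05 log-units on the study-size dataset) is a standing
  correctness check; both are additionally validated against a dense 2-D
  grid-quadrature oracle on an intercept-only model.

The latent mode is the default: with conjugate augmentation it is both the
faithful missing-data treatment and the fastest engine; the integrated mode
serves as the independent validation route.

**Priors** (the source analysis' exact prior scales are not published; these
are weakly informative defaults justified by the 0–60 s response range, all
configurable): coefficients N(0, 1) on log seconds / N(0, 20 s) on raw
seconds; intercept N(log 30, 1) / N(30 s, 20 s); half-Normal(1) /
half-Normal(20 s) on both standard deviations.

**Diagnostics**: ≥ 4 chains by default; split-R-hat and bulk ESS (arviz) per
reported parameter; parameters violating R-hat ≤ 1.01 or ESS ≥ 400 are
listed in `convergence_warnings` and surfaced by the CLI. Intervals are
equal-tailed, at 90% and 95% by default, with a "credible" flag when an
interval excludes zero.

**Summaries**: Bayesian R² is computed per draw as
var(η)/(var(η) + σ_e²) over the observations, with η = Xβ + Zu on the
model's response scale — so the log-normal and normal models are each
scored on their own scale, mirroring how the pseudo-R² of the ML models is
reported. Posterior-predictive cell intervals simulate a new subject per
draw (fresh intercept and residual) and apply the ceiling when the model
censors. Within-subject difference posteriors report
mean(2-Change) − mean(1-Change) per condition × order, on the log scale
and in seconds (log-normal population mean `exp(μ + (σ_u² + σ_e²)/2)`).

## Aggregate model

The cross-experiment fit is the censored log-normal variant over the
21-term scheme, with a single subject-intercept variance shared across
experiments (nothing suggests stratified variance components, and the
shared choice is the more parsimonious; it is flagged as a choice).
Restricted to brightness rows, the aggregate coding spans exactly the
single-experiment coding (verified algebraically in the tests), so dropping
the length experiment reduces the model to the single-experiment one up to
reparameterization. `derived_contrast` evaluates any weighted combination
of implied cell means per draw — e.g. the incongruent-condition difference
between dimensions averaging over trial type and order. Note that derived
contrasts are reproducible from the published coefficients only up to the
coding convention: coefficient magnitudes for nested product terms depend
on code values that the source tables do not print.

## Power simulation

Monte-Carlo power for any mixed-ANOVA effect: simulate under a
user-specified coefficient vector, fit, count rejections at α, report the
binomial MC-SE. The study's original sample size was justified by .95
power for the condition × trial-type interaction at an effect size taken
from a predecessor experiment and never printed, so the module reports
power curves over sample sizes and effect scalings instead of claiming to
reproduce a specific figure. Type-I calibration (power at a null effect
equals α) and a closed-form noncentral-t oracle on a paired sub-design
(made locally Gaussian by a small residual SD) validate the machinery.

## Numerical choices and degenerate inputs

* Truncated-normal draws use inverse-CDF sampling through the survival
  function, with an exponential-rejection fallback beyond 6 SDs.
* Slice sampling uses stepping-out (width 0.5 on the log-SD scale) with
  shrinkage; no tuning parameters are exposed.
* The profiled ML optimizer searches log λ in [−15, 10] to 1e−10; a rank-
  deficient design raises before fitting.
* Zero within-group variance in the one-way ANOVA yields a flagged
  undefined F; a zero effect SS yields F = 0 even when the error MS is
  also zero.
* The generator accepts σ_e = 0 (degenerate, for exact-value checks);
  the samplers require positive response noise.
* `n_per_cell` must be even so the familiarization group can be
  counterbalanced exactly; odd values raise.
* Problem sizes in the validation harnesses: calibration uses 200
  replicates at the study's 48-subject size with a single 800-draw chain
  per replicate (the conjugate sampler's mixing makes one chain adequate
  for interval endpoints); ML recovery uses 150–200 replicates at
  n_per_cell = 200; the studentized-range oracle uses 10⁶ draws.

## Known limitations

* Printed coefficient magnitudes in the source tables are reproducible
  only up to the (unpublished) contrast code values and covariate scaling;
  this package's coding makes every coefficient a labelled mean difference,
  which need not match the original scaling constant-for-constant.
* The normal-likelihood variants can place predictive mass below 0 s;
  they are included for comparison, as in the original analysis, not as a
  recommended model.
* The mixed ANOVA and marginal means require balanced designs; the
  multilevel and Bayesian fits do not.
* No survival/frailty analysis, no model stacking or information criteria,
  and no non-parametric tests — all outside the analysis family this
  package reproduces.
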