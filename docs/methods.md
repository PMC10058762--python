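# Methods

This note documents the models implemented in `dnas`, the choices made
where the design was genuinely open, and what the synthetic cohorts do
and do not establish about behaviour on real data.

## The Dietary Non-Adherence Score

For an intake vector `x` over `n` food groups (default 10: cereals and
tubers, vegetables, fruits, meat, aquatic products, soybean and nuts,
eggs, dairy, edible oil, salt) and a guideline reference `y` (midpoint
of each group's recommended range, g/day), the score is the Euclidean
distance `sqrt(Σ (x_i − y_i)²)` on a normalized scale.

**Normalization.**  Raw grams would let bulky groups (cereals, dairy,
vegetables — hundreds of g/day) dominate groups measured in single grams
(salt, oil), and the distance would carry units.  The default `ratio`
mode divides each group by its reference, so every group contributes on
a comparable dimensionless scale, the reference maps to the all-ones
vector, and the score is invariant to jointly rescaling a group's intake
and its reference.  Typical scores then fall in the low single digits
(a diet off by 100% of the reference in four groups scores 2.0).  Raw
`grams` and sample `zscore` modes are retained as options; z-scoring
makes the score sample-dependent, which is why it is not the default.

**Metric.**  Euclidean is the default; Manhattan (`Σ|x_i − y_i|`) is
offered because "summing the per-group distances" is a natural L1
variant.  For identical inputs euclidean ≤ manhattan.

**Degenerate inputs.**  A zero reference in ratio mode raises rather
than silently substituting a scale; negative intakes, duplicated
(subject, round) pairs, and non-finite normalized entries are errors.

The bundled guideline CSV ships plausible range values for the ten
groups and is intended to be replaced by a verified table
(`load_guideline`) for any substantive analysis.

## Latent-class trajectory model

Subject `i` with `m_i` DNAS observations `y_i` at ages `a_i` belongs to
class `g ∈ 1..G` with probability `π_g`.  Within class `g`:

```
y_ij = β0_g + β1_g (a_ij − ā) + b_i + ε_ij,
b_i ~ N(0, τ²),  ε_ij ~ N(0, σ²)
```

Ages are centered at the observation-mean age `ā` for conditioning, so
`β0_g` is the class mean DNAS at the average age and `β1_g` the age
slope (score units per year).  Variance components are shared across
classes.  The marginal likelihood is the exact finite mixture of
multivariate normals with compound-symmetric covariance
`V_i = τ² J + σ² I` — evaluated in closed form via the Woodbury
identity, no numerical integration.

**Random-effects structure.**  The model uses a subject-level random
intercept only.  With at most four observations per subject a random
age-slope variance is weakly identified, and the intercept already
absorbs the dominant between-subject correlation; a shared-variance
random slope was judged not worth the added fragility.

**Fitting.**  EM over the joint latent structure (class label, random
intercept).  The E-step computes posterior class weights and the
conditional moments of `b_i`; the M-step updates `π`, the class fixed
effects (weighted least squares on the de-attenuated responses), and
both variance components in closed form.  The observed-data
log-likelihood is therefore monotone non-decreasing; each fit asserts
this internally.  Convergence: relative log-likelihood change < 1e-8
(default), max 500 iterations, non-convergence returned flagged with a
warning.  σ² is floored at 1e-10; τ² may reach 0 (degenerating to
independent observations).

**Initialization and label switching.**  Starts partition subjects by
quantiles of their mean DNAS (start 0 deterministic; later starts
randomly reassign 25% of subjects, seed-controlled); the best of
`n_starts` final likelihoods wins.  Fitted classes are reported in
ascending order of `β0_g` (low / medium / high), which makes results
seed-stable up to estimation noise.

**Model selection.**  BIC = −2·logL + k·log(N_subjects), with the number
of subjects (not observations) as the sample size, following mixed-model
convention; `select_n_classes` fits G = 1..G_max and returns the full
comparison table.

**Inference on slopes.**  Wald SEs from a central-finite-difference
Hessian of the marginal log-likelihood in an unconstrained
parametrization (log variances, multinomial logits).  These are
approximate: they ignore class-count selection, so reported p-values are
descriptive rather than formally valid post-selection tests.

**Identifiability caveat.**  Whether the classes are recoverable depends
on their separation relative to the subject-level noise
`sqrt(τ² + σ²/m)`.  At the default emulation settings (class means
3.3/4.8/5.9, between-subject SD 1.0, residual SD 0.8) the components
overlap heavily and the mixture MLE is only weakly tied to the
generating partition: EM initialized at the generating values drifts to
a different, equally likely decomposition even at the full cohort size.
This mirrors a real limitation of trajectory analyses on noisy scores.
The package therefore distinguishes the *emulation* defaults from the
*validation* fixture `CohortConfig.well_separated()` (between-subject SD
0.35, residual SD 0.5, putting adjacent class means ~2.5–3.5 effective
SDs apart), on which parameter recovery and BIC class-count selection
are demonstrated.  Conclusions about recovery on heavily overlapping
cohorts should not be drawn from those tests.

## Survival analysis

**Time scale.**  Time-on-study: follow-up years from enrollment to death
or loss to follow-up, with administrative censoring at the study end;
age at entry enters the adjusted models as a covariate.

**Person-year rates.**  Per group: `1000 · events / Σ follow-up`.  The
95% interval is the Poisson log-rate normal approximation
`exp(log r ± 1.96/√events)`, switching to the exact chi-square interval
below 10 events; zero events give rate 0 with a one-sided upper bound,
flagged.

**Cox models.**  `fit_cox` delegates to lifelines (Efron tie handling,
the default: death times recorded at coarse resolution make ties
expected).  A compact in-package Newton–Raphson solver provides the
Breslow variant, used for cross-checks; the two agree to ~1e-5 on
tie-free data.  Degenerate designs fail early with informative errors
(constant covariate; collinear pair named; no events).

**Sequential adjustment.**  Four nested models for the class hazard
ratios (class 1 = reference): unadjusted; + age, sex, region; + chronic
disease, medicine use, smoking, physical activity, energy intake, BMI;
+ drinking, income, education.  Region and education are dummy-coded
with first-level reference; income and physical activity enter linearly.
Under positive confounding each added block attenuates the class log-HR.

**Restricted cubic splines.**  Harrell's natural-spline basis: `k` knots
give `k−1` columns (linear term + truncated cubics constrained to
linearity beyond the boundary knots, scaled by the squared boundary
span).  Knots sit at the conventional quantiles (3 knots: 0.10 / 0.50 /
0.90).  For each candidate knot count (default 3, 4, 5) a Cox model on
the basis plus the fully adjusted covariate set is fit and scored by a
Cox coefficient of determination; the largest wins.  The default R² is
Royston–Sauerbrei R²_D (rankits of the prognostic index scaled by
√(8/π), refit as a single covariate, `R²_D = (D²/κ²)/(π²/6 + D²/κ²)`),
with Nagelkerke's as an option — the appropriate "R² for Cox" is
genuinely ambiguous, so the choice is explicit and configurable.
The curve is centered so HR = 1 exactly at the reference exposure;
`reference="auto"` uses the grid point minimizing the fitted log-HR over
the observed range (the lowest-risk diet score), and a fixed value may
be supplied instead.  Pointwise 95% bands come from the delta method on
the basis-contrast covariance.

## Synthetic cohorts

`generate_cohort` emulates the target design: ~4533 subjects, entry age
truncated-normal(43.3, 8.3) on [30, 60], four dietary rounds (2004,
2006, 2009, 2011), three latent classes with shares 378/3522/633, means
3.3/4.8/5.9, slopes −0.020/0.000/+0.008, between-subject SD 1.0 and
residual SD 0.8; exponential event times at class rates 11.8/28.8/44.5
per 1000 person-years; loss-to-follow-up hazard 0.07/year, calibrated so
the median follow-up lands near 6.9 years once mortality and the 11-year
administrative cutoff are accounted for; covariates with class-linked
directions (smoking and physical activity rising with class, income and
medicine use falling).  `covariate_log_hr` tilts the event hazard by
covariate effects, which is how `CohortConfig.confounded()` builds a
fixture with a true confounder in every adjustment block.

**Score-to-intake inversion.**  Intended scores are converted to intake
vectors in the ratio-normalized space: place the diet at `1 + s·u` for a
random unit direction `u`, sign-flipping any component that would drive
a coordinate negative (this preserves the length exactly), then multiply
by the reference grams.  Re-scoring generated intakes reproduces the
intended DNAS to machine precision, which is the property downstream
stages need; per-food marginal distributions, energy–food coupling, and
food-composition realism are *not* modelled.

**Exclusion rules.**  `apply_exclusions` drops subjects with baseline
age outside [30, 60], fewer than 3 dietary rounds, energy outside
[500, 8000] kcal/day at any round, missing food-group amounts, missing
key covariates, or cancer/pregnancy flags, and reports per-rule counts.
The generator can plant disjoint violations of each rule at configured
fractions so the filter is verifiable against known counts; the filter
is idempotent.

**What passing tests show.**  Generator-based tests establish that each
stage recovers what was planted under its stated conditions — they do
not establish robustness to real-data features the generator omits:
informative dropout, measurement error in recalls, secular dietary
trends distinct from ageing, regional diet structure, or non-exponential
hazards.

## Problem sizes

The test suite and `scripts/acceptance.py` run at reduced sizes chosen
to exercise the statistics without waste: full-size (4533-subject)
cohorts for scoring, exclusions, rates and follow-up summaries;
1000–1500 subjects for trajectory recovery and selection (with 10–20
seeded replicates where a frequency is asserted); 2000–3000 subjects for
hazard-ratio recovery and attenuation.  All randomness is
seed-controlled; identical seed and config reproduce byte-identical
tables and manifest.

## Known limitations

- Random intercept only; no random slopes or class-specific variance
  components.
- Class membership is intercept-only (no covariates in the mixing
  model), and classes enter Cox models by modal assignment, ignoring
  posterior uncertainty.
- Slope p-values ignore model selection; spline bands are pointwise.
- The score is direction-blind: it measures distance from the
  recommended pattern, not whether groups are over- or under-consumed.
- No competing risks, time-varying covariates, or proportional-hazards
  diagnostics.
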