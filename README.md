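# dnas

Tools for studying **dietary guideline adherence as a trajectory**, and its
association with all-cause mortality, in longitudinal nutrition cohorts.

Many diet-quality indices score each food group separately and sum the
component scores, which can hide imbalance between groups.  The **Dietary
Non-Adherence Score (DNAS)** instead treats a diet as a point in food-group
space and measures its Euclidean distance from the guideline-recommended
pattern:

```
DNAS(x, y) = sqrt( Σ_i (x_i − y_i)² ),   i = 1..n food groups
```

where `x_i` is the individual's intake of group *i* and `y_i` the guideline
reference (midpoint of the recommended range).  By default both are expressed
as ratios to the reference, so the recommended pattern sits at the all-ones
vector, a score of 0 means perfect adherence, and the score is dimensionless.

Around that score the package provides a full epidemiological pipeline:

- **`dnas.guidelines`** — guideline tables as data, intake normalization,
  scoring of longitudinal intake panels (Euclidean or Manhattan metric).
- **`dnas.lctm`** — latent-class linear mixed trajectory models of DNAS over
  age (`y_ij = β0_g + β1_g·age_ij + b_i + ε_ij` within class *g*), fit by EM
  on the exact multivariate-normal marginal likelihood, with BIC class-count
  selection and posterior classification.
- **`dnas.survival`** — person-year mortality rates with Poisson intervals,
  Cox proportional-hazards models with a sequential (4-model) confounder
  ladder, and restricted-cubic-spline Cox dose-response with knot-count
  selection by a Cox coefficient of determination.
- **`dnas.simulate`** — a synthetic longitudinal cohort generator with known
  ground truth (latent classes, random intercepts, event times) emulating a
  middle-aged cohort followed over four dietary survey rounds, plus the
  staged eligibility/exclusion rules.
- **`dnas.pipeline`** — end-to-end orchestration with a reproducible report
  bundle (tables, figures, manifest keyed by config hash + seed).

It is aimed at nutritional-epidemiology analysts who want a tested, scriptable
implementation of this design — or a simulation bench for studying its
statistical behaviour — without access to restricted cohort data.

## Worked example

```python
import warnings
from dnas import (CohortConfig, generate_cohort, default_guideline, score_panel,
                  TrajectoryPanel, fit_lctm, person_year_rates)

cohort = generate_cohort(CohortConfig.well_separated(n_subjects=800, seed=7))
dnas = score_panel(cohort.intake, default_guideline())
fit = fit_lctm(TrajectoryPanel.from_frame(dnas), 3, n_starts=3, seed=1)
print(fit.summary_frame().round(4))

records = cohort.survival.merge(
    fit.posterior_frame()[["subject_id", "modal_class"]], on="subject_id"
).rename(columns={"modal_class": "class"})
for r in person_year_rates(records):
    print(f"class {r.group}: {r.n_events} deaths / {r.person_years:.0f} PY = "
          f"{r.rate:.1f} per 1000 PY (95% CI {r.ci_lower:.1f}-{r.ci_upper:.1f})")
```

Output:

```
 class  mean_dnas_at_center  age_slope  slope_se  slope_p     pi
     1               3.1435    -0.0046    0.0072   0.5232 0.0871
     2               4.8204    -0.0026    0.0022   0.2278 0.7992
     3               5.9977     0.0141    0.0062   0.0233 0.1137
class 1: 6 deaths / 484 PY = 12.4 per 1000 PY (95% CI 4.5-27.0)
class 2: 143 deaths / 4307 PY = 33.2 per 1000 PY (95% CI 28.2-39.1)
class 3: 20 deaths / 482 PY = 41.5 per 1000 PY (95% CI 26.8-64.3)
```

The three classes are reported in ascending order of mean DNAS at the mean
age (low / medium / high non-adherence).  Here the fit recovers the planted
class structure: mean scores near 3.3 / 4.8 / 5.9, a small low-adherence
class (~9%) with the lowest mortality and a high-non-adherence class (~11%)
whose score rises with age and whose death rate is roughly 3-4x higher.
`sequential_models` then quantifies those contrasts as hazard ratios under
increasing confounder adjustment, and `fit_rcs_cox` estimates the continuous
dose-response of baseline DNAS with HR fixed to 1 at the reference score.

A `dnas` console script exposes the same stages
(`dnas simulate | score | lctm | survival | run`); see `dnas --help`.

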