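"""Synthetic longitudinal diet cohorts with known ground truth.

The generator emulates the design of a middle-aged Chinese nutrition
cohort: subjects aged 30-60 at entry, four dietary survey rounds at 2-3
year spacing, a three-class latent trajectory structure for the dietary
non-adherence score (DNAS), class-specific all-cause-mortality rates,
administrative censoring at the study end, and staged exclusion rules.
Every observable table is derived from an explicit ground truth (class
labels, random intercepts, uncensored event times) so the scoring,
trajectory, and survival stages can each be validated against what was
planted.

DNAS-to-intake inversion: on the ratio-normalized scale the guideline
reference is the all-ones vector, so an intake with intended score s is
placed at 1 + s*u for a random unit direction u; coordinates that would
go negative have their direction component sign-flipped (which preserves
the length exactly), so re-scoring the emitted grams reproduces the
intended DNAS to machine precision.  Only the score's distribution
matters downstream; per-food realism is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .guidelines import GuidelineSpec, default_guideline

__all__ = ["CohortConfig", "SimulatedCohort", "generate_cohort", "apply_exclusions"]

#: Key covariates whose missingness triggers exclusion.
KEY_COVARIATES = ["income", "smoker", "chronic_disease", "medicine", "physical_activity"]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the emulated cohort: 4533 subjects, three latent
    DNAS classes with means 3.3 / 4.8 / 5.9 at the mean entry age (43.3
    years), age slopes -0.020 / 0.000 / +0.008 DNAS units per year, and
    class mortality rates 11.8 / 28.8 / 44.5 per 1000 person-years with
    administrative censoring at the 2015 study end.
    """

    n_subjects: int = 4533
    survey_years: tuple[int, ...] = (2004, 2006, 2009, 2011)
    entry_age_mean: float = 43.3
    entry_age_sd: float = 8.3
    entry_age_range: tuple[float, float] = (30.0, 60.0)
    class_shares: tuple[float, ...] = (378.0, 3522.0, 633.0)  # normalized below
    class_means: tuple[float, ...] = (3.3, 4.8, 5.9)  # DNAS at centering age
    class_slopes: tuple[float, ...] = (-0.020, 0.000, 0.008)  # per year of age
    centering_age: float = 43.3
    between_sd: float = 1.0  # subject-level random-intercept SD
    residual_sd: float = 0.8  # round-level residual SD
    class_rates_per_1000py: tuple[float, ...] = (11.8, 28.8, 44.5)
    censoring_year: int = 2015
    # calibrated so total exit hazard (dropout + ~0.03/yr mortality)
    # yields a median follow-up near 6.9 years under 11-yr admin censoring
    dropout_rate: float = 0.07
    #: log-hazard effects of covariate columns (builds confounded fixtures)
    covariate_log_hr: dict = field(default_factory=dict)
    # class-linked covariate models (directions: smoking and physical
    # activity rise with class, income and medicine use fall)
    smoker_prev: tuple[float, ...] = (0.296, 0.431, 0.487)
    medicine_prev: tuple[float, ...] = (0.241, 0.192, 0.164)
    income_mean: tuple[float, ...] = (18393.0, 10933.0, 6307.0)
    pa_mean: tuple[float, ...] = (1518.0, 3158.0, 3714.0)
    pa_sd: float = 1500.0
    #: scalar = class-independent; a per-class tuple builds confounded fixtures
    female_prev: float | tuple[float, ...] = 0.505
    disease_prev: float = 0.32
    drinker_prev: float | tuple[float, ...] = 0.525
    energy_mean: float = 2224.0
    energy_sd: float = 503.0
    bmi_mean: float = 23.3
    bmi_sd: float = 3.2
    # planted-exclusion fractions (disjoint subject subsets); all 0 = clean
    frac_pregnant: float = 0.0
    frac_cancer: float = 0.0
    frac_low_energy: float = 0.0
    frac_high_energy: float = 0.0
    frac_missing_food: float = 0.0
    frac_missing_covariate: float = 0.0
    frac_two_rounds: float = 0.0
    frac_age_out: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shares = np.asarray(self.class_shares, dtype=float)
        if np.any(shares <= 0):
            raise ValueError("class shares must be positive")
        self.pi = shares / shares.sum()
        G = len(self.pi)
        for name in ("class_means", "class_slopes", "class_rates_per_1000py",
                     "smoker_prev", "medicine_prev", "income_mean", "pa_mean"):
            if len(getattr(self, name)) != G:
                raise ValueError(f"{name} must have one entry per class")
        if np.any(np.asarray(self.class_rates_per_1000py) <= 0):
            raise ValueError("mortality rates must be positive")
        if self.between_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("variance components must be positive")
        if list(self.survey_years) != sorted(set(self.survey_years)):
            raise ValueError("survey years must be strictly ascending")
        frac_total = (self.frac_pregnant + self.frac_cancer + self.frac_low_energy
                      + self.frac_high_energy + self.frac_missing_food
                      + self.frac_missing_covariate + self.frac_two_rounds
                      + self.frac_age_out)
        if frac_total > 0.9:
            raise ValueError("planted exclusion fractions exceed the cohort")

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    @classmethod
    def well_separated(cls, **overrides) -> "CohortConfig":
        """Validation fixture with cleanly separated trajectory classes.

        Keeps the default class means, shares, slopes and mortality
        rates but shrinks the variance components (between-subject SD
        0.35, residual SD 0.5) so adjacent class means sit ~2.5-3.5
        effective subject-level SDs apart.  Used for parameter-recovery
        and class-count-selection checks, where the property under test
        presumes identifiable classes; the plain defaults emulate the
        observed cohort's much heavier overlap.
        """
        base = dict(between_sd=0.35, residual_sd=0.5)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def confounded(cls, **overrides) -> "CohortConfig":
        """Fixture where every adjustment block contains a true confounder.

        Sex (demographic block), smoking (risk-factor block) and
        drinking (socio-economic block) are class-linked *and* carry
        real log-hazard effects, so each step of the sequential Cox
        ladder removes genuine positive confounding and the class
        hazard ratios attenuate monotonically in expectation.
        """
        base = dict(
            between_sd=0.35,
            residual_sd=0.5,
            female_prev=(0.70, 0.50, 0.30),  # female protective, rarer in class 3
            smoker_prev=(0.10, 0.45, 0.80),
            drinker_prev=(0.25, 0.50, 0.75),
            covariate_log_hr={"sex": -0.6, "smoker": 0.8, "drinker": 0.5},
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def homogeneous(cls, **overrides) -> "CohortConfig":
        """Single-class cohort (no latent structure), for null checks."""
        base = dict(
            class_shares=(1.0,),
            class_means=(4.8,),
            class_slopes=(0.0,),
            class_rates_per_1000py=(29.6,),
            smoker_prev=(0.431,),
            medicine_prev=(0.192,),
            income_mean=(10933.0,),
            pa_mean=(3158.0,),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("pi", None)
        return d


@dataclass
class SimulatedCohort:
    intake: pd.DataFrame  # long format, one row per (subject, round)
    survival: pd.DataFrame  # one row per subject
    truth: pd.DataFrame  # planted class, random intercept, event time
    config: CohortConfig


def _invert_score(target: np.ndarray, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Normalized intake vectors at exact distance ``target`` from all-ones."""
    n = len(target)
    u = rng.standard_normal((n, n_groups))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = 1.0 + target[:, None] * u
    # sign-flip direction components that would drive a coordinate negative;
    # |delta| is unchanged so the distance stays exactly `target`
    neg = v < 0
    v = np.where(neg, 1.0 + target[:, None] * np.abs(u), v)
    return v


def generate_cohort(
    config: CohortConfig, guideline: GuidelineSpec | None = None
) -> SimulatedCohort:
    """Draw a full synthetic cohort; byte-reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    spec = guideline if guideline is not None else default_guideline()
    n = config.n_subjects
    G = config.n_classes
    years = np.asarray(config.survey_years)
    n_rounds = len(years)

    cls = rng.choice(G, size=n, p=config.pi)
    lo, hi = config.entry_age_range
    a = (lo - config.entry_age_mean) / config.entry_age_sd
    b = (hi - config.entry_age_mean) / config.entry_age_sd
    age_entry = truncnorm.rvs(
        a, b, loc=config.entry_age_mean, scale=config.entry_age_sd,
        size=n, random_state=rng,
    )
    b_i = rng.normal(0.0, config.between_sd, size=n)

    means = np.asarray(config.class_means)
    slopes = np.asarray(config.class_slopes)

    # longitudinal DNAS targets and intake inversion
    rows = []
    subject_ids = np.array([f"S{i:05d}" for i in range(n)])
    offsets = years - years[0]
    ages = age_entry[:, None] + offsets[None, :]  # (n, rounds)
    eps = rng.normal(0.0, config.residual_sd, size=(n, n_rounds))
    target = (
        means[cls][:, None]
        + slopes[cls][:, None] * (ages - config.centering_age)
        + b_i[:, None]
        + eps
    )
    target = np.clip(target, 0.0, None)
    energy = np.clip(
        rng.normal(config.energy_mean, config.energy_sd, size=(n, n_rounds)),
        600.0, 6000.0,
    )
    vnorm = _invert_score(target.ravel(), spec.n_groups, rng)
    grams = vnorm * spec.reference_g  # de-normalize from the ratio scale

    intake = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_rounds),
            "round": np.tile(years, n),
            "age_years": ages.ravel(),
            "energy_kcal": energy.ravel(),
        }
    )
    for j, gname in enumerate(spec.groups):
        intake[gname] = grams[:, j]

    # covariates with class-linked directions
    smoker = (rng.random(n) < np.asarray(config.smoker_prev)[cls]).astype(int)
    medicine = (rng.random(n) < np.asarray(config.medicine_prev)[cls]).astype(int)
    income = rng.lognormal(
        mean=np.log(np.asarray(config.income_mean)[cls]) - 0.5, sigma=1.0, size=n
    )
    pa = np.clip(
        rng.normal(np.asarray(config.pa_mean)[cls], config.pa_sd), 0.0, None
    )
    def _prev(p):
        return np.asarray(p, dtype=float)[cls] if np.ndim(p) else float(p)

    survival = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age_entry": age_entry,
            "sex": (rng.random(n) < _prev(config.female_prev)).astype(int),
            "region": rng.choice(["north", "central", "south"], size=n),
            "chronic_disease": (rng.random(n) < config.disease_prev).astype(int),
            "medicine": medicine,
            "smoker": smoker,
            "physical_activity": pa,
            "energy_kcal": energy[:, 0],
            "bmi": rng.normal(config.bmi_mean, config.bmi_sd, size=n),
            "drinker": (rng.random(n) < _prev(config.drinker_prev)).astype(int),
            "income": income,
            "education": rng.choice(
                ["primary", "secondary", "tertiary"], size=n, p=[0.45, 0.40, 0.15]
            ),
            "pregnant": np.zeros(n, dtype=int),
            "cancer": np.zeros(n, dtype=int),
        }
    )

    # survival: exponential event times at the class rate, optionally tilted
    # by covariate effects (confounded fixtures); loss to follow-up and
    # administrative censoring at the study end
    haz = np.asarray(config.class_rates_per_1000py)[cls] / 1000.0
    for col, gamma in config.covariate_log_hr.items():
        haz = haz * np.exp(gamma * survival[col].to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / haz)
    t_admin = float(config.censoring_year - years[0])
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    followup = np.minimum(np.minimum(t_event, t_drop), t_admin)
    followup = np.maximum(followup, 1e-6)
    survival["followup_years"] = followup
    survival["event"] = (t_event <= np.minimum(t_drop, t_admin)).astype(int)

    truth = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "true_class": cls + 1,
            "random_intercept": b_i,
            "true_event_time": t_event,
            "planted_exclusion": "",
        }
    )
    # keep intended per-round scores for round-trip checks
    for r, yr in enumerate(years):
        truth[f"target_dnas_{yr}"] = target[:, r]

    cohort = SimulatedCohort(intake=intake, survival=survival, truth=truth,
                             config=config)
    _plant_exclusions(cohort, spec, rng)
    return cohort


def _plant_exclusions(cohort: SimulatedCohort, spec: GuidelineSpec,
                      rng: np.random.Generator) -> None:
    """Inject disjoint rule violations at the configured fractions."""
    cfg = cohort.config
    n = cfg.n_subjects
    order = rng.permutation(n)
    pos = 0

    def take(frac: float) -> np.ndarray:
        nonlocal pos
        k = int(round(frac * n))
        sel = order[pos: pos + k]
        pos += k
        return sel

    intake, surv, truth = cohort.intake, cohort.survival, cohort.truth
    sid = surv["subject_id"].to_numpy()
    baseline_round = cfg.survey_years[0]

    def mark(idx: np.ndarray, label: str) -> None:
        truth.loc[truth["subject_id"].isin(sid[idx]), "planted_exclusion"] = label

    idx = take(cfg.frac_pregnant)
    surv.loc[idx, "pregnant"] = 1
    mark(idx, "pregnant")

    idx = take(cfg.frac_cancer)
    surv.loc[idx, "cancer"] = 1
    mark(idx, "cancer")

    idx = take(cfg.frac_low_energy)
    sel = intake["subject_id"].isin(sid[idx]) & (intake["round"] == baseline_round)
    intake.loc[sel, "energy_kcal"] = 400.0
    mark(idx, "low_energy")

    idx = take(cfg.frac_high_energy)
    sel = intake["subject_id"].isin(sid[idx]) & (intake["round"] == baseline_round)
    intake.loc[sel, "energy_kcal"] = 9000.0
    mark(idx, "high_energy")

    idx = take(cfg.frac_missing_food)
    sel = intake["subject_id"].isin(sid[idx]) & (intake["round"] == baseline_round)
    intake.loc[sel, spec.groups[0]] = np.nan
    mark(idx, "missing_food")

    idx = take(cfg.frac_missing_covariate)
    surv.loc[idx, "income"] = np.nan
    mark(idx, "missing_covariate")

    idx = take(cfg.frac_two_rounds)
    keep_rounds = list(cfg.survey_years[:2])
    drop = intake["subject_id"].isin(sid[idx]) & ~intake["round"].isin(keep_rounds)
    cohort.intake = intake = intake[~drop].reset_index(drop=True)
    mark(idx, "two_rounds")

    idx = take(cfg.frac_age_out)
    half = len(idx) // 2
    young, old = idx[:half], idx[half:]
    surv.loc[young, "age_entry"] = 25.0
    surv.loc[old, "age_entry"] = 65.0
    for which, new_age in ((young, 25.0), (old, 65.0)):
        for s in sid[which]:
            m = intake["subject_id"] == s
            offs = intake.loc[m, "round"].to_numpy() - baseline_round
            intake.loc[m, "age_years"] = new_age + offs
    mark(idx, "age_out")


def apply_exclusions(
    intake: pd.DataFrame,
    survival: pd.DataFrame,
    min_rounds: int = 3,
    age_range: tuple[float, float] = (30.0, 60.0),
    energy_range: tuple[float, float] = (500.0, 8000.0),
    key_covariates: Sequence[str] = tuple(KEY_COVARIATES),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the cohort eligibility rules; returns filtered tables + log.

    Rules (a subject violating any is dropped from both tables):
    baseline age within ``age_range``; more than ``min_rounds - 1``
    dietary rounds; energy within ``energy_range`` at every round; no
    missing food-group amounts; no missing key covariates; no cancer /
    pregnancy-or-lactation flag.  The log counts subjects violating each
    rule (a subject can violate several).  The filter is idempotent.
    """
    food_cols = [c for c in intake.columns
                 if c not in ("subject_id", "round", "age_years", "energy_kcal")]
    surv = survival.set_index("subject_id")
    by_subject = intake.groupby("subject_id")

    violations: dict[str, set] = {}
    age = surv["age_entry"]
    violations["age_outside_range"] = set(
        age[(age < age_range[0]) | (age > age_range[1])].index
    )
    rounds = by_subject.size()
    violations["too_few_rounds"] = set(rounds[rounds < min_rounds].index)
    bad_energy = intake[
        (intake["energy_kcal"] < energy_range[0])
        | (intake["energy_kcal"] > energy_range[1])
        | intake["energy_kcal"].isna()
    ]
    violations["extreme_energy"] = set(bad_energy["subject_id"])
    missing_food = intake[intake[food_cols].isna().any(axis=1)]
    violations["missing_food_group"] = set(missing_food["subject_id"])
    present = [c for c in key_covariates if c in surv.columns]
    violations["missing_covariate"] = set(surv[surv[present].isna().any(axis=1)].index)
    flags = set()
    for col in ("cancer", "pregnant"):
        if col in surv.columns:
            flags |= set(surv[surv[col] == 1].index)
    violations["cancer_or_pregnancy"] = flags

    excluded = set().union(*violations.values())
    keep = [s for s in surv.index if s not in excluded]
    log = {f"excluded_{k}": len(v) for k, v in violations.items()}
    log["excluded_total"] = len(excluded)
    log["n_retained"] = len(keep)
    intake_f = intake[intake["subject_id"].isin(keep)].reset_index(drop=True)
    survival_f = survival[survival["subject_id"].isin(keep)].reset_index(drop=True)
    return intake_f, survival_f, log
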