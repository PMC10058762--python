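"""Person-year rates, Cox fits against oracles, and spline construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from dnas.simulate import CohortConfig, generate_cohort
from dnas.survival import (
    SurvivalError,
    fit_cox,
    fit_rcs_cox,
    person_year_rates,
    rcs_basis,
    rcs_knots,
    sequential_models,
)


def two_group_exponential(seed, n=2000, hr=2.0, base_rate=0.05, admin=11.0):
    rng = np.random.default_rng(seed)
    g = (rng.random(n) < 0.5).astype(float)
    lam = base_rate * hr ** g
    t = rng.exponential(1.0 / lam)
    return pd.DataFrame(
        {
            "followup_years": np.minimum(t, admin),
            "event": (t <= admin).astype(int),
            "g": g,
        }
    )


class TestRates:
    def test_direct_arithmetic(self):
        df = pd.DataFrame(
            {
                "followup_years": np.full(100, 5.0),
                "event": [1] * 10 + [0] * 90,
                "class": 1,
            }
        )
        (est,) = person_year_rates(df)
        assert est.person_years == 500.0
        assert est.rate == pytest.approx(20.0)
        assert est.ci_lower <= est.rate <= est.ci_upper

    def test_zero_events_flagged_one_sided(self):
        df = pd.DataFrame(
            {"followup_years": np.full(20, 5.0), "event": 0, "class": 1}
        )
        (est,) = person_year_rates(df)
        assert est.rate == 0.0
        assert est.flagged
        assert est.ci_lower == 0.0 and est.ci_upper > 0.0

    def test_zero_person_years_errors(self):
        df = pd.DataFrame({"followup_years": [0.0], "event": [1], "class": [1]})
        with pytest.raises(SurvivalError, match="person-years"):
            person_year_rates(df)

    def test_matches_groupwise_sum_oracle(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "followup_years": rng.uniform(0.5, 11, 500),
                "event": rng.integers(0, 2, 500),
                "class": rng.integers(1, 4, 500),
            }
        )
        for est in person_year_rates(df):
            sub = df[df["class"] == est.group]
            events = sum(sub["event"])
            py = sum(sub["followup_years"])
            assert est.rate == pytest.approx(1000.0 * events / py, abs=1e-10)
            assert est.n_events == events


class TestFitCox:
    def test_null_binary_covariate_gives_unit_hr(self):
        # two groups with identical event-time structure
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = pd.DataFrame(
            {
                "followup_years": times * 2,
                "event": [1, 1, 1, 0, 0] * 2,
                "g": [0.0] * 5 + [1.0] * 5,
            }
        )
        fit = fit_cox(df, ["g"])
        assert fit.hr["g"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_small_instance_matches_brute_force_partial_likelihood(self, ties):
        rng = np.random.default_rng(7)
        n = 10
        T = rng.exponential(1, n) + np.arange(n) * 1e-4  # tie-free
        E = (rng.random(n) < 0.8).astype(int)
        E[0] = 1
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({"followup_years": T, "event": E, "x": x})

        def neg_pl(b):
            ll = 0.0
            for i in range(n):
                if E[i] == 1:
                    risk = T >= T[i]
                    ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return -ll

        oracle = minimize_scalar(
            neg_pl, bounds=(-5, 5), method="bounded", options={"xatol": 1e-10}
        ).x
        fit = fit_cox(df, ["x"], ties=ties)
        assert fit.coef["x"] == pytest.approx(oracle, abs=1e-4)

    def test_efron_breslow_agree_without_ties(self):
        df = two_group_exponential(1, n=300)
        fe = fit_cox(df, ["g"], ties="efron")
        fb = fit_cox(df, ["g"], ties="breslow")
        assert fe.coef["g"] == pytest.approx(fb.coef["g"], abs=1e-5)
        assert fe.se["g"] == pytest.approx(fb.se["g"], rel=1e-3)

    def test_hr_recovery_two_group_exponential(self):
        df = two_group_exponential(2, n=2000, hr=2.0)
        fit = fit_cox(df, ["g"])
        assert 1.8 <= fit.hr["g"] <= 2.2

    def test_no_events_rejected(self):
        df = pd.DataFrame({"followup_years": [1.0, 2.0], "event": 0, "x": [0.0, 1.0]})
        with pytest.raises(SurvivalError, match="event"):
            fit_cox(df, ["x"])

    def test_collinear_pair_named(self):
        df = two_group_exponential(3, n=100)
        df["g2"] = df["g"] * 2.0
        with pytest.raises(SurvivalError, match="'g' and 'g2'"):
            fit_cox(df, ["g", "g2"])

    def test_constant_covariate_rejected(self):
        df = two_group_exponential(3, n=100)
        df["c"] = 1.0
        with pytest.raises(SurvivalError, match="degenerate"):
            fit_cox(df, ["g", "c"])


@pytest.fixture(scope="module")
def confounded_records():
    cfg = CohortConfig.confounded(n_subjects=3000, seed=9)
    cohort = generate_cohort(cfg)
    surv = cohort.survival.merge(
        cohort.truth[["subject_id", "true_class"]], on="subject_id"
    ).rename(columns={"true_class": "class"})
    return surv


class TestSequentialModels:
    def test_shape_and_reference_class(self, confounded_records):
        fits, table = sequential_models(confounded_records)
        assert len(table) == 4
        assert list(fits) == ["model1", "model2", "model3", "model4"]
        assert {"hr_class2", "hr_class3"} <= set(table.columns)

    def test_confounder_adjustment_attenuates_hr(self, confounded_records):
        _, table = sequential_models(confounded_records)
        for c in (2, 3):
            log_hr = np.log(table[f"hr_class{c}"].to_numpy())
            assert np.all(np.diff(log_hr) <= 0)

    def test_null_class_effect_gives_unit_hrs(self):
        cfg = CohortConfig.well_separated(
            n_subjects=2000, seed=5, class_rates_per_1000py=(28.0, 28.0, 28.0)
        )
        cohort = generate_cohort(cfg)
        surv = cohort.survival.merge(
            cohort.truth[["subject_id", "true_class"]], on="subject_id"
        ).rename(columns={"true_class": "class"})
        _, table = sequential_models(surv)
        hrs = table[["hr_class2", "hr_class3"]].to_numpy().ravel()
        assert np.all(np.abs(np.log(hrs)) < 0.45)

    def test_missing_covariate_lists_requirement(self, confounded_records):
        broken = confounded_records.drop(columns=["bmi"])
        with pytest.raises(SurvivalError, match="model3.*bmi"):
            sequential_models(broken)


def textbook_rcs(x, knots):
    """Independent restricted-cubic-spline construction (explicit loop)."""
    k = list(knots)
    K = len(k)
    scale = (k[-1] - k[0]) ** 2
    out = np.empty((len(x), K - 1))
    for r, xv in enumerate(x):
        out[r, 0] = xv
        for j in range(K - 2):
            def plus3(u):
                return max(u, 0.0) ** 3
            t = (
                plus3(xv - k[j])
                - plus3(xv - k[K - 2]) * (k[-1] - k[j]) / (k[-1] - k[K - 2])
                + plus3(xv - k[-1]) * (k[K - 2] - k[j]) / (k[-1] - k[K - 2])
            )
            out[r, j + 1] = t / scale
    return out


class TestRcsBasis:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        knots = np.array([1.0, 3.0, 5.5, 8.0])
        assert np.allclose(rcs_basis(x, knots), textbook_rcs(x, knots), atol=1e-10)

    def test_nonlinear_columns_vanish_at_or_below_first_knot(self):
        knots = np.array([2.0, 5.0, 8.0])
        b = rcs_basis(np.array([0.5, 2.0]), knots)
        assert np.allclose(b[:, 1:], 0.0)

    def test_linear_beyond_boundary_knots(self):
        """Second differences vanish outside the boundary knots."""
        knots = np.array([2.0, 4.0, 6.0, 8.0])
        rng = np.random.default_rng(1)
        coef = rng.normal(0, 1, 3)
        h = 0.1
        for x0 in (9.5, 12.0, -1.0, 1.0):
            pts = np.array([x0 - h, x0, x0 + h])
            f = rcs_basis(pts, knots) @ coef
            second = (f[0] - 2 * f[1] + f[2]) / h ** 2
            assert second == pytest.approx(0.0, abs=1e-8)

    def test_value_and_derivatives_continuous_at_knots(self):
        knots = np.array([2.0, 4.0, 6.0, 8.0])
        rng = np.random.default_rng(2)
        coef = rng.normal(0, 1, 3)
        h = 1e-4
        for kv in knots:
            left = rcs_basis(np.array([kv - 2 * h, kv - h]), knots) @ coef
            right = rcs_basis(np.array([kv + h, kv + 2 * h]), knots) @ coef
            at = rcs_basis(np.array([kv]), knots) @ coef
            d_left = (at[0] - left[1]) / h
            d_right = (right[0] - at[0]) / h
            assert d_left == pytest.approx(d_right, abs=1e-3)

    def test_unsorted_or_duplicate_knots_rejected(self):
        with pytest.raises(SurvivalError):
            rcs_basis(np.arange(5.0), np.array([3.0, 1.0, 5.0]))
        with pytest.raises(SurvivalError):
            rcs_basis(np.arange(5.0), np.array([1.0, 1.0, 5.0]))

    def test_harrell_quantile_placement(self):
        x = np.linspace(0, 100, 1001)
        assert np.allclose(rcs_knots(x, 3), [10, 50, 90])


def linear_hazard_records(seed, n=3000, slope=0.35):
    rng = np.random.default_rng(seed)
    x = rng.normal(4.8, 1.0, n)
    lam = 0.02 * np.exp(slope * (x - 4.8))
    t = rng.exponential(1.0 / lam)
    return pd.DataFrame(
        {
            "followup_years": np.minimum(t, 11.0),
            "event": (t <= 11.0).astype(int),
            "baseline_dnas": x,
        }
    )


class TestFitRcsCox:
    def test_linear_truth_gives_small_nonlinear_terms_and_monotone_curve(self):
        curve = fit_rcs_cox(linear_hazard_records(3), candidate_knots=(3,))
        # band from repeated linear-truth simulation; true value is 0
        assert np.all(np.abs(curve.nonlinear_coef) < 0.5)
        assert np.all(np.diff(curve.log_hr) >= -1e-9)

    def test_hr_is_one_at_reference_exactly(self):
        curve = fit_rcs_cox(linear_hazard_records(4), candidate_knots=(3, 4, 5))
        bref_idx = np.argmin(np.abs(curve.grid - curve.reference))
        # reference lies on the evaluation grid in auto mode
        assert curve.grid[bref_idx] == curve.reference
        assert curve.hr[bref_idx] == 1.0

    def test_fixed_reference_respected(self):
        curve = fit_rcs_cox(
            linear_hazard_records(5), candidate_knots=(3,), reference=3.6
        )
        assert curve.reference == 3.6
        from dnas.survival import rcs_basis as rb

        at_ref = (rb(np.array([3.6]), curve.knots) - rb(np.array([3.6]), curve.knots))
        assert np.exp(at_ref @ curve.coef)[0] == 1.0

    def test_increasing_hazard_yields_increasing_curve(self):
        curve = fit_rcs_cox(linear_hazard_records(6), candidate_knots=(3,))
        assert curve.log_hr[-1] > curve.log_hr[0]

    def test_r2_table_covers_candidates(self):
        curve = fit_rcs_cox(linear_hazard_records(7), candidate_knots=(3, 4, 5))
        assert sorted(curve.r2_table["n_knots"]) == [3, 4, 5]
        assert curve.r2 == curve.r2_table["r2"].max()

    def test_too_few_distinct_exposures_rejected(self):
        df = linear_hazard_records(8, n=50)
        df["baseline_dnas"] = np.repeat(np.arange(5), 10).astype(float)
        with pytest.raises(SurvivalError, match="distinct"):
            fit_rcs_cox(df)
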