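"""Mortality rates, Cox models, and restricted-cubic-spline dose-response.

Time scale is time-on-study (follow-up years from enrollment to death or
loss to follow-up); age at entry enters the adjusted models as a
covariate.  Cox fits use the Efron approximation for tied event times by
default (a hand-rolled Newton solver provides the Breslow variant for
cross-checks).  The dose-response of baseline DNAS is modelled with
restricted (natural) cubic splines: piecewise cubics constrained to be
linear beyond the boundary knots, knots at Harrell's recommended
quantiles, with the knot count chosen by a Cox coefficient of
determination (Royston-Sauerbrei R^2_D by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import chi2, norm

__all__ = [
    "RateEstimate",
    "CoxFit",
    "SplineCurve",
    "person_year_rates",
    "fit_cox",
    "sequential_models",
    "rcs_basis",
    "rcs_knots",
    "fit_rcs_cox",
    "MODEL_BLOCKS",
]


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# person-year mortality rates


@dataclass(frozen=True)
class RateEstimate:
    """Mortality rate per 1000 person-years for one group, with 95% CI."""

    group: object
    n_events: int
    person_years: float
    rate: float  # per 1000 person-years
    ci_lower: float
    ci_upper: float
    flagged: bool = False  # zero events: one-sided interval


def _rate_ci(events: int, py: float, exact: bool) -> tuple[float, float]:
    if events == 0:
        upper = chi2.ppf(0.95, 2) / 2.0
        return 0.0, 1000.0 * upper / py
    if exact:
        lo = chi2.ppf(0.025, 2 * events) / 2.0
        hi = chi2.ppf(0.975, 2 * events + 2) / 2.0
        return 1000.0 * lo / py, 1000.0 * hi / py
    r = events / py
    half = 1.96 / np.sqrt(events)
    return 1000.0 * r * np.exp(-half), 1000.0 * r * np.exp(half)


def person_year_rates(
    records: pd.DataFrame,
    group_col: str = "class",
    time_col: str = "followup_years",
    event_col: str = "event",
    exact_when_sparse: bool = True,
) -> list[RateEstimate]:
    """Events / person-years per group, as a rate per 1000 person-years.

    The CI is the Poisson log-rate normal approximation
    exp(log r +/- 1.96/sqrt(events)); with fewer than 10 events (and
    ``exact_when_sparse``) the exact Poisson (chi-square) interval is
    used instead.  Zero events give rate 0 with a one-sided interval,
    flagged.
    """
    out = []
    for grp, sub in records.groupby(group_col, sort=True):
        py = float(sub[time_col].sum())
        if py <= 0:
            raise SurvivalError(f"group {grp!r} has zero person-years")
        events = int(sub[event_col].sum())
        exact = exact_when_sparse and events < 10
        lo, hi = _rate_ci(events, py, exact)
        out.append(
            RateEstimate(
                group=grp,
                n_events=events,
                person_years=py,
                rate=1000.0 * events / py,
                ci_lower=lo,
                ci_upper=hi,
                flagged=events == 0,
            )
        )
    return out


def rates_frame(rates: list[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in rates],
            "n_events": [r.n_events for r in rates],
            "person_years": [r.person_years for r in rates],
            "rate_per_1000py": [r.rate for r in rates],
            "ci_lower": [r.ci_lower for r in rates],
            "ci_upper": [r.ci_upper for r in rates],
        }
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    coef: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    loglik: float
    ties: str
    n_events: int
    n: int
    cov: pd.DataFrame | None = None
    loglik_null: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_lower": self.ci_lower,
                "hr_ci_upper": self.ci_upper,
            }
        )


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    dead = [c for c, s in zip(X.columns, sd) if s == 0]
    if dead:
        raise SurvivalError(f"degenerate (constant) covariates: {dead}")
    if X.shape[1] > 1:
        corr = np.corrcoef(arr, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        for i, j in zip(*iu):
            if abs(corr[i, j]) > 1 - 1e-8:
                raise SurvivalError(
                    f"collinear covariates: {X.columns[i]!r} and {X.columns[j]!r}"
                )


def _breslow_newton(T, E, X, max_iter=100, tol=1e-10):
    """Newton-Raphson on the Breslow partial likelihood."""
    n, p = X.shape
    order = np.argsort(-T, kind="stable")  # descending time
    T, E, X = T[order], E[order], X[order]
    beta = np.zeros(p)
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        w = np.exp(eta)
        # cumulative sums over the risk set (descending time => cumsum)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * X, axis=0)
        s2 = np.cumsum(w[:, None, None] * X[:, :, None] * X[:, None, :], axis=0)
        # risk set for an event at t includes all with T >= t; with ties on
        # descending order, take the last index of each tied block
        uniq_last = np.r_[np.flatnonzero(np.diff(T) != 0), n - 1]
        last_map = np.empty(n, dtype=int)
        start = 0
        for idx in uniq_last:
            last_map[start: idx + 1] = idx
            start = idx + 1
        ev = np.flatnonzero(E == 1)
        k = last_map[ev]
        ll = float(np.sum(eta[ev]) - np.sum(np.log(s0[k])))
        grad = X[ev].sum(axis=0) - (s1[k] / s0[k, None]).sum(axis=0)
        xbar = s1[k] / s0[k, None]
        info = (s2[k] / s0[k, None, None]).sum(axis=0) - np.einsum(
            "ki,kj->ij", xbar, xbar
        )
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as e:
            raise SurvivalError(f"singular information matrix: {e}") from e
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 50:
            raise SurvivalError("Cox fit diverged (possible complete separation)")
        beta = beta + step
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
    cov = np.linalg.inv(info)
    return beta, cov, ll


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "followup_years",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit with Wald 95% CIs.

    ``ties='efron'`` delegates to lifelines; ``ties='breslow'`` uses the
    package's own Newton solver on the Breslow partial likelihood.
    """
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise SurvivalError(f"missing covariate columns: {missing}")
    n_events = int(records[event_col].sum())
    if n_events < 1:
        raise SurvivalError("Cox model needs at least one event")
    X = records[covariates].astype(float)
    _check_design(X)

    if ties == "efron":
        df = pd.concat(
            [records[[time_col, event_col]].reset_index(drop=True),
             X.reset_index(drop=True)],
            axis=1,
        )
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col=time_col, event_col=event_col)
        except Exception as e:  # lifelines raises ConvergenceError and others
            raise SurvivalError(f"Cox fit failed to converge: {e}") from e
        coef = cph.params_
        se = cph.standard_errors_
        ll = float(cph.log_likelihood_)
        cov = pd.DataFrame(cph.variance_matrix_, index=coef.index, columns=coef.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = float(cph.log_likelihood_ratio_test().test_statistic)
        ll_null = ll - stat / 2.0
    elif ties == "breslow":
        beta, covm, ll = _breslow_newton(
            records[time_col].to_numpy(dtype=float),
            records[event_col].to_numpy(dtype=float),
            X.to_numpy(dtype=float),
        )
        coef = pd.Series(beta, index=covariates)
        se = pd.Series(np.sqrt(np.diag(covm)), index=covariates)
        cov = pd.DataFrame(covm, index=covariates, columns=covariates)
        ll_null = None
    else:
        raise SurvivalError(f"unknown ties method: {ties!r}")

    z = norm.ppf(0.975)
    return CoxFit(
        coef=coef,
        se=se,
        hr=np.exp(coef),
        ci_lower=np.exp(coef - z * se),
        ci_upper=np.exp(coef + z * se),
        loglik=ll,
        ties=ties,
        n_events=n_events,
        n=len(records),
        cov=cov,
        loglik_null=ll_null,
    )


#: Covariate blocks added cumulatively across the model ladder.
MODEL_BLOCKS: dict[str, list[str]] = {
    "model1": [],
    "model2": ["age_entry", "sex", "region"],
    "model3": [
        "chronic_disease",
        "medicine",
        "smoker",
        "physical_activity",
        "energy_kcal",
        "bmi",
    ],
    "model4": ["drinker", "income", "education"],
}

_CATEGORICAL = ("region", "education")


def _expand_categoricals(records: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code categorical covariates (first level = reference)."""
    use = records.copy()
    out_cols: list[str] = []
    for c in cols:
        if c in _CATEGORICAL and not np.issubdtype(use[c].dtype, np.number):
            dummies = pd.get_dummies(use[c], prefix=c, drop_first=True, dtype=float)
            use = pd.concat([use, dummies], axis=1)
            out_cols.extend(dummies.columns)
        else:
            out_cols.append(c)
    return use, out_cols


def sequential_models(
    records: pd.DataFrame,
    class_col: str = "class",
    time_col: str = "followup_years",
    event_col: str = "event",
    ties: str = "efron",
) -> tuple[dict[str, CoxFit], pd.DataFrame]:
    """The four-model adjustment ladder for trajectory-class hazard ratios.

    Model 1 enters class only; Models 2-4 add demographic, risk-factor,
    and socio-economic blocks cumulatively.  Class 1 is the reference;
    the returned table has one row per model and one HR (95% CI) column
    per non-reference class.
    """
    classes = np.sort(records[class_col].unique())
    if len(classes) < 2:
        raise SurvivalError("need at least two classes for hazard ratios")
    use = records.copy()
    class_cols = []
    for c in classes[1:]:
        col = f"class_{c}"
        use[col] = (use[class_col] == c).astype(float)
        class_cols.append(col)

    fits: dict[str, CoxFit] = {}
    rows = []
    cum: list[str] = []
    for name, block in MODEL_BLOCKS.items():
        missing = [c for c in block if c not in records.columns]
        if missing:
            raise SurvivalError(
                f"{name} requires covariates {block}; missing: {missing}"
            )
        cum = cum + block
        expanded, cum_cols = _expand_categoricals(use, cum)
        fit = fit_cox(
            expanded,
            class_cols + cum_cols,
            time_col=time_col,
            event_col=event_col,
            ties=ties,
        )
        fits[name] = fit
        row: dict[str, object] = {"model": name, "adds": "+".join(block) or "unadjusted"}
        for c, col in zip(classes[1:], class_cols):
            row[f"hr_class{c}"] = fit.hr[col]
            row[f"hr_class{c}_lo"] = fit.ci_lower[col]
            row[f"hr_class{c}_hi"] = fit.ci_upper[col]
        rows.append(row)
    return fits, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restricted cubic splines

#: Harrell's recommended knot quantiles by knot count.
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def rcs_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knot locations at Harrell's recommended quantiles of ``x``."""
    if n_knots not in _KNOT_QUANTILES:
        raise SurvivalError(f"unsupported knot count: {n_knots}")
    return np.quantile(np.asarray(x, dtype=float), _KNOT_QUANTILES[n_knots])


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (k-1 columns for k knots).

    First column is x itself; the k-2 nonlinear columns are the truncated
    cubics constrained so the function space is linear beyond the
    boundary knots (continuous value, first and second derivative at
    every knot), scaled by (k_last - k_first)^2 so coefficients share the
    scale of the linear term.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or len(k) < 3:
        raise SurvivalError("need at least 3 knots")
    if np.any(np.diff(k) <= 0):
        raise SurvivalError("knots must be strictly ascending and distinct")
    K = len(k)
    scale = (k[-1] - k[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    denom = k[-1] - k[-2]
    for j in range(K - 2):
        term = (
            cube(x - k[j])
            - cube(x - k[-2]) * (k[-1] - k[j]) / denom
            + cube(x - k[-1]) * (k[-2] - k[j]) / denom
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def _royston_d_r2(pi: np.ndarray, T: np.ndarray, E: np.ndarray) -> float:
    """Royston-Sauerbrei R^2_D from the prognostic index.

    Rankits of the PI scaled by sqrt(8/pi) are refit as a single Cox
    covariate; its coefficient D gives R^2_D = (D^2/kappa^2) /
    (pi^2/6 + D^2/kappa^2) with kappa^2 = 8/pi.
    """
    n = len(pi)
    ranks = pd.Series(pi).rank(method="average").to_numpy()
    z = norm.ppf((ranks - 0.375) / (n + 0.25))
    kappa2 = 8.0 / np.pi
    q = z / np.sqrt(kappa2)
    df = pd.DataFrame({"t": T, "e": E, "q": q})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    D = float(cph.params_["q"])
    return (D ** 2 / kappa2) / (np.pi ** 2 / 6.0 + D ** 2 / kappa2)


def _nagelkerke_r2(fit: CoxFit) -> float:
    if fit.loglik_null is None:
        raise SurvivalError("null log-likelihood unavailable for this fit")
    n = fit.n
    num = 1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / n)
    den = 1.0 - np.exp(2.0 * fit.loglik_null / n)
    return num / den


@dataclass
class SplineCurve:
    """Fitted dose-response of the hazard on an exposure, HR(reference)=1."""

    knots: np.ndarray
    coef: np.ndarray  # spline-basis coefficients
    cov: np.ndarray  # their covariance block
    grid: np.ndarray
    log_hr: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference: float
    r2: float
    r2_method: str
    r2_table: pd.DataFrame
    fit: CoxFit

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def nonlinear_coef(self) -> np.ndarray:
        return self.coef[1:].copy()

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "log_hr": self.log_hr,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def fit_rcs_cox(
    records: pd.DataFrame,
    exposure: str = "baseline_dnas",
    covariates: list[str] | None = None,
    candidate_knots: tuple[int, ...] = (3, 4, 5),
    reference: float | str = "auto",
    r2_method: str = "royston",
    time_col: str = "followup_years",
    event_col: str = "event",
    grid_size: int = 100,
) -> SplineCurve:
    """Restricted-cubic-spline Cox dose-response for a continuous exposure.

    For each candidate knot count, knots go at Harrell's quantiles, a Cox
    model is fit on the spline basis plus ``covariates``, and a Cox R^2
    is computed; the knot count with the largest R^2 wins.  The returned
    curve is centered so HR equals 1 exactly at the reference exposure
    (default: the exposure value minimizing the fitted log-HR over the
    observed range).
    """
    x = records[exposure].to_numpy(dtype=float)
    if len(np.unique(x)) < 10:
        raise SurvivalError("exposure needs at least 10 distinct values")
    covariates = list(covariates or [])
    expanded, cov_cols = _expand_categoricals(records, covariates)

    results = []
    for nk in candidate_knots:
        knots = rcs_knots(x, nk)
        if len(np.unique(knots)) != nk:
            warnings.warn(f"{nk}-knot candidate skipped: duplicate knot locations")
            continue
        basis = rcs_basis(x, knots)
        spline_cols = [f"rcs{j + 1}" for j in range(basis.shape[1])]
        df = expanded.reset_index(drop=True).copy()
        for j, c in enumerate(spline_cols):
            df[c] = basis[:, j]
        try:
            fit = fit_cox(df, spline_cols + cov_cols,
                          time_col=time_col, event_col=event_col)
        except SurvivalError as e:
            warnings.warn(f"{nk}-knot candidate failed: {e}")
            continue
        pi_full = (df[spline_cols + cov_cols].to_numpy(dtype=float)
                   @ fit.coef.to_numpy())
        if r2_method == "royston":
            r2 = _royston_d_r2(pi_full, df[time_col].to_numpy(),
                               df[event_col].to_numpy())
        elif r2_method == "nagelkerke":
            r2 = _nagelkerke_r2(fit)
        else:
            raise SurvivalError(f"unknown r2 method: {r2_method!r}")
        results.append((nk, knots, fit, spline_cols, r2))
    if not results:
        raise SurvivalError("no spline candidate converged")

    r2_table = pd.DataFrame(
        {"n_knots": [r[0] for r in results], "r2": [r[4] for r in results]}
    )
    nk, knots, fit, spline_cols, r2 = max(results, key=lambda r: r[4])

    scoef = fit.coef[spline_cols].to_numpy()
    scov = fit.cov.loc[spline_cols, spline_cols].to_numpy()
    grid = np.linspace(x.min(), x.max(), grid_size)
    raw = rcs_basis(grid, knots) @ scoef
    if reference == "auto":
        ref = float(grid[np.argmin(raw)])
    else:
        ref = float(reference)
    bref = rcs_basis(np.array([ref]), knots)[0]
    contrast = rcs_basis(grid, knots) - bref
    log_hr = contrast @ scoef
    var = np.einsum("ij,jk,ik->i", contrast, scov, contrast)
    half = 1.96 * np.sqrt(np.clip(var, 0.0, None))
    return SplineCurve(
        knots=knots,
        coef=scoef,
        cov=scov,
        grid=grid,
        log_hr=log_hr,
        hr=np.exp(log_hr),
        ci_lower=np.exp(log_hr - half),
        ci_upper=np.exp(log_hr + half),
        reference=ref,
        r2=r2,
        r2_method=r2_method,
        r2_table=r2_table,
        fit=fit,
    )
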