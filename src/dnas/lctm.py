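"""Latent-class linear mixed trajectory models for DNAS over age.

The model: subject i with observations y_i = (y_i1, ..., y_im) at ages
a_i belongs to latent class g with prior probability pi_g.  Within class
g,

    y_ij = beta0_g + beta1_g * (a_ij - a_bar) + b_i + eps_ij,

with a shared subject-level random intercept b_i ~ N(0, tau^2) and
residual eps_ij ~ N(0, sigma^2) (variance components shared across
classes).  Marginally, y_i | class g is multivariate normal with mean
X_i beta_g and covariance V_i = tau^2 J + sigma^2 I, so the observed-data
log-likelihood is

    l(theta) = sum_i log sum_g pi_g phi(y_i; X_i beta_g, V_i),

evaluated in closed form — no numerical integration.  Fitting is by EM
over the joint latent structure (class label, random intercept): the
E-step computes posterior class weights and the conditional moments of
b_i; the M-step has closed-form updates for pi, the class-specific
fixed effects, and both variance components, so the log-likelihood is
monotone non-decreasing across iterations.

Classes are reported in canonical order of ascending fitted mean at the
centering age (low / medium / high trajectories), which resolves label
switching across seeds.  The number of classes is chosen by BIC with the
number of *subjects* as the sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "TrajectoryPanel",
    "LctmParams",
    "LctmFit",
    "marginal_loglik",
    "fit_lctm",
    "select_n_classes",
    "classify",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class LctmError(ValueError):
    pass


@dataclass
class TrajectoryPanel:
    """Per-subject DNAS observations on a padded rectangular layout.

    ``y``/``age`` are (N, m_max) arrays padded with zeros where ``mask``
    is False; ``age_center`` is subtracted from ages before fitting so
    intercepts are interpreted at the sample-mean age.
    """

    ids: np.ndarray
    y: np.ndarray
    age: np.ndarray
    mask: np.ndarray
    age_center: float

    def __post_init__(self) -> None:
        self.m = self.mask.sum(axis=1)
        if np.any(self.m < 1):
            raise LctmError("every subject needs at least one observation")
        if not (np.all(np.isfinite(self.y[self.mask]))
                and np.all(np.isfinite(self.age[self.mask]))):
            raise LctmError("non-finite DNAS value or age")
        # centered ages, zeroed off-mask so padded sums are exact
        self.a = np.where(self.mask, self.age - self.age_center, 0.0)
        self.yz = np.where(self.mask, self.y, 0.0)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.m.sum())

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        value_col: str = "score",
        age_col: str = "age_years",
        id_col: str = "subject_id",
        age_center: float | None = None,
    ) -> "TrajectoryPanel":
        """Build a panel from a long-format DNAS table.

        ``age_center`` defaults to the observation-level mean age.
        """
        if len(df) == 0:
            raise LctmError("empty trajectory panel")
        if age_center is None:
            age_center = float(df[age_col].mean())
        grouped = df.sort_values([id_col]).groupby(id_col, sort=True)
        ids = np.array(list(grouped.groups.keys()))
        sizes = grouped.size().to_numpy()
        m_max = int(sizes.max())
        n = len(ids)
        y = np.zeros((n, m_max))
        age = np.zeros((n, m_max))
        mask = np.zeros((n, m_max), dtype=bool)
        for i, (_, sub) in enumerate(grouped):
            k = len(sub)
            y[i, :k] = sub[value_col].to_numpy(dtype=float)
            age[i, :k] = sub[age_col].to_numpy(dtype=float)
            mask[i, :k] = True
        return cls(ids=ids, y=y, age=age, mask=mask, age_center=age_center)


@dataclass
class LctmParams:
    """Model parameters: class fixed effects, mixing weights, variances."""

    beta: np.ndarray  # (G, 2): intercept at centering age, age slope
    pi: np.ndarray  # (G,)
    tau2: float  # random-intercept variance
    sigma2: float  # residual variance

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if self.beta.shape[0] != self.pi.shape[0]:
            raise LctmError("beta and pi disagree on the number of classes")
        if not np.isclose(self.pi.sum(), 1.0):
            raise LctmError("mixing proportions must sum to 1")
        if np.any(self.pi <= 0):
            raise LctmError("mixing proportions must be positive")
        if self.tau2 < 0:
            raise LctmError("random-intercept variance must be >= 0")
        if self.sigma2 <= 0:
            raise LctmError("residual variance must be > 0")

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    def n_parameters(self) -> int:
        g = self.n_classes
        return 2 * g + (g - 1) + 2


def _class_logdens(panel: TrajectoryPanel, params: LctmParams) -> np.ndarray:
    """(N, G) log phi(y_i; X_i beta_g, tau^2 J + sigma^2 I).

    Uses the Woodbury/compound-symmetry closed form: with m_i
    observations, det V_i = sigma^{2(m-1)} (sigma^2 + m tau^2) and
    r' V^{-1} r = (sum r^2 - tau^2 (sum r)^2 / (sigma^2 + m tau^2)) / sigma^2.
    """
    m = panel.m
    s2, t2 = params.sigma2, params.tau2
    denom = s2 + m * t2  # (N,)
    if np.any(denom <= 0) or s2 <= 0:
        raise LctmError("non-positive-definite marginal covariance")
    logdet = (m - 1) * np.log(s2) + np.log(denom)
    out = np.empty((panel.n_subjects, params.n_classes))
    for g in range(params.n_classes):
        mu = params.beta[g, 0] + params.beta[g, 1] * panel.a
        r = np.where(panel.mask, panel.yz - mu, 0.0)
        s1 = r.sum(axis=1)
        ss = (r * r).sum(axis=1)
        quad = (ss - t2 * s1 * s1 / denom) / s2
        out[:, g] = -0.5 * (m * _LOG2PI + logdet + quad)
    return out


def marginal_loglik(panel: TrajectoryPanel, params: LctmParams) -> float:
    """Observed-data log-likelihood sum_i log sum_g pi_g phi_ig."""
    ld = _class_logdens(panel, params) + np.log(params.pi)
    return float(logsumexp(ld, axis=1).sum())


def _posterior(panel: TrajectoryPanel, params: LctmParams):
    ld = _class_logdens(panel, params) + np.log(params.pi)
    tot = logsumexp(ld, axis=1)
    w = np.exp(ld - tot[:, None])
    return w, float(tot.sum())


def _em_step(panel: TrajectoryPanel, params: LctmParams) -> LctmParams:
    """One EM iteration; closed-form M-step over (pi, beta, sigma^2, tau^2)."""
    w, _ = _posterior(panel, params)
    m = panel.m
    s2, t2 = params.sigma2, params.tau2
    denom = s2 + m * t2
    vpost = t2 * s2 / denom  # Var(b_i | y_i, class) — class-independent
    G = params.n_classes
    n, n_obs = panel.n_subjects, panel.n_obs

    # conditional mean of b_i per class: tau^2 * sum(resid) / (sigma^2 + m tau^2)
    bhat = np.empty((n, G))
    for g in range(G):
        mu = params.beta[g, 0] + params.beta[g, 1] * panel.a
        r = np.where(panel.mask, panel.yz - mu, 0.0)
        bhat[:, g] = t2 * r.sum(axis=1) / denom

    pi_new = w.mean(axis=0)
    pi_new = np.clip(pi_new, 1e-12, None)
    pi_new /= pi_new.sum()

    # weighted least squares per class on target y_ij - bhat_ig
    sum_a = panel.a.sum(axis=1)
    sum_aa = (panel.a * panel.a).sum(axis=1)
    sum_y = panel.yz.sum(axis=1)
    sum_ay = (panel.a * panel.yz).sum(axis=1)
    beta_new = np.empty_like(params.beta)
    for g in range(G):
        wg = w[:, g]
        A = np.array(
            [
                [np.dot(wg, m.astype(float)), np.dot(wg, sum_a)],
                [np.dot(wg, sum_a), np.dot(wg, sum_aa)],
            ]
        )
        c = np.array(
            [
                np.dot(wg, sum_y - m * bhat[:, g]),
                np.dot(wg, sum_ay - sum_a * bhat[:, g]),
            ]
        )
        beta_new[g] = np.linalg.solve(A, c)

    # variance components
    sse = 0.0
    for g in range(G):
        mu = beta_new[g, 0] + beta_new[g, 1] * panel.a
        r = np.where(panel.mask, panel.yz - mu - bhat[:, g][:, None], 0.0)
        sse += np.dot(w[:, g], (r * r).sum(axis=1) + m * vpost)
    sigma2_new = max(sse / n_obs, 1e-10)
    tau2_new = max(float((w * (bhat * bhat + vpost[:, None])).sum() / n), 0.0)

    return LctmParams(beta=beta_new, pi=pi_new, tau2=tau2_new, sigma2=sigma2_new)


def _init_params(
    panel: TrajectoryPanel, G: int, rng: np.random.Generator, perturb: bool
) -> LctmParams:
    """Quantile split of subject-mean DNAS, optionally randomly perturbed."""
    ybar = panel.yz.sum(axis=1) / panel.m
    order = np.argsort(ybar, kind="stable")
    assign = np.empty(panel.n_subjects, dtype=int)
    bounds = np.linspace(0, panel.n_subjects, G + 1).astype(int)
    for g in range(G):
        assign[order[bounds[g]:bounds[g + 1]]] = g
    if perturb:
        flip = rng.random(panel.n_subjects) < 0.25
        assign[flip] = rng.integers(0, G, size=int(flip.sum()))
    beta = np.empty((G, 2))
    for g in range(G):
        sel = assign == g
        if sel.sum() < 2:
            sel = np.ones(panel.n_subjects, dtype=bool)
        yg = panel.yz[sel][panel.mask[sel]]
        ag = panel.a[sel][panel.mask[sel]]
        X = np.column_stack([np.ones_like(ag), ag])
        beta[g], *_ = np.linalg.lstsq(X, yg, rcond=None)
    counts = np.bincount(assign, minlength=G).astype(float)
    pi = np.clip(counts / counts.sum(), 0.02, None)
    pi /= pi.sum()
    resid_var = float(np.var(panel.yz[panel.mask]))
    tau2 = max(0.25 * resid_var, 1e-4)
    sigma2 = max(0.5 * resid_var, 1e-4)
    return LctmParams(beta=beta, pi=pi, tau2=tau2, sigma2=sigma2)


@dataclass
class LctmFit:
    """A fitted latent-class trajectory model, classes in low→high order."""

    params: LctmParams
    loglik: float
    n_parameters: int
    bic: float
    posterior: np.ndarray  # (N, G)
    modal_class: np.ndarray  # (N,), 1-based
    ids: np.ndarray
    converged: bool
    n_iter: int
    loglik_history: np.ndarray
    age_center: float
    n_subjects: int
    slope_se: np.ndarray | None = None
    slope_p: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.params.n_classes

    @property
    def slopes(self) -> np.ndarray:
        """Per-class age coefficient (DNAS units per year)."""
        return self.params.beta[:, 1].copy()

    @property
    def class_means(self) -> np.ndarray:
        """Fitted mean DNAS at the centering age, per class."""
        return self.params.beta[:, 0].copy()

    def summary_frame(self) -> pd.DataFrame:
        g = self.n_classes
        return pd.DataFrame(
            {
                "class": np.arange(1, g + 1),
                "mean_dnas_at_center": self.class_means,
                "age_slope": self.slopes,
                "slope_se": self.slope_se if self.slope_se is not None else np.nan,
                "slope_p": self.slope_p if self.slope_p is not None else np.nan,
                "pi": self.params.pi,
            }
        )

    def posterior_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"subject_id": self.ids})
        for g in range(self.n_classes):
            out[f"prob_class{g + 1}"] = self.posterior[:, g]
        out["modal_class"] = self.modal_class
        return out


def _canonicalize(params: LctmParams, posterior: np.ndarray):
    order = np.argsort(params.beta[:, 0], kind="stable")
    params = LctmParams(
        beta=params.beta[order],
        pi=params.pi[order],
        tau2=params.tau2,
        sigma2=params.sigma2,
    )
    return params, posterior[:, order]


def _pack(params: LctmParams) -> np.ndarray:
    g = params.n_classes
    alpha = np.log(params.pi[1:] / params.pi[0]) if g > 1 else np.empty(0)
    return np.concatenate(
        [params.beta.ravel(), [np.log(params.sigma2), np.log(max(params.tau2, 1e-12))], alpha]
    )


def _unpack(theta: np.ndarray, G: int) -> LctmParams:
    beta = theta[: 2 * G].reshape(G, 2)
    sigma2 = float(np.exp(theta[2 * G]))
    tau2 = float(np.exp(theta[2 * G + 1]))
    if G > 1:
        a = np.concatenate([[0.0], theta[2 * G + 2:]])
        pi = np.exp(a - logsumexp(a))
    else:
        pi = np.ones(1)
    return LctmParams(beta=beta, pi=pi, tau2=tau2, sigma2=sigma2)


def _slope_wald(panel: TrajectoryPanel, params: LctmParams):
    """Approximate slope SEs from the observed information (numeric Hessian)."""
    theta0 = _pack(params)
    G = params.n_classes

    def f(th: np.ndarray) -> float:
        return marginal_loglik(panel, _unpack(th, G))

    p = theta0.size
    h = 1e-4 * np.maximum(np.abs(theta0), 1.0)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(theta0 + ei + ej)
            fpm = f(theta0 + ei - ej)
            fmp = f(theta0 - ei + ej)
            fmm = f(theta0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    cov = np.linalg.inv(-H)
    slope_idx = np.arange(G) * 2 + 1
    var = np.diag(cov)[slope_idx]
    if np.any(var <= 0):
        raise np.linalg.LinAlgError("non-positive slope variance")
    se = np.sqrt(var)
    z = params.beta[:, 1] / se
    pval = 2 * norm.sf(np.abs(z))
    return se, pval


def fit_lctm(
    panel: TrajectoryPanel,
    G: int,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    compute_se: bool = True,
) -> LctmFit:
    """Fit a G-class trajectory model by EM, best of ``n_starts`` starts.

    The first start uses the deterministic quantile split of subject-mean
    DNAS; subsequent starts randomly perturb it (seed-controlled).
    Convergence is declared when the relative log-likelihood change drops
    below ``tol``; non-convergence returns a flagged fit with a warning.
    """
    if G < 1:
        raise LctmError("G must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, LctmParams, np.ndarray, bool, int] | None = None
    for start in range(max(n_starts, 1)):
        params = _init_params(panel, G, rng, perturb=start > 0)
        ll_prev = -np.inf
        history = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            params = _em_step(panel, params)
            ll = marginal_loglik(panel, params)
            history.append(ll)
            if ll + 1e-9 < ll_prev:
                warnings.warn("EM log-likelihood decreased; numerical issue")
            if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
                converged = True
                break
            ll_prev = ll
        ll = history[-1]
        if best is None or ll > best[0]:
            best = (ll, params, np.asarray(history), converged, it)
    ll, params, history, converged, n_iter = best  # type: ignore[misc]
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations (G={G})")
    if np.any(params.pi < 1e-4):
        warnings.warn(f"near-empty class in G={G} fit (min pi={params.pi.min():.2e})")

    posterior, _ = _posterior(panel, params)
    params, posterior = _canonicalize(params, posterior)
    slope_se = slope_p = None
    if compute_se:
        try:
            slope_se, slope_p = _slope_wald(panel, params)
        except np.linalg.LinAlgError:
            warnings.warn("observed information not invertible; slope SEs unavailable")
    k = params.n_parameters()
    n = panel.n_subjects
    return LctmFit(
        params=params,
        loglik=ll,
        n_parameters=k,
        bic=-2.0 * ll + k * np.log(n),
        posterior=posterior,
        modal_class=posterior.argmax(axis=1) + 1,
        ids=panel.ids.copy(),
        converged=converged,
        n_iter=n_iter,
        loglik_history=history,
        age_center=panel.age_center,
        n_subjects=n,
        slope_se=slope_se,
        slope_p=slope_p,
    )


def select_n_classes(
    panel: TrajectoryPanel,
    G_max: int,
    n_starts: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, list[LctmFit]]:
    """Fit G = 1..G_max and pick the class count with the lowest BIC.

    Returns (chosen G, comparison table, fits); non-converged fits stay
    in the table with a flag.
    """
    if G_max < 1:
        raise LctmError("G_max must be >= 1")
    rows = []
    fits = []
    for g in range(1, G_max + 1):
        fit = fit_lctm(panel, g, n_starts=n_starts, seed=seed + g, **fit_kwargs)
        fits.append(fit)
        rows.append(
            {
                "G": g,
                "loglik": fit.loglik,
                "n_parameters": fit.n_parameters,
                "bic": fit.bic,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["bic"].idxmin(), "G"])
    return chosen, table, fits


def classify(
    fit: LctmFit, panel: TrajectoryPanel, subject_ids=None
) -> pd.DataFrame:
    """Posterior class probabilities and modal class under a fitted model.

    ``subject_ids`` restricts the output; ids absent from the panel raise.
    """
    posterior, _ = _posterior(panel, fit.params)
    out = pd.DataFrame({"subject_id": panel.ids})
    for g in range(fit.n_classes):
        out[f"prob_class{g + 1}"] = posterior[:, g]
    out["modal_class"] = posterior.argmax(axis=1) + 1
    if subject_ids is not None:
        missing = set(subject_ids) - set(panel.ids.tolist())
        if missing:
            raise LctmError(f"subjects absent from panel: {sorted(missing)[:5]}")
        out = out.set_index("subject_id").loc[list(subject_ids)].reset_index()
    return out
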