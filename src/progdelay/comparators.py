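"""Benchmark analyses: MMRM-style longitudinal model and Cox PH.

The longitudinal comparator measures the treatment effect vertically, in
CDR-SB points at the final visit; its default form is the constrained
longitudinal data analysis (cLDA) model with a shared baseline mean across
randomized arms, free arm-by-visit means afterwards, and an unstructured
covariance. A classic change-from-baseline MMRM with baseline as a
covariate is available as an option.

The survival comparator dichotomizes each subject's trajectory at the
progression-to-dementia threshold (CDR-SB >= 4.5 at a post-baseline
visit) and fits a Cox proportional-hazards model for the arm indicator.
Events sit exactly at visit times, so ties are heavy; Efron's method is
the default tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import norm

from ._mvnfit import arm_stats, fit_clda
from .trajectories import ACTIVE, PLACEBO, TrialDataset

PROGRESSION_THRESHOLD = 4.5


@dataclass
class MMRMFit:
    """Vertical (score-scale) treatment-effect estimate at the final visit."""

    visit_months: np.ndarray
    means_by_arm_visit: pd.DataFrame  # index visit_month, columns placebo/active
    cfb_diff_final: float  # placebo minus active change from baseline, points
    percent_reduction: float | None  # of the placebo change from baseline
    se: float | None
    wald_p_final: float | None
    fitted_cov: np.ndarray = field(repr=False)
    converged: bool = True
    loglik: float | None = None
    model: str = "clda"


def fit_mmrm(data: TrialDataset, model: str = "clda") -> MMRMFit:
    """Fit the longitudinal comparator by maximum likelihood.

    ``model="clda"`` (default) is the shared-baseline constrained model on
    the raw scores; ``model="cfb"`` analyses change from baseline with the
    (centred) baseline score as a per-visit covariate.
    """
    if model == "clda":
        return _fit_clda_mmrm(data)
    if model == "cfb":
        return _fit_cfb_mmrm(data)
    raise ValueError("model must be 'clda' or 'cfb'")


def _fit_clda_mmrm(data: TrialDataset) -> MMRMFit:
    wide_p = data.wide(PLACEBO).to_numpy()
    wide_a = data.wide(ACTIVE).to_numpy()
    if np.isnan(wide_p).any() or np.isnan(wide_a).any():
        raise ValueError("all subjects must be observed on the common visit grid")
    stats = arm_stats(wide_p, wide_a)
    t = np.asarray(data.visit_months)
    res = fit_clda(stats)
    v = t.size
    j = v - 1
    cfb_p = res.placebo_means[-1] - res.placebo_means[0]
    cfb_a = res.active_means[-1] - res.active_means[0]
    diff = float(cfb_p - cfb_a)  # equals p_J - a_J under the shared baseline
    pct = float(diff / cfb_p) if cfb_p > 0 else None

    se = p_val = None
    if res.cov_beta is not None:
        c = np.zeros(1 + 2 * j)
        c[j] = 1.0
        c[2 * j] = -1.0
        var = res.contrast_variance(c)
        if var is not None and var > 0:
            se = float(np.sqrt(var))
            p_val = float(2.0 * norm.sf(abs(diff) / se))

    means = pd.DataFrame(
        {"placebo": res.placebo_means, "active": res.active_means},
        index=pd.Index(t, name="visit_month"),
    )
    return MMRMFit(
        visit_months=t,
        means_by_arm_visit=means,
        cfb_diff_final=diff,
        percent_reduction=pct,
        se=se,
        wald_p_final=p_val,
        fitted_cov=res.sigma,
        converged=res.converged,
        loglik=res.loglik,
        model="clda",
    )


def _fit_cfb_mmrm(data: TrialDataset, tol: float = 1e-10, max_iter: int = 500) -> MMRMFit:
    # change-from-baseline outcome, centred baseline as per-visit covariate
    t = np.asarray(data.visit_months)
    j = t.size - 1
    wide_p = data.wide(PLACEBO).to_numpy()
    wide_a = data.wide(ACTIVE).to_numpy()
    b_all = np.concatenate([wide_p[:, 0], wide_a[:, 0]])
    b_mean = b_all.mean()
    moms = {}
    for arm, wide in ((PLACEBO, wide_p), (ACTIVE, wide_a)):
        y = wide[:, 1:] - wide[:, [0]]
        b = wide[:, 0] - b_mean
        moms[arm] = dict(
            n=wide.shape[0],
            sum_b=b.sum(),
            sum_b2=(b**2).sum(),
            sum_y=y.sum(axis=0),
            sum_by=(b[:, None] * y).sum(axis=0),
            yy=y.T @ y,
            y=y,
            b=b,
        )
    n = moms[PLACEBO]["n"] + moms[ACTIVE]["n"]
    # with a degenerate baseline (zero-noise data) the covariate drops out
    use_gamma = (moms[PLACEBO]["sum_b2"] + moms[ACTIVE]["sum_b2"]) > 1e-10
    dim = 3 * j if use_gamma else 2 * j

    def gls(sig_inv):
        a = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        for gi, arm in enumerate((PLACEBO, ACTIVE)):
            m = moms[arm]
            sl = slice(gi * j, (gi + 1) * j)
            a[sl, sl] += m["n"] * sig_inv
            rhs[sl] += sig_inv @ m["sum_y"]
            if use_gamma:
                a[sl, 2 * j :] += m["sum_b"] * sig_inv
                a[2 * j :, sl] += m["sum_b"] * sig_inv
                a[2 * j :, 2 * j :] += m["sum_b2"] * sig_inv
                rhs[2 * j :] += sig_inv @ m["sum_by"]
        beta, mat = np.linalg.solve(a, rhs), a
        if not use_gamma:
            beta = np.concatenate([beta, np.zeros(j)])
        return beta, mat

    def scatter_cfb(beta):
        gamma = beta[2 * j :]
        s = np.zeros((j, j))
        for gi, arm in enumerate((PLACEBO, ACTIVE)):
            m = moms[arm]
            mg = beta[gi * j : (gi + 1) * j]
            mu_y = np.outer(mg, m["sum_y"]) + np.outer(gamma, m["sum_by"])
            mu_mu = (
                m["n"] * np.outer(mg, mg)
                + m["sum_b"] * (np.outer(mg, gamma) + np.outer(gamma, mg))
                + m["sum_b2"] * np.outer(gamma, gamma)
            )
            s += m["yy"] - mu_y - mu_y.T + mu_mu
        return s / n

    beta, _ = gls(np.eye(j))
    sigma = scatter_cfb(beta)
    singular = bool(np.linalg.eigvalsh(sigma).min() < 1e-10 * max(1.0, np.trace(sigma)))
    converged = True
    ll = None
    a_mat = None
    if not singular:
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            sig_inv = np.linalg.inv(sigma)
            beta, a_mat = gls(sig_inv)
            sigma = scatter_cfb(beta)
            _, logdet = np.linalg.slogdet(sigma)
            ll = -0.5 * n * (j * np.log(2.0 * np.pi) + logdet + j)
            if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
                converged = True
                break
            ll_prev = ll

    m_p, m_a = beta[:j], beta[j : 2 * j]
    diff = float(m_p[-1] - m_a[-1])
    pct = float(diff / m_p[-1]) if m_p[-1] > 0 else None
    se = p_val = None
    if a_mat is not None:
        c = np.zeros(a_mat.shape[0])
        c[j - 1] = 1.0
        c[2 * j - 1] = -1.0
        var = float(c @ np.linalg.inv(a_mat) @ c)
        if var > 0:
            se = float(np.sqrt(var))
            p_val = float(2.0 * norm.sf(abs(diff) / se))

    means = pd.DataFrame(
        {"placebo": np.concatenate([[0.0], m_p]), "active": np.concatenate([[0.0], m_a])},
        index=pd.Index(t, name="visit_month"),
    )
    return MMRMFit(
        visit_months=t,
        means_by_arm_visit=means,
        cfb_diff_final=diff,
        percent_reduction=pct,
        se=se,
        wald_p_final=p_val,
        fitted_cov=sigma,
        converged=converged,
        loglik=ll,
        model="cfb",
    )


@dataclass(frozen=True)
class ProgressionEvents:
    """First crossing of the dementia threshold per subject.

    ``data`` has one row per subject: ``subject_id, arm, event_time,
    event_flag`` (1 = progressed, 0 = censored at the last observed
    visit). Events sit exactly at visit months; no interval-censoring
    adjustment is attempted.
    """

    data: pd.DataFrame
    threshold: float


def dichotomize_progression(
    data: TrialDataset, threshold: float = PROGRESSION_THRESHOLD
) -> ProgressionEvents:
    """Dichotomize trajectories into progression-to-dementia events.

    The event time is the first post-baseline visit at which the score
    reaches the threshold; baseline values never count as events, so a
    subject already at or above the threshold at baseline is still at risk
    and events only at a post-baseline crossing. Subjects who never cross
    are censored at their last observed visit.
    """
    wide = data.wide()
    months = np.asarray(wide.columns, dtype=float)
    post = months > 0
    y = wide.to_numpy()[:, post]
    post_months = months[post]
    crossed = y >= threshold
    any_event = crossed.any(axis=1)
    first_idx = crossed.argmax(axis=1)
    event_time = np.where(any_event, post_months[first_idx], post_months[-1])
    arms = data.arm_of().reindex(wide.index)
    out = pd.DataFrame(
        {
            "subject_id": wide.index,
            "arm": arms.to_numpy(),
            "event_time": event_time,
            "event_flag": any_event.astype(int),
        }
    ).reset_index(drop=True)
    return ProgressionEvents(data=out, threshold=float(threshold))


@dataclass
class CoxFit:
    """Arm hazard ratio for progression to dementia."""

    hazard_ratio: float | None
    log_hr_se: float | None
    wald_p: float | None
    n_events: dict[str, int]
    estimable: bool
    ties: str = "efron"


def fit_cox(events: ProgressionEvents, ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards fit of the active-vs-placebo indicator.

    Efron's approximation (default) handles the heavy ties produced by
    events at a handful of discrete visit times; Breslow is available via
    ``ties="breslow"``. Zero events or failed estimation (e.g. complete
    separation) yield a fit flagged non-estimable.
    """
    df = events.data.copy()
    n_events = (
        df.groupby("arm")["event_flag"].sum().astype(int).reindex([PLACEBO, ACTIVE]).fillna(0)
    )
    n_events = {arm: int(k) for arm, k in n_events.items()}
    if df["event_flag"].sum() == 0:
        return CoxFit(None, None, None, n_events, estimable=False, ties=ties)
    df["treat"] = (df["arm"] == ACTIVE).astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(
            df[["event_time", "event_flag", "treat"]],
            duration_col="event_time",
            event_col="event_flag",
            fit_options={"precision": 1e-9},
        )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return CoxFit(None, None, None, n_events, estimable=False, ties=ties)
    if ties == "breslow":
        # refit the scalar coefficient under the Breslow partial likelihood
        beta = _breslow_coefficient(df)
        if beta is None:
            return CoxFit(None, None, None, n_events, estimable=False, ties=ties)
        coef, se = beta
    elif ties == "efron":
        coef = float(cph.params_["treat"])
        se = float(cph.standard_errors_["treat"])
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")
    p = float(2.0 * norm.sf(abs(coef) / se)) if se > 0 else None
    return CoxFit(
        hazard_ratio=float(np.exp(coef)),
        log_hr_se=se,
        wald_p=p,
        n_events=n_events,
        estimable=True,
        ties=ties,
    )


def _breslow_coefficient(df: pd.DataFrame):
    """Breslow-ties Cox coefficient for a single binary covariate."""
    from scipy.optimize import minimize_scalar

    times = df["event_time"].to_numpy()
    flags = df["event_flag"].to_numpy().astype(bool)
    x = df["treat"].to_numpy()
    event_times = np.unique(times[flags])

    def negloglik(beta: float) -> float:
        ll = 0.0
        for tt in event_times:
            dead = flags & (times == tt)
            risk = times >= tt
            ll += beta * x[dead].sum() - dead.sum() * np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(negloglik, bounds=(-10, 10), method="bounded")
    if not res.success:
        return None
    h = 1e-4
    info = (negloglik(res.x + h) - 2 * res.fun + negloglik(res.x - h)) / h**2
    if info <= 0:
        return None
    return float(res.x), float(1.0 / np.sqrt(info))
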