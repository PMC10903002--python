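"""Time-based progression model for repeated measures (PMRM).

The model expresses the active arm's mean at visit j as the placebo mean
trajectory evaluated at a shifted time, ``g(t_j - delta_j)``, where g is a
smooth interpolant of the per-visit placebo means. Treatment effects are
therefore in units of time (months of delayed progression), one free shift
per post-baseline visit -- no proportionality of the slowing across visits
is assumed. Baseline means are shared across arms (randomization), and
residuals are multivariate normal with an unstructured covariance.

Estimation is full maximum likelihood. Because the mean structure is
saturated given the shifts, the covariance can be profiled out in closed
form and the optimization runs over the per-visit placebo means and shifts
only, with the profile objective ``log det S(alpha, delta)`` where S is
the mean residual scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize
from scipy.stats import norm

from ._mvnfit import (
    ArmStats,
    arm_stats,
    fit_clda,
    is_singular,
    mvn_loglik,
    numeric_hessian,
    scatter,
)
from .trajectories import ACTIVE, PLACEBO, TrialDataset

# starting proportional-slowing fractions for the coarse multi-start grid
_START_FRACTIONS = (0.0, 0.10, 0.20, 0.30)


class _LinearTailSpline:
    """Natural cubic spline with linear extrapolation at both ends.

    The linear tails keep warped times slightly outside the visit range
    from producing cubic blow-up; inside the range this is the plain
    natural spline through the knots.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x0, self.x1 = float(x[0]), float(x[-1])
        self._spline = CubicSpline(x, y, bc_type="natural")
        d = self._spline.derivative()
        self.y0, self.y1 = float(y[0]), float(y[-1])
        self.s0, self.s1 = float(d(x[0])), float(d(x[-1]))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self._spline(np.clip(t, self.x0, self.x1))
        out = np.where(t < self.x0, self.y0 + self.s0 * (t - self.x0), out)
        out = np.where(t > self.x1, self.y1 + self.s1 * (t - self.x1), out)
        return out if out.ndim else float(out)


class _LinearInterp:
    def __init__(self, x, y):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        self.slope_lo = (self.y[1] - self.y[0]) / (self.x[1] - self.x[0])
        self.slope_hi = (self.y[-1] - self.y[-2]) / (self.x[-1] - self.x[-2])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.x, self.y)
        out = np.where(t < self.x[0], self.y[0] + self.slope_lo * (t - self.x[0]), out)
        out = np.where(t > self.x[-1], self.y[-1] + self.slope_hi * (t - self.x[-1]), out)
        return out if out.ndim else float(out)


class _SplineOps:
    """Linear-operator form of the natural cubic spline with linear tails.

    For fixed knots, spline values (and slopes) at any query points are
    linear in the knot ordinates, so evaluation reduces to a weight matrix
    times the ordinates. This is what makes the profile likelihood cheap:
    the reference curve never has to be re-built inside the optimizer, and
    the gradient of the warped active means is available in closed form.
    Agrees with :func:`reference_curve` to numerical precision.
    """

    def __init__(self, knots: np.ndarray):
        x = np.asarray(knots, dtype=float)
        n = x.size
        h = np.diff(x)
        # second derivatives M = C @ y with natural boundary (M_0 = M_{n-1} = 0)
        t_mat = np.zeros((n - 2, n - 2))
        d_mat = np.zeros((n - 2, n))
        for i in range(1, n - 1):
            r = i - 1
            t_mat[r, r] = (h[i - 1] + h[i]) / 3.0
            if r > 0:
                t_mat[r, r - 1] = h[i - 1] / 6.0
            if r < n - 3:
                t_mat[r, r + 1] = h[i] / 6.0
            d_mat[r, i - 1] = 1.0 / h[i - 1]
            d_mat[r, i] = -1.0 / h[i - 1] - 1.0 / h[i]
            d_mat[r, i + 1] = 1.0 / h[i]
        c = np.zeros((n, n))
        c[1:-1] = np.linalg.solve(t_mat, d_mat)
        self.x, self.h, self.c, self.n = x, h, c, n
        e = np.eye(n)
        # boundary slopes as rows acting on y
        self.slope_lo = (e[1] - e[0]) / h[0] - h[0] / 6.0 * c[1]
        self.slope_hi = (e[n - 1] - e[n - 2]) / h[n - 2] + h[n - 2] / 6.0 * c[n - 2]

    def weights(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Value and derivative weight matrices at query points ``u``."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        x, h, c, n = self.x, self.h, self.c, self.n
        e = np.eye(n)
        val = np.empty((u.size, n))
        der = np.empty((u.size, n))
        for q, uq in enumerate(u):
            if uq <= x[0]:
                val[q] = e[0] + (uq - x[0]) * self.slope_lo
                der[q] = self.slope_lo
            elif uq >= x[-1]:
                val[q] = e[n - 1] + (uq - x[-1]) * self.slope_hi
                der[q] = self.slope_hi
            else:
                i = int(np.searchsorted(x, uq, side="right") - 1)
                a = (x[i + 1] - uq) / h[i]
                b = (uq - x[i]) / h[i]
                val[q] = (
                    a * e[i]
                    + b * e[i + 1]
                    + h[i] ** 2 / 6.0 * ((a**3 - a) * c[i] + (b**3 - b) * c[i + 1])
                )
                der[q] = (e[i + 1] - e[i]) / h[i] + h[i] / 6.0 * (
                    -(3 * a**2 - 1) * c[i] + (3 * b**2 - 1) * c[i + 1]
                )
        return val, der


def reference_curve(alphas, visit_months):
    """Smooth placebo reference trajectory: month -> CDR-SB points.

    Natural cubic spline through ``(visit_months, alphas)``, extrapolated
    linearly with the boundary slope outside the visit range. With fewer
    than three visits a linear interpolant is returned with a warning.
    """
    x = np.asarray(visit_months, dtype=float)
    y = np.asarray(alphas, dtype=float)
    if x.size != y.size:
        raise ValueError("alphas and visit_months lengths differ")
    if x.size < 3:
        warnings.warn("fewer than 3 visits: falling back to linear interpolation")
        return _LinearInterp(x, y)
    return _LinearTailSpline(x, y)


@dataclass
class PMRMFit:
    """Result of a time-based PMRM fit.

    ``delays`` are the fitted per-visit time shifts of the active arm in
    months (positive = slowed progression); ``percent_slowing`` divides
    each by its visit time.
    """

    visit_months: np.ndarray
    ref_means: np.ndarray  # fitted placebo means per visit (incl. baseline)
    delays: np.ndarray  # per post-baseline visit, months
    delay_se: np.ndarray | None
    fitted_cov: np.ndarray = field(repr=False)
    loglik: float | None
    converged: bool
    wald_p_final: float | None
    n_subjects: int

    @property
    def percent_slowing(self) -> np.ndarray:
        return self.delays / self.visit_months[1:]

    def reference_curve(self):
        return reference_curve(self.ref_means, self.visit_months)


def pmrm_loglik(data: TrialDataset, alphas, delays, sigma) -> float:
    """Exact model log-likelihood at given parameter values.

    Useful as an optimizer oracle: the fitted log-likelihood must be at
    least the value at the data-generating parameters.
    """
    stats = _stats_from(data)
    alphas = np.asarray(alphas, float)
    delays = np.asarray(delays, float)
    t = np.asarray(data.visit_months)
    g = reference_curve(alphas, t)
    mu_a = np.concatenate(([alphas[0]], g(t[1:] - delays)))
    return mvn_loglik(stats, alphas, mu_a, np.asarray(sigma, float))


def _stats_from(data: TrialDataset) -> ArmStats:
    wide_p = data.wide(PLACEBO).to_numpy()
    wide_a = data.wide(ACTIVE).to_numpy()
    if wide_p.size == 0 or wide_a.size == 0:
        raise ValueError("both arms must be present")
    if np.isnan(wide_p).any() or np.isnan(wide_a).any():
        raise ValueError("all subjects must be observed on the common visit grid")
    return arm_stats(wide_p, wide_a)


def _active_means(theta: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = t.size
    alphas = theta[:v]
    delays = theta[v:]
    g = reference_curve(alphas, t)
    mu_a = np.concatenate(([alphas[0]], np.atleast_1d(g(t[1:] - delays))))
    return alphas, mu_a


def _invert_reference(g, target: float, t_j: float, t_max: float) -> float:
    """Solve g(u) = target for the warp time u, preferring the root nearest
    the visit time. Falls back to the nearest grid point when no sign
    change brackets the target (e.g. target outside the curve's range)."""
    from scipy.optimize import brentq

    lo, hi = -t_max, t_max
    grid = np.linspace(lo, hi, 481)
    vals = np.asarray(g(grid)) - target
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(lambda u: float(g(u)) - target, a, b, xtol=1e-10)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        return float(grid[np.argmin(np.abs(vals))])
    return min(roots, key=lambda r: abs(r - t_j))


def fit_pmrm(data: TrialDataset, ftol: float = 1e-12, rel_ll_tol: float = 1e-8) -> PMRMFit:
    """Maximum-likelihood fit of the time-based PMRM.

    The unstructured covariance is profiled out, leaving an optimization
    over per-visit placebo means and per-visit delays. Starting points are
    (a) a warm start obtained by inverting the reference curve at the
    constrained-longitudinal fitted active means and (b) a coarse grid of
    proportional slowing fractions; the best polished solution wins.
    Standard errors come from the inverse observed information of the mean
    parameters (orthogonal to the covariance block for Gaussian models).
    Delays are constrained to ``|delta_j| <= t_j`` so the active arm is
    never warped to before baseline.
    """
    stats = _stats_from(data)
    t = np.asarray(data.visit_months)
    v = t.size
    j = v - 1
    if v < 3:
        raise ValueError("need at least three visits to fit the PMRM")

    if is_singular(stats):
        return _fit_noise_free(stats, t)

    clda = fit_clda(stats)
    ops = _SplineOps(t)
    w_p, w_a = stats.n_p / stats.n, stats.n_a / stats.n
    e0 = np.zeros(v)
    e0[0] = 1.0

    def objective(theta: np.ndarray, with_grad: bool = False):
        alphas = theta[:v]
        delays = theta[v:]
        val_w, der_w = ops.weights(t[1:] - delays)
        mu_a = np.empty(v)
        mu_a[0] = alphas[0]
        mu_a[1:] = val_w @ alphas
        s = scatter(stats, alphas, mu_a)
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            if with_grad:
                return 1e10, np.zeros_like(theta)
            return 1e10
        if not with_grad:
            return logdet
        d_p = stats.ybar_p - alphas
        d_a = stats.ybar_a - mu_a
        sp = np.linalg.solve(s, d_p)
        sa = np.linalg.solve(s, d_a)
        grad_alpha = -2.0 * w_p * sp - 2.0 * w_a * (e0 * sa[0] + val_w.T @ sa[1:])
        gprime = der_w @ alphas
        grad_delta = 2.0 * w_a * sa[1:] * gprime
        return logdet, np.concatenate([grad_alpha, grad_delta])

    # warm start: invert the reference curve at the cLDA active means
    g0 = reference_curve(clda.placebo_means, t)
    warm_delays = np.array(
        [
            np.clip(t[k] - _invert_reference(g0, clda.active_means[k], t[k], t[-1]), -t[k], t[k])
            for k in range(1, v)
        ]
    )
    starts = [np.concatenate([clda.placebo_means, warm_delays])]
    alpha0 = np.concatenate(
        [[(stats.n_p * stats.ybar_p[0] + stats.n_a * stats.ybar_a[0]) / stats.n], stats.ybar_p[1:]]
    )
    grid_starts = [np.concatenate([alpha0, frac * t[1:]]) for frac in _START_FRACTIONS]
    grid_starts.sort(key=objective)
    starts.append(grid_starts[0])

    bounds = [(None, None)] * v + [(-t[k], t[k]) for k in range(1, v)]
    best = None
    for x0 in starts:
        res = minimize(
            lambda th: objective(th, with_grad=True),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    alphas, mu_a = _active_means(theta, t)
    sigma = scatter(stats, alphas, mu_a)
    sign, logdet = np.linalg.slogdet(sigma)
    loglik = -0.5 * stats.n * (v * np.log(2.0 * np.pi) + logdet + v)
    # converged if the optimizer says so, or if it stalled in the line
    # search with an (essentially) zero gradient at a finite optimum
    at_optimum = bool(np.abs(np.asarray(best.jac)).max() < 1e-5)
    converged = (bool(best.success) or at_optimum) and sign > 0

    if np.any(np.diff(alphas) < -1e-8):
        warnings.warn("fitted placebo trajectory is non-monotone; delays remain defined")

    delay_se = None
    wald_p = None
    try:
        sig_inv = np.linalg.inv(sigma)

        def mean_negloglik(th: np.ndarray) -> float:
            a = th[:v]
            val_w, _ = ops.weights(t[1:] - th[v:])
            m = np.concatenate(([a[0]], val_w @ a))
            return 0.5 * stats.n * float(np.trace(sig_inv @ scatter(stats, a, m)))

        hess = numeric_hessian(mean_negloglik, theta)
        cov = np.linalg.inv(hess)
        var_delays = np.diag(cov)[v:]
        if np.all(var_delays > 0):
            delay_se = np.sqrt(var_delays)
            z = theta[v:][-1] / delay_se[-1]
            wald_p = float(2.0 * norm.sf(abs(z)))
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information: standard errors unavailable")

    return PMRMFit(
        visit_months=t,
        ref_means=alphas,
        delays=theta[v:],
        delay_se=delay_se,
        fitted_cov=sigma,
        loglik=loglik,
        converged=converged,
        wald_p_final=wald_p,
        n_subjects=stats.n,
    )


def _fit_noise_free(stats: ArmStats, t: np.ndarray) -> PMRMFit:
    """Degenerate (zero residual scatter) limit: exact interpolation.

    The saturated mean structure fits the arm means exactly, so the least
    squares solution is the shared-baseline cell means with delays from
    inverting the reference curve; no standard errors exist.
    """
    v = t.size
    alphas = np.concatenate(
        [[(stats.n_p * stats.ybar_p[0] + stats.n_a * stats.ybar_a[0]) / stats.n], stats.ybar_p[1:]]
    )
    g = reference_curve(alphas, t)
    delays = np.array(
        [
            np.clip(t[k] - _invert_reference(g, stats.ybar_a[k], t[k], t[-1]), -t[k], t[k])
            for k in range(1, v)
        ]
    )
    mu_a = np.concatenate(([alphas[0]], np.atleast_1d(g(t[1:] - delays))))
    return PMRMFit(
        visit_months=t,
        ref_means=alphas,
        delays=delays,
        delay_se=None,
        fitted_cov=scatter(stats, alphas, mu_a),
        loglik=None,
        converged=True,
        wald_p_final=None,
        n_subjects=stats.n,
    )


def delay_confidence_interval(
    fit: PMRMFit, visit: float, level: float = 0.95, scale: str = "months"
) -> tuple[float, float]:
    """Wald confidence interval for the delay at a post-baseline visit.

    ``scale="months"`` gives the interval on the time-shift scale;
    ``scale="percent"`` divides the endpoints by the visit time.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.delay_se is None:
        raise ValueError("standard errors unavailable for this fit")
    post = fit.visit_months[1:]
    matches = np.where(np.isclose(post, visit))[0]
    if matches.size == 0:
        raise ValueError(f"visit {visit} not on the post-baseline schedule {post}")
    k = int(matches[0])
    z = norm.ppf(0.5 + level / 2.0)
    lo = fit.delays[k] - z * fit.delay_se[k]
    hi = fit.delays[k] + z * fit.delay_se[k]
    if scale == "percent":
        return (lo / post[k], hi / post[k])
    if scale != "months":
        raise ValueError("scale must be 'months' or 'percent'")
    return (float(lo), float(hi))
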