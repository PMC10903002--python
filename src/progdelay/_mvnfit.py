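"""Shared multivariate-normal likelihood machinery.

Both longitudinal fits in this package (the time-based progression model
and the constrained longitudinal comparator) are Gaussian likelihoods over
a common visit grid with an unstructured covariance. The data enter only
through per-arm visit means and the pooled within-arm scatter, so all
estimation here works on those sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Relative threshold below which the total scatter matrix is treated as
# singular (noise-free data); estimation then falls back to least squares.
_SINGULAR_TOL = 1e-10


@dataclass
class ArmStats:
    """Sufficient statistics of a two-arm repeated-measures dataset."""

    ybar_p: np.ndarray  # placebo visit means, length V
    ybar_a: np.ndarray  # active visit means, length V
    within: np.ndarray  # pooled within-arm scatter / n, V x V
    n_p: int
    n_a: int

    @property
    def n(self) -> int:
        return self.n_p + self.n_a

    @property
    def n_visits(self) -> int:
        return self.ybar_p.size


def arm_stats(y_p: np.ndarray, y_a: np.ndarray) -> ArmStats:
    y_p = np.asarray(y_p, dtype=float)
    y_a = np.asarray(y_a, dtype=float)
    n_p, n_a = y_p.shape[0], y_a.shape[0]
    ybar_p = y_p.mean(axis=0)
    ybar_a = y_a.mean(axis=0)
    rp = y_p - ybar_p
    ra = y_a - ybar_a
    within = (rp.T @ rp + ra.T @ ra) / (n_p + n_a)
    return ArmStats(ybar_p, ybar_a, within, n_p, n_a)


def scatter(stats: ArmStats, mu_p: np.ndarray, mu_a: np.ndarray) -> np.ndarray:
    """Mean residual outer-product matrix S for given arm mean vectors.

    S is the ML covariance estimate when the means are fixed, and
    ``-n/2 log det S`` is (up to constants) the profile log-likelihood.
    """
    n = stats.n
    d_p = stats.ybar_p - mu_p
    d_a = stats.ybar_a - mu_a
    return (
        stats.within
        + (stats.n_p / n) * np.outer(d_p, d_p)
        + (stats.n_a / n) * np.outer(d_a, d_a)
    )


def mvn_loglik(stats: ArmStats, mu_p: np.ndarray, mu_a: np.ndarray, sigma: np.ndarray) -> float:
    """Exact multivariate-normal log-likelihood of the dataset."""
    v = stats.n_visits
    s = scatter(stats, mu_p, mu_a)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    tr = float(np.trace(np.linalg.solve(sigma, s)))
    return -0.5 * stats.n * (v * np.log(2.0 * np.pi) + logdet + tr)


def is_singular(stats: ArmStats) -> bool:
    """True when the total scatter cannot support a full-rank covariance."""
    s = scatter(stats, stats.ybar_p, stats.ybar_a)
    # include between-arm spread so a shared-mean misfit still counts as signal
    tot = s + np.outer(stats.ybar_p - stats.ybar_a, stats.ybar_p - stats.ybar_a)
    eig = np.linalg.eigvalsh(tot)
    return bool(eig.min() < _SINGULAR_TOL * max(1.0, eig.max()))


def _clda_design(v: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrices mapping beta = (alpha0, p_1..p_{V-1}, a_1..a_{V-1})
    to per-arm mean vectors under the shared-baseline constraint."""
    j = v - 1
    x_p = np.zeros((v, 1 + 2 * j))
    x_a = np.zeros((v, 1 + 2 * j))
    x_p[0, 0] = x_a[0, 0] = 1.0
    x_p[1:, 1 : 1 + j] = np.eye(j)
    x_a[1:, 1 + j :] = np.eye(j)
    return x_p, x_a


@dataclass
class CldaFit:
    """ML fit of the constrained longitudinal model (shared baseline mean,
    free arm-by-visit means post baseline, unstructured covariance)."""

    placebo_means: np.ndarray
    active_means: np.ndarray
    sigma: np.ndarray
    loglik: float | None
    cov_beta: np.ndarray | None  # covariance of (alpha0, p_j, a_j)
    converged: bool
    singular: bool
    n_iter: int

    def contrast_variance(self, c: np.ndarray) -> float | None:
        if self.cov_beta is None:
            return None
        return float(c @ self.cov_beta @ c)


def fit_clda(stats: ArmStats, tol: float = 1e-10, max_iter: int = 500) -> CldaFit:
    """Iterative GLS (flip-flop) maximum likelihood for the constrained model.

    Alternates the closed-form GLS mean update given the covariance with
    the closed-form ML covariance update given the means; each step is an
    exact conditional maximizer, so the log-likelihood is monotone.
    """
    v = stats.n_visits
    x_p, x_a = _clda_design(v)

    def gls_beta(sig_inv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = stats.n_p * x_p.T @ sig_inv @ x_p + stats.n_a * x_a.T @ sig_inv @ x_a
        b = stats.n_p * x_p.T @ sig_inv @ stats.ybar_p + stats.n_a * x_a.T @ sig_inv @ stats.ybar_a
        return np.linalg.solve(a, b), a

    # OLS start (Sigma = I)
    beta, _ = gls_beta(np.eye(v))
    if is_singular(stats):
        mu_p, mu_a = x_p @ beta, x_a @ beta
        return CldaFit(
            placebo_means=mu_p,
            active_means=mu_a,
            sigma=scatter(stats, mu_p, mu_a),
            loglik=None,
            cov_beta=None,
            converged=True,
            singular=True,
            n_iter=0,
        )

    ll_prev = -np.inf
    sigma = scatter(stats, x_p @ beta, x_a @ beta)
    converged = False
    it = 0
    a_mat = np.eye(beta.size)
    for it in range(1, max_iter + 1):
        sig_inv = np.linalg.inv(sigma)
        beta, a_mat = gls_beta(sig_inv)
        mu_p, mu_a = x_p @ beta, x_a @ beta
        sigma = scatter(stats, mu_p, mu_a)
        sign, logdet = np.linalg.slogdet(sigma)
        ll = -0.5 * stats.n * (v * np.log(2.0 * np.pi) + logdet + v)
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll

    sig_inv = np.linalg.inv(sigma)
    _, a_mat = gls_beta(sig_inv)
    return CldaFit(
        placebo_means=x_p @ beta,
        active_means=x_a @ beta,
        sigma=sigma,
        loglik=ll,
        cov_beta=np.linalg.inv(a_mat),
        converged=converged,
        singular=False,
        n_iter=it,
    )


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian with parameter-scaled steps."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        f_pp = f(x + ei)
        f_mm = f(x - ei)
        f0 = f(x)
        hess[i, i] = (f_pp - 2.0 * f0 + f_mm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess
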