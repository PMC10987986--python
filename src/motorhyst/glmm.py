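"""Random-intercept logistic regression by marginal maximum likelihood.

Fits  logit P(y=1) = x'beta + u_j,  u_j ~ Normal(0, sigma^2)  per group j,
integrating the random intercept out of the likelihood with adaptive
Gauss-Hermite quadrature: the integrand of each group's marginal
likelihood is re-centred at its mode (found by Newton's method) and
scaled by its curvature before applying the Hermite rule, which keeps a
modest number of nodes accurate even for large groups.  The marginal
log-likelihood is maximized over (beta, log sigma) and Wald covariance
is obtained from a finite-difference Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = ["GLMMResult", "fit_logistic_glmm", "marginal_loglik"]

_GH_NODES = 15


def _group_mode(eta0: np.ndarray, y: np.ndarray, sigma2: float) -> tuple[float, float]:
    """Newton mode of the per-group joint log-density over the intercept u."""
    u = 0.0
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(eta0 + u)))
        g = float(np.sum(y - p)) - u / sigma2
        h = -float(np.sum(p * (1.0 - p))) - 1.0 / sigma2
        step = g / h
        u_new = u - step
        if abs(u_new - u) < 1e-10:
            u = u_new
            break
        u = u_new
    p = 1.0 / (1.0 + np.exp(-(eta0 + u)))
    h = -float(np.sum(p * (1.0 - p))) - 1.0 / sigma2
    return u, h


def _group_loglik_agh(
    eta0: np.ndarray, y: np.ndarray, sigma: float, nodes: np.ndarray, weights: np.ndarray
) -> float:
    sigma2 = sigma * sigma
    u_star, h = _group_mode(eta0, y, sigma2)
    tau = 1.0 / np.sqrt(-h)
    u = u_star + np.sqrt(2.0) * tau * nodes  # (K,)
    eta = eta0[:, None] + u[None, :]  # (n, K)
    # Bernoulli log-lik: y*eta - log(1 + e^eta), computed stably
    ll = y[:, None] * eta - np.logaddexp(0.0, eta)
    log_prior = -0.5 * (u / sigma) ** 2 - 0.5 * np.log(2 * np.pi * sigma2)
    log_integrand = ll.sum(axis=0) + log_prior
    # int e^{h(u)} du  ~=  sqrt(2)*tau * sum_k w_k e^{x_k^2} e^{h(u_k)}
    log_terms = np.log(weights) + nodes**2 + log_integrand
    m = log_terms.max()
    return float(m + np.log(np.sum(np.exp(log_terms - m))) + 0.5 * np.log(2.0) + np.log(tau))


def marginal_loglik(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_slices: Sequence[tuple[int, int]],
    n_nodes: int = _GH_NODES,
    adaptive: bool = True,
) -> float:
    """Marginal log-likelihood at theta = (beta..., log sigma).

    With ``adaptive=False`` a plain (non-recentred) Hermite rule is used;
    that variant serves as an independent cross-check at high node
    counts.
    """
    beta = theta[:-1]
    sigma = float(np.exp(theta[-1]))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    eta_all = X @ beta
    total = 0.0
    for lo, hi in group_slices:
        eta0 = eta_all[lo:hi]
        yj = y[lo:hi]
        if adaptive:
            total += _group_loglik_agh(eta0, yj, sigma, nodes, weights)
        else:
            u = np.sqrt(2.0) * sigma * nodes
            eta = eta0[:, None] + u[None, :]
            ll = (yj[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
            log_terms = np.log(weights / np.sqrt(np.pi)) + ll
            m = log_terms.max()
            total += float(m + np.log(np.sum(np.exp(log_terms - m))))
    return total


@dataclass
class GLMMResult:
    """Fitted random-intercept logistic model."""

    beta: np.ndarray
    sigma: float
    cov_beta: np.ndarray  # Wald covariance of the fixed effects
    loglik: float
    column_names: list[str]
    converged: bool
    n_obs: int = 0
    n_groups: int = 0

    def coef(self, name: str) -> float:
        return float(self.beta[self.column_names.index(name)])

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Linear-combination estimate and its standard error."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        return est, se


def _group_slices(groups: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    bounds = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1], True])
    slices = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]
    return order, slices


def fit_logistic_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    column_names: Sequence[str] | None = None,
    n_nodes: int = _GH_NODES,
) -> GLMMResult:
    """Fit the random-intercept logistic model by adaptive quadrature.

    ``X`` must include an intercept column.  Non-convergence of the
    optimizer is reported on the result, never silently ignored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or len(X) != len(y) != len(groups):
        raise ValueError("X, y and groups must have matching lengths")
    names = list(column_names) if column_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    order, slices = _group_slices(groups)
    Xs, ys = X[order], y[order]

    # warm start from ordinary logistic regression
    from sklearn.linear_model import LogisticRegression

    k = X.shape[1]
    if y.min() != y.max():
        lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000, fit_intercept=False)
        lr.fit(Xs, ys)
        beta0 = lr.coef_.ravel()
    else:
        beta0 = np.zeros(k)
    theta0 = np.r_[beta0, np.log(0.5)]

    def neg(theta):
        return -marginal_loglik(theta, Xs, ys, slices, n_nodes=n_nodes)

    bounds = [(None, None)] * k + [(np.log(1e-4), np.log(50.0))]
    res = optimize.minimize(
        neg, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x

    # observed-information covariance by central finite differences
    h = np.maximum(1e-4, 1e-4 * np.abs(theta))
    n = len(theta)
    H = np.zeros((n, n))
    f0 = neg(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (neg(theta + ei) - 2 * f0 + neg(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    neg(theta + ei + ej) - neg(theta + ei - ej)
                    - neg(theta - ei + ej) + neg(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    cov_beta = cov_full[:k, :k]

    return GLMMResult(
        beta=theta[:k],
        sigma=float(np.exp(theta[-1])),
        cov_beta=cov_beta,
        loglik=float(-res.fun),
        column_names=names,
        converged=bool(res.success),
        n_obs=len(y),
        n_groups=len(slices),
    )
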