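"""Linear mixed models with a per-animal random intercept and optional
residual AR(1) / continuous-time AR(1) correlation, fitted by maximum
likelihood.

The marginal model for animal g with n_g observations is

    y_g = X_g beta + 1 b_g + e_g,   b_g ~ N(0, sb^2),  e_g ~ N(0, se^2 R_g)

where R_g is the identity, the discrete AR(1) matrix rho^|i-j| (order within
animal), or the continuous-time AR(1) matrix rho^|t_i - t_j| (irregular
spacing). beta and the overall residual scale are profiled out analytically;
the remaining one or two variance parameters (variance ratio, correlation)
are optimized numerically. ML (not REML) is used throughout so that
information-criterion comparisons across fixed-effect structures are valid.

Numerics: both AR(1) variants are Gauss-Markov along the ordering, so the
inverse of R_g is tridiagonal in closed form; combined with a rank-one
Woodbury update for the random-intercept term every likelihood evaluation is
O(n_g), which keeps large candidate sets and simulation studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

MAX_RHO = 0.999


@dataclass
class LMMFit:
    """ML fit of one mixed model."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    k: int                      # fixed effects + variance/correlation params
    sigma_b: float
    sigma_e: float
    rho: float | None
    converged: bool


def _neighbor_rho(correlation: str, n: int, times: np.ndarray | None,
                  rho: float) -> np.ndarray:
    """Correlation between successive observations (length n-1)."""
    if correlation == "none" or rho == 0.0 or n < 2:
        return np.zeros(max(n - 1, 0))
    if correlation == "ar1":
        return np.full(n - 1, rho)
    if correlation == "car1":
        if times is None:
            raise ValueError("car1 correlation needs observation times")
        dt = np.maximum(np.diff(times), 1e-8)
        return rho ** dt
    raise ValueError(f"unknown correlation structure: {correlation}")


def _rinv_apply(v: np.ndarray, d: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Multiply the tridiagonal R^-1 (diag d, off-diag e) onto v (1-D or 2-D)."""
    d_ = d[:, None] if v.ndim > 1 else d
    e_ = e[:, None] if v.ndim > 1 else e
    out = d_ * v
    if len(e):
        out[:-1] += e_ * v[1:]
        out[1:] += e_ * v[:-1]
    return out


def _rinv_coeffs(r: np.ndarray, n: int):
    """Closed-form tridiagonal inverse of the AR-type correlation matrix.

    For neighbor correlations r_i the inverse has off-diagonal
    -r_i/(1-r_i^2) and diagonal 1 + sum of r^2/(1-r^2) contributions from
    each adjacent link; log|R| = sum log(1-r_i^2).
    """
    if n == 1 or not len(r):
        return np.ones(n), np.zeros(0), 0.0
    s = r ** 2 / (1.0 - r ** 2)
    d = np.ones(n)
    d[:-1] += s
    d[1:] += s
    e = -r / (1.0 - r ** 2)
    logdet = float(np.sum(np.log(1.0 - r ** 2)))
    return d, e, logdet


def _group_stats(y, X, t, correlation, gamma2, rho):
    """(XtWX, XtWy, ytWy, log|W|) for W = gamma2 * J + R via Woodbury."""
    n = len(y)
    r = _neighbor_rho(correlation, n, t, rho)
    d, e, logdet_r = _rinv_coeffs(r, n)
    Ry = _rinv_apply(y, d, e)
    RX = _rinv_apply(X, d, e)
    u = _rinv_apply(np.ones(n), d, e)
    S = float(u.sum())
    c = gamma2 / (1.0 + gamma2 * S)
    uy = float(u @ y)
    uX = u @ X
    XtWX = X.T @ RX - c * np.outer(uX, uX)
    XtWy = X.T @ Ry - c * uX * uy
    ytWy = float(y @ Ry) - c * uy * uy
    logdet = logdet_r + np.log1p(gamma2 * S)
    return XtWX, XtWy, ytWy, logdet


def _profiled_neg_loglik(theta, y, X, starts, dt, correlation):
    """-log-likelihood profiled over beta and the residual scale.

    theta = (log gamma,) or (log gamma, logit rho) with
    gamma^2 = sb^2 / se^2. Operates on group-stacked arrays: ``starts`` are
    the row indices where each group begins and ``dt`` the neighbor time (or
    order) gaps, NaN across group boundaries — R^-1 is block tridiagonal, so
    one global tridiagonal apply covers all groups at once.

    Returns (nll, (beta, XtWX, se2, gamma2, rho)).
    """
    theta = np.clip(theta, -30.0, 30.0)
    gamma2 = np.exp(2.0 * theta[0])
    rho = (MAX_RHO / (1.0 + np.exp(-theta[1]))) if len(theta) > 1 else 0.0
    n = len(y)
    boundary = np.isnan(dt)
    if correlation == "none" or rho == 0.0:
        r = np.zeros(n - 1) if n > 1 else np.zeros(0)
    else:
        gaps = np.where(boundary, 1.0, dt)
        r = np.where(boundary, 0.0,
                     rho ** (gaps if correlation == "car1" else 1.0))
    d, e, logdet_r = _rinv_coeffs(r, n)
    Ry = _rinv_apply(y, d, e)
    RX = _rinv_apply(X, d, e)
    u = _rinv_apply(np.ones(n), d, e)
    S = np.add.reduceat(u, starts)
    uy = np.add.reduceat(u * y, starts)
    uX = np.add.reduceat(u[:, None] * X, starts, axis=0)
    c = gamma2 / (1.0 + gamma2 * S)
    XtWX = X.T @ RX - (uX * c[:, None]).T @ uX
    XtWy = X.T @ Ry - uX.T @ (c * uy)
    ytWy = float(y @ Ry) - float(np.sum(c * uy * uy))
    logdet = logdet_r + float(np.sum(np.log1p(gamma2 * S)))
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = max(ytWy - beta @ XtWy, 1e-12)
    se2 = rss / n
    nll = 0.5 * (n * np.log(2.0 * np.pi * se2) + n + logdet)
    return nll, (beta, XtWX, se2, gamma2, rho)


def fit_lmm(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
            times: np.ndarray | None = None,
            correlation: str = "none") -> LMMFit:
    """Fit the random-intercept mixed model by ML.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix (with intercept).
    groups : group (animal) label per observation.
    times : observation times per row, required for ``correlation="car1"``
        (rows must be time-sorted within each group).
    correlation : "none", "ar1" (order within group) or "car1" (by time).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    times = np.asarray(times, float)[order] if times is not None else None
    if correlation == "car1" and times is None:
        raise ValueError("car1 correlation needs observation times")

    n, p = X.shape
    new_group = np.concatenate([[True], groups[1:] != groups[:-1]])
    starts = np.nonzero(new_group)[0]
    if times is not None:
        dt = np.maximum(np.diff(times), 1e-8)
    else:
        dt = np.ones(max(n - 1, 0))
    dt = np.where(new_group[1:], np.nan, dt)   # NaN marks group boundaries
    n_var = 2 if correlation == "none" else 3   # sb, se (+ rho)
    theta0s = ([[np.log(0.5)], [np.log(0.05)], [np.log(2.0)]]
               if correlation == "none"
               else [[np.log(0.5), 0.0], [np.log(0.05), 1.5],
                     [np.log(2.0), -1.5]])
    # screen the starts on raw likelihood, polish only from the best one
    def nll_of(th):
        return _profiled_neg_loglik(th, y, X, starts, dt, correlation)[0]

    theta0 = min(theta0s, key=nll_of)
    best = minimize(nll_of, np.asarray(theta0), method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300})
    nll, packed = _profiled_neg_loglik(best.x, y, X, starts, dt, correlation)
    if packed is None:
        raise RuntimeError("mixed-model likelihood evaluation failed")
    beta, XtWX, se2, gamma2, rho = packed
    cov_beta = se2 * np.linalg.pinv(XtWX)
    # near-singular designs can leave tiny negative diagonals
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    return LMMFit(
        beta=beta, se=se, loglik=-nll,
        n=n, k=p + n_var,
        sigma_b=float(np.sqrt(se2 * gamma2)), sigma_e=float(np.sqrt(se2)),
        rho=float(rho) if correlation != "none" else None,
        converged=bool(best.success))


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in first-appearance order."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]
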