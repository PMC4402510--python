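"""Background correction and between-sample normalization of intensities.

Background correction uses the normal + exponential convolution model:
observed intensity X = B + S with B ~ N(mu, sigma^2) ambient noise and
S ~ Exp(mean alpha) true signal.  The corrected value is the posterior mean
E[S | X = x], which is strictly positive and monotone in x, so subsequent
log-transformation (with a moderate offset) never produces missing values.

Between-sample normalization offers quantile normalization (all columns
forced to the identical empirical distribution) and cyclic loess (pairwise
M-vs-A loess curves subtracted half from each column, cycled).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special, stats

from .datamodel import ExpressionMatrix, NormexpParams

__all__ = [
    "normexp_fit",
    "normexp_loglik",
    "normexp_correct",
    "quantile_normalize",
    "cyclic_loess_normalize",
    "log_with_offset",
    "weighted_loess",
]


def normexp_loglik(params: NormexpParams, x: np.ndarray) -> float:
    """Log-likelihood of intensities under the normal+exponential model.

    The convolution density has the closed form

        f(x) = (1/alpha) exp((mu - x)/alpha + sigma^2/(2 alpha^2))
               * Phi((x - mu)/sigma - sigma/alpha)

    evaluated in log space (log Phi via log_ndtr) for stability.
    """
    mu, sigma, alpha = params.mu, params.sigma, params.alpha
    z = (x - mu) / sigma - sigma / alpha
    ll = -np.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(z)
    return float(np.sum(ll))


def normexp_fit(x: np.ndarray, max_iter: int = 500) -> NormexpParams:
    """Maximum-likelihood fit of the normal+exponential convolution.

    Starts from method-of-moments (matching mean, variance and third
    central moment) and refines by Nelder–Mead on (mu, log sigma, log alpha).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        warnings.warn("normexp_fit: fewer than 50 finite values; estimates may be unstable")
    if np.ptp(x) == 0:
        raise ValueError("constant intensities: sigma is not identifiable")

    m1 = np.mean(x)
    v = np.var(x)
    m3 = np.mean((x - m1) ** 3)
    alpha0 = max((max(m3, 1e-12) / 2.0) ** (1.0 / 3.0), 1e-6 * np.sqrt(v))
    sigma0 = np.sqrt(max(v - alpha0**2, 0.01 * v))
    mu0 = m1 - alpha0

    def negll(theta):
        mu, lsig, lalp = theta
        sigma, alpha = np.exp(lsig), np.exp(lalp)
        z = (x - mu) / sigma - sigma / alpha
        ll = -np.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(z)
        return -np.sum(ll)

    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                            options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-8})
    if not res.success and res.status != 1:   # status 1 = maxiter reached
        raise RuntimeError(f"normexp_fit failed to converge: {res.message}; last iterate {res.x}")
    mu, sigma, alpha = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    return NormexpParams(mu=float(mu), sigma=sigma, alpha=alpha)


def normexp_correct(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Posterior-mean background correction E[signal | observed = x].

    Given X = B + S, the signal conditional on X = x is a normal
    distribution with mean a = x - mu - sigma^2/alpha and sd sigma truncated
    to (0, inf), whose mean a + sigma * phi(a/sigma)/Phi(a/sigma) is strictly
    positive and monotone non-decreasing in x.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, alpha = params.mu, params.sigma, params.alpha
    a = x - mu - sigma**2 / alpha
    z = a / sigma
    # phi(z)/Phi(z) computed in log space; stable for very negative z
    ratio = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    out = a + sigma * ratio
    return np.maximum(out, np.finfo(float).tiny)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to the identical empirical distribution.

    The value at rank r is replaced by the mean across columns of the
    rank-r values; tied values within a column receive the mean of their
    tied target values (deterministic and idempotent).
    """
    Y = m.values
    if np.isnan(Y).any():
        raise ValueError("quantile normalization does not accept missing values; "
                         "use cyclic loess instead")
    G, N = Y.shape
    if N == 1:
        return m.copy()
    sorted_cols = np.sort(Y, axis=0)
    target = sorted_cols.mean(axis=1)
    out = np.empty_like(Y)
    for j in range(N):
        col = Y[:, j]
        o = np.argsort(col, kind="mergesort")
        vals_sorted = col[o]
        assigned = target.copy()
        # average target over runs of tied values
        boundaries = np.flatnonzero(np.diff(vals_sorted) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [G]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = target[s:e].mean()
        out[o, j] = assigned
    res = m.copy()
    res.values = out
    return res


def weighted_loess(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                   span: float = 0.7, iterations: int = 3,
                   grid_size: int = 200) -> np.ndarray:
    """Local linear regression with tricube kernel and prior weights.

    The curve is evaluated at ``grid_size`` points spanning x and linearly
    interpolated back to the input positions.  ``iterations`` robustness
    passes downweight outliers with Tukey bisquare weights.  Points with
    prior weight 0 do not influence the curve but still receive fitted
    values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    w_prior = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    use = (w_prior > 0) & np.isfinite(x) & np.isfinite(y)
    xs, ys, ws = x[use], y[use], w_prior[use]
    if xs.size < 5:
        return np.full(n, np.nanmean(y))
    grid = np.linspace(xs.min(), xs.max(), min(grid_size, xs.size))
    k = max(int(np.ceil(span * xs.size)), 3)
    robust = np.ones(xs.size)
    fit_grid = np.empty(grid.size)
    for it in range(iterations + 1):
        for i, g in enumerate(grid):
            d = np.abs(xs - g)
            h = np.partition(d, k - 1)[k - 1]
            h = max(h, 1e-12)
            tric = np.clip(1 - (d / h) ** 3, 0, 1) ** 3
            wloc = tric * ws * robust
            sw = wloc.sum()
            if sw <= 0:
                fit_grid[i] = np.nan
                continue
            xm = (wloc * xs).sum() / sw
            ym = (wloc * ys).sum() / sw
            sxx = (wloc * (xs - xm) ** 2).sum()
            slope = (wloc * (xs - xm) * (ys - ym)).sum() / sxx if sxx > 1e-12 else 0.0
            fit_grid[i] = ym + slope * (g - xm)
        if it < iterations:
            resid = ys - np.interp(xs, grid, fit_grid)
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = np.clip(resid / (6.0 * s), -1, 1)
            robust = (1 - u**2) ** 2
    return np.interp(x, grid, fit_grid)


def cyclic_loess_normalize(m: ExpressionMatrix, span: float = 0.7,
                           iterations: int = 3) -> ExpressionMatrix:
    """Pairwise M-vs-A loess normalization, cycled over all column pairs.

    For every ordered pair (i, j), a loess curve of M = x_i - x_j on
    A = (x_i + x_j)/2 is subtracted half from column i and added half to
    column j; the full cycle is repeated ``iterations`` times.  Observation
    weights (if present) act as loess prior weights.
    """
    Y = m.values.copy()
    G, N = Y.shape
    if N < 2:
        return m.copy()
    W = m.obs_weights
    for _ in range(iterations):
        for i in range(N - 1):
            for j in range(i + 1, N):
                A = 0.5 * (Y[:, i] + Y[:, j])
                M = Y[:, i] - Y[:, j]
                finite = np.isfinite(A) & np.isfinite(M)
                w = None
                if W is not None:
                    w = np.where(finite, W[:, i] * W[:, j], 0.0)
                else:
                    w = finite.astype(float)
                curve = weighted_loess(np.where(finite, A, np.nanmean(A)),
                                       np.where(finite, M, 0.0),
                                       weights=w, span=span, iterations=1)
                Y[:, i] -= curve / 2.0
                Y[:, j] += curve / 2.0
    res = m.copy()
    res.values = Y
    return res


def log_with_offset(m: ExpressionMatrix, offset: float = 16.0) -> ExpressionMatrix:
    """log2(x + offset) transform of raw intensities.

    Already-log data (kind='log_intensity') passes through unchanged.  The
    offset keeps low intensities away from zero so the transform never
    produces -inf or NaN; offset + min(x) must be positive.
    """
    if m.kind == "log_intensity":
        return m.copy()
    Y = m.values
    if np.nanmin(Y) < 0:
        raise ValueError("negative intensities; background correction guarantees positivity")
    if np.nanmin(Y) + offset <= 0:
        raise ValueError("offset too small: log2 of a non-positive value")
    res = m.copy()
    res.values = np.log2(Y + offset)
    res.kind = "log_intensity"
    return res
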