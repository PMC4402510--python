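"""Gene-wise linear modelling.

Each gene's expression vector y_g (length N) is modelled as

    y_g = X beta_g + e_g,      Var(e_g) = sigma_g^2 * C_g

where X is the shared N x p design matrix and C_g is diagonal
(1 / weights) or, with a block structure, equicorrelated within blocks at a
consensus correlation rho shared by all genes.  Fitting is ordinary /
weighted / generalized least squares, vectorized across genes, with an
optional Huber-weighted robust variant.

The consensus correlation itself is estimated by per-gene REML profiled over
rho on a common grid, combined across genes by a trimmed mean on the
atanh (Fisher-z) scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BlockStructure, DesignSpec, ExpressionMatrix, LinearFit

__all__ = [
    "lm_fit",
    "contrasts_fit",
    "duplicate_correlation",
    "array_weights",
    "remove_batch_effect",
]

_HUBER_K = 1.345


def _block_cov(block: list[str], rho: float) -> np.ndarray:
    b = np.asarray(block)
    same = b[:, None] == b[None, :]
    V = np.where(same, rho, 0.0)
    np.fill_diagonal(V, 1.0)
    return V


def _fit_core(Y: np.ndarray, X: np.ndarray, W: np.ndarray | None,
              Vinv: np.ndarray | None):
    """Batched (weighted / generalized) least squares.

    Y: (G, N) with NaN allowed (treated as weight 0);
    W: (G, N) nonnegative weights or None; Vinv: (N, N) inverse correlation
    or None (identity).  Returns (beta, cov, sigma2, df, fitted) where cov is
    (G, p, p) unscaled coefficient covariance.
    """
    G, N = Y.shape
    p = X.shape[1]
    nan_mask = np.isnan(Y)
    Yz = np.where(nan_mask, 0.0, Y)

    if W is None:
        W = np.ones_like(Y)
    W = np.where(nan_mask, 0.0, W)
    n_obs = (W > 0).sum(axis=1)
    df = n_obs - p

    if Vinv is None:
        # normal equations with diagonal weights, batched
        A = np.einsum("gn,np,nq->gpq", W, X, X)
        b = np.einsum("gn,gn,np->gp", W, Yz, X)
    else:
        if nan_mask.any():
            # exact handling of missing data under correlation requires
            # per-gene subsetting of V; fall back to a per-gene loop
            return _fit_core_loop(Y, X, W, np.linalg.inv(Vinv))
        sw = np.sqrt(W)
        T = sw[:, :, None] * X[None, :, :]          # (G, N, p)
        A = np.einsum("gnp,nm,gmq->gpq", T, Vinv, T)
        b = np.einsum("gnp,nm,gm->gp", T, Vinv, sw * Yz)

    cov = np.linalg.inv(A)
    beta = np.einsum("gpq,gq->gp", cov, b)
    fitted = beta @ X.T                              # (G, N)
    resid = np.where(nan_mask, 0.0, Y - fitted)
    if Vinv is None:
        rss = np.einsum("gn,gn->g", W, resid**2)
    else:
        sw = np.sqrt(W)
        rw = sw * resid
        rss = np.einsum("gn,nm,gm->g", rw, Vinv, rw)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
    sigma2 = np.where(df > 0, sigma2, np.nan)
    return beta, cov, sigma2, df.astype(float), fitted


def _fit_core_loop(Y, X, W, V):
    """Per-gene GLS with missing observations dropped (V subset per gene)."""
    G, N = Y.shape
    p = X.shape[1]
    beta = np.full((G, p), np.nan)
    cov = np.full((G, p, p), np.nan)
    sigma2 = np.full(G, np.nan)
    df = np.zeros(G)
    fitted = np.full((G, N), np.nan)
    for g in range(G):
        keep = (~np.isnan(Y[g])) & (W[g] > 0)
        n = keep.sum()
        df[g] = n - p
        if n < p:
            continue
        Vs = V[np.ix_(keep, keep)] * np.outer(1 / np.sqrt(W[g, keep]), 1 / np.sqrt(W[g, keep]))
        L = np.linalg.cholesky(Vs)
        Xt = np.linalg.solve(L, X[keep])
        yt = np.linalg.solve(L, Y[g, keep])
        A = Xt.T @ Xt
        cov[g] = np.linalg.inv(A)
        beta[g] = cov[g] @ (Xt.T @ yt)
        r = yt - Xt @ beta[g]
        sigma2[g] = (r @ r) / (n - p) if n > p else np.nan
        fitted[g] = X @ beta[g]
    return beta, cov, sigma2, df, fitted


def lm_fit(m: ExpressionMatrix, design: DesignSpec,
           block: BlockStructure | None = None,
           robust: bool = False,
           weights: np.ndarray | None = None) -> LinearFit:
    """Fit a linear model to every gene.

    Weights are the elementwise product of the matrix's observation and
    sample weights (and ``weights`` if given).  Missing values are dropped
    per observation with the residual df reduced accordingly.  With a block
    structure, generalized least squares under equicorrelated within-block
    covariance at the supplied consensus correlation.  ``robust`` switches to
    iteratively reweighted least squares with Huber weights (k = 1.345);
    df_residual is left unchanged.
    """
    design.check_full_rank()
    X = design.design
    Y = m.values
    G, N = Y.shape
    p = X.shape[1]
    if X.shape[0] != N:
        raise ValueError(f"design has {X.shape[0]} rows but matrix has {N} samples")

    W = m.combined_weights()
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.ndim == 1:
            weights = np.broadcast_to(weights[None, :], Y.shape)
        W = weights if W is None else W * weights

    Vinv = None
    if block is not None:
        V = _block_cov(block.block, block.correlation)
        Vinv = np.linalg.inv(V)

    if robust:
        beta, cov, sigma2, df, fitted = _fit_robust(Y, X, W, Vinv)
    else:
        beta, cov, sigma2, df, fitted = _fit_core(Y, X, W, Vinv)

    stdev_unscaled = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        amean = np.nanmean(Y, axis=1)
    sigma = np.sqrt(sigma2)

    # collapse per-gene covariance to a single matrix when it is shared
    coef_cov: np.ndarray = cov
    if np.all(np.isfinite(cov)) and np.allclose(cov, cov[0][None, :, :], rtol=1e-10, atol=0):
        coef_cov = cov[0]

    return LinearFit(
        coefficients=beta,
        stdev_unscaled=stdev_unscaled,
        sigma=sigma,
        df_residual=df,
        amean=amean,
        coef_cov=coef_cov,
        col_names=list(design.coef_names),
        gene_ids=list(m.gene_ids),
    )


def _fit_robust(Y, X, W, Vinv, n_iter: int = 20):
    """Huber IRLS on top of any base weights; scale via MAD of residuals."""
    base_W = np.ones_like(Y) if W is None else W.copy()
    beta, cov, sigma2, df, fitted = _fit_core(Y, X, base_W, Vinv)
    Wr = base_W
    for _ in range(n_iter):
        resid = Y - fitted
        sw_resid = np.sqrt(base_W) * np.where(np.isnan(resid), 0.0, resid)
        mad = np.nanmedian(np.abs(sw_resid), axis=1) / 0.6745
        mad = np.where(mad <= 0, np.nanstd(sw_resid, axis=1) + 1e-12, mad)
        u = np.abs(sw_resid) / np.maximum(mad[:, None], 1e-300)
        hub = np.minimum(1.0, _HUBER_K / np.maximum(u, 1e-300))
        Wr = base_W * hub
        beta, cov, _, _, fitted = _fit_core(Y, X, Wr, Vinv)
    # robust residual scale: weighted RSS over df using the Huber weights
    resid = np.where(np.isnan(Y), 0.0, Y - fitted)
    rss = np.einsum("gn,gn->g", Wr, resid**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
    return beta, cov, sigma2, df, fitted


def contrasts_fit(fit: LinearFit, contrasts: np.ndarray,
                  names: list[str] | None = None) -> LinearFit:
    """Re-express a fit in terms of contrasts of the coefficients.

    coefficients -> coefficients @ C;  stdev_unscaled -> sqrt(diag(C' V C))
    per gene, where V is the gene's unscaled coefficient covariance.
    """
    C = np.asarray(contrasts, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    p = fit.n_coef
    if C.shape[0] != p:
        raise ValueError(f"contrast matrix has {C.shape[0]} rows, fit has {p} coefficients")
    if names is None:
        names = [f"C{i+1}" for i in range(C.shape[1])]

    coef = fit.coefficients @ C
    V = fit.coef_cov
    if V.ndim == 2:
        newV = C.T @ V @ C
        stdev = np.sqrt(np.maximum(np.diag(newV), 0.0))[None, :] * np.ones((fit.n_genes, 1))
        cov_out: np.ndarray = newV
    else:
        cov_out = np.einsum("pk,gpq,ql->gkl", C, V, C)
        stdev = np.sqrt(np.maximum(np.diagonal(cov_out, axis1=1, axis2=2), 0.0))

    return LinearFit(
        coefficients=coef,
        stdev_unscaled=stdev,
        sigma=fit.sigma.copy(),
        df_residual=fit.df_residual.copy(),
        amean=fit.amean.copy(),
        coef_cov=cov_out,
        col_names=list(names),
        gene_ids=list(fit.gene_ids),
    )


def duplicate_correlation(m: ExpressionMatrix, design: DesignSpec,
                          block: list[str],
                          trim: float = 0.15,
                          grid_size: int = 81) -> float:
    """Consensus intrablock correlation.

    For each gene, the REML log-likelihood of a random-intercept
    (equicorrelated-within-block) model is profiled over rho on a shared
    grid; the per-gene maximizers (quadratically refined, clamped to
    |rho| <= 0.99) are combined by a 15%-trimmed mean on the atanh scale and
    transformed back.
    """
    design.check_full_rank()
    X = design.design
    Y = m.values
    if np.isnan(Y).any():
        raise ValueError("duplicate_correlation does not support missing values")
    block = [str(b) for b in block]
    sizes = pd.Series(block).value_counts()
    if (sizes < 2).all():
        raise ValueError("all blocks are singletons; correlation is not estimable")
    if m.n_genes < 50:
        warnings.warn("fewer than 50 genes; consensus correlation may be unstable")

    kmax = int(sizes.max())
    rho_min = max(-0.95, -1.0 / (kmax - 1) + 0.02)
    grid = np.linspace(rho_min, 0.99, grid_size)

    G, N = Y.shape
    p = X.shape[1]
    ll = np.empty((grid_size, G))
    for i, rho in enumerate(grid):
        V = _block_cov(block, rho)
        L = np.linalg.cholesky(V)
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Xt = np.linalg.solve(L, X)
        Yt = np.linalg.solve(L, Y.T)          # (N, G)
        Q, R = np.linalg.qr(Xt)
        logdetXX = 2.0 * np.log(np.abs(np.diag(R))).sum()
        resid = Yt - Q @ (Q.T @ Yt)
        rss = np.einsum("ng,ng->g", resid, resid)
        ll[i] = -0.5 * (logdetV + logdetXX + (N - p) * np.log(np.maximum(rss, 1e-300)))

    best = np.argmax(ll, axis=0)
    rho_hat = grid[best]
    # quadratic refinement where the max is interior
    interior = (best > 0) & (best < grid_size - 1)
    b = best[interior]
    y0, y1, y2 = ll[b - 1, np.flatnonzero(interior)], ll[b, np.flatnonzero(interior)], ll[b + 1, np.flatnonzero(interior)]
    denom = y0 - 2 * y1 + y2
    step = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    h = grid[1] - grid[0]
    rho_hat[interior] = grid[b] + np.clip(step, -1, 1) * h
    rho_hat = np.clip(rho_hat, -0.99, 0.99)

    z = np.arctanh(rho_hat)
    return float(np.tanh(stats.trim_mean(z, proportiontocut=trim)))


def array_weights(m: ExpressionMatrix, design: DesignSpec,
                  prior_weights: np.ndarray | None = None,
                  max_iter: int = 50, tol: float = 1e-4) -> np.ndarray:
    """Relative sample (array) precision weights.

    Fits the heteroscedastic model Var(e_gj) = sigma_g^2 / w_j by iterating
    between gene-wise weighted least squares and a moment update of the
    per-sample log-variance factors (mean leverage-corrected standardized
    squared residual across genes).  ``prior_weights`` (G x N) are known
    observation-level weights multiplied into the fit.  Weights are
    normalized to geometric mean 1.
    """
    design.check_full_rank()
    X = design.design
    Y = m.values
    G, N = Y.shape
    p = X.shape[1]
    if N <= p + 1:
        raise ValueError("array weight estimation needs N > p + 1")
    if np.isnan(Y).any():
        raise ValueError("array_weights does not support missing values")
    if prior_weights is not None:
        prior_weights = np.asarray(prior_weights, dtype=float)
        if prior_weights.shape != Y.shape:
            raise ValueError("prior_weights must be G x N")

    w = np.ones(N)
    for _ in range(max_iter):
        if prior_weights is None:
            Wmat = np.broadcast_to(w[None, :], Y.shape)
        else:
            Wmat = prior_weights * w[None, :]
        beta, cov, sigma2, df, fitted = _fit_core(Y, X, Wmat, None)
        # hat-matrix diagonal h_gj = x_j' A_g^-1 x_j * W_gj
        if prior_weights is None:
            A_inv = cov[0]
            h = np.clip(np.einsum("np,pq,nq->n", X, A_inv, X) * w, 0.0, 0.99)[None, :]
        else:
            h = np.clip(np.einsum("np,gpq,nq->gn", X, cov, X) * Wmat, 0.0, 0.99)
        resid = Y - fitted
        ok = sigma2 > 0
        hh = h if h.shape[0] == G else np.broadcast_to(h, Y.shape)
        z = (Wmat[ok] * resid[ok] ** 2) / (sigma2[ok, None] * (1 - hh[ok]))
        v = z.mean(axis=0)                      # estimates w_j / w_j_true
        v = np.maximum(v, 1e-8)
        w_new = w / v
        w_new = w_new / np.exp(np.mean(np.log(w_new)))
        delta = np.max(np.abs(np.log(w_new) - np.log(w)))
        w = w_new
        if delta < tol:
            break
    else:
        warnings.warn("array_weights did not converge; returning last iterate")
    return w


def remove_batch_effect(m: ExpressionMatrix, batch: list[str],
                        design: DesignSpec | None = None) -> ExpressionMatrix:
    """Subtract fitted additive batch terms from the expression values.

    Batch levels are coded sum-to-zero so the corrected values stay centred
    on the grand mean; treatment terms in ``design`` are fitted jointly and
    retained.  Raises when batch is aliased with the design.
    """
    batch = [str(b) for b in batch]
    levels: list[str] = []
    for b in batch:
        if b not in levels:
            levels.append(b)
    if len(levels) == 1:
        return m.copy()
    N = m.n_samples
    if len(batch) != N:
        raise ValueError("batch length must equal the number of samples")
    # sum-to-zero coding: one column per non-last level
    B = np.zeros((N, len(levels) - 1))
    for i, b in enumerate(batch):
        j = levels.index(b)
        if j < len(levels) - 1:
            B[i, j] = 1.0
        else:
            B[i, :] = -1.0

    X0 = design.design if design is not None else np.ones((N, 1))
    full = np.hstack([X0, B])
    r_full = np.linalg.matrix_rank(full)
    if r_full < np.linalg.matrix_rank(X0) + np.linalg.matrix_rank(B):
        raise ValueError("batch is aliased (collinear) with the design; cannot separate effects")

    Y = m.values
    nan_mask = np.isnan(Y)
    if nan_mask.any():
        raise ValueError("remove_batch_effect does not support missing values")
    coef, *_ = np.linalg.lstsq(full, Y.T, rcond=None)
    batch_coef = coef[X0.shape[1]:, :]            # (len(levels)-1, G)
    corrected = Y - (B @ batch_coef).T
    out = m.copy()
    out.values = corrected
    return out
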