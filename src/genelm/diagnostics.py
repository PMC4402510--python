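"""Exploratory statistics: MDS on leading fold changes, mean-difference
values, and residual-sd vs abundance profiles.

These functions return the numeric data behind the classical diagnostic
plots; rendering is left to the caller (matplotlib works directly on the
returned arrays).
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import ExpressionMatrix, LinearFit
from .ebayes import _lowess_fit

__all__ = ["mds_leading_lfc", "mean_difference", "md_fit", "sa_profile"]

log = logging.getLogger(__name__)


def mds_leading_lfc(m: ExpressionMatrix, top: int = 500,
                    selection: str = "pairwise", dims: int = 2):
    """Multidimensional scaling of samples on leading log-fold-changes.

    The distance between two samples is the root-mean-square of the ``top``
    largest absolute log-differences between them ("leading fold change").
    selection='pairwise' picks the top genes anew for every pair;
    selection='common' picks one top set by overall variability.  Classical
    (Torgerson) MDS of the squared distances yields the coordinates; each
    returned axis has its first non-zero loading positive.

    Returns (coordinates (N, dims), distance matrix (N, N)).
    """
    Y = m.values
    G, N = Y.shape
    if N < 3:
        raise ValueError("MDS needs at least 3 samples")
    if top < 2:
        raise ValueError("top must be >= 2")
    top = min(top, G)

    if selection == "common":
        mean = Y.mean(axis=1, keepdims=True)
        var = ((Y - mean) ** 2).mean(axis=1)
        keep = np.argsort(-var, kind="mergesort")[:top]
        Ysub = Y[keep]
        D = np.zeros((N, N))
        for i in range(N - 1):
            diff = Ysub[:, i + 1:] - Ysub[:, [i]]
            D[i, i + 1:] = np.sqrt((diff**2).mean(axis=0))
        D = D + D.T
    elif selection == "pairwise":
        D = np.zeros((N, N))
        for i in range(N - 1):
            for j in range(i + 1, N):
                d2 = (Y[:, i] - Y[:, j]) ** 2
                lead = np.sort(d2)[-top:]
                D[i, j] = D[j, i] = np.sqrt(lead.mean())
    else:
        raise ValueError("selection must be 'pairwise' or 'common'")

    # classical MDS: double-centre the squared distances
    D2 = D**2
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(-eigval)
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((N, dims))
    for k in range(min(dims, N)):
        if eigval[k] > 0:
            v = eigvec[:, k] * np.sqrt(eigval[k])
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                v = -v
            coords[:, k] = v
    return coords, D


def mean_difference(m: ExpressionMatrix, column: int):
    """Mean-difference (MA) values of one sample against the virtual array.

    The virtual array is the row-wise mean of all *other* columns;
    A = (column + virtual)/2, M = column - virtual.
    """
    Y = m.values
    N = Y.shape[1]
    if N < 2:
        raise ValueError("mean-difference needs at least 2 samples")
    col = Y[:, column]
    others = np.delete(Y, column, axis=1)
    virtual = np.nanmean(others, axis=1)
    A = 0.5 * (col + virtual)
    M = col - virtual
    return A, M


def md_fit(fit: LinearFit, coef: str | int = 0):
    """Mean-difference values from a fitted model: (average log-expression,
    log-fold-change for the chosen coefficient)."""
    j = fit.col_index(coef)
    return fit.amean.copy(), fit.coefficients[:, j].copy()


def sa_profile(fit: LinearFit, span: float = 0.5):
    """Residual sd vs abundance profile (data behind a sigma-vs-A plot).

    Returns (A, sqrt(sigma), trend) where trend is the robust lowess of
    sqrt(sigma) on A — the same curve a trended variance prior would use.
    Rows with unavailable sigma are dropped (count logged).
    """
    ok = np.isfinite(fit.sigma) & np.isfinite(fit.amean)
    dropped = int((~ok).sum())
    if dropped:
        log.info("sa_profile: dropping %d genes with unavailable sigma", dropped)
    A = fit.amean[ok]
    s = np.sqrt(fit.sigma[ok])
    trend = _lowess_fit(A, s, span=span)
    return A, s, trend
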