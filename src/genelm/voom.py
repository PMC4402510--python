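"""RNA-seq counts: logCPM transformation, TMM scale normalization, and
mean-variance precision weights.

Counts are transformed to log2 counts-per-million with a small prior count.
Because the technical variance of logCPM decreases with count size, the
empirical sqrt-standard-deviation vs average-log-count trend of the
gene-wise linear model residuals is estimated by lowess and inverted into
per-observation precision weights (inverse fourth power of the predicted
sqrt-sd), which downstream weighted least squares consumes like any other
observation weights.
"""

from __future__ import annotations

import warnings

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .datamodel import DesignSpec, ExpressionMatrix, VoomResult
from .linmod import array_weights, lm_fit

__all__ = [
    "logcpm",
    "tmm_factors",
    "voom",
    "voom_with_quality_weights",
    "filter_by_expression",
]


def _lib_sizes(counts: ExpressionMatrix, lib_sizes=None, norm_factors=None) -> np.ndarray:
    if lib_sizes is None:
        lib = counts.values.sum(axis=0)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be strictly positive")
    return lib


def logcpm(counts: ExpressionMatrix, lib_sizes: np.ndarray | None = None,
           prior_count: float = 0.5, norm_factors: np.ndarray | None = None) -> ExpressionMatrix:
    """log2 counts per million: log2((count + prior) / (lib + 1) * 1e6)."""
    if counts.kind != "counts":
        raise ValueError("logcpm expects kind='counts'")
    lib = _lib_sizes(counts, lib_sizes, norm_factors)
    vals = np.log2((counts.values + prior_count) / (lib[None, :] + 1.0) * 1e6)
    out = counts.copy()
    out.values = vals
    out.kind = "logcpm"
    return out


def tmm_factors(counts: ExpressionMatrix, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scale normalization factors.

    Per sample, the factor is 2 to the precision-weighted doubly-trimmed
    mean of gene-wise M-values (log-ratio of library-normalized proportions)
    against a reference column (the one whose 75th CPM percentile is closest
    to the mean such percentile).  Factors are rescaled to geometric mean 1.
    """
    Y = counts.values
    G, N = Y.shape
    if N < 2:
        raise ValueError("TMM needs at least two samples")
    lib = Y.sum(axis=0)
    if (lib <= 0).any():
        j = int(np.argmin(lib))
        raise ValueError(f"sample {counts.sample_ids[j]!r} has zero total count")

    cpm = Y / lib[None, :] * 1e6
    f75 = np.quantile(cpm, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(N)
    xr, Nr = Y[:, ref], lib[ref]
    for j in range(N):
        if j == ref:
            continue
        x, Nj = Y[:, j], lib[j]
        keep = (x > 0) & (xr > 0)
        if keep.sum() < 2:
            continue
        pj, pr = x[keep] / Nj, xr[keep] / Nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        # asymptotic (delta-method) variance of M; precision weights
        v = (Nj - x[keep]) / (Nj * x[keep]) + (Nr - xr[keep]) / (Nr * xr[keep])
        n = M.size
        rM = np.argsort(np.argsort(M, kind="mergesort"), kind="mergesort") + 1
        rA = np.argsort(np.argsort(A, kind="mergesort"), kind="mergesort") + 1
        keep2 = (rM > n * logratio_trim) & (rM <= n * (1 - logratio_trim)) \
            & (rA > n * sum_trim) & (rA <= n * (1 - sum_trim))
        if not keep2.any():
            continue
        w = 1.0 / v[keep2]
        factors[j] = 2.0 ** (np.sum(w * M[keep2]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def voom(counts: ExpressionMatrix, design: DesignSpec,
         lib_sizes: np.ndarray | None = None,
         norm_factors: np.ndarray | None = None,
         span: float = 0.5,
         sample_weights: np.ndarray | None = None) -> VoomResult:
    """Mean-variance precision weights for logCPM values.

    1. transform counts to logCPM with effective library sizes;
    2. fit the gene-wise linear model, collect residual sd s_g and mean;
    3. lowess the sqrt residual sd on average log2 count;
    4. map each observation's fitted logCPM to a fitted log2 count,
       interpolate the trend (flat beyond its range) and set
       weight = predicted sqrt-sd to the power -4.
    """
    if counts.n_genes < 10:
        raise ValueError("too few genes to estimate the mean-variance trend (need >= 10)")
    lib = _lib_sizes(counts, lib_sizes, norm_factors)
    zero_rows = (counts.values.sum(axis=1) == 0)
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} genes have all-zero counts; "
                      "consider filtering before voom")
    y = logcpm(counts, lib_sizes=lib)
    if sample_weights is not None:
        y.sample_weights = np.asarray(sample_weights, dtype=float)

    fit = lm_fit(y, design)
    if np.nansum(fit.df_residual) < 2:
        raise ValueError("fewer than 2 residual degrees of freedom overall")

    sx = fit.amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(fit.sigma)
    ok = np.isfinite(sx) & np.isfinite(sy)
    curve = _sm_lowess(sy[ok], sx[ok], frac=span, it=3, return_sorted=True)
    cx, cy = curve[:, 0], curve[:, 1]
    cx, idx = np.unique(cx, return_index=True)
    cy = cy[idx]

    fitted_logcpm = fit.coefficients @ design.design.T
    fitted_logcount = fitted_logcpm + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, cx, cy)   # flat extrapolation
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    w = pred_sqrt_sd ** (-4.0)

    elist = y.copy()
    elist.obs_weights = w
    if sample_weights is not None:
        elist.sample_weights = np.asarray(sample_weights, dtype=float)
    return VoomResult(elist=elist, trend_x=sx, trend_y=sy, lib_sizes=lib,
                      sample_weights=None if sample_weights is None
                      else np.asarray(sample_weights, dtype=float))


def voom_with_quality_weights(counts: ExpressionMatrix, design: DesignSpec,
                              lib_sizes: np.ndarray | None = None,
                              norm_factors: np.ndarray | None = None,
                              span: float = 0.5) -> VoomResult:
    """voom combined with sample quality weights, estimated iteratively.

    Round 1: voom without sample weights, then array weights on the weighted
    logCPM.  Round 2: voom again using those sample weights, then re-estimate
    the array weights.  The returned elist carries obs_weights equal to the
    voom weight times the sample weight.
    """
    v = voom(counts, design, lib_sizes=lib_sizes, norm_factors=norm_factors, span=span)
    aw = array_weights(v.elist, design, prior_weights=v.elist.obs_weights)
    v = voom(counts, design, lib_sizes=lib_sizes, norm_factors=norm_factors,
             span=span, sample_weights=aw)
    aw = array_weights(v.elist, design, prior_weights=v.elist.obs_weights)
    # final voom layer under the final sample weights, so the returned
    # obs_weights are exactly (voom layer) x (sample layer)
    v = voom(counts, design, lib_sizes=lib_sizes, norm_factors=norm_factors,
             span=span, sample_weights=aw)
    elist = v.elist.copy()
    elist.obs_weights = v.elist.obs_weights * aw[None, :]
    elist.sample_weights = None
    return VoomResult(elist=elist, trend_x=v.trend_x, trend_y=v.trend_y,
                      lib_sizes=v.lib_sizes, sample_weights=aw)


def filter_by_expression(counts: ExpressionMatrix, design: DesignSpec | None = None,
                         min_cpm: float = 1.0, min_samples: int | None = None) -> np.ndarray:
    """Boolean mask of genes with CPM > min_cpm in enough samples.

    ``min_samples`` defaults to the smallest group size implied by a
    treatment-means design (columns of 0/1 indicators), else 1.
    """
    lib = counts.values.sum(axis=0)
    cpm = counts.values / np.maximum(lib, 1.0)[None, :] * 1e6
    if min_samples is None:
        if design is not None and np.isin(design.design, (0.0, 1.0)).all():
            sizes = design.design.sum(axis=0)
            min_samples = int(max(1, sizes.min()))
        else:
            min_samples = 1
    return (cpm > min_cpm).sum(axis=1) >= min_samples
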