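"""Empirical Bayes moderation of gene-wise variances and derived tests.

The gene-wise residual variances s2_g (on df_g degrees of freedom) are
modelled as draws from a scaled inverse-chi-square prior with hyper-
parameters (df_prior = d0, s2_prior = s0^2), estimated by moment matching on
z = log(s2) using digamma/trigamma identities.  The posterior variance

    s2_post_g = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)

replaces s2_g in the t-statistics, whose null distribution becomes Student-t
on d0 + df_g degrees of freedom.  A mean-variance trend replaces the scalar
s0^2 by a smooth function of average log-expression; the robust variant
estimates per-gene prior df so hyper-variable outlier genes are squeezed
less.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

from .datamodel import FDistPrior, LinearFit, TestResults

__all__ = [
    "trigamma_inverse",
    "fit_fdist",
    "squeeze_var",
    "moderated_stats",
    "treat",
    "p_adjust",
    "top_table",
    "decide_tests",
    "prop_true_null",
]


def trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing mapping; very large y maps to ~1/y, small y to
    ~1/sqrt(y) asymptotically.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif) / x) < 1e-10:
            break
    return x if x.size > 1 else x


_LOWESS_SPAN = 0.5


def _lowess_fit(x: np.ndarray, y: np.ndarray, span: float = _LOWESS_SPAN,
                iterations: int = 3) -> np.ndarray:
    """Robust lowess of y on x, returned at the original x positions."""
    out = _sm_lowess(y, x, frac=span, it=iterations, return_sorted=False)
    return np.asarray(out, dtype=float)


# variance of a standard normal winsorized at its (0.05, 0.95) quantiles,
# used to de-attenuate the winsorized moment estimate in the robust fit
def _winsor_var_factor(alpha: float) -> float:
    a = stats.norm.ppf(alpha)
    inner = (1 - 2 * alpha) - (-2 * a * stats.norm.pdf(a))
    return float(inner + 2 * alpha * a**2)


def fit_fdist(s2: np.ndarray, df: np.ndarray | float,
              covariate: np.ndarray | None = None) -> FDistPrior:
    """Moment estimation of the scaled-F prior for residual variances.

    Works on z = log(s2):

        E[z] = log(s0^2) + psi(d0/2) - log(d0/2) + psi(df/2) ... terms
        Var[z] - psi'(df/2) = psi'(d0/2)

    solved for d0 by Newton inversion of the trigamma function.  With a
    covariate, log(s0^2) follows the robust lowess fit of z on the covariate
    and the moments are taken on residuals (trended prior).  Genes with
    df <= 0 or non-finite s2 are excluded.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if not ok.any():
        raise ValueError("no genes with positive finite s2 and df > 0")
    z = np.log(s2[ok])
    dfo = df[ok]
    # E[log(s2)] = log(sigma2) + psi(df/2) - log(df/2); remove the df part
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)

    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)[ok]
        efit = _lowess_fit(cov, e)
        resid = e - efit
        emean_pergene = efit
        evar = float(np.var(resid, ddof=1))
    else:
        emean = float(np.mean(e))
        emean_pergene = None
        evar = float(np.var(e, ddof=1))

    evar -= float(np.mean(special.polygamma(1, dfo / 2.0)))
    if evar > 0:
        d0 = float(2.0 * trigamma_inverse(evar)[0])
        shift = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    else:
        d0 = np.inf
        shift = 0.0

    if covariate is not None:
        # per-gene prior at every input position (re-fit to cover excluded genes)
        covall = np.asarray(covariate, dtype=float)
        efit_all = np.interp(covall, *_sorted_xy(np.asarray(covariate, dtype=float)[ok], efit))
        s2_prior = np.exp(efit_all + shift)
        return FDistPrior(df_prior=d0, s2_prior=s2_prior, trended=True)
    if np.isinf(d0):
        # no excess variance: the prior is a point mass; its natural-scale
        # mean is the best estimate (exact for constant s2)
        s2_prior = float(np.mean(s2[ok]))
    else:
        s2_prior = float(np.exp(emean + shift))
    return FDistPrior(df_prior=d0, s2_prior=s2_prior)


def _sorted_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    o = np.argsort(x, kind="mergesort")
    xs, ys = x[o], y[o]
    # collapse duplicate x for np.interp
    xs_u, idx = np.unique(xs, return_index=True)
    return xs_u, ys[idx]


def fit_fdist_robust(s2: np.ndarray, df: np.ndarray | float,
                     covariate: np.ndarray | None = None,
                     winsor: tuple[float, float] = (0.05, 0.95)) -> FDistPrior:
    """Robust prior fit: winsorized moments plus per-gene prior df.

    z = log(s2) is winsorized at the given quantiles before moment matching
    (with a normal-based de-attenuation of the winsorized variance), so that
    hyper-variable genes do not inflate d0's denominator.  Genes whose
    variance is an upper-tail outlier under the fitted prior receive a
    reduced per-gene df_prior (down to ~0), so they are squeezed less.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)

    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)[ok]
        efit = _lowess_fit(cov, e)
        ecentred = e - efit
    else:
        efit = None
        ecentred = e - np.mean(e)

    lo, hi = np.quantile(ecentred, winsor)
    ewin = np.clip(ecentred, lo, hi)
    correction = 1.0 / _winsor_var_factor(winsor[0])
    evar = float(np.var(ewin, ddof=1)) * correction
    evar -= float(np.mean(special.polygamma(1, dfo / 2.0)))
    if evar > 0:
        d0 = float(2.0 * trigamma_inverse(evar)[0])
        shift = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    else:
        d0 = np.inf
        shift = 0.0

    if covariate is not None:
        base = efit + np.mean(ewin)
    else:
        base = np.full(ok.sum(), np.mean(e) + np.mean(ewin))
    s0_log = base + shift
    s2_prior_ok = np.exp(s0_log)

    # per-gene prior df: upper-tail outliers under s0^2 * F(df, d0) get a
    # smaller d0 so their large variances are not squeezed away
    G = int(ok.sum())
    if np.isfinite(d0):
        tail = stats.f.sf(s2[ok] / s2_prior_ok, dfo, d0)
    else:
        tail = stats.chi2.sf(dfo * s2[ok] / s2_prior_ok, dfo)
    prob_not_outlier = np.minimum(1.0, tail * G)   # Bonferroni-scaled tail prob
    d_floor = 0.01
    d0_gene = prob_not_outlier * min(d0, 1e12) + (1 - prob_not_outlier) * d_floor
    d0_full = np.full(s2.shape, min(d0, 1e12))
    d0_full[ok] = d0_gene

    if covariate is not None:
        covall = np.asarray(covariate, dtype=float)
        efit_all = np.interp(covall, *_sorted_xy(np.asarray(covariate, dtype=float)[ok], s0_log))
        return FDistPrior(df_prior=d0_full, s2_prior=np.exp(efit_all),
                          trended=True, robust=True)
    s2_prior_scalar = float(np.exp(np.mean(e) + np.mean(ewin) + shift))
    return FDistPrior(df_prior=d0_full, s2_prior=s2_prior_scalar, robust=True)


def squeeze_var(s2: np.ndarray, df: np.ndarray | float, prior: FDistPrior) -> np.ndarray:
    """Posterior (shrunken) variances: (d0*s0^2 + df*s2) / (d0 + df).

    d0 = +inf returns s0^2 for every gene; genes with df = 0 get s0^2.
    Per-gene d0/s0^2 vectors are broadcast elementwise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    d0 = np.broadcast_to(np.asarray(prior.df_prior, dtype=float), s2.shape)
    s0 = np.broadcast_to(np.asarray(prior.s2_prior, dtype=float), s2.shape)
    out = np.empty_like(s2)
    inf = np.isinf(d0)
    out[inf] = s0[inf]
    fin = ~inf
    s2f = np.where(np.isfinite(s2), s2, 0.0)
    denom = d0[fin] + df[fin]
    out[fin] = np.where(denom > 0,
                        (d0[fin] * s0[fin] + df[fin] * s2f[fin]) / np.maximum(denom, 1e-300),
                        s0[fin])
    return out


def _coef_correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _f_from_correlation(R: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, int]:
    """F = t' R^+ t / rank(R) for rows of t, via eigen-decomposition."""
    w, V = np.linalg.eigh(R)
    tol = w.max() * R.shape[0] * np.finfo(float).eps
    keep = w > tol
    rank = int(keep.sum())
    x = (t @ V[:, keep]) / np.sqrt(w[keep])[None, :]
    return np.sum(x**2, axis=1) / rank, rank


def _estimate_var_prior(t: np.ndarray, stdev_unscaled: np.ndarray,
                        df_total: np.ndarray, proportion: float) -> float:
    """Coefficient-variance prior v0 by quantile matching on the top genes.

    Among the top proportion/2 fraction of genes by |t|, each observed
    |t| is compared with the Student-t quantile it would have under the
    null given its rank; the excess is attributed to the coefficient prior
    variance v0 = u^2 * ((t/q)^2 - 1), averaged over those genes.
    """
    t = np.abs(np.asarray(t, dtype=float).ravel())
    u2 = np.asarray(stdev_unscaled, dtype=float).ravel() ** 2
    dft = np.asarray(df_total, dtype=float).ravel()
    ok = np.isfinite(t)
    t, u2, dft = t[ok], u2[ok], dft[ok]
    n = t.size
    ntarget = int(np.ceil(proportion / 2.0 * n))
    if ntarget < 1:
        return 0.0
    p_eff = max(ntarget / n, proportion)
    o = np.argsort(-t, kind="mergesort")[:ntarget]
    tt, uu, dd = t[o], u2[o], dft[o]
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, np.where(np.isfinite(dd), dd, 1e6))
    ptarget = ((r - 0.5) / n - (1.0 - p_eff) * p0) / p_eff
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        q = stats.t.isf(ptarget[pos] / 2.0, np.where(np.isfinite(dd[pos]), dd[pos], 1e6))
        v0[pos] = uu[pos] * np.maximum((tt[pos] / q) ** 2 - 1.0, 0.0)
    return float(np.mean(v0))


def moderated_stats(fit: LinearFit, trend: bool = False, robust: bool = False,
                    proportion: float = 0.01,
                    prior: FDistPrior | None = None) -> LinearFit:
    """Empirical Bayes moderated t, F and B (log-odds) statistics.

    Squeezes the residual variances towards the common (or trended) prior
    and computes per-coefficient moderated t-statistics with d0 + df_g
    degrees of freedom, an overall moderated F per gene (contrasts
    orthogonalized through the coefficient covariance), and the Bayesian
    log-odds of differential expression under a two-component model with
    prior DE probability ``proportion``.
    """
    if fit.sigma is None:
        raise ValueError("fit must carry sigma/df_residual")
    df = fit.df_residual
    if np.all(df <= 0):
        raise ValueError("all residual df are zero; variances are not estimable")
    s2 = fit.sigma**2
    covariate = fit.amean if trend else None
    if prior is None:
        if robust:
            prior = fit_fdist_robust(s2, df, covariate=covariate)
        else:
            prior = fit_fdist(s2, df, covariate=covariate)

    s2_post = squeeze_var(s2, df, prior)
    d0 = np.broadcast_to(np.asarray(prior.df_prior, dtype=float), s2.shape)
    df_total = df + d0

    se = fit.stdev_unscaled * np.sqrt(s2_post)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coefficients / se
    dft = np.where(np.isfinite(df_total), df_total, 1e12)
    p = 2.0 * stats.t.sf(np.abs(t), dft[:, None])

    # overall F across the k columns, orthogonalized per gene through the
    # coefficient correlation (rank-safe: redundant contrasts collapse)
    k = fit.n_coef
    if k == 1:
        F = t[:, 0] ** 2
        f_rank = 1
    else:
        V = fit.coef_cov
        if V.ndim == 2:
            Fi = _f_from_correlation(_coef_correlation(V), t)
            F, f_rank = Fi
        else:
            F = np.empty(fit.n_genes)
            f_rank = 1
            for g in range(fit.n_genes):
                Fg, f_rank = _f_from_correlation(_coef_correlation(V[g]), t[[g]])
                F[g] = float(Fg[0])
    F_p = stats.f.sf(F, f_rank, dft)

    # B statistic (log posterior odds of DE)
    v0 = _estimate_var_prior(t, fit.stdev_unscaled, df_total[:, None] * np.ones_like(t), proportion)
    u2 = fit.stdev_unscaled**2
    r = (u2 + v0) / u2
    t2 = t**2
    with np.errstate(over="ignore", invalid="ignore"):
        kernel = np.where(
            np.isfinite(df_total)[:, None],
            (1.0 + df_total[:, None]) / 2.0
            * np.log((t2 + df_total[:, None]) / (t2 / r + df_total[:, None])),
            t2 * (1.0 - 1.0 / r) / 2.0,
        )
    lods = np.log(proportion / (1.0 - proportion)) - 0.5 * np.log(r) + kernel

    out = LinearFit(
        coefficients=fit.coefficients.copy(),
        stdev_unscaled=fit.stdev_unscaled.copy(),
        sigma=fit.sigma.copy(),
        df_residual=fit.df_residual.copy(),
        amean=None if fit.amean is None else fit.amean.copy(),
        coef_cov=fit.coef_cov.copy(),
        col_names=list(fit.col_names),
        gene_ids=list(fit.gene_ids),
        df_prior=prior.df_prior,
        s2_prior=prior.s2_prior,
        s2_post=s2_post,
        df_total=df_total,
        t=t,
        p_value=p,
        lods=lods,
        F=F,
        F_p=F_p,
        var_prior_coef=v0,
        proportion=proportion,
    )
    return out


def treat(fit: LinearFit, lfc: float) -> LinearFit:
    """Test |logFC| > lfc rather than != 0 (moderated thresholded t-test).

    p = P(T > (|b| - lfc)/se) + P(T > (|b| + lfc)/se) on d0 + df_g df.
    lfc = 0 reproduces the ordinary moderated two-sided p-value.
    """
    if lfc < 0:
        raise ValueError("lfc threshold must be non-negative")
    if fit.s2_post is None:
        raise ValueError("apply moderated_stats before treat")
    se = fit.stdev_unscaled * np.sqrt(fit.s2_post)[:, None]
    acoef = np.abs(fit.coefficients)
    dft = np.where(np.isfinite(fit.df_total), fit.df_total, 1e12)[:, None]
    t_right = (acoef - lfc) / se
    t_left = (acoef + lfc) / se
    p = stats.t.sf(t_right, dft) + stats.t.sf(t_left, dft)
    out = LinearFit(**{**fit.__dict__})
    out.t = np.sign(fit.coefficients) * t_right
    out.p_value = p
    return out


_ADJUST = {"BH": "fdr_bh", "BY": "fdr_by", "holm": "holm",
           "bonferroni": "bonferroni", "none": None}


def p_adjust(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjusted p-values (BH, BY, holm, bonferroni)."""
    p = np.asarray(p, dtype=float)
    if method not in _ADJUST:
        raise ValueError(f"unknown adjustment {method!r}; choose from {list(_ADJUST)}")
    if np.isnan(p).any():
        out = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            out[ok] = p_adjust(p[ok], method)
        return out
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=_ADJUST[method])[1]


def top_table(fit: LinearFit, coef: str | int = 0, number: int = 10,
              adjust: str = "BH", sort_by: str = "p") -> pd.DataFrame:
    """Ranked table of results for one coefficient/contrast.

    Columns: logFC, AveExpr, t, P.Value, adj.P.Val, B.  adj.P.Val is
    computed across all genes before truncation to ``number``.
    """
    if fit.p_value is None:
        raise ValueError("apply moderated_stats before top_table")
    j = fit.col_index(coef)
    df = pd.DataFrame({
        "logFC": fit.coefficients[:, j],
        "AveExpr": fit.amean,
        "t": fit.t[:, j],
        "P.Value": fit.p_value[:, j],
        "adj.P.Val": p_adjust(fit.p_value[:, j], adjust),
        "B": fit.lods[:, j] if fit.lods is not None else np.nan,
    }, index=pd.Index(fit.gene_ids, name="id"))
    if sort_by == "p":
        order = np.lexsort((-np.abs(df["t"].to_numpy()), df["P.Value"].to_numpy()))
    elif sort_by == "logFC":
        order = np.argsort(-np.abs(df["logFC"].to_numpy()), kind="mergesort")
    elif sort_by == "B":
        order = np.argsort(-df["B"].to_numpy(), kind="mergesort")
    elif sort_by == "none":
        order = np.arange(len(df))
    else:
        raise ValueError("sort_by must be one of 'p', 'logFC', 'B', 'none'")
    df = df.iloc[order]
    return df.head(number) if number is not None else df


def decide_tests(fit: LinearFit, method: str = "separate", adjust: str = "BH",
                 p_threshold: float = 0.05, lfc: float = 0.0) -> TestResults:
    """Classify each gene x contrast as -1/0/+1.

    method='separate' adjusts each contrast's p-values independently;
    method='global' adjusts the pooled vector of all G x c p-values then
    reshapes, giving error-rate control across contrasts and genes jointly.
    """
    if fit.p_value is None:
        raise ValueError("apply moderated_stats before decide_tests")
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    P = fit.p_value
    if method == "separate":
        adj = np.column_stack([p_adjust(P[:, j], adjust) for j in range(P.shape[1])])
    elif method == "global":
        adj = p_adjust(P.ravel(), adjust).reshape(P.shape)
    else:
        raise ValueError("method must be 'separate' or 'global'")
    sig = adj <= p_threshold
    if lfc > 0:
        sig &= np.abs(fit.coefficients) >= lfc
    codes = np.where(sig, np.sign(fit.t).astype(int), 0)
    return TestResults(codes=codes, gene_ids=list(fit.gene_ids),
                       col_names=list(fit.col_names), method=method,
                       adjust_method=adjust, p_threshold=p_threshold,
                       lfc_threshold=lfc)


# ---------------------------------------------------------------------------
# proportion of true null hypotheses


def _convex_mixture_density(p: np.ndarray, n_theta: int = 100,
                            n_iter: int = 200):
    """ML fit of a convex decreasing density on [0,1] as a mixture of the
    uniform density and triangular densities f_theta(x) = 2(theta-x)+/theta^2,
    by EM over the mixture weights.  Returns (weights, density_at(p))."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0)
    thetas = np.linspace(1.0 / n_theta, 1.0, n_theta)
    # component density matrix: n x (n_theta + 1); last column = uniform
    D = np.maximum(thetas[None, :] - p[:, None], 0.0) * 2.0 / thetas[None, :] ** 2
    D = np.column_stack([D, np.ones_like(p)])
    w = np.full(D.shape[1], 1.0 / D.shape[1])
    for _ in range(n_iter):
        mix = D @ w
        mix = np.maximum(mix, 1e-300)
        resp = D * (w[None, :] / mix[:, None])
        w_new = resp.mean(axis=0)
        if np.max(np.abs(w_new - w)) < 1e-8:
            w = w_new
            break
        w = w_new
    dens = D @ w
    return w, dens


def prop_true_null(p: np.ndarray, method: str = "lfdr") -> float:
    """Estimate the proportion pi0 of true null hypotheses from p-values.

    Methods: 'mean' = min(1, 2*mean(p)); 'hist' = iterative histogram-based
    estimate; 'convest' = f(1) of the ML convex decreasing density fit;
    'lfdr' = average of local-false-discovery-rate upper bounds min(1, 1/f(p)).
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 20:
        warnings.warn("fewer than 20 p-values; pi0 estimate may be unstable")
    if method == "mean":
        return float(min(1.0, 2.0 * np.mean(p)))
    if method == "hist":
        nbins = 20
        counts, _ = np.histogram(p, bins=np.linspace(0, 1, nbins + 1))
        i = 0
        while i < nbins - 1:
            m = counts[i:].mean()
            if counts[i] > m:
                i += 1
            else:
                break
        pi0 = counts[i:].mean() * nbins / p.size
        return float(min(1.0, max(0.0, pi0)))
    if method == "convest":
        w, _ = _convex_mixture_density(p)
        return float(min(1.0, max(0.0, w[-1])))   # density at 1 = uniform weight
    if method == "lfdr":
        _, dens = _convex_mixture_density(p)
        lfdr = np.minimum(1.0, 1.0 / np.maximum(dens, 1e-300))
        return float(min(1.0, max(0.0, np.mean(lfdr))))
    raise ValueError("method must be one of 'lfdr', 'mean', 'hist', 'convest'")
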