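"""Gene set inference.

Three families of tests are provided:

* rank tests (:func:`gene_set_test`) — Wilcoxon rank-sum of the set's
  gene-wise statistics against the rest; fast, but assumes the genes are
  independent, so p-values are optimistic when set genes are correlated;
* competitive tests with correlation adjustment (:func:`camera`) — the mean
  inter-gene correlation of the set is estimated from the residual space of
  the linear model and converted into a variance inflation factor
  VIF = 1 + (m-1)*rho applied to the set-level two-sample test;
* rotation tests (:func:`roast`, :func:`mroast`, :func:`romer`) — Monte
  Carlo tests drawing random directions uniformly on the sphere of the
  (residual + contrast) space of the linear model; a "smoothed permutation"
  that remains exact for small, complex designs.  roast is self-contained,
  romer is a competitive (enrichment-style) rotation test.

Overlap enrichment for a fixed DE list uses the hypergeometric distribution,
and :func:`barcode_profile` returns the numeric data behind a barcode
enrichment plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DesignSpec, ExpressionMatrix, GeneSetCollection
from .ebayes import fit_fdist, p_adjust, squeeze_var

__all__ = [
    "gene_set_test",
    "camera",
    "roast",
    "mroast",
    "romer",
    "enrich_overlap",
    "barcode_profile",
]


def gene_set_test(statistics: np.ndarray, index: np.ndarray,
                  alternative: str = "mixed") -> float:
    """Wilcoxon rank-sum test of set statistics versus all other genes.

    ``alternative``: 'up' (set statistics larger), 'down' (smaller) or
    'mixed' (|statistics| larger).  Exact null distribution when the smaller
    group has <= 10 members and there are no ties; otherwise the normal
    approximation with continuity correction.
    """
    s = np.asarray(statistics, dtype=float)
    idx = np.asarray(index)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    G = s.size
    m = idx.size
    if m < 1:
        raise ValueError("empty gene set")
    if m >= G:
        raise ValueError("gene set contains every gene; the rank test is undefined")
    if alternative == "mixed":
        s = np.abs(s)
        alt = "greater"
    elif alternative == "up":
        alt = "greater"
    elif alternative == "down":
        alt = "less"
    else:
        raise ValueError("alternative must be 'up', 'down' or 'mixed'")
    in_set = np.zeros(G, dtype=bool)
    in_set[idx] = True
    x, y = s[in_set], s[~in_set]
    no_ties = np.unique(s).size == G
    method = "exact" if (min(x.size, y.size) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.pvalue)


def _residual_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the residual space of the design (N x (N-p))."""
    N, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    return Q[:, p:]


def _contrast_direction(X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Unit vector a/|a| with a = X (X'X)^-1 c, so that a'y estimates c'beta
    (scaled); orthogonal to the residual space."""
    XtX = X.T @ X
    a = X @ np.linalg.solve(XtX, contrast)
    nrm = np.linalg.norm(a)
    if nrm <= 0:
        raise ValueError("contrast is zero within the design")
    return a / nrm


def _resolve_contrast(design: DesignSpec, contrast) -> np.ndarray:
    if isinstance(contrast, (str,)):
        j = design.coef_names.index(contrast)
        c = np.zeros(design.n_coef)
        c[j] = 1.0
        return c
    c = np.asarray(contrast, dtype=float).ravel()
    if c.size == design.n_coef:
        return c
    raise ValueError("contrast must be a coefficient name or a length-p vector")


def _zscores_from_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Normal-quantile equivalents of t statistics (sign preserved)."""
    dff = np.where(np.isfinite(df), df, 1e12)
    p = stats.t.sf(np.abs(t), dff)
    p = np.clip(p, 1e-300, 0.5)
    return np.sign(t) * stats.norm.isf(p)


def camera(m: ExpressionMatrix, sets: GeneSetCollection, design: DesignSpec,
           contrast, fixed_cor: float | None = None,
           use_ranks: bool = False) -> pd.DataFrame:
    """Competitive gene set test with inter-gene correlation adjustment.

    Gene-wise moderated t statistics are converted to normal-score
    equivalents; for each set, the mean inter-gene correlation rho (floored
    at 0) is estimated from unit-normalized residual effects unless
    ``fixed_cor`` is given; the set-vs-rest two-sample t-test then inflates
    the set variance by VIF = 1 + (m-1)rho.  BH adjustment across sets.
    """
    from .linmod import contrasts_fit, lm_fit

    design.check_full_rank()
    c = _resolve_contrast(design, contrast)
    X = design.design
    G, N = m.shape
    d = N - X.shape[1]
    if d < 1:
        raise ValueError("camera needs at least 1 residual degree of freedom")

    fit = contrasts_fit(lm_fit(m, design), c[:, None], names=["contrast"]).ebayes()
    z = _zscores_from_t(fit.t[:, 0], fit.df_total)

    Q2 = _residual_basis(X)
    U = m.values @ Q2                                      # (G, d) residual effects
    norms = np.linalg.norm(U, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    U = U / norms[:, None]

    indices = sets.indices(m.gene_ids)
    mean_all = z.mean()
    var_all = z.var(ddof=1)
    # estimated correlations are noisy at d residual df: the reference
    # distribution keeps the residual df rather than ~G
    df_cam = (G - 2) if fixed_cor is not None else min(d, G - 2)
    rows = []
    for name in sets.names():
        idx = indices[name]
        mset = idx.size
        if mset == 0:
            continue
        note = ""
        if fixed_cor is not None:
            rho = float(fixed_cor)
            vif = 1.0 + (mset - 1) * rho
        elif mset < 2:
            rho, vif, note = 0.0, 1.0, "singleton set: VIF forced to 1"
        else:
            ssum = U[idx].sum(axis=0)
            rho = (ssum @ ssum - mset) / (mset * (mset - 1))
            rho = max(rho, 0.0)                            # avoid anti-conservative VIF < 1
            vif = 1.0 + (mset - 1) * rho
        m2 = G - mset
        mean_set = z[idx].mean()
        delta = G / m2 * (mean_set - mean_all)
        var_pooled = ((G - 1) * var_all - delta**2 * mset * m2 / G) / (G - 2)
        var_pooled = max(var_pooled, 1e-300)
        tstat = delta / np.sqrt(var_pooled * (vif / mset + 1.0 / m2))
        p_down = stats.t.cdf(tstat, df_cam)
        p_up = stats.t.sf(tstat, df_cam)
        two = 2.0 * min(p_down, p_up)
        rows.append({
            "set": name, "n_genes": mset, "correlation": rho, "vif": vif,
            "direction": "up" if tstat > 0 else "down",
            "statistic": tstat, "p_value": two, "note": note,
        })
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = p_adjust(out["p_value"].to_numpy(), "BH")
    return out.sort_values("p_value", kind="mergesort")


# ---------------------------------------------------------------------------
# rotation tests


def _rotation_scores(m: ExpressionMatrix, design: DesignSpec, contrast):
    """Project data onto (contrast direction + residual basis).

    Returns Z (G, d+1) whose first column estimates the contrast (up to a
    positive scale) and remaining d columns span the residual space, plus d.
    Under the gene-wise null all d+1 coordinates are iid N(0, sigma_g^2), so
    a uniformly random rotation of the first coordinate leaves the
    distribution invariant.
    """
    design.check_full_rank()
    X = design.design
    c = _resolve_contrast(design, contrast)
    d = X.shape[0] - X.shape[1]
    if d < 1:
        raise ValueError("rotation tests need at least 1 residual degree of freedom")
    w1 = _contrast_direction(X, c)
    Q2 = _residual_basis(X)
    B = np.column_stack([w1, Q2])                        # (N, d+1)
    Z = m.values @ B
    return Z, d


def _rotation_matrix(rng: np.random.Generator, nrot: int, dim: int) -> np.ndarray:
    R = rng.standard_normal((nrot, dim))
    return R / np.linalg.norm(R, axis=1, keepdims=True)


def _moderated_rotation_t(Z: np.ndarray, d: int, prior, z1: np.ndarray) -> np.ndarray:
    """Moderated t-like scores given first-coordinate values z1 (any shape
    broadcastable against Z's genes)."""
    total = np.einsum("gk,gk->g", Z, Z)
    s2 = (total[..., None] - z1**2 if z1.ndim > 1 else total - z1**2) / d
    s2 = np.maximum(s2, 0.0)
    s2_post = squeeze_var(s2, float(d), prior)
    return z1 / np.sqrt(np.maximum(s2_post, 1e-300))


def _set_stat(scores: np.ndarray, how: str, direction: str) -> np.ndarray:
    """Summaries along axis 0 (genes); scores may be 1-D or (m, nrot)."""
    s = scores if direction == "up" else -scores
    if how == "mean":
        return s.mean(axis=0)
    if how == "floormean":
        return np.maximum(s, 0.0).mean(axis=0)
    if how == "mean50":
        k = int(np.ceil(s.shape[0] / 2))
        return np.sort(s, axis=0)[-k:].mean(axis=0)
    if how == "msq":
        return (s**2).mean(axis=0)
    raise ValueError("set_stat must be one of 'mean', 'floormean', 'mean50', 'msq'")


def roast(m: ExpressionMatrix, set_index, design: DesignSpec, contrast,
          nrot: int = 999, set_stat: str = "mean",
          directions: np.ndarray | None = None,
          gene_weights: np.ndarray | None = None,
          seed: int | np.random.Generator = 0) -> dict:
    """Self-contained rotation test for one gene set.

    Gene-wise moderated t-like scores (residual variances squeezed with the
    empirical Bayes prior estimated from all genes) are summarized over the
    set, and the summary is recalibrated under ``nrot`` random rotations of
    the contrast direction within the (d+1)-dimensional score space.
    p = (b+1)/(nrot+1) where b counts rotations at least as extreme, so
    p-values take only the values k/(nrot+1).  Optional per-gene directions
    (±1) and weights multiply the scores before summarizing.
    """
    if nrot < 1:
        raise ValueError("nrot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z, d = _rotation_scores(m, design, contrast)
    idx = np.asarray(set_index)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty gene set")

    s2_all = np.maximum((np.einsum("gk,gk->g", Z, Z) - Z[:, 0] ** 2) / d, 0.0)
    prior = fit_fdist(s2_all[s2_all > 0], float(d))

    R = _rotation_matrix(rng, nrot, d + 1)
    return _roast_one(Z[idx], d, prior, R, set_stat, directions, gene_weights, nrot)


def _roast_one(Zs, d, prior, R, set_stat, directions, gene_weights, nrot) -> dict:
    mult = np.ones(Zs.shape[0])
    if directions is not None:
        mult = mult * np.asarray(directions, dtype=float)
    if gene_weights is not None:
        mult = mult * np.asarray(gene_weights, dtype=float)

    t_obs = _moderated_rotation_t(Zs, d, prior, Zs[:, 0]) * mult
    z1_rot = Zs @ R.T                                    # (m, nrot)
    t_rot = _moderated_rotation_t(Zs, d, prior, z1_rot) * mult[:, None]

    out = {"n_genes": int(Zs.shape[0])}
    for direction in ("up", "down"):
        obs = _set_stat(t_obs, set_stat, direction)
        rot = _set_stat(t_rot, set_stat, direction)
        b = int((rot >= obs).sum())
        out[f"p_{direction}"] = (b + 1) / (nrot + 1)
        out[f"stat_{direction}"] = float(obs)
    obs = _set_stat(t_obs, "msq", "up")
    rot = _set_stat(t_rot, "msq", "up")
    out["p_mixed"] = (int((rot >= obs).sum()) + 1) / (nrot + 1)
    out["stat_mixed"] = float(obs)
    out["direction"] = "up" if out["p_up"] <= out["p_down"] else "down"
    return out


def mroast(m: ExpressionMatrix, sets: GeneSetCollection, design: DesignSpec,
           contrast, nrot: int = 999, set_stat: str = "mean",
           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """roast for a battery of sets sharing one rotation stream; BH across sets."""
    if nrot < 1:
        raise ValueError("nrot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z, d = _rotation_scores(m, design, contrast)
    s2_all = np.maximum((np.einsum("gk,gk->g", Z, Z) - Z[:, 0] ** 2) / d, 0.0)
    prior = fit_fdist(s2_all[s2_all > 0], float(d))
    R = _rotation_matrix(rng, nrot, d + 1)

    indices = sets.indices(m.gene_ids)
    rows = []
    for name in sets.names():
        idx = indices[name]
        if idx.size == 0:
            continue
        dirs = wts = None
        if name in sets.directions or name in sets.gene_weights:
            members = [g for g in sets.sets[name] if g in set(m.gene_ids)]
            dmap = sets.directions.get(name, {})
            wmap = sets.gene_weights.get(name, {})
            by_row = {m.gene_ids[i]: k for k, i in enumerate(idx)}
            dirs = np.ones(idx.size)
            wts = np.ones(idx.size)
            for g in members:
                k = by_row.get(g)
                if k is None:
                    continue
                dirs[k] = dmap.get(g, 1)
                wts[k] = wmap.get(g, 1.0)
        res = _roast_one(Z[idx], d, prior, R, set_stat, dirs, wts, nrot)
        res["set"] = name
        rows.append(res)
    out = pd.DataFrame(rows).set_index("set")
    for col in ("p_up", "p_down", "p_mixed"):
        out["adj_" + col] = p_adjust(out[col].to_numpy(), "BH")
    return out


def romer(m: ExpressionMatrix, sets: GeneSetCollection, design: DesignSpec,
          contrast, nrot: int = 9999,
          seed: int | np.random.Generator = 0,
          block_size: int = 500) -> pd.DataFrame:
    """Competitive rotation enrichment test (GSEA-style, rotation-based).

    For each rotation the moderated t-like scores of *all* genes are
    recomputed and ranked; the set statistic is the mean rank of member
    genes.  Tail probabilities with the plus-one correction give p_up,
    p_down and p_mixed (mean rank of |t|); BH adjustment across sets.
    """
    if nrot < 1:
        raise ValueError("nrot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z, d = _rotation_scores(m, design, contrast)
    G = Z.shape[0]
    indices = sets.indices(m.gene_ids)
    names = [n for n in sets.names() if indices[n].size > 0]
    for n in names:
        if indices[n].size >= G:
            raise ValueError(f"set {n!r} contains every gene")

    s2_all = np.maximum((np.einsum("gk,gk->g", Z, Z) - Z[:, 0] ** 2) / d, 0.0)
    prior = fit_fdist(s2_all[s2_all > 0], float(d))

    t_obs = _moderated_rotation_t(Z, d, prior, Z[:, 0])
    r_obs = stats.rankdata(t_obs)
    r_obs_abs = stats.rankdata(np.abs(t_obs))
    obs_mean = {n: r_obs[indices[n]].mean() for n in names}
    obs_mean_abs = {n: r_obs_abs[indices[n]].mean() for n in names}

    ge_up = {n: 0 for n in names}
    ge_down = {n: 0 for n in names}
    ge_mixed = {n: 0 for n in names}
    done = 0
    while done < nrot:
        nb = min(block_size, nrot - done)
        R = _rotation_matrix(rng, nb, d + 1)
        t_rot = _moderated_rotation_t(Z, d, prior, Z @ R.T)     # (G, nb)
        ranks = np.empty_like(t_rot)
        order = np.argsort(t_rot, axis=0, kind="mergesort")
        ranks[order, np.arange(nb)[None, :]] = np.arange(1, G + 1)[:, None]
        ranks_abs = np.empty_like(t_rot)
        order = np.argsort(np.abs(t_rot), axis=0, kind="mergesort")
        ranks_abs[order, np.arange(nb)[None, :]] = np.arange(1, G + 1)[:, None]
        for n in names:
            idx = indices[n]
            mr = ranks[idx].mean(axis=0)
            ge_up[n] += int((mr >= obs_mean[n]).sum())
            ge_down[n] += int((mr <= obs_mean[n]).sum())
            mra = ranks_abs[idx].mean(axis=0)
            ge_mixed[n] += int((mra >= obs_mean_abs[n]).sum())
        done += nb

    rows = []
    for n in names:
        rows.append({
            "set": n, "n_genes": int(indices[n].size),
            "mean_rank": obs_mean[n],
            "p_up": (ge_up[n] + 1) / (nrot + 1),
            "p_down": (ge_down[n] + 1) / (nrot + 1),
            "p_mixed": (ge_mixed[n] + 1) / (nrot + 1),
        })
    out = pd.DataFrame(rows).set_index("set")
    for col in ("p_up", "p_down", "p_mixed"):
        out["adj_" + col] = p_adjust(out[col].to_numpy(), "BH")
    return out


def enrich_overlap(de_genes, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric overlap enrichment for a fixed DE list.

    Sets are intersected with the universe; p is the upper-tail probability
    of an overlap at least as large as observed.  BH adjustment across sets.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    de = set(map(str, de_genes))
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    Nu = len(universe)
    nde = len(de)
    rows = []
    for name, members in sets.sets.items():
        setg = set(members) & universe
        k = len(setg & de)
        K = len(setg)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, Nu, nde, K))
        rows.append({"set": name, "set_size": K, "de_size": nde,
                     "overlap": k, "p_value": p})
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = p_adjust(out["p_value"].to_numpy(), "BH")
    return out.sort_values("p_value", kind="mergesort")


def barcode_profile(statistics: np.ndarray, index, weights: np.ndarray | None = None,
                    bandwidth: float = 0.1, grid_size: int = 101):
    """Numeric data for a barcode enrichment plot.

    Genes are ranked by statistic (descending: position 1 = largest).
    Returns (positions, grid, enrichment): sorted 1-based positions of the
    set genes, a grid over relative rank in [0, 1], and the kernel-smoothed
    relative enrichment (local set density over the uniform density, with
    optional gene weights), computed with boundary reflection.
    """
    s = np.asarray(statistics, dtype=float)
    idx = np.asarray(index)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty gene set")
    G = s.size
    order = np.argsort(-s, kind="mergesort")
    pos_of = np.empty(G, dtype=int)
    pos_of[order] = np.arange(1, G + 1)
    positions = np.sort(pos_of[idx])

    w = np.ones(idx.size) if weights is None else np.asarray(weights, dtype=float)
    w = w[np.argsort(pos_of[idx])]
    x = (positions - 0.5) / G
    xr = np.concatenate([x, -x, 2 - x])
    wr = np.concatenate([w, w, w])
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = np.zeros(grid_size)
    for xi, wi in zip(xr, wr):
        dens += wi * stats.norm.pdf((grid - xi) / bandwidth)
    dens /= bandwidth * w.sum()
    return positions, grid, dens
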