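"""Differential splicing from exon-level linear model fits.

An exon-level fit (after voom for RNA-seq) provides per-exon log-fold-change
estimates for the contrast of interest.  Differential exon usage shows up as
an exon whose coefficient deviates from the precision-weighted average
coefficient of all exons in its gene.  Residual variances are pooled within
genes and moderated across genes; each exon gets a t-statistic for its
deviation, and each gene both an F-statistic over its exon deviations and a
Simes-aggregated p-value over its k-1 smallest exon p-values (the
deviations carry only k-1 degrees of freedom because their precision-
weighted sum is zero).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import LinearFit
from .ebayes import fit_fdist, p_adjust, squeeze_var

__all__ = ["diff_splice"]

log = logging.getLogger(__name__)


def diff_splice(exon_fit: LinearFit, gene_ids, coef: str | int = 0
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test for differential exon usage within genes.

    Parameters
    ----------
    exon_fit
        Linear fit on the exon-level matrix (rows = exons).
    gene_ids
        Per-exon gene labels, aligned with the fit's rows.
    coef
        Coefficient/contrast to test.

    Returns ``(exon_table, gene_table)``.  Genes need >= 2 exons;
    single-exon genes are dropped with a logged count.
    """
    j = exon_fit.col_index(coef)
    genes = np.asarray([str(g) for g in gene_ids])
    if genes.size != exon_fit.n_genes:
        raise ValueError("gene_ids length must equal the number of exons in the fit")

    tab = pd.DataFrame({
        "gene": genes,
        "beta": exon_fit.coefficients[:, j],
        "u2": exon_fit.stdev_unscaled[:, j] ** 2,
        "s2": exon_fit.sigma**2,
        "df": exon_fit.df_residual,
        "exon_id": exon_fit.gene_ids,
    })
    nexons = tab.groupby("gene", sort=False)["beta"].transform("size")
    dropped = int((nexons < 2).sum())
    if dropped:
        log.info("diff_splice: dropping %d single-exon genes", dropped)
    tab = tab[nexons >= 2].copy()
    if tab.empty:
        raise ValueError("no genes with >= 2 exons")

    grp = tab.groupby("gene", sort=False)
    # pooled gene-level residual variance, moderated across genes
    gene_df = grp["df"].sum()
    gene_s2 = grp.apply(lambda s: np.sum(s["df"] * s["s2"]) / max(np.sum(s["df"]), 1e-300),
                        include_groups=False)
    prior = fit_fdist(gene_s2.to_numpy(), gene_df.to_numpy())
    gene_s2_post = pd.Series(
        squeeze_var(gene_s2.to_numpy(), gene_df.to_numpy(), prior), index=gene_s2.index)
    d0 = prior.df_prior
    gene_df_total = np.minimum(gene_df + d0, float(gene_df.sum()))

    # precision-weighted gene mean coefficient and deviations
    winv = 1.0 / tab["u2"]
    wsum = winv.groupby(tab["gene"], sort=False).transform("sum")
    betabar = (tab["beta"] * winv).groupby(tab["gene"], sort=False).transform("sum") / wsum
    dev = tab["beta"] - betabar
    s2p = tab["gene"].map(gene_s2_post)
    t_unadj = dev / np.sqrt(tab["u2"] * s2p)
    one_minus_lev = 1.0 - winv / wsum
    t = t_unadj / np.sqrt(one_minus_lev)
    dft = tab["gene"].map(gene_df_total).to_numpy()
    p = 2.0 * stats.t.sf(np.abs(t), dft)

    exon_table = pd.DataFrame({
        "gene": tab["gene"].to_numpy(),
        "logFC_vs_gene": (dev / one_minus_lev).to_numpy(),
        "t": t.to_numpy(),
        "p_value": p,
    }, index=pd.Index(tab["exon_id"], name="exon"))
    exon_table["adj_p"] = p_adjust(exon_table["p_value"].to_numpy(), "BH")

    # gene level: F over the unadjusted t's (k-1 free deviations) and Simes
    # over the k-1 smallest exon p-values
    t2sum = (t_unadj**2).groupby(tab["gene"], sort=False).sum()
    k = grp["beta"].size()
    F = t2sum / (k - 1)
    F_p = pd.Series(stats.f.sf(F.to_numpy(), (k - 1).to_numpy(),
                               gene_df_total.to_numpy()), index=F.index)
    simes = exon_table.groupby("gene", sort=False)["p_value"].apply(
        lambda ps: float(min(1.0, np.min(
            np.sort(ps.to_numpy())[: len(ps) - 1]
            * (len(ps) - 1) / np.arange(1, len(ps))))))

    gene_table = pd.DataFrame({
        "n_exons": k, "F": F, "F_p": F_p, "simes_p": simes,
    })
    gene_table.index.name = "gene"
    gene_table["adj_F_p"] = p_adjust(gene_table["F_p"].to_numpy(), "BH")
    gene_table["adj_simes_p"] = p_adjust(gene_table["simes_p"].to_numpy(), "BH")
    return exon_table, gene_table
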