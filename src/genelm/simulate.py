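"""Synthetic expression data with known ground truth.

Every generator is a pure function of its seed and parameters (NumPy
Generator/PCG64), returning the simulated matrix together with the truth
needed to score downstream inference:

* :func:`sim_log_matrix` — log-intensity data matching the moderation
  model: gene variances drawn from a scaled inverse-chi-square prior
  (hyper-parameters d0, s0^2, optionally abundance-dependent), a fraction of
  genes differentially expressed with normal log-fold-changes.
* :func:`sim_counts_nb` — negative-binomial RNA-seq counts with gene means
  log-uniform over a range, a decreasing dispersion trend and library sizes
  varying ±30%.
* :func:`sim_blocks` — equicorrelated within-block errors for consensus
  correlation estimation.
* :func:`sim_correlated_sets` — null data in which designated gene sets
  share a latent factor inducing a target within-set correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import DesignSpec, ExpressionMatrix, GeneSetCollection

__all__ = [
    "sim_log_matrix",
    "sim_counts_nb",
    "sim_blocks",
    "sim_correlated_sets",
    "sim_exon_matrix",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _inv_chisq(rng, size, d0, s0_sq):
    """sigma^2 ~ s0^2 * d0 / chi2(d0); d0 = inf gives the constant s0^2."""
    if np.isinf(d0):
        return np.full(size, s0_sq)
    return s0_sq * d0 / rng.chisquare(d0, size=size)


def sim_log_matrix(G: int, design: DesignSpec, de_fraction: float = 0.1,
                   logfc_sd: float = 1.0, d0: float = 4.0, s0_sq: float = 0.05,
                   trend: bool = False, de_coef: int = -1,
                   seed=0) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-intensity matrix under the moderated-variance model.

    Baseline abundances are uniform on [4, 14] (log2 scale); gene variances
    come from the scaled inverse-chi-square prior (multiplied, when
    ``trend``, by a smooth decreasing function of abundance); a
    ``de_fraction`` of genes get a N(0, logfc_sd^2) effect on design column
    ``de_coef``.  Returns the matrix and a truth table with columns
    (is_de, true_logfc, true_sigma2).
    """
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = _rng(seed)
    X = design.design
    N = X.shape[0]
    base = rng.uniform(4.0, 14.0, size=G)
    sigma2 = _inv_chisq(rng, G, d0, s0_sq)
    if trend:
        sigma2 = sigma2 * (0.5 + 2.0 * np.exp(-(base - 4.0) / 2.0))
    n_de = int(round(de_fraction * G))
    is_de = np.zeros(G, dtype=bool)
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    is_de[de_idx] = True
    logfc = np.zeros(G)
    logfc[is_de] = rng.normal(0.0, logfc_sd, size=n_de)

    noise = rng.standard_normal((G, N)) * np.sqrt(sigma2)[:, None]
    Y = base[:, None] + noise
    Y += logfc[:, None] * X[:, de_coef][None, :]

    gene_ids = [f"g{i+1}" for i in range(G)]
    sample_ids = [f"s{j+1}" for j in range(N)]
    m = ExpressionMatrix(values=Y, gene_ids=gene_ids, sample_ids=sample_ids,
                         kind="log_intensity")
    truth = pd.DataFrame({"is_de": is_de, "true_logfc": logfc,
                          "true_sigma2": sigma2}, index=gene_ids)
    return m, truth


def sim_exon_matrix(n_genes: int, n_exons: int, design: DesignSpec,
                    spike_fraction: float = 0.0, spike_lfc: float = 2.0,
                    d0: float = 8.0, s0_sq: float = 0.05, de_coef: int = -1,
                    seed=0) -> tuple[ExpressionMatrix, list[str], pd.DataFrame]:
    """Exon-level log-intensity matrix for differential splicing tests.

    Every gene has ``n_exons`` exon rows sharing one residual variance drawn
    from the scaled inverse-chi-square prior (exons of a gene are measured
    on the same transcript, so a common variance is the realistic regime).
    In a ``spike_fraction`` of genes, exon 0 is shifted by ``spike_lfc`` on
    design column ``de_coef`` while the other exons are unchanged.

    Returns (matrix, per-exon gene labels, truth per gene with column
    ``spiked``).
    """
    rng = _rng(seed)
    X = design.design
    N = X.shape[0]
    G = n_genes * n_exons
    base = np.repeat(rng.uniform(4.0, 14.0, size=n_genes), n_exons)
    sigma2 = np.repeat(_inv_chisq(rng, n_genes, d0, s0_sq), n_exons)
    n_spiked = int(round(spike_fraction * n_genes))
    spiked = np.zeros(n_genes, dtype=bool)
    spiked[rng.choice(n_genes, size=n_spiked, replace=False) if n_spiked else []] = True

    Y = base[:, None] + rng.standard_normal((G, N)) * np.sqrt(sigma2)[:, None]
    first_exon_rows = np.flatnonzero(spiked) * n_exons
    Y[first_exon_rows] += spike_lfc * X[:, de_coef][None, :]

    gene_labels = [f"G{i // n_exons + 1}" for i in range(G)]
    exon_ids = [f"G{i // n_exons + 1}:e{i % n_exons + 1}" for i in range(G)]
    sample_ids = [f"s{j+1}" for j in range(N)]
    m = ExpressionMatrix(values=Y, gene_ids=exon_ids, sample_ids=sample_ids,
                         kind="log_intensity")
    truth = pd.DataFrame({"spiked": spiked},
                         index=[f"G{i+1}" for i in range(n_genes)])
    return m, gene_labels, truth


def default_dispersion_trend(mu: np.ndarray) -> np.ndarray:
    """Decreasing NB dispersion: phi(mu) = 0.05 + 10/mu."""
    return 0.05 + 10.0 / np.maximum(mu, 1e-9)


def sim_counts_nb(G: int, design: DesignSpec, mean_range=(5.0, 5000.0),
                  dispersion_trend=default_dispersion_trend,
                  de_fraction: float = 0.0, lfc: float = 2.0,
                  de_coef: int = -1, lib_variation: float = 0.3,
                  seed=0) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts with a decreasing mean-dispersion trend.

    Gene base means are log-uniform over ``mean_range``; per-sample library
    factors are uniform on 1 ± ``lib_variation``; DE genes get a log2
    fold-change of ±``lfc`` (random sign) on design column ``de_coef``.
    """
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = _rng(seed)
    X = design.design
    N = X.shape[0]
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=G))
    phi = np.asarray(dispersion_trend(mu), dtype=float)
    if (phi <= 0).any():
        raise ValueError("dispersion trend must be positive")

    n_de = int(round(de_fraction * G))
    is_de = np.zeros(G, dtype=bool)
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    is_de[de_idx] = True
    logfc = np.zeros(G)
    logfc[is_de] = rng.choice([-lfc, lfc], size=n_de)

    lib_factor = rng.uniform(1.0 - lib_variation, 1.0 + lib_variation, size=N)
    mean_mat = mu[:, None] * lib_factor[None, :] * 2.0 ** (logfc[:, None] * X[:, de_coef][None, :])
    r = 1.0 / phi
    p = r[:, None] / (r[:, None] + mean_mat)
    counts = rng.negative_binomial(r[:, None], p).astype(float)

    gene_ids = [f"g{i+1}" for i in range(G)]
    sample_ids = [f"s{j+1}" for j in range(N)]
    m = ExpressionMatrix(values=counts, gene_ids=gene_ids, sample_ids=sample_ids,
                         kind="counts")
    truth = pd.DataFrame({"is_de": is_de, "true_logfc": logfc,
                          "true_mean": mu, "true_dispersion": phi}, index=gene_ids)
    return m, truth


def sim_blocks(G: int, n_blocks: int, block_size: int, rho: float,
               sigma2: float = 0.25, seed=0) -> tuple[ExpressionMatrix, list[str]]:
    """Null data with equicorrelated within-block errors.

    Samples are grouped into ``n_blocks`` blocks of ``block_size``; errors
    within a block share correlation ``rho`` (must exceed -1/(block_size-1)
    for a valid covariance).  Returns the matrix and the block labels.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("|rho| must be < 1")
    if block_size > 1 and rho <= -1.0 / (block_size - 1):
        raise ValueError("rho too negative for this block size")
    rng = _rng(seed)
    N = n_blocks * block_size
    V = np.full((block_size, block_size), rho)
    np.fill_diagonal(V, 1.0)
    L = np.linalg.cholesky(V)
    base = rng.uniform(4.0, 14.0, size=G)
    Y = np.empty((G, N))
    for b in range(n_blocks):
        z = rng.standard_normal((G, block_size))
        Y[:, b * block_size:(b + 1) * block_size] = z @ L.T
    Y = base[:, None] + np.sqrt(sigma2) * Y
    blocks = [f"b{b+1}" for b in range(n_blocks) for _ in range(block_size)]
    gene_ids = [f"g{i+1}" for i in range(G)]
    sample_ids = [f"s{j+1}" for j in range(N)]
    return ExpressionMatrix(values=Y, gene_ids=gene_ids, sample_ids=sample_ids,
                            kind="log_intensity"), blocks


def sim_correlated_sets(G: int, set_size: int, rho_within: float,
                        n_sets: int = 50, N: int = 20, sigma2: float = 1.0,
                        seed=0) -> tuple[ExpressionMatrix, GeneSetCollection]:
    """Null data in which designated sets share a latent factor.

    Genes in set k follow y = sqrt(rho) f_k + sqrt(1-rho) e with a shared
    per-sample factor f_k, so every within-set gene pair has correlation
    ``rho_within``; remaining genes are independent.  There is no
    differential expression.
    """
    if not (0.0 <= rho_within < 1.0):
        raise ValueError("rho_within must lie in [0, 1)")
    if n_sets * set_size > G:
        raise ValueError("n_sets * set_size exceeds the number of genes")
    rng = _rng(seed)
    base = rng.uniform(4.0, 14.0, size=G)
    Y = rng.standard_normal((G, N))
    sets: dict[str, list[str]] = {}
    gene_ids = [f"g{i+1}" for i in range(G)]
    for k in range(n_sets):
        rows = np.arange(k * set_size, (k + 1) * set_size)
        f = rng.standard_normal(N)
        Y[rows] = np.sqrt(rho_within) * f[None, :] + np.sqrt(1 - rho_within) * Y[rows]
        sets[f"set{k+1}"] = [gene_ids[r] for r in rows]
    Y = base[:, None] + np.sqrt(sigma2) * Y
    sample_ids = [f"s{j+1}" for j in range(N)]
    m = ExpressionMatrix(values=Y, gene_ids=gene_ids, sample_ids=sample_ids,
                         kind="log_intensity")
    return m, GeneSetCollection(sets=sets)
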