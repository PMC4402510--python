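"""Core data containers for gene-wise linear modelling.

The central objects mirror the classical expression-analysis workflow:

* :class:`ExpressionMatrix` — a genes × samples numeric matrix with optional
  observation-level and sample-level precision weights.
* :class:`DesignSpec` — the samples × coefficients design matrix, optionally
  with a coefficients × contrasts matrix.
* :class:`LinearFit` — the results object produced by fitting gene-wise
  linear models; extended in place by empirical Bayes moderation with
  posterior variances and moderated test statistics.
* :class:`GeneSetCollection` — named sets of gene identifiers with optional
  per-gene direction (±1) and weight annotation.
* :class:`TestResults` — a genes × contrasts classification in {−1, 0, +1}.

Gene identifiers are opaque strings matched exactly (case-sensitive).
Rows are always genes, columns always samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DesignSpec",
    "LinearFit",
    "GeneSetCollection",
    "TestResults",
    "NormexpParams",
    "FDistPrior",
    "BlockStructure",
    "VoomResult",
]

_KINDS = ("log_intensity", "counts", "logcpm")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with row/column annotation.

    Parameters
    ----------
    values
        Numeric matrix, shape (G, N).  Interpretation depends on ``kind``:
        log2 intensities, raw counts, or log2 counts-per-million.
    gene_ids, sample_ids
        Row and column labels; lengths must match ``values``.
    obs_weights
        Optional strictly positive G × N precision weights, one per
        observation.
    sample_weights
        Optional strictly positive length-N sample (array) weights.
    kind
        One of ``log_intensity``, ``counts``, ``logcpm``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    kind: str = "log_intensity"
    obs_weights: np.ndarray | None = None
    sample_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x samples)")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        G, N = self.values.shape
        if len(self.gene_ids) != G:
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != {G} rows")
        if len(self.sample_ids) != N:
            raise ValueError(f"sample_ids length {len(self.sample_ids)} != {N} columns")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "counts":
            body = self.values
            if np.isnan(body).any():
                raise ValueError("missing values are not allowed for kind='counts'")
            if (body < 0).any():
                raise ValueError("counts must be non-negative")
        if self.obs_weights is not None:
            self.obs_weights = np.asarray(self.obs_weights, dtype=float)
            if self.obs_weights.shape != self.values.shape:
                raise ValueError("obs_weights shape must match values")
            if not np.all(np.isfinite(self.obs_weights)) or (self.obs_weights <= 0).any():
                raise ValueError("obs_weights must be finite and strictly positive")
        if self.sample_weights is not None:
            self.sample_weights = np.asarray(self.sample_weights, dtype=float)
            if self.sample_weights.shape != (N,):
                raise ValueError("sample_weights must have length N")
            if not np.all(np.isfinite(self.sample_weights)) or (self.sample_weights <= 0).any():
                raise ValueError("sample_weights must be finite and strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def combined_weights(self) -> np.ndarray | None:
        """Elementwise product of observation and sample weights (or None)."""
        if self.obs_weights is None and self.sample_weights is None:
            return None
        w = np.ones_like(self.values)
        if self.obs_weights is not None:
            w = w * self.obs_weights
        if self.sample_weights is not None:
            w = w * self.sample_weights[None, :]
        return w

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "log_intensity", **kw) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            kind=kind,
            **kw,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            kind=self.kind,
            obs_weights=None if self.obs_weights is None else self.obs_weights.copy(),
            sample_weights=None if self.sample_weights is None else self.sample_weights.copy(),
        )


@dataclass
class DesignSpec:
    """Samples × coefficients design matrix, with optional contrasts.

    ``contrasts`` maps fitted coefficients onto tested contrasts: a p × c
    matrix whose rows align with ``coef_names``.
    """

    design: np.ndarray
    coef_names: list[str]
    contrasts: np.ndarray | None = None
    contrast_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be a 2-D matrix (samples x coefficients)")
        p = self.design.shape[1]
        self.coef_names = [str(c) for c in self.coef_names]
        if len(self.coef_names) != p:
            raise ValueError("coef_names length must equal number of design columns")
        if self.contrasts is not None:
            self.contrasts = np.asarray(self.contrasts, dtype=float)
            if self.contrasts.ndim == 1:
                self.contrasts = self.contrasts[:, None]
            if self.contrasts.shape[0] != p:
                raise ValueError("contrast rows must align with coefficients")
            if self.contrast_names is None:
                self.contrast_names = [f"C{i+1}" for i in range(self.contrasts.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    def check_full_rank(self) -> None:
        """Raise if the design is column-rank deficient, naming the columns."""
        X = self.design
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify a set of dependent columns via QR pivoting
            from scipy.linalg import qr

            _, R, piv = qr(X, pivoting=True, mode="economic")
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
            dep = [self.coef_names[j] for j in piv[rank:]]
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"dependent columns: {dep}"
            )

    @classmethod
    def from_groups(cls, groups: Sequence[str]) -> "DesignSpec":
        """Treatment-means design: one indicator column per group level,
        levels ordered by first appearance; every row sums to 1."""
        groups = [str(g) for g in groups]
        levels: list[str] = []
        for g in groups:
            if g not in levels:
                levels.append(g)
        X = np.zeros((len(groups), len(levels)))
        for i, g in enumerate(groups):
            X[i, levels.index(g)] = 1.0
        return cls(design=X, coef_names=levels)


@dataclass
class LinearFit:
    """Results of gene-wise (weighted) least squares, per gene.

    Fields prior to moderation:

    coefficients : (G, k) estimated coefficients or contrasts, log2 scale
    stdev_unscaled : (G, k) unscaled standard deviations u such that
        se(beta_hat) = u * sigma
    sigma : (G,) residual standard deviation (NaN when df_residual == 0)
    df_residual : (G,) residual degrees of freedom
    amean : (G,) average log-expression per gene
    coef_cov : (k, k) or (G, k, k) unscaled covariance of the coefficients
    col_names : labels for the coefficient/contrast columns

    Empirical Bayes moderation adds df_prior, s2_prior, s2_post, t, p_value,
    lods, F, F_p (see :func:`genelm.ebayes.moderated_stats`).
    """

    coefficients: np.ndarray
    stdev_unscaled: np.ndarray
    sigma: np.ndarray
    df_residual: np.ndarray
    amean: np.ndarray
    coef_cov: np.ndarray
    col_names: list[str]
    gene_ids: list[str]
    # empirical Bayes extensions (populated by moderated_stats)
    df_prior: float | np.ndarray | None = None
    s2_prior: float | np.ndarray | None = None
    s2_post: np.ndarray | None = None
    df_total: np.ndarray | None = None
    t: np.ndarray | None = None
    p_value: np.ndarray | None = None
    lods: np.ndarray | None = None
    F: np.ndarray | None = None
    F_p: np.ndarray | None = None
    var_prior_coef: float | None = None
    proportion: float | None = None

    @property
    def n_genes(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_coef(self) -> int:
        return self.coefficients.shape[1]

    def col_index(self, coef: str | int) -> int:
        if isinstance(coef, (int, np.integer)):
            return int(coef)
        try:
            return self.col_names.index(str(coef))
        except ValueError:
            raise KeyError(f"unknown coefficient {coef!r}; have {self.col_names}") from None

    # --- fluent results-object interface -----------------------------------
    def contrasts(self, contrasts: np.ndarray, names: list[str] | None = None) -> "LinearFit":
        from .linmod import contrasts_fit

        return contrasts_fit(self, contrasts, names=names)

    def ebayes(self, trend: bool = False, robust: bool = False,
               proportion: float = 0.01) -> "LinearFit":
        from .ebayes import moderated_stats

        return moderated_stats(self, trend=trend, robust=robust, proportion=proportion)

    def treat(self, lfc: float) -> "LinearFit":
        from .ebayes import treat as _treat

        return _treat(self, lfc)

    def top_table(self, coef: str | int = 0, number: int = 10,
                  adjust: str = "BH", sort_by: str = "p") -> pd.DataFrame:
        from .ebayes import top_table as _top_table

        return _top_table(self, coef=coef, number=number, adjust=adjust, sort_by=sort_by)

    def decide_tests(self, method: str = "separate", adjust: str = "BH",
                     p_threshold: float = 0.05, lfc: float = 0.0) -> "TestResults":
        from .ebayes import decide_tests as _decide_tests

        return _decide_tests(self, method=method, adjust=adjust,
                             p_threshold=p_threshold, lfc=lfc)

    def summary(self) -> str:
        """Plain-text summary of the fit and, if present, the moderation."""
        lines = []
        lines.append("Gene-wise linear model fit")
        lines.append("==========================")
        lines.append(f"Genes:            {self.n_genes}")
        lines.append(f"Coefficients:     {', '.join(self.col_names)}")
        with np.errstate(invalid="ignore"):
            lines.append(f"Residual df:      median {np.nanmedian(self.df_residual):.3g}")
            lines.append(f"Residual sd:      median {np.nanmedian(self.sigma):.4g}")
        if self.df_prior is not None:
            d0 = np.atleast_1d(np.asarray(self.df_prior, dtype=float))
            s0 = np.atleast_1d(np.asarray(self.s2_prior, dtype=float))
            lines.append("")
            lines.append("Empirical Bayes moderation")
            lines.append("--------------------------")
            d0txt = "inf" if np.isinf(d0).all() else f"{np.median(d0):.4g}"
            lines.append(f"Prior df (d0):    {d0txt}")
            lines.append(f"Prior var (s0^2): median {np.median(s0):.4g}")
            nsig = int((self.p_value < 0.05).sum()) if self.p_value is not None else 0
            lines.append(f"p < 0.05 (unadjusted): {nsig} of {self.p_value.size}")
        return "\n".join(lines)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-gene direction (±1) and weight."""

    sets: dict[str, list[str]]
    directions: dict[str, dict[str, int]] = field(default_factory=dict)
    gene_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            memb = set(members)
            for mapping, label in ((self.directions, "directions"),
                                   (self.gene_weights, "gene_weights")):
                extra = set(mapping.get(name, {})) - memb
                if extra:
                    raise ValueError(f"{label} for set {name!r} reference non-members: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def indices(self, gene_ids: Sequence[str]) -> dict[str, np.ndarray]:
        """Map each set to integer row indices into ``gene_ids`` (exact match)."""
        pos = {g: i for i, g in enumerate(gene_ids)}
        out = {}
        for name, members in self.sets.items():
            idx = [pos[g] for g in members if g in pos]
            out[name] = np.asarray(sorted(set(idx)), dtype=int)
        return out


@dataclass
class TestResults:
    """Genes × contrasts classification: −1 (down), 0 (not DE), +1 (up)."""

    codes: np.ndarray
    gene_ids: list[str]
    col_names: list[str]
    method: str = "separate"
    adjust_method: str = "BH"
    p_threshold: float = 0.05
    lfc_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("codes must contain only -1, 0, +1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.gene_ids, columns=self.col_names)

    def summary(self) -> pd.DataFrame:
        df = self.to_dataframe()
        return pd.DataFrame({
            "down": (df == -1).sum(),
            "not_de": (df == 0).sum(),
            "up": (df == 1).sum(),
        }).T


@dataclass
class NormexpParams:
    """Parameters of the normal + exponential convolution model.

    Observed intensity = N(mu, sigma^2) noise + Exp(mean alpha) signal.
    """

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")


@dataclass
class FDistPrior:
    """Scaled-F prior for gene-wise residual variances.

    s2_g ~ s2_prior * F(df_g, df_prior).  df_prior may be +inf (all variances
    equal to the prior); s2_prior may be a per-gene vector when a mean-variance
    trend is fitted; robust fitting yields a per-gene df_prior vector.
    """

    df_prior: float | np.ndarray
    s2_prior: float | np.ndarray
    trended: bool = False
    robust: bool = False

    def __post_init__(self) -> None:
        d0 = np.atleast_1d(np.asarray(self.df_prior, dtype=float))
        s0 = np.atleast_1d(np.asarray(self.s2_prior, dtype=float))
        if (d0 < 0).any():
            raise ValueError("df_prior must be >= 0 (0 = no shrinkage, inf = complete)")
        if (s0 <= 0).any() or not np.all(np.isfinite(s0)):
            raise ValueError("s2_prior must be positive and finite")


@dataclass
class BlockStructure:
    """Sample blocking with a shared (consensus) intrablock correlation."""

    block: list[str]
    correlation: float

    def __post_init__(self) -> None:
        self.block = [str(b) for b in self.block]
        if not (-1.0 < self.correlation < 1.0):
            raise ValueError("correlation must lie strictly within (-1, 1)")
        sizes = pd.Series(self.block).value_counts()
        if (sizes < 2).all():
            raise ValueError("at least one block must contain >= 2 samples")


@dataclass
class VoomResult:
    """Output of the mean-variance precision-weight transformation.

    elist holds logCPM values with per-observation weights; (trend_x,
    trend_y) is the fitted sqrt-standard-deviation vs average log2 count
    trend; lib_sizes are the effective library sizes used.
    """

    elist: ExpressionMatrix
    trend_x: np.ndarray
    trend_y: np.ndarray
    lib_sizes: np.ndarray
    sample_weights: np.ndarray | None = None
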