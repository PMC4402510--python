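"""Model-object interface over the gene-wise linear modelling functions.

`GeneExpressionLM` bundles an expression matrix with a design (and optional
blocking / contrasts) the way statistical modelling packages pair a model
class with a results class: ``fit()`` runs gene-wise (generalized/weighted)
least squares and returns a :class:`~genelm.datamodel.LinearFit` results
object, whose ``ebayes()``, ``contrasts()``, ``treat()``, ``top_table()``,
``decide_tests()`` and ``summary()`` methods drive the downstream analysis.

Typical use::

    model = GeneExpressionLM.from_counts(counts, design)   # voom weights
    results = model.fit().ebayes(trend=True)
    print(results.summary())
    table = results.top_table(coef="B", number=20)
"""

from __future__ import annotations

import numpy as np

from .datamodel import BlockStructure, DesignSpec, ExpressionMatrix, LinearFit, VoomResult
from .linmod import array_weights, duplicate_correlation, lm_fit
from .voom import voom, voom_with_quality_weights

__all__ = ["GeneExpressionLM"]


class GeneExpressionLM:
    """Gene-wise linear model for an expression matrix.

    Parameters
    ----------
    data
        :class:`ExpressionMatrix` of log-intensities or logCPM (counts go
        through :meth:`from_counts`).  Observation/sample weights on the
        matrix are honoured by the fit.
    design
        :class:`DesignSpec`; must be full column rank.
    block
        Optional :class:`BlockStructure` for correlated samples; use
        :meth:`estimate_block_correlation` to obtain the consensus
        correlation first.
    """

    def __init__(self, data: ExpressionMatrix, design: DesignSpec,
                 block: BlockStructure | None = None):
        design.check_full_rank()
        if design.n_samples != data.n_samples:
            raise ValueError("design rows must match the number of samples")
        self.data = data
        self.design = design
        self.block = block
        self.voom_result: VoomResult | None = None

    # --- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df, design: DesignSpec, kind: str = "log_intensity",
                       **kw) -> "GeneExpressionLM":
        return cls(ExpressionMatrix.from_dataframe(df, kind=kind), design, **kw)

    @classmethod
    def from_counts(cls, counts: ExpressionMatrix, design: DesignSpec,
                    norm_factors: np.ndarray | None = None,
                    quality_weights: bool = False, span: float = 0.5,
                    **kw) -> "GeneExpressionLM":
        """Build the model from RNA-seq counts via mean-variance precision
        weights (optionally combined with sample quality weights)."""
        if quality_weights:
            v = voom_with_quality_weights(counts, design, norm_factors=norm_factors,
                                          span=span)
        else:
            v = voom(counts, design, norm_factors=norm_factors, span=span)
        model = cls(v.elist, design, **kw)
        model.voom_result = v
        return model

    # --- estimation --------------------------------------------------------
    def estimate_block_correlation(self, block: list[str]) -> BlockStructure:
        """Consensus intrablock correlation; stores and returns the structure."""
        rho = duplicate_correlation(self.data, self.design, block)
        self.block = BlockStructure(block=block, correlation=rho)
        return self.block

    def estimate_sample_weights(self) -> np.ndarray:
        """Relative array quality weights; attached to the data for fitting."""
        w = array_weights(self.data, self.design,
                          prior_weights=self.data.obs_weights)
        self.data.sample_weights = w
        return w

    def fit(self, robust: bool = False) -> LinearFit:
        """Gene-wise (weighted / generalized) least squares."""
        return lm_fit(self.data, self.design, block=self.block, robust=robust)
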