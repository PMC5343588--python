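"""scikit-learn style normalizer estimators.

Each normalizer is a transformer over a genes × samples DataFrame:
``fit`` estimates the per-sample correction from the data (and, for the
condition-decomposition methods, the experimental design), ``transform``
applies it.  Hyperparameters follow the sklearn ``get_params`` /
``set_params`` protocol, so the estimators compose with pipelines,
cloning and grid search.  Note the domain orientation: columns are the
assay samples being normalized, rows are genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .baselines import median_offsets, quantile_normalize
from .io import ExperimentDesign, NormalizationResult, apply_offsets
from .orchestrator import CDConfig, normalize_cd

__all__ = [
    "MedianNormalizer",
    "QuantileNormalizer",
    "MedianCDNormalizer",
    "SVCDNormalizer",
]


def _check_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples (columns)")
    return X


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Conventional Median (scale) normalization.

    Subtracts each sample's median over the gene subset, centered so the
    global expression level is preserved.

    Parameters
    ----------
    genes : sequence of gene ids or None
        Subset used for the medians (default: all genes).

    Attributes
    ----------
    offsets_ : pd.Series
        Per-sample additive offsets (log2 units), zero mean.
    """

    def __init__(self, genes=None):
        self.genes = genes

    def fit(self, X, y=None):
        X = _check_frame(X)
        self.offsets_ = median_offsets(X, self.genes)
        return self

    def transform(self, X):
        if not hasattr(self, "offsets_"):
            raise NotFittedError("call fit first")
        X = _check_frame(X)
        return X - self.offsets_.reindex(X.columns)

    def result_(self) -> NormalizationResult:
        return NormalizationResult(
            method="median", total=self.offsets_, within=self.offsets_.copy(),
            between=pd.Series(dtype=float),
        )


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization (limma dialect, mean-of-tied-ranks).

    ``fit`` stores the mean order-statistic reference distribution;
    ``transform`` maps each sample's ranks onto it.  Not a per-sample
    shift: the full distribution of every sample is replaced.
    """

    def fit(self, X, y=None):
        X = _check_frame(X)
        self.reference_distribution_ = np.sort(X.to_numpy(dtype=float), axis=0).mean(axis=1)
        return self

    def transform(self, X):
        if not hasattr(self, "reference_distribution_"):
            raise NotFittedError("call fit first")
        X = _check_frame(X)
        ref = self.reference_distribution_
        from scipy.stats import rankdata

        x = X.to_numpy(dtype=float)
        out = np.empty_like(x)
        # map average ranks onto the reference quantile grid
        grid = np.linspace(1, x.shape[0], num=ref.size)
        for j in range(x.shape[1]):
            ranks = rankdata(x[:, j], method="average")
            out[:, j] = np.interp(ranks, grid, ref)
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    def fit_transform(self, X, y=None, **kwargs):
        X = _check_frame(X)
        self.fit(X)
        return quantile_normalize(X)


class _CDNormalizerBase(TransformerMixin, BaseEstimator):
    """Shared fit/transform machinery of the CD normalizers."""

    _method = ""

    def _config(self) -> CDConfig:
        raise NotImplementedError

    def fit(self, X, y=None, *, design: ExperimentDesign):
        """Estimate offsets from the matrix and its experimental design."""
        X = _check_frame(X)
        result = normalize_cd(X, design, self._config())
        self.result_ = result
        self.offsets_ = result.total
        self.within_offsets_ = result.within
        self.between_offsets_ = result.between
        self.novariation_genes_ = result.novariation_genes
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.diagnostics_ = result.diagnostics
        self.pvalues_ = result.pvalues
        self.statistical_error_ = result.statistical_error
        return self

    def transform(self, X):
        if not hasattr(self, "result_"):
            raise NotFittedError("call fit first")
        return apply_offsets(_check_frame(X), self.result_)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


class MedianCDNormalizer(_CDNormalizerBase):
    """Median Condition-Decomposition (MedianCD) normalization.

    Median normalization of each condition's replicates, then an
    iterative between-condition median normalization restricted to the
    automatically detected no-variation genes.  With all genes forced
    into the between step it reduces exactly to conventional Median
    normalization.
    """

    _method = "mediancd"

    def __init__(self, ks_alpha=0.001, min_novariation=100, tol_hard=0.001,
                 tol_soft=0.10, soft_run=10, extra_steps=10, max_outer_steps=100,
                 novariation_override=None):
        self.ks_alpha = ks_alpha
        self.min_novariation = min_novariation
        self.tol_hard = tol_hard
        self.tol_soft = tol_soft
        self.soft_run = soft_run
        self.extra_steps = extra_steps
        self.max_outer_steps = max_outer_steps
        self.novariation_override = novariation_override

    def _config(self) -> CDConfig:
        return CDConfig(
            method="mediancd", ks_alpha=self.ks_alpha,
            min_novariation=self.min_novariation,
            mediancd_tol_hard=self.tol_hard, mediancd_tol_soft=self.tol_soft,
            soft_run=self.soft_run, extra_steps=self.extra_steps,
            max_outer_steps=self.max_outer_steps,
            novariation_override=None if self.novariation_override is None
            else tuple(self.novariation_override),
        )


class SVCDNormalizer(_CDNormalizerBase):
    """Standard-Vector Condition-Decomposition (SVCD) normalization.

    Standard-Vector normalization of each condition's replicates and of
    the condition means, restricted in the between step to the detected
    no-variation genes.  The estimator is distribution-free and keeps
    between-condition variation that Median/Quantile normalization would
    remove under unbalanced differential expression.
    """

    _method = "svcd"

    def __init__(self, ks_alpha=0.001, min_novariation=100, sv_trim=0.01,
                 sv_tol_hard=0.01, sv_tol_soft=0.10, sv_soft_run=10,
                 sv_max_steps=100, extra_steps=10, max_outer_steps=100,
                 novariation_override=None):
        self.ks_alpha = ks_alpha
        self.min_novariation = min_novariation
        self.sv_trim = sv_trim
        self.sv_tol_hard = sv_tol_hard
        self.sv_tol_soft = sv_tol_soft
        self.sv_soft_run = sv_soft_run
        self.sv_max_steps = sv_max_steps
        self.extra_steps = extra_steps
        self.max_outer_steps = max_outer_steps
        self.novariation_override = novariation_override

    def _config(self) -> CDConfig:
        return CDConfig(
            method="svcd", ks_alpha=self.ks_alpha,
            min_novariation=self.min_novariation, sv_trim=self.sv_trim,
            sv_tol_hard=self.sv_tol_hard, sv_tol_soft=self.sv_tol_soft,
            sv_soft_run=self.sv_soft_run, sv_max_steps=self.sv_max_steps,
            extra_steps=self.extra_steps, max_outer_steps=self.max_outer_steps,
            novariation_override=None if self.novariation_override is None
            else tuple(self.novariation_override),
        )
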