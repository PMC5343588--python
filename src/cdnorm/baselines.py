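"""Conventional Median and Quantile between-sample normalization.

Median normalization equalizes the per-sample medians; the median step is
also reused inside MedianCD normalization, where it can be restricted to
a gene subset.  Quantile normalization forces every sample's empirical
distribution to the mean order-statistic distribution (the limma
dialect: rank ties share the mean of their would-be values) and is a
full matrix transform, not a per-sample shift.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import NormalizationResult

__all__ = ["median_offsets", "median_normalize", "quantile_normalize"]


def median_offsets(m: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.Series:
    """Centered per-sample medians over a gene subset (default: all)."""
    sub = m if genes is None else m.loc[list(genes)]
    if sub.shape[0] == 0:
        raise ValueError("empty gene subset")
    med = sub.median(axis=0)
    return med - med.mean()


def median_normalize(m: pd.DataFrame, genes: Sequence[str] | None = None) -> NormalizationResult:
    """Conventional Median normalization as a per-sample offset result."""
    offsets = median_offsets(m, genes)
    return NormalizationResult(
        method="median",
        total=offsets,
        within=offsets.copy(),
        between=pd.Series(dtype=float),
        iterations=0,
        converged=True,
    )


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization with mean-of-tied-ranks tie handling."""
    x = m.to_numpy(dtype=float)
    g, s = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, g + 1, dtype=float)
    for j in range(s):
        ranks = rankdata(x[:, j], method="average")
        # fractional (tied) ranks interpolate between neighboring order stats
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)
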