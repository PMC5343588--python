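"""Exact condition decomposition of the normalization problem.

In log2 scale the observed data of condition *k* are ``Y = X + a·1ᵀ``
with one additive factor per sample.  Splitting every sample vector into
its mean and residual parts decomposes the problem exactly and linearly
into one within-condition normalization per condition (acting on the
residual, i.e. the zero-sum part of the offsets) and a single
between-condition normalization acting on the condition means.  The
grand-mean component is unidentifiable and fixed by the global centering
convention (mean total offset = 0 over all samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExperimentDesign, NormalizationResult

__all__ = ["ConditionSlice", "ConditionMeanMatrix", "split_by_condition", "condition_means", "compose"]


@dataclass(frozen=True)
class ConditionSlice:
    """All replicate samples of one experimental condition (g × n)."""

    condition_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError(
                f"condition {self.condition_id!r} has {self.values.shape[1]} sample(s); "
                "a minimum of two samples is required per experimental condition"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ConditionMeanMatrix:
    """Per-gene condition means and within-condition variances (g × c)."""

    means: pd.DataFrame
    within_variances: pd.DataFrame

    def __post_init__(self) -> None:
        if self.means.shape != self.within_variances.shape:
            raise ValueError("means and variances dimensions differ")
        if (self.within_variances.to_numpy() < -1e-12).any():
            raise ValueError("negative within-condition variance")


def split_by_condition(m: pd.DataFrame, d: ExperimentDesign) -> list[ConditionSlice]:
    """Partition the matrix columns into one slice per condition."""
    unknown = [s for s in m.columns if s not in d.condition_of]
    if unknown:
        raise ValueError(f"samples absent from design: {unknown}")
    slices = []
    for cond in d.conditions:
        cols = [s for s in m.columns if d.condition_of[s] == cond]
        if cols:
            slices.append(ConditionSlice(cond, m[cols]))
    return slices


def condition_means(slices: list[ConditionSlice], within: NormalizationResult) -> ConditionMeanMatrix:
    """Condition means and unbiased variances of within-normalized values.

    Offsets are applied before reduction, so the variances are those of
    the offset-applied values (required by the downstream ANOVA).
    """
    means = {}
    variances = {}
    for sl in slices:
        shifted = sl.values - within.within.reindex(sl.sample_ids)
        means[sl.condition_id] = shifted.mean(axis=1)
        variances[sl.condition_id] = shifted.var(axis=1, ddof=1)
    return ConditionMeanMatrix(pd.DataFrame(means), pd.DataFrame(variances))


def compose(within: NormalizationResult, between: pd.Series, d: ExperimentDesign) -> NormalizationResult:
    """Combine within-sample and per-condition offsets into total offsets.

    ``total(sample) = within(sample) + between(condition)``, then the
    totals are centered to zero mean over all samples.
    """
    missing = {d.condition_of[s] for s in within.within.index} - set(between.index)
    if missing:
        raise ValueError(f"missing between offsets for conditions {sorted(missing)}")
    samples = within.within.index
    cond = np.array([d.condition_of[s] for s in samples])
    total = within.within + between.reindex(cond).to_numpy()
    shift = total.mean()
    total = total - shift
    return NormalizationResult(
        method=within.method,
        total=total,
        within=within.within.copy(),
        between=between - shift,
        novariation_genes=within.novariation_genes,
        iterations=within.iterations,
        converged=within.converged,
        diagnostics=within.diagnostics,
        pvalues=within.pvalues,
        statistical_error=within.statistical_error,
    )
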