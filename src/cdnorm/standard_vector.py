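"""Standard-Vector normalization of one set of exchangeable samples.

The expression levels of gene *j* across the *s* samples of a condition
form an *s*-dimensional vector.  After standardization (mean subtraction
and scaling to unit Euclidean norm) these *standard vectors* lie on the
unit (s−2)-sphere inside the zero-sum hyperplane.  If the samples are
exchangeable and correctly normalized, the distribution of standard
vectors is permutation-invariant with zero expected value; a nonzero
additive offset vector tilts the mean standard vector toward the
(centered) offset.  This motivates the iterative estimator

    offsets ← offsets + scale · (mean standard vector of the residuals),

with ``scale`` the median residual norm of the retained genes — a robust
mapping from sphere displacements back to log2 units.  At the fixed point
the trimmed mean standard vector vanishes, which is exactly the
exchangeability condition.  The method is distribution-free: no
Gaussianity is assumed, only exchangeability of samples within the set.

For s = 2 the sphere degenerates to two points and the procedure reduces
to a robust correction of the between-sample log difference, the
degenerate global-Loess case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardVectorSet",
    "SVConvergence",
    "standardize",
    "sv_step",
    "estimate_statistical_error",
    "sv_normalize",
]

_MIN_GENES = 10


@dataclass(frozen=True)
class StandardVectorSet:
    """Unit-norm, zero-sum gene vectors retained after trimming."""

    vectors: np.ndarray  # g' × s
    gene_ids: np.ndarray  # ids of retained genes, aligned with rows
    trimmed_gene_ids: frozenset
    scale: float  # median residual norm of retained genes

    @property
    def n_genes(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class SVConvergence:
    step: int
    mean_vector_norm: float
    numerical_error: float
    statistical_error: float
    status: str  # running | converged | max_steps

    def __post_init__(self) -> None:
        if self.numerical_error < 0 or self.statistical_error < 0:
            raise ValueError("errors must be non-negative")


def standardize(values: pd.DataFrame | np.ndarray, trim_fraction: float = 0.01,
                *, two_sided: bool = True) -> StandardVectorSet:
    """Build the standard-vector set of a g × s matrix.

    Each gene row is centered and scaled to unit norm.  Genes whose
    residual variance falls in the extreme ``trim_fraction`` of the
    variance distribution are excluded (symmetric by default: half the
    fraction from each tail), as are zero-variance genes.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if isinstance(values, pd.DataFrame):
        gene_ids = values.index.to_numpy()
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        gene_ids = np.arange(x.shape[0])
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    resid = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(resid, axis=1)
    variances = (norms**2) / (x.shape[1] - 1)
    keep = norms > 0
    if trim_fraction > 0 and keep.sum() > 0:
        v = variances[keep]
        if two_sided:
            lo, hi = np.quantile(v, [trim_fraction / 2, 1 - trim_fraction / 2])
            keep &= (variances >= lo) & (variances <= hi)
        else:
            hi = np.quantile(v, 1 - trim_fraction)
            keep &= variances <= hi
    if keep.sum() < _MIN_GENES:
        raise ValueError(
            f"only {int(keep.sum())} genes retained after trimming; "
            f"at least {_MIN_GENES} are required to estimate offsets"
        )
    vectors = resid[keep] / norms[keep, None]
    return StandardVectorSet(
        vectors=vectors,
        gene_ids=gene_ids[keep],
        trimmed_gene_ids=frozenset(gene_ids[~keep]),
        scale=float(np.median(norms[keep])),
    )


def estimate_statistical_error(sv: StandardVectorSet) -> float:
    """Sampling error of the offset estimate, in log2 units.

    Assuming independent genes, the mean standard vector has standard
    error ``componentwise_sd / sqrt(g')``; its Euclidean norm times the
    robust scale maps it to offset units.
    """
    if sv.n_genes < _MIN_GENES:
        raise ValueError("too few genes to estimate the statistical error")
    sd = sv.vectors.std(axis=0, ddof=1)
    return float(sv.scale * np.linalg.norm(sd) / np.sqrt(sv.n_genes))


def sv_step(sv: StandardVectorSet, step: int = 0) -> tuple[np.ndarray, SVConvergence]:
    """One update of the iterative estimator.

    Returns the zero-sum offset update ``u = scale × mean standard
    vector`` and a convergence record; the caller subtracts ``u`` from
    every sample (equivalently adds it to the running offsets).
    """
    mean_vec = sv.vectors.mean(axis=0)
    u = sv.scale * mean_vec
    s = sv.vectors.shape[1]
    record = SVConvergence(
        step=step,
        mean_vector_norm=float(np.linalg.norm(mean_vec)),
        numerical_error=float(np.linalg.norm(u) / np.sqrt(s)),
        statistical_error=estimate_statistical_error(sv),
        status="running",
    )
    return u, record


def sv_normalize(values: pd.DataFrame | np.ndarray, *, trim_fraction: float = 0.01,
                 tol_hard: float = 0.01, tol_soft: float = 0.10, soft_run: int = 10,
                 max_steps: int = 100) -> tuple[pd.Series | np.ndarray, list[SVConvergence]]:
    """Standard-Vector normalization of one g × s matrix.

    Iterates :func:`sv_step`, re-standardizing (and re-trimming) the
    residuals each step, until the numerical error is below
    ``tol_hard`` × the statistical error, or below ``tol_soft`` × it for
    ``soft_run`` consecutive steps.  Returns zero-sum per-sample offsets
    and the convergence trace; non-convergence is flagged in the last
    record's status, never silently dropped.
    """
    is_frame = isinstance(values, pd.DataFrame)
    x = values.to_numpy(dtype=float) if is_frame else np.asarray(values, dtype=float)
    s = x.shape[1]
    offsets = np.zeros(s)
    trace: list[SVConvergence] = []
    soft_count = 0
    for t in range(1, max_steps + 1):
        sv = standardize(x - offsets, trim_fraction)
        u, rec = sv_step(sv, step=t)
        offsets = offsets + u
        if rec.numerical_error < tol_hard * rec.statistical_error:
            trace.append(SVConvergence(rec.step, rec.mean_vector_norm,
                                       rec.numerical_error, rec.statistical_error,
                                       "converged"))
            break
        if rec.numerical_error < tol_soft * rec.statistical_error:
            soft_count += 1
        else:
            soft_count = 0
        if soft_count >= soft_run:
            trace.append(SVConvergence(rec.step, rec.mean_vector_norm,
                                       rec.numerical_error, rec.statistical_error,
                                       "converged"))
            break
        trace.append(rec)
    else:
        last = trace[-1]
        trace[-1] = SVConvergence(last.step, last.mean_vector_norm,
                                  last.numerical_error, last.statistical_error,
                                  "max_steps")
    offsets = offsets - offsets.mean()
    if is_frame:
        return pd.Series(offsets, index=values.columns), trace
    return offsets, trace
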