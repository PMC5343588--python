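"""Synthetic expression datasets with known differential expression.

The generator draws each gene's values as independent normal variates in
log2 scale.  Per treatment, a fraction of differentially expressed genes
(DEGs) is drawn log-uniformly; a dataset-wide reserve of genes is never
differentially expressed in any treatment, and the remaining pool is
guaranteed to be differentially expressed somewhere, so the count of
all-treatment negatives equals the reserve exactly.  Each treatment
belongs to a direction class (mostly over-expressed, mostly
under-expressed, or balanced) controlling the probability that each of
its DEGs is shifted up rather than down.  A DEG's treatment mean differs
from its control mean by ``effect_scale`` times the gene's variance
(literal default) or its standard deviation.  Finally, per-sample
normalization offsets are added, emulating the technical scale factors a
normalizer must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ExperimentDesign

__all__ = ["GeneratorSpec", "SyntheticTruth", "generate", "generate_null_like"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic dataset generator.

    Defaults mirror the simulation study this package benchmarks with:
    42 treatments sharing 9 controls, biological triplicates, per-
    treatment DEG fractions log-uniform on [0.9%, 90%], a 10% never-DE
    reserve, DEG effect equal to twice the gene variance, and treatment
    direction classes in thirds with over-expression probabilities
    0.9 / 0.1 / 0.5.
    """

    g: int = 10000
    n_treatments: int = 42
    n_controls: int = 9
    n_replicates: int = 3
    gene_means: np.ndarray | None = None
    gene_variances: np.ndarray | None = None
    mean_loc: float = 8.0
    mean_scale: float = 2.0
    sd_log_median: float = 0.0  # per-gene sd lognormal, median 1.0 log2 units
    sd_log_sigma: float = 0.3
    deg_fraction_range: tuple[float, float] = (0.009, 0.90)
    never_de_fraction: float = 0.10
    effect_rule: str = "variance"  # or "sd"
    effect_scale: float = 2.0
    p_over: tuple[float, float, float] = (0.9, 0.1, 0.5)  # over / under / balanced
    offset_sd: float = 0.2
    true_offsets: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.never_de_fraction < 1:
            raise ValueError("never_de_fraction must be in (0, 1)")
        lo, hi = self.deg_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("deg_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.effect_rule not in ("variance", "sd"):
            raise ValueError("effect_rule must be 'variance' or 'sd'")
        if self.n_controls < 1 or self.n_treatments < 1 or self.n_replicates < 2:
            raise ValueError("need >=1 treatment, >=1 control, >=2 replicates")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    de_indicator: pd.DataFrame  # genes × treatments, bool
    direction: pd.DataFrame  # genes × treatments, {+1, -1, 0}
    reserved_null_genes: tuple[str, ...]
    true_offsets: pd.Series
    deg_fractions: pd.Series  # the drawn f per treatment
    spec: GeneratorSpec

    def all_null_genes(self) -> pd.Index:
        """Genes not differentially expressed in any treatment."""
        return self.de_indicator.index[~self.de_indicator.any(axis=1)]


def _condition_layout(spec: GeneratorSpec) -> tuple[list[str], dict[str, str], ExperimentDesign]:
    width = max(2, len(str(max(spec.n_treatments, spec.n_controls))))
    controls = [f"ctl{i + 1:0{width}d}" for i in range(spec.n_controls)]
    treatments = [f"trt{i + 1:0{width}d}" for i in range(spec.n_treatments)]
    control_of = {t: controls[i % spec.n_controls] for i, t in enumerate(treatments)}
    condition_of: dict[str, str] = {}
    for cond in controls + treatments:
        for r in range(spec.n_replicates):
            condition_of[f"{cond}_r{r + 1}"] = cond
    design = ExperimentDesign(condition_of=condition_of, control_of=control_of)
    return treatments, control_of, design


def _draw_deg_sets(spec: GeneratorSpec, rng: np.random.Generator,
                   pool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-treatment DEG indicator over the non-reserved pool.

    Draws each treatment's DEG count from the log-uniform fraction range
    and its members uniformly from the pool, then enforces that every
    pool gene is hit by at least one treatment: each untouched gene is
    swapped into a random treatment in place of a gene that is covered
    at least twice, keeping all per-treatment counts exact.
    """
    lo, hi = spec.deg_fraction_range
    t = spec.n_treatments
    if hi <= 0:
        return np.zeros((pool.size, t), dtype=bool), np.zeros(t)
    if lo <= 0:
        lo = min(hi, 1e-6)
    fractions = np.exp(rng.uniform(np.log(lo), np.log(hi), size=t))
    counts = np.round(fractions * spec.g).astype(int)
    if counts.max() > pool.size:
        raise ValueError(
            f"largest DEG count {counts.max()} exceeds the non-reserved pool ({pool.size})"
        )
    indicator = np.zeros((pool.size, t), dtype=bool)
    for j in range(t):
        chosen = rng.choice(pool.size, size=counts[j], replace=False)
        indicator[chosen, j] = True
    hits = indicator.sum(axis=1)
    for gi in np.flatnonzero(hits == 0):
        order = rng.permutation(t)
        for j in order:
            candidates = np.flatnonzero(indicator[:, j] & (hits >= 2))
            if candidates.size:
                out = rng.choice(candidates)
                indicator[out, j] = False
                hits[out] -= 1
                indicator[gi, j] = True
                hits[gi] = 1
                break
        # if no treatment has a swappable gene, the gene stays untouched
    return indicator, fractions


def generate(spec: GeneratorSpec) -> tuple[pd.DataFrame, ExperimentDesign, SyntheticTruth]:
    """Generate an expression matrix, its design, and the ground truth."""
    rng = np.random.default_rng(spec.seed)
    g = spec.g
    gene_ids = np.array([f"gene{i + 1:06d}" for i in range(g)])
    means = (
        np.asarray(spec.gene_means, dtype=float)
        if spec.gene_means is not None
        else rng.normal(spec.mean_loc, spec.mean_scale, size=g)
    )
    variances = (
        np.asarray(spec.gene_variances, dtype=float)
        if spec.gene_variances is not None
        else rng.lognormal(spec.sd_log_median, spec.sd_log_sigma, size=g) ** 2
    )
    if means.size != g or variances.size != g or (variances <= 0).any():
        raise ValueError("gene_means/gene_variances must have length g with variances > 0")

    treatments, control_of, design = _condition_layout(spec)
    n_reserved = round(spec.never_de_fraction * g)
    reserved = rng.choice(g, size=n_reserved, replace=False)
    reserved_mask = np.zeros(g, dtype=bool)
    reserved_mask[reserved] = True
    pool = np.flatnonzero(~reserved_mask)

    pool_indicator, fractions = _draw_deg_sets(spec, rng, pool)
    de = np.zeros((g, spec.n_treatments), dtype=bool)
    de[pool] = pool_indicator

    # direction classes assigned round-robin so small numbers of
    # treatments keep exact thirds: over, under, balanced, over, ...
    direction = np.zeros((g, spec.n_treatments), dtype=np.int8)
    for j in range(spec.n_treatments):
        p_over = spec.p_over[j % 3]
        idx = np.flatnonzero(de[:, j])
        up = rng.random(idx.size) < p_over
        direction[idx, j] = np.where(up, 1, -1)

    sd = np.sqrt(variances)
    effect_base = variances if spec.effect_rule == "variance" else sd
    samples = design.samples
    n_samples = len(samples)
    if spec.true_offsets is not None:
        offsets = np.asarray(spec.true_offsets, dtype=float)
        if offsets.size != n_samples:
            raise ValueError("true_offsets length must equal the number of samples")
    else:
        offsets = rng.normal(0.0, spec.offset_sd, size=n_samples)
        offsets -= offsets.mean()

    treatment_index = {t: j for j, t in enumerate(treatments)}
    x = np.empty((g, n_samples))
    for si, s in enumerate(samples):
        cond = design.condition_of[s]
        mu = means.copy()
        j = treatment_index.get(cond)
        if j is not None:
            mu = mu + direction[:, j] * spec.effect_scale * effect_base
        x[:, si] = rng.normal(mu, sd) + offsets[si]

    matrix = pd.DataFrame(x, index=gene_ids, columns=samples)
    truth = SyntheticTruth(
        de_indicator=pd.DataFrame(de, index=gene_ids, columns=treatments),
        direction=pd.DataFrame(direction, index=gene_ids, columns=treatments),
        reserved_null_genes=tuple(gene_ids[np.sort(reserved)]),
        true_offsets=pd.Series(offsets, index=samples),
        deg_fractions=pd.Series(fractions, index=treatments),
        spec=spec,
    )
    return matrix, design, truth


def generate_null_like(reference: pd.DataFrame, d: ExperimentDesign,
                       offsets: pd.Series | np.ndarray | None, seed: int,
                       *, variance_floor: float = 1e-6) -> pd.DataFrame:
    """Null dataset matched gene-by-gene to a reference matrix.

    Draws per-gene normal variates with the reference's sample mean and
    sample variance (no condition structure — the null hypothesis of no
    differential expression), then adds the given per-sample offsets.
    Zero-variance reference genes have their variance floored.
    """
    if reference.isna().any().any():
        raise ValueError("reference matrix must be complete")
    rng = np.random.default_rng(seed)
    mu = reference.mean(axis=1).to_numpy()
    var = reference.var(axis=1, ddof=1).to_numpy()
    var = np.maximum(var, variance_floor)
    samples = [s for s in reference.columns]
    if offsets is None:
        a = np.zeros(len(samples))
    elif isinstance(offsets, pd.Series):
        a = offsets.reindex(samples).to_numpy(dtype=float)
    else:
        a = np.asarray(offsets, dtype=float)
    x = rng.normal(mu[:, None], np.sqrt(var)[:, None], size=(mu.size, len(samples))) + a
    return pd.DataFrame(x, index=reference.index, columns=samples)


def null_spec(spec: GeneratorSpec) -> GeneratorSpec:
    """The matching null-hypothesis spec: no differential expression."""
    return replace(spec, deg_fraction_range=(0.0, 0.0))
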