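"""MedianCD and SVCD normalization.

Both methods follow the condition-decomposition recipe: first an
independent within-condition normalization of each condition's
replicates using all genes (no gene varies within a condition, so no
lack-of-variation assumption is involved); then a between-condition
normalization that iteratively identifies no-variation genes and
re-normalizes until the set converges; and finally one more
between-condition normalization using only the detected no-variation
genes.  MedianCD performs every step with medians, SVCD with
Standard-Vector normalization.

The between step differs between the methods in where the median/vector
reduction happens: MedianCD takes, per condition, the average over the
condition's samples of the per-sample median over the gene subset —
which makes MedianCD with all genes coincide exactly with conventional
Median normalization — while SVCD runs Standard-Vector normalization on
the g × c matrix of condition means.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .decomposition import ConditionMeanMatrix, compose, condition_means, split_by_condition
from .io import ExperimentDesign, NormalizationResult, filter_complete
from .novariation import anova_pvalues, select_novariation
from .baselines import median_offsets
from .standard_vector import sv_normalize

__all__ = ["CDConfig", "normalize_cd", "mediancd_converged", "variation_curve"]


@dataclass(frozen=True)
class CDConfig:
    """Configuration of a condition-decomposition normalization."""

    method: str = "svcd"  # "svcd" | "mediancd"
    ks_alpha: float = 0.001
    min_novariation: int = 100
    mediancd_tol_hard: float = 0.001  # 0.1% relative change in sd of factors
    mediancd_tol_soft: float = 0.10
    soft_run: int = 10
    extra_steps: int = 10
    sv_trim: float = 0.01
    sv_tol_hard: float = 0.01
    sv_tol_soft: float = 0.10
    sv_soft_run: int = 10
    sv_max_steps: int = 100
    max_outer_steps: int = 100
    novariation_override: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("svcd", "mediancd"):
            raise ValueError("method must be 'svcd' or 'mediancd'")
        if min(self.mediancd_tol_hard, self.mediancd_tol_soft, self.sv_tol_hard,
               self.sv_tol_soft) <= 0:
            raise ValueError("tolerances must be positive")
        if self.soft_run < 1 or self.extra_steps < 1:
            raise ValueError("soft_run and extra_steps must be >= 1")


def mediancd_converged(sd_history: Sequence[float], cfg: CDConfig) -> bool:
    """MedianCD outer-loop criterion on the sd of the between factors.

    True when the relative change of the standard deviation is below the
    hard tolerance, or below the soft tolerance for ``soft_run``
    consecutive steps; an exactly zero sd converges immediately.
    """
    if len(sd_history) < 1:
        return False
    if sd_history[-1] == 0:
        return True
    if len(sd_history) < 2:
        return False
    prev, cur = sd_history[-2], sd_history[-1]
    if prev == 0:
        return True
    if abs(cur - prev) / prev < cfg.mediancd_tol_hard:
        return True
    if len(sd_history) >= cfg.soft_run + 1:
        recent = sd_history[-(cfg.soft_run + 1):]
        rels = [
            abs(b - a) / a if a > 0 else 0.0
            for a, b in zip(recent[:-1], recent[1:])
        ]
        if all(r < cfg.mediancd_tol_soft for r in rels):
            return True
    return False


def _within_normalize(slices, cfg: CDConfig) -> tuple[pd.Series, list[dict]]:
    offsets = {}
    diagnostics = []
    for sl in slices:
        if cfg.method == "mediancd":
            w = median_offsets(sl.values)
            diagnostics.append({"phase": "within", "condition": sl.condition_id,
                                "method": "median", "iterations": 0})
        else:
            w, trace = sv_normalize(
                sl.values, trim_fraction=cfg.sv_trim, tol_hard=cfg.sv_tol_hard,
                tol_soft=cfg.sv_tol_soft, soft_run=cfg.sv_soft_run,
                max_steps=cfg.sv_max_steps,
            )
            diagnostics.append({
                "phase": "within", "condition": sl.condition_id, "method": "sv",
                "iterations": trace[-1].step, "status": trace[-1].status,
                "numerical_error": trace[-1].numerical_error,
                "statistical_error": trace[-1].statistical_error,
            })
        offsets.update(w.to_dict())
    return pd.Series(offsets, dtype=float), diagnostics


def _between_step(genes: pd.Index, b: pd.Series, mn: pd.DataFrame, cm: ConditionMeanMatrix,
                  d: ExperimentDesign, cfg: CDConfig) -> tuple[pd.Series, float]:
    """One full between-condition normalization restricted to ``genes``.

    Returns the zero-mean per-condition offset update relative to the
    current cumulative offsets ``b``, plus the statistical error of the
    estimate (NaN for the median method).
    """
    conds = list(b.index)
    if cfg.method == "mediancd":
        med = mn.loc[genes].median(axis=0)  # per-sample median over subset
        loc = pd.Series(
            {k: med[d.samples_of(k)].mean() - b[k] for k in conds}, dtype=float
        )
        delta = loc - loc.mean()
        return delta, float("nan")
    shifted = cm.means.loc[genes, conds] - b
    offs, trace = sv_normalize(
        shifted, trim_fraction=cfg.sv_trim, tol_hard=cfg.sv_tol_hard,
        tol_soft=cfg.sv_tol_soft, soft_run=cfg.sv_soft_run, max_steps=cfg.sv_max_steps,
    )
    return offs, trace[-1].statistical_error


def normalize_cd(m: pd.DataFrame, d: ExperimentDesign, cfg: CDConfig | None = None) -> NormalizationResult:
    """Full MedianCD or SVCD normalization of a complete matrix."""
    cfg = cfg or CDConfig()
    m = filter_complete(m)
    slices = split_by_condition(m, d)
    conds = [sl.condition_id for sl in slices]

    within, diagnostics = _within_normalize(slices, cfg)
    within_result = NormalizationResult(
        method=cfg.method, total=within.copy(), within=within,
        between=pd.Series(dtype=float),
    )
    cm = condition_means(slices, within_result)
    mn = m - within.reindex(m.columns)  # within-normalized sample-level data
    cond_of_col = np.array([d.condition_of[s] for s in mn.columns])

    override = None
    if cfg.novariation_override is not None:
        override = pd.Index([g for g in cfg.novariation_override if g in m.index])
        if override.empty:
            raise ValueError("novariation_override contains no gene of the matrix")

    b = pd.Series(0.0, index=conds)

    def reselect(current_b: pd.Series):
        pvals = anova_pvalues(
            mn - pd.Series(current_b[cond_of_col].to_numpy(), index=mn.columns), d
        )
        if override is not None:
            return pvals, frozenset(override)
        import warnings

        with warnings.catch_warnings():
            # the small-set warning is re-raised on the final set only
            warnings.simplefilter("ignore")
            sel = select_novariation(pvals, cfg.ks_alpha, min_genes=cfg.min_novariation)
        return pvals, frozenset(sel.gene_ids)

    # identify no-variation genes before the first between step: the raw
    # condition shifts are the (small) true normalization factors, while a
    # between step using all genes would inject the very bias the
    # no-variation detection exists to avoid.  If no uniform tail exists
    # at this stage, fall back to one all-genes step and retry.
    try:
        pvals, initial_set = reselect(b)
    except ValueError:
        delta, _ = _between_step(m.index, b, mn, cm, d, cfg)
        b = b + delta
        pvals, initial_set = reselect(b)
        diagnostics.append({"phase": "between", "step": 0,
                            "note": "all-genes fallback step"})
    genes = pd.Index(sorted(initial_set))
    sd_history: list[float] = []
    soft_count = 0
    converged = False
    extra_sets: list[frozenset] = []
    last_set = initial_set
    step = 0
    while step < cfg.max_outer_steps:
        step += 1
        delta, stat_err = _between_step(genes, b, mn, cm, d, cfg)
        b = b + delta
        pvals, new_set = reselect(b)
        num_err = float(np.linalg.norm(delta) / np.sqrt(len(conds)))
        sd_history.append(float(b.std(ddof=1)))
        diagnostics.append({
            "phase": "between", "step": step, "offset_sd": sd_history[-1],
            "numerical_error": num_err, "statistical_error": stat_err,
            "novariation_size": len(new_set),
        })
        if not converged:
            if cfg.method == "mediancd":
                converged = mediancd_converged(sd_history, cfg)
            else:
                if num_err < cfg.sv_tol_hard * stat_err:
                    converged = True
                elif num_err < cfg.sv_tol_soft * stat_err:
                    soft_count += 1
                    if soft_count >= cfg.sv_soft_run:
                        converged = True
                else:
                    soft_count = 0
            if converged:
                diagnostics[-1]["converged"] = True
        else:
            extra_sets.append(new_set)
            if len(extra_sets) >= cfg.extra_steps:
                break
        if new_set:
            last_set = new_set
        genes = override if override is not None else pd.Index(sorted(new_set))

    if extra_sets:
        final_set = frozenset.intersection(*extra_sets)
    else:
        final_set = last_set
    if not final_set:
        import warnings

        warnings.warn("intersection of no-variation sets is empty; "
                      "falling back to the last non-empty set")
        final_set = last_set
    final_genes = pd.Index(sorted(final_set))

    b_final, stat_err = _between_step(final_genes, pd.Series(0.0, index=conds), mn, cm, d, cfg)
    pvals = anova_pvalues(
        mn - pd.Series(b_final[cond_of_col].to_numpy(), index=mn.columns), d
    )
    diagnostics.append({
        "phase": "final", "novariation_size": len(final_genes),
        "statistical_error": stat_err,
    })

    partial = NormalizationResult(
        method=cfg.method, total=within.copy(), within=within,
        between=pd.Series(dtype=float),
        novariation_genes=tuple(final_genes),
        iterations=step, converged=converged, diagnostics=diagnostics,
        pvalues=pvals.pvalues, statistical_error=stat_err,
    )
    return compose(partial, b_final, d)


def variation_curve(m: pd.DataFrame, d: ExperimentDesign, cfg: CDConfig,
                    result: NormalizationResult, sizes: Sequence[int],
                    selection: str = "by_decreasing_p",
                    seed: int | None = None) -> pd.DataFrame:
    """Detected between-condition variation versus number of genes used.

    For each requested size ``k`` the final between step is redone with
    ``k`` genes — the top k by decreasing ANOVA p-value, or a uniform
    random subset — and the variation is measured as the standard
    deviation, across conditions, of the within-condition averages of
    the per-sample grand means of the normalized data.
    """
    if selection not in ("by_decreasing_p", "random"):
        raise ValueError("selection must be 'by_decreasing_p' or 'random'")
    m = filter_complete(m)
    slices = split_by_condition(m, d)
    conds = [sl.condition_id for sl in slices]
    within, _ = _within_normalize(slices, cfg)
    within_result = NormalizationResult(
        method=cfg.method, total=within.copy(), within=within,
        between=pd.Series(dtype=float),
    )
    cm = condition_means(slices, within_result)
    mn = m - within.reindex(m.columns)
    rng = np.random.default_rng(seed)
    if selection == "by_decreasing_p":
        if result.pvalues is None:
            raise ValueError("result carries no p-values; run normalize_cd first")
        ranked = result.pvalues.sort_values(ascending=False, kind="stable").index
    rows = []
    zero = pd.Series(0.0, index=conds)
    for k in sizes:
        if k > m.shape[0]:
            raise ValueError(f"requested {k} genes but matrix has {m.shape[0]}")
        if selection == "by_decreasing_p":
            genes = pd.Index(ranked[:k])
        else:
            genes = pd.Index(rng.choice(m.index.to_numpy(), size=k, replace=False))
        b_k, _ = _between_step(genes, zero, mn, cm, d, cfg)
        partial = NormalizationResult(
            method=cfg.method, total=within.copy(), within=within,
            between=pd.Series(dtype=float),
        )
        total = compose(partial, b_k, d).total
        grand = (m - total.reindex(m.columns)).mean(axis=0)  # per-sample grand mean
        cond_avg = [grand[d.samples_of(c)].mean() for c in conds]
        rows.append({"n_genes": int(k), "variation": float(np.std(cond_avg, ddof=1))})
    return pd.DataFrame(rows)
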