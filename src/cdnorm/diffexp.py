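"""Differential expression calling and benchmark metrics.

Calling uses per-gene two-sample Student t-tests (pooled variance by
default, Welch optional) on log2 values, with Benjamini–Hochberg
adjustment controlling the false discovery rate independently for each
treatment-versus-control comparison.  The evaluation metrics mirror the
simulation study: true positive rate (true positives / treatment
positives), FDR (false positives / detected positives, 0 when nothing is
detected), the balance statistic B (mean of a ±1 indicator over detected
DEGs: +1 over-expressed, −1 under-expressed), absolute fold-change
quartiles, and ROC points swept over the p-value thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExperimentDesign, apply_offsets
from .orchestrator import CDConfig, normalize_cd
from .baselines import median_normalize, quantile_normalize
from .simulate import GeneratorSpec, SyntheticTruth, generate

__all__ = [
    "ttest_treatment",
    "balance",
    "evaluate",
    "EvalReport",
    "benchmark_suite",
    "plot_rates_vs_balance",
]


@dataclass(frozen=True)
class EvalReport:
    """Per-treatment evaluation against generator truth."""

    tpr: float
    fdr: float
    balance: float  # NaN when nothing is detected
    n_detected: int
    n_true_positives: int
    n_false_positives: int
    n_treatment_positives: int
    fc_quartiles: tuple[float, float, float]  # |log2 FC| of detected DEGs
    roc: pd.DataFrame  # threshold sweep: fpr, tpr columns


def ttest_treatment(m: pd.DataFrame, d: ExperimentDesign, treatment: str,
                    control: str | None = None, *, fdr: float = 0.05,
                    equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test of a treatment against its control, per gene.

    ``m`` must already be normalized.  Returns a DataFrame with columns
    ``statistic, pvalue, adjusted_pvalue, log2fc, call``.  Degenerate
    genes (zero pooled variance) get p = 1 when the means agree and p = 0
    otherwise.
    """
    if control is None:
        control = d.control_of.get(treatment)
        if control is None:
            raise ValueError(f"no control recorded for treatment {treatment}")
    ts = d.samples_of(treatment)
    cs = d.samples_of(control)
    if len(ts) < 2 or len(cs) < 2:
        raise ValueError("both conditions need at least 2 replicates")
    xt = m[ts].to_numpy(dtype=float)
    xc = m[cs].to_numpy(dtype=float)
    res = stats.ttest_ind(xt, xc, axis=1, equal_var=equal_var)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    stat[~np.isfinite(stat)] = 0.0
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "statistic": stat,
            "pvalue": p,
            "adjusted_pvalue": adj,
            "log2fc": log2fc,
            "call": adj <= fdr,
        },
        index=m.index,
    )


def balance(table: pd.DataFrame) -> float:
    """Balance B of detected DEGs: +1 per over-, −1 per under-expressed.

    Returns NaN when no DEG is detected (the statistic is undefined).
    """
    detected = table[table["call"]]
    if detected.empty:
        return float("nan")
    return float(np.sign(detected["log2fc"]).mean())


def evaluate(table: pd.DataFrame, truth: SyntheticTruth, treatment: str, *,
             known_genes: pd.Index | None = None) -> EvalReport:
    """Confusion metrics of one treatment's calls against the truth.

    ``known_genes`` optionally restricts detected and treatment
    positives/negatives to a designated subset (the spike-in style of
    evaluation); by default all genes are used.
    """
    if known_genes is not None:
        table = table.loc[table.index.intersection(known_genes)]
    truth_pos = truth.de_indicator[treatment].reindex(table.index, fill_value=False).astype(bool)
    detected = table["call"]
    tp = int((detected & truth_pos).sum())
    fp = int((detected & ~truth_pos).sum())
    n_det = int(detected.sum())
    n_pos = int(truth_pos.sum())
    fc = table.loc[detected, "log2fc"].abs()
    quart = tuple(np.quantile(fc, [0.25, 0.5, 0.75])) if n_det else (np.nan,) * 3
    # ROC over the sorted unique p-values
    order = table["pvalue"].sort_values(kind="stable")
    pos_sorted = truth_pos.reindex(order.index).to_numpy()
    n_neg = len(table) - n_pos
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    roc = pd.DataFrame(
        {
            "threshold": order.to_numpy(),
            "tpr": tps / n_pos if n_pos else np.nan,
            "fpr": fps / n_neg if n_neg else np.nan,
        }
    )
    return EvalReport(
        tpr=tp / n_pos if n_pos else float("nan"),
        fdr=fp / n_det if n_det else 0.0,
        balance=balance(table),
        n_detected=n_det,
        n_true_positives=tp,
        n_false_positives=fp,
        n_treatment_positives=n_pos,
        fc_quartiles=quart,
        roc=roc,
    )


def _normalize(method: str, m: pd.DataFrame, d: ExperimentDesign,
               cfg: CDConfig | None = None) -> pd.DataFrame:
    if method == "median":
        return apply_offsets(m, median_normalize(m))
    if method == "quantile":
        return quantile_normalize(m)
    if method in ("mediancd", "svcd"):
        base = cfg or CDConfig()
        if base.method != method:
            from dataclasses import replace

            base = replace(base, method=method)
        return apply_offsets(m, normalize_cd(m, d, base))
    raise ValueError(f"unknown normalization method {method!r}")


def benchmark_suite(specs: list[GeneratorSpec], methods: list[str], reps: int,
                    seed: int, *, fdr: float = 0.05,
                    cfg: CDConfig | None = None) -> pd.DataFrame:
    """Simulate → normalize → call → evaluate over a grid.

    Returns one row per (scenario, replicate, method, treatment) with the
    drawn DEG fraction, balance, TPR and FDR — the raw material of the
    power/FDR-versus-balance figures.
    """
    rows = []
    rng = np.random.SeedSequence(seed)
    for si, spec in enumerate(specs):
        for rep, child in enumerate(rng.spawn(reps)):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            from dataclasses import replace

            m, d, truth = generate(replace(spec, seed=sub_seed))
            for method in methods:
                norm = _normalize(method, m, d, cfg)
                for trt in d.treatments:
                    table = ttest_treatment(norm, d, trt, fdr=fdr)
                    rep_eval = evaluate(table, truth, trt)
                    true_dir = truth.direction[trt]
                    n_de = int(truth.de_indicator[trt].sum())
                    true_b = (
                        float(true_dir[true_dir != 0].mean()) if n_de else float("nan")
                    )
                    rows.append({
                        "scenario": si,
                        "replicate": rep,
                        "method": method,
                        "treatment": trt,
                        "deg_fraction": float(truth.deg_fractions[trt]),
                        "true_balance": true_b,
                        "detected_balance": rep_eval.balance,
                        "tpr": rep_eval.tpr,
                        "fdr": rep_eval.fdr,
                        "n_detected": rep_eval.n_detected,
                    })
    return pd.DataFrame(rows)


def plot_rates_vs_balance(results: pd.DataFrame, path: str) -> None:
    """Plot TPR and FDR against the true balance of differential
    expression, one marker style per normalization method.

    ``results`` is the tidy frame produced by :func:`benchmark_suite`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for method, sub in results.groupby("method"):
        axes[0].scatter(sub["true_balance"], sub["tpr"], label=method, alpha=0.6, s=18)
        axes[1].scatter(sub["true_balance"], sub["fdr"], label=method, alpha=0.6, s=18)
    axes[0].set_ylabel("true positive rate")
    axes[1].set_ylabel("false discovery rate")
    axes[1].axhline(0.05, ls="--", c="gray", lw=1)
    for ax in axes:
        ax.set_xlabel("balance B of differential expression")
        ax.set_xlim(-1.05, 1.05)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
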