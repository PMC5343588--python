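"""Core data types and delimited-text I/O.

An expression matrix is a :class:`pandas.DataFrame` with genes as rows
(index = gene identifiers) and samples as columns (columns = sample
identifiers).  Values are background-corrected expression levels on the
log2 scale; ``NaN`` marks a missing measurement.  The experimental design
maps each sample to a condition and each treatment condition to its
control condition.

Normalization results are per-sample additive offsets (log2 units),
decomposed into a within-condition part (zero-sum inside each condition)
and a between-condition part (one value per condition).  The convention
throughout the package is that total offsets are centered so their mean
over all samples is zero, which preserves the global expression level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentDesign",
    "NormalizationResult",
    "read_expression",
    "write_expression",
    "read_design",
    "validate_matrix",
    "filter_complete",
    "apply_offsets",
    "write_result",
    "read_result",
]


class ParseError(ValueError):
    """Raised when a delimited input file fails validation."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample-to-condition map plus treatment-to-control pairing.

    Parameters
    ----------
    condition_of : dict
        Maps every sample id to exactly one condition id.
    control_of : dict
        Maps each treatment condition id to its control condition id.
        Controls either map to themselves or are absent.
    conditions : tuple
        Condition order used for reporting (defaults to first appearance).
    """

    condition_of: dict[str, str]
    control_of: dict[str, str] = field(default_factory=dict)
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        conds = list(dict.fromkeys(self.condition_of.values()))
        if self.conditions:
            missing = set(conds) - set(self.conditions)
            if missing:
                raise ValueError(f"conditions list misses {sorted(missing)}")
        else:
            object.__setattr__(self, "conditions", tuple(conds))
        counts = self.replicate_counts()
        bad = {k: v for k, v in counts.items() if v < 2}
        if bad:
            raise ValueError(
                "a minimum of two samples is required per experimental "
                f"condition; offending conditions: {bad}"
            )
        for trt, ctl in self.control_of.items():
            if trt not in self.conditions or ctl not in self.conditions:
                raise ValueError(f"control pairing {trt}->{ctl} references unknown condition")

    @property
    def samples(self) -> list[str]:
        return list(self.condition_of)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.condition_of.values():
            counts[c] = counts.get(c, 0) + 1
        return counts

    @property
    def treatments(self) -> list[str]:
        return [t for t, c in self.control_of.items() if c != t]


@dataclass
class NormalizationResult:
    """Per-sample offsets of a between-sample normalization.

    ``total[s] = within[s] + between[condition_of[s]]`` for the
    condition-decomposition methods, then centered to zero mean over all
    samples.  Baseline methods fill ``within`` with the centered totals
    and ``between`` with zeros.
    """

    method: str
    total: pd.Series
    within: pd.Series
    between: pd.Series
    novariation_genes: tuple[str, ...] = ()
    iterations: int = 0
    converged: bool = True
    diagnostics: list[dict] = field(default_factory=list)
    pvalues: pd.Series | None = None
    statistical_error: float = float("nan")

    def offset_of(self, sample: str) -> float:
        return float(self.total[sample])


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants, returning ``m`` unchanged."""
    if m.shape[0] < 1 or m.shape[1] < 2:
        raise ValueError(f"need at least 1 gene and 2 samples, got {m.shape}")
    if m.index.duplicated().any():
        dup = m.index[m.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene ids: {dup}")
    if m.columns.duplicated().any():
        dup = m.columns[m.columns.duplicated()].unique().tolist()
        raise ParseError(f"duplicate sample ids: {dup}")
    values = m.to_numpy(dtype=float)
    bad = ~(np.isfinite(values) | np.isnan(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(f"non-finite value at gene {m.index[i]}, sample {m.columns[j]}")
    return m


def read_expression(path: str | Path, *, sep: str | None = None, linear: bool = False) -> pd.DataFrame:
    """Read a genes × samples expression matrix from delimited text.

    First column holds gene ids, header row holds sample ids.  TSV is the
    default dialect; comma is auto-detected.  Empty cells become NaN
    (missing).  With ``linear=True`` values are log2-transformed on read.
    """
    path = Path(path)
    if sep is None:
        header = path.open().readline()
        sep = "," if ("," in header and "\t" not in header) else "\t"
    try:
        m = pd.read_csv(path, sep=sep, index_col=0)
    except ValueError as exc:  # ragged or non-numeric rows
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    m.index.name = None
    m.columns.name = None
    try:
        m = m.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell in {path}: {exc}") from exc
    if linear:
        m = np.log2(m)
    return validate_matrix(m)


def write_expression(m: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    m.to_csv(path, sep=sep, index_label="gene_id")


def read_design(path: str | Path, *, sep: str | None = None) -> ExperimentDesign:
    """Read a design table with columns sample_id, condition_id and an
    optional control_condition_id (stated per-sample on treatment rows)."""
    path = Path(path)
    if sep is None:
        header = path.open().readline()
        sep = "," if ("," in header and "\t" not in header) else "\t"
    t = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "condition_id"}
    if not required.issubset(t.columns):
        raise ParseError(f"design needs columns {sorted(required)}, got {list(t.columns)}")
    if t["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in design")
    condition_of = dict(zip(t["sample_id"], t["condition_id"]))
    control_of: dict[str, str] = {}
    if "control_condition_id" in t.columns:
        for cond, ctl in zip(t["condition_id"], t["control_condition_id"]):
            if isinstance(ctl, str) and ctl:
                prev = control_of.setdefault(cond, ctl)
                if prev != ctl:
                    raise ParseError(f"conflicting controls for condition {cond}")
    return ExperimentDesign(condition_of=condition_of, control_of=control_of)


def write_design(d: ExperimentDesign, path: str | Path, *, sep: str = "\t") -> None:
    rows = [
        {
            "sample_id": s,
            "condition_id": c,
            "control_condition_id": d.control_of.get(c, ""),
        }
        for s, c in d.condition_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def filter_complete(m: pd.DataFrame) -> pd.DataFrame:
    """Keep only genes measured in all samples, preserving order."""
    keep = m.notna().all(axis=1)
    if not keep.any():
        raise ValueError("no gene is complete in all samples")
    return m.loc[keep]


def apply_offsets(m: pd.DataFrame, r: NormalizationResult) -> pd.DataFrame:
    """Subtract each sample's total offset from its column."""
    missing = [s for s in m.columns if s not in r.total.index]
    if missing:
        raise ValueError(f"result lacks offsets for samples {missing}")
    return m - r.total.reindex(m.columns)


def write_result(r: NormalizationResult, path: str | Path) -> None:
    """Write offsets as delimited text plus a JSON sidecar with the
    no-variation gene ids, diagnostics and convergence state."""
    path = Path(path)
    rows = pd.DataFrame(
        {
            "sample_id": r.total.index,
            "within": r.within.reindex(r.total.index).to_numpy(),
            "total": r.total.to_numpy(),
        }
    )
    rows.to_csv(path, sep="\t", index=False)
    sidecar = {
        "method": r.method,
        "between": {str(k): float(v) for k, v in r.between.items()},
        "novariation_genes": list(r.novariation_genes),
        "iterations": int(r.iterations),
        "converged": bool(r.converged),
        "diagnostics": r.diagnostics,
        "statistical_error": None
        if np.isnan(r.statistical_error)
        else float(r.statistical_error),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_result(path: str | Path) -> NormalizationResult:
    path = Path(path)
    rows = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    meta = json.loads(Path(str(path) + ".json").read_text())
    total = pd.Series(rows["total"].to_numpy(), index=rows["sample_id"], name="total")
    within = pd.Series(rows["within"].to_numpy(), index=rows["sample_id"], name="within")
    between = pd.Series(meta["between"], dtype=float)
    err = meta.get("statistical_error")
    return NormalizationResult(
        method=meta["method"],
        total=total,
        within=within,
        between=between,
        novariation_genes=tuple(meta["novariation_genes"]),
        iterations=meta["iterations"],
        converged=meta["converged"],
        diagnostics=meta["diagnostics"],
        statistical_error=float("nan") if err is None else float(err),
    )
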