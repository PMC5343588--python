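# cdnorm — variation-preserving between-sample normalization

`cdnorm` normalizes gene expression matrices (microarray or RNA-Seq, in
log2 scale) **without assuming that most genes are non-differentially
expressed**. Conventional between-sample methods — Median, Quantile, and
the RNA-Seq scaling family (TMM, DESeq, RPKM) — estimate each sample's
technical offset from all genes, which silently removes biological
variation whenever differential expression is widespread or unbalanced
between over- and under-expression, shrinking fold changes and breaking
FDR control in downstream tests. This package implements the two
condition-decomposition methods that avoid the assumption, **MedianCD**
and **SVCD** normalization, together with Median/Quantile baselines, a
synthetic-data generator with known ground truth, and power/FDR
evaluation utilities. It is written for transcriptomics analysts and
methodologists benchmarking normalization.

## The model

In log2 scale the observed expression of condition *k* is
`Y^(k) = X^(k) + 1 a^(k)ᵀ`, one additive offset per sample. The problem
decomposes exactly into per-condition **within** normalizations of the
replicates (where no gene varies, so all genes can be used) and a single
**between** normalization of the condition means — the only step exposed
to the lack-of-variation assumption. That step is restricted to
*no-variation genes*: the largest upper tail of the per-gene one-way
ANOVA p-values consistent with uniformity under a one-sided
Kolmogorov–Smirnov test (α = 0.001), re-identified iteratively as the
normalization improves.

Each normalization step uses medians (MedianCD) or the **standard-vector
estimator** (SVCD): each gene's replicate vector, centered and scaled to
unit norm, lies on the unit (s−2)-sphere in the zero-sum hyperplane;
exchangeability of correctly normalized samples forces the mean standard
vector to zero, and the distribution-free iterate
`offsets ← offsets + scale · mean(standard vector)` converges to that
fixed point with a statistical error that shrinks as g^(−1/2). See
`docs/methods.md` for the full account.

## Worked example

The estimators follow the scikit-learn transformer protocol over a
genes × samples DataFrame (fit learns per-sample offsets, transform
applies them):

```python
import numpy as np
from cdnorm import (GeneratorSpec, SVCDNormalizer, MedianNormalizer,
                    generate, ttest_treatment, evaluate)

# unbalanced differential expression: ~50% DEGs, 90% of them over-expressed
spec = GeneratorSpec(g=4000, n_treatments=6, n_controls=6, n_replicates=5,
                     deg_fraction_range=(0.4, 0.6), p_over=(0.9, 0.9, 0.9),
                     seed=5)
expr, design, truth = generate(spec)

for name, est in [("Median", MedianNormalizer()), ("SVCD", SVCDNormalizer())]:
    normalized = (est.fit(expr) if name == "Median"
                  else est.fit(expr, design=design)).transform(expr)
    fdr, tpr = [], []
    for trt in design.treatments:
        rep = evaluate(ttest_treatment(normalized, design, trt, fdr=0.05),
                       truth, trt)
        fdr.append(rep.fdr); tpr.append(rep.tpr)
    print(f"{name:>6}: mean TPR={np.mean(tpr):.2f}  mean FDR={np.mean(fdr):.3f}")

svcd = SVCDNormalizer().fit(expr, design=design)
print(f"SVCD found {len(svcd.novariation_genes_)} no-variation genes "
      f"in {svcd.n_iter_} iterations (converged: {svcd.converged_})")
rmse = float(np.sqrt(((svcd.offsets_ - truth.true_offsets) ** 2).mean()))
print(f"offset recovery RMSE: {rmse:.3f} log2 units "
      f"(statistical error: {svcd.statistical_error_:.3f})")
```

prints

```
Median: mean TPR=0.29  mean FDR=0.216
  SVCD: mean TPR=0.54  mean FDR=0.023
SVCD found 446 no-variation genes in 22 iterations (converged: True)
offset recovery RMSE: 0.043 log2 units (statistical error: 0.060)
```

Median normalization absorbs the one-sided expression shift into its
offsets: its false discovery rate (0.216) is four times the nominal 5%
bound and it misses almost half of the true DEGs that SVCD finds. SVCD
keeps the FDR at the bound (0.023 ≤ 0.05) because its between step uses
only the 446 genes it could not distinguish from non-varying ones, and
it recovers the injected per-sample offsets to 0.04 log2 units — within
its own error estimate.

A thin CLI mirrors the library:

```sh
cdnorm simulate --genes 5000 --treatments 12 --controls 12 --seed 1 --out sim
cdnorm normalize --method svcd --data sim.expr.tsv --design sim.design.tsv --out norm
cdnorm diffexp --data norm.normalized.tsv --design sim.design.tsv --out de
```

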