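# Methods

## The normalization problem

Between-sample normalization corrects the per-sample technical scale
factor that both microarrays and RNA-Seq introduce when each sample's
total mRNA/cDNA mass is equalized during the assay. In the usual log2
scale the observed data of condition *k* are

    Y^(k) = X^(k) + 1 a^(k)ᵀ ,

with `X` the true expression (genes × samples) and `a^(k)` one additive
offset per sample. Median, Quantile, and the RNA-Seq scaling methods
(TMM, DESeq, RPKM) estimate `a` from all (or most) genes, which is only
valid when most genes do not change between conditions — the
*lack-of-variation assumption*. When differential expression is
widespread and unbalanced between over- and under-expression, those
estimators absorb the biological signal into the offsets: variation is
removed, fold changes shrink, and the false discovery rate (FDR) of
downstream tests is no longer controlled.

## Condition decomposition

Splitting each sample vector into its mean and residual parts decomposes
the problem exactly and linearly into

1. one **within-condition** normalization per condition, acting on the
   zero-sum (residual) part of the offsets — no gene varies between
   replicates of one condition, so all genes can be used; and
2. one **between-condition** normalization of the condition means,
   acting on one offset per condition.

Only step 2 is exposed to the lack-of-variation assumption, and the
package avoids it there by restricting the step to *no-variation genes*
(below). The grand mean is unidentifiable; the package fixes it by
centering total offsets to zero mean over all samples, which preserves
the global expression level. Totals therefore satisfy
`total(s) = within(s) + between(condition(s))` with within-offsets
summing to zero inside each condition.

Two estimators perform the individual normalization steps:

**Median step.** Per-sample medians, centered. For the between step the
per-condition offset is the average over the condition's samples of the
per-sample median over the gene subset. With the subset forced to all
genes this reproduces conventional Median normalization *exactly* (an
identity the test suite asserts to 1e-12); the median-of-condition-means
variant would not have this property, which is why the sample-median
average was chosen.

**Standard-vector step.** The replicate values of gene *j* form an
*s*-vector; after mean subtraction and scaling to unit norm these
*standard vectors* lie on the unit (s−2)-sphere inside the zero-sum
hyperplane. Exchangeability of correctly normalized replicates implies
the standard-vector distribution has zero mean, so a residual offset
tilts the empirical mean vector toward (the centered part of) the
offset. The iterate

    offsets ← offsets + scale · mean(standard vectors),

with `scale` the median residual norm of retained genes, has exactly
that zero-mean condition as its fixed point, is first-order exact for
small offsets, and bounds each gene's influence (unit vectors), making
it robust and distribution-free. Per step the 1% most extreme residual
variances are trimmed (symmetric two-sided by default, 0.5% per tail;
the one-sided variant is available) and zero-variance genes are always
excluded. The statistical error of the estimate is the standard error
of the mean standard vector under gene independence, mapped to log2
units: `scale · ‖componentwise sd‖ / √g`. Iteration stops when the
per-step offset change (`‖u‖/√s`) falls below 1% of the statistical
error, or below 10% of it for 10 consecutive steps, with a default cap
of 100 steps; hitting the cap flags the result as non-converged rather
than masking it. For s = 2 the sphere degenerates to two points and the
fixed point is the median log-difference correction — the degenerate
global-Loess case, agreeing with the mean log-difference for symmetric
noise.

## No-variation genes

A no-variation gene shows no evidence of differential expression under
a per-gene one-way fixed-effects ANOVA across all conditions (F with
c−1 and N−c degrees of freedom, computed on offset-adjusted data;
degenerate all-equal genes get p = 1). Rather than assuming a fraction
of non-differentially expressed genes, the selection makes one search in
p-value space: genes are sorted by p, and candidate thresholds p₀ are
scanned from the largest upper tail {p ≥ p₀} downward. Each tail is
rescaled to u = (p − p₀)/(1 − p₀) — uniform on [0,1] under the null —
and tested with a one-sided Kolmogorov–Smirnov test using
D⁺ = sup(F̂ − F), the direction sensitive to the excess of small
p-values that contaminating DEGs produce. The largest tail not rejected
at α = 0.001 is the no-variation set. The scan is evaluated exactly for
every candidate threshold, block-vectorized; candidates are pre-screened
with the refined one-sided asymptotic `P ≈ exp(−(6md+1)²/(18m))`
(accurate to <5% at m = 100, <1% beyond 300) at level α/2, and the
exact Smirnov probability decides at the boundary. A floor of 100
selected genes is enforced, with a warning below 500 — offset estimation
needs several hundred genes to be useful. Ties in p are broken by gene
id, so the result does not depend on input order.

## MedianCD and SVCD

Both condition-decomposition methods proceed identically, differing only
in the step estimator (median vs standard vector):

1. within-condition normalization of every condition, all genes;
2. identification of no-variation genes on the within-normalized data,
   then an iterated loop: between-normalize the condition means
   restricted to the current set, re-run the ANOVA on offset-adjusted
   data, re-select the set;
3. after the convergence criterion first holds, 10 further iterations
   are run and their sets intersected;
4. a final between-condition normalization from scratch on the
   intersected set, followed by composition and global centering.

The identification deliberately precedes the first between step: the
raw condition shifts are the (typically small) technical offsets,
whereas an initial all-genes between step would inject exactly the
DE-driven bias the method exists to avoid — under strongly unbalanced
differential expression that bias destroys the p-value uniformity the
selection needs. If the initial identification finds no uniform tail,
one all-genes step is applied as a fallback and identification is
retried; a selection failure after that propagates as an error, because
the data then genuinely lack a usable no-variation population.

Convergence: MedianCD requires the relative change of the standard
deviation of the between factors to drop below 0.1%, or below 10% for
10 consecutive steps (an exactly zero sd converges immediately); SVCD
compares the outer step's numerical error `‖Δb‖/√c` with the
standard-vector statistical error using the same 1% / 10%-for-10 rule.
A 30% soft tolerance (useful for particularly ill-behaved data) is
available as a configuration override, not a default. An empty
intersection falls back to the last non-empty set with a warning. The
orchestrator contains no randomness; results are deterministic given
the input.

## Synthetic data generator

The generator emulates the simulation study's construction: independent
per-gene normal variates in log2 scale, a design of T treatments sharing
C controls (round-robin pairing) with n replicates each, per-treatment
DEG fractions drawn log-uniformly, a dataset-wide never-DE reserve, DEG
effects equal to `effect_scale ×` the gene's variance, treatment-level
direction classes, and injected per-sample offsets. Defaults, all
overridable:

| parameter | default | rationale |
|---|---|---|
| DEG fraction range | [0.9%, 90%], log-uniform per treatment | the study's stated range |
| never-DE reserve | 10% of genes | the study's stated reserve |
| effect rule | difference = 2 × variance | the literal stated rule; a `sd` option (2 × σ) is provided because the literal rule is dimensionally odd |
| direction classes | thirds: mostly-over / mostly-under / balanced, assigned round-robin so small T keeps exact thirds | stated class structure; round-robin keeps it exact |
| p(over) per class | 0.9 / 0.1 / 0.5 | the exact probabilities are not printed; these match the near ±1 balance values reported |
| gene means | N(8, 2²) log2 | typical microarray intensity range |
| gene sd | lognormal, median 1.0, log-sd 0.3 | the study drew per-gene variances from its real dataset (not redistributable); the median is inferred from the printed fold-change scale — effects are twice the variance and the median detected fold change exceeds 2-fold (1 log2) for two thirds of treatments, giving 2σ² ≈ 1 |
| sample offsets | N(0, 0.2²), centered | modest technical scale factors; real offsets can be supplied explicitly |

The never-DE reserve is exact: after the per-treatment draws, any
non-reserved gene untouched by every treatment is swapped into a random
treatment in place of a gene that is covered at least twice, so
per-treatment DEG counts are preserved and the all-treatment negatives
equal the reserve exactly. `generate_null_like` mirrors the null-dataset
construction from a reference matrix (per-gene means and variances, no
condition structure, injected offsets).

What the generator does **not** emulate: gene–gene correlation,
intensity-dependent (non-linear) effects, missing values, count noise
(RNA-Seq), or batch structure. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to those real-data complications.

## Differential expression and evaluation

DE calling uses per-gene two-sample Student t-tests (pooled variance by
default — classic small-replicate microarray practice; Welch available)
with Benjamini–Hochberg adjustment at a 5% bound, independently per
treatment/control comparison. The study's empirical-Bayes moderated
test is intentionally out of scope; plain t-tests are reported to give
very similar comparative results at lower absolute power. Evaluation
computes, per treatment: TPR (true positives / treatment positives),
FDR (false positives / detected positives, 0 when nothing is detected),
the balance B (mean ±1 indicator over detected DEGs), absolute
fold-change quartiles, and ROC points over the p-value sweep, optionally
restricted to a designated known-gene subset (spike-in style).

## Numerical choices and scales

* Degenerate tests: zero within- and between-variance → p = 1; zero
  variance with a mean difference → p = 0, flagged.
* All tie-breaks (trimming, p-value sorting) are stable on gene id.
* The acceptance script and heavy tests use scaled-down problem sizes —
  5,000–10,000 genes, 12–42 treatments, 10 or 5 replicate datasets —
  chosen so each quantity's Monte-Carlo error is small relative to the
  effect being measured.
* The purity of the detected no-variation set is bounded above by the
  fraction of DEGs whose effects are statistically invisible to the
  ANOVA (genes in the low tail of the variance distribution have effects
  2σ² ≪ σ); measured purity is therefore sensitive to the left tail of
  the variance meta-model, which real datasets fix empirically.

## Known limitations

Only flat single-factor designs are supported (no multi-factor or
paired structures). The matrix must be complete for CD normalization;
`filter_complete` is applied and logged. Conditions need at least two
replicates, and normalization quality degrades below several hundred
no-variation genes. Very few conditions (c ≤ 6) concentrate any
between-offset estimation error into few ANOVA degrees of freedom,
which can make the no-variation search fail under extreme unbalanced
differential expression — surfaced as an error rather than a silently
wrong result.
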