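# Methods

## Scope and model

`comboseq` analyses a two-drug-combination bulk RNA-seq design downstream
of quantification: inputs are a genes × samples integer count matrix, a
sample sheet (cell line, condition, replicate) and a GMT pathway
annotation.  Read-level processing (QC, trimming, alignment, counting) and
identifier mapping are out of scope.  Contrasts are always one treatment
condition against the matched vehicle control within a single cell line.

### Differential expression

Counts follow a negative binomial with the quadratic mean–variance law
`Var = mu + alpha * mu^2`; this parameterisation is fixed once and used
identically by the simulator and the test.  The per-gene model is a
two-group log-link GLM with size-factor offsets:

    log mu_gj = log s_j + beta0_g + beta1_g * x_j .

* **Size factors** are median-of-ratios: reference genes are those with no
  zero count, and `s_j = median_g (y_gj / geomean_g)`.  A single sample
  gets `s = 1`.  If *every* gene contains a zero, a fallback restricted to
  each gene's positive entries is used (it can be disabled, in which case
  the condition is reported as an explicit error).
* **Dispersion** is estimated by gene-wise method of moments on normalised
  counts, `alpha_g = (s^2 - mean) / mean^2`, pooled across all groups with
  at least two replicates by degrees of freedom.  By default the estimate
  is shrunk halfway toward a mean–dispersion trend `a0 + a1/mu` fitted to
  decile-binned means of the (unclipped) gene-wise values; the midpoint
  uses the unclipped values so that the clip-at-zero does not bias the
  shrunk estimate upward.  Estimates are floored at `1e-8`.  Estimating
  dispersion from **all conditions of a cell line** (rather than the two
  contrasted groups alone) is the pipeline default: it doubles the residual
  degrees of freedom and visibly tightens Wald calibration.
* **Fitting** is iteratively reweighted least squares, vectorised across
  genes, with working weights `mu / (1 + alpha * mu)`.  Iteration stops at
  a relative deviance change ≤ 1e-8 *or* a parameter step ≤ 1e-10
  (whichever first, per gene), with a 100-iteration cap; non-converged
  genes keep their estimate but get a missing p-value and are excluded
  from the BH denominator.  In the Poisson limit (`alpha = 0`) the fitted
  fold change equals the log2 ratio of size-factor-weighted group means
  exactly; the suite checks agreement to better than 10 significant digits
  and cross-checks the p-value against an independent Poisson-GLM
  likelihood fit.
* **Degenerate genes.** All-zero genes are flagged `filtered_all_zero`,
  carry no p-values and do not enter the BH denominator.  Genes all-zero
  in exactly one group cannot be fitted (the MLE diverges); they receive a
  finite point estimate by adding a 0.5 pseudocount to both group totals,
  a Wald test evaluated at that estimate, and a `separated` flag.
* **Multiple testing** is Benjamini–Hochberg step-up, implemented
  in-package and verified against a brute-force evaluation of
  `min_{j>=rank} p_(j) * m / j`.
* **DEG calling** uses inclusive thresholds (`p <= alpha`,
  `|log2FC| >= cutoff`), defaults `alpha = 0.05` on the **adjusted** p and
  `|log2FC| >= 1.0`.  Whether the significance gate refers to raw or
  adjusted p is genuinely ambiguous in this kind of protocol description;
  adjusted is the common reporting convention and is the default, with a
  raw-p mode available (`p_column="raw"`).

The estimator intentionally omits Cox-Reid adjustment, MAP dispersion
shrinkage, independent filtering and outlier replacement.  Its guarantees
are therefore its own contracts — Poisson-limit exactness, BH agreement,
and null calibration (fraction of raw p < 0.05 within [0.03, 0.07] on
pure-null triplicate simulations, pooled over seeds) — not numerical
equality with any heavier reference implementation.

A caveat worth knowing: because the GLM weights libraries by depth, size
factors absorb depth changes *exactly* only in the equal-weight limit.
Rescaling every library leaves fold changes essentially untouched;
rescaling a single library moves each fold change by a fraction of its
standard error (the suite bounds this at < 1 se, mean < 0.05 log2 units).

### Combination set algebra

Exclusivity is defined on significance status, not fold-change magnitude:
`exclusive(combo) = DEG(combo) \ (DEG(monoA) ∪ DEG(monoB))`, mirroring
Venn-diagram logic.  *Enhanced* regulation requires significance in both
contrasts, equal fold-change sign, and strictly larger magnitude under the
combination — ties and sign flips do not count, since "stronger
deregulated" leaves those cases open and the strict reading is the
conservative one.  Fold-change ranges are reported over the DEG set (with
the thresholds recorded); an empty DEG set yields an explicit empty range
rather than an exception.  Top-k signatures (k = 20 by default) rank the
combination's DEGs by |log2FC| with deterministic tie-breaks
(|log2FC| desc, p asc, gene id asc) and annotate each gene with both mono
fold changes, an exclusivity flag and an enhancement flag.

### Pathway over-representation

Selection gates for enrichment are raw `p <= 0.05` and `|log2FC| >= 1.25`
per direction (the protocol quotes these gates without adjustment, so raw
is the default; configurable).  The universe is the set of tested
(non-all-zero) genes of the contrast — an expression-aware background —
rather than the whole annotation.  Each pathway is intersected with the
universe; the statistic is the hypergeometric upper tail `P(X >= k)`
(scipy's stable survival function; verified against exact rational
enumeration to ≤ 1e-12 for all N ≤ 25).  "Affected genes > 5" is read
strictly as `k >= 6`.  Records failing the gates are dropped *before*
ranks are assigned; rankings are per direction, ordered by
(p asc, k desc, name asc) — the ordering key is not dictated by the
protocol, so an alternative (k desc, p asc) remains configurable — and
truncated to the top 50.

The combination-specificity rule: a (pathway, direction) qualifies when
the combination ranks it ≤ 20 (`top_in`) and each mono ranking either
omits it or ranks it strictly beyond 30 (`top_out`); unranked monos count
as excluded.  Because the inclusive/exclusive reading of the mono gate is
ambiguous exactly at rank 30, rows failing *only* through a mono rank of
exactly `top_out` are flagged `boundary` rather than silently dropped.
Applied to the 14 reference rank triplets shipped with the acceptance
script, the literal rule admits 13 and flags the single rank-30 row as the
boundary case.

### Rank–rank overlap

The published notion of a rank–rank matrix is cited without formulas, so
the module fixes a minimal, testable variant and documents it as an
interpretation: the top-n (default 100) significant genes of each contrast
are ranked by |log2FC|; for every pair of cutoffs on a step-10 grid the
prefix overlap `k_ij` is scored by `-log10 P(X >= k_ij)` under
hypergeometric(N, i, j) with N the number of tested genes, capped at 300.
One-sided enrichment only; up- and down-regulated lists can be compared
separately; no four-quadrant variant and no permutation correction.

## The synthetic generator

The generator emulates the study design: two cell lines × five conditions
(control, two mono agents, each agent + inhibitor) × 3 replicates, with
~22 000 genes at full scale.  Genes belong to planted classes — null,
monoA_only, monoB_only, shared, comboA_exclusive, comboB_exclusive,
enhanced — apportioned by largest remainder so class counts are exact.
Mono effects *carry into* the matching combination (the drug is still
present there); combination-exclusive genes respond only under their
combination; enhanced genes get `lfc = ±1.5` under one mono and `±2.5`
(same sign) under its combination, mirroring the reported pattern of
histone repression deepening under the combined exposure.  Signs are
random per gene; the default planted |log2FC| is 2.

Baselines are log-normal (median 100, log-sd 1.0) and per-sample size
factors are jittered log2-uniformly in ±0.2 — enough to exercise
normalisation without dominating signal.  Counts are NB draws under the
same `Var = mu + alpha mu^2` law the test assumes, dispersion 0.1 by
default.  Since no library sizes or dispersions are published for the
original data, these defaults are chosen for testability, not fidelity.
Pathways are emitted as GMT: one pathway per planted class seeded at
configurable purity (default 1.0, 20 members) plus uniform background
pathways.

**What passing means.**  Recovery results (combination-exclusive
sensitivity/precision ≥ 0.8, planted-pathway qualification, null
specificity) show the pipeline is *internally consistent*: it recovers
structure generated under its own model at realistic depths.  They do not
certify behaviour under features the generator omits — batch effects,
gene–gene correlation, isoform structure, outlier samples, or
misspecified mean–variance relationships.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (`numpy` Generator
seeded per purpose), and identical seeds give bit-identical counts,
pathways and reports; `summary.json` deliberately echoes thresholds but
not file paths so repeated runs are byte-comparable.  The test and
acceptance simulations use 500–2000 genes and five seeds per claim —
large enough for the binomial tolerances asserted, small enough that the
whole suite runs in well under a minute — while the generator's full-scale
defaults (22 000 genes, two cell lines) remain the package defaults.

## Known limitations

* Two-group contrasts only: no multi-factor designs, batch covariates or
  shrunken fold-change estimators.
* Wald calibration at n = 3 rests on asymptotic normality plus estimated
  dispersions; the null tail is measurably near the upper edge of its
  tolerance band, which is why dispersion pooling across conditions is
  the default.
* No formal synergy scoring (Bliss/Loewe/HSA); the set algebra
  characterises additivity qualitatively.
* Gene identifiers are matched as exact strings between counts and GMT;
  no aliasing or ID mapping.
* The heatmap export is a plain unclustered image.
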