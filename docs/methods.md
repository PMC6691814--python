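# Methods

This note records the models, parameter choices and numerical conventions
behind `rbpnet`, and what the synthetic-data checks do and do not show
about real data.

## Differential expression

**Model.** Counts are negative binomial: for gene g in sample j of group r,
E[c_gj] = s_j q_g 2^(β_gr) and Var = μ + α_g μ². Size factors s_j are
median-of-ratios: the median over all-positive genes of c_gj divided by the
gene's geometric mean across samples. Genes with counts below 10 in every
sample are removed first.

**Dispersion.** α_g is estimated by method of moments on normalized counts,
(s² − m)/m² per group, pooled across groups weighted by degrees of freedom
and floored at 10⁻⁸. With 4 replicates per group this estimator is very
noisy (3 degrees of freedom), which makes a plug-in Wald test
anti-conservative: on null simulations (2,000 genes, 4 vs 4, α = 0.1) the
raw p-values were visibly non-uniform (mean KS statistic 0.054) and about
1.2% of genes reached padj ≤ 0.05. The test therefore moderates each
gene's dispersion 50/50 toward the across-gene mean before computing
standard errors — a deliberately simple empirical-Bayes-style shrinkage in
the spirit of the dispersion sharing that dedicated DE packages perform.
With it, the same null simulations give a mean KS statistic of ~0.024 and
a padj ≤ 0.05 fraction of ~4 × 10⁻⁴, while sensitivity for planted
|log₂FC| = 2 effects stays ~0.89. The moderation weight is a `fit`
parameter (`dispersion_moderation`, default 0.5; 0 recovers the raw
estimator).

**Wald test.** On normalized group means m_ref, m_test:
log₂FC = log₂((m_test + c)/(m_ref + c)) with pseudocount c = 0.5 (this
makes swapping the contrast exactly negate the estimate). The variance of
each group mean follows the NB law propagated through the size factors,
Var(m) = n⁻² Σ_j (m/s_j + α m²), and the delta method gives the SE of the
log ratio. P-values are two-sided normal; adjustment is Benjamini–Hochberg
(via statsmodels), verified in the tests against a brute-force step-up
implementation written from the definition.

**Selection and clustering.** DE calls use |log₂FC| ≥ 1.5 and padj ≤ 0.05
with *inclusive* boundaries, applied uniformly. Expression-pattern clusters
come from average-linkage hierarchical clustering (Euclidean distance) of
row-z-scored shifted-log expression, with the tree cut to exactly k
clusters and labels renumbered by decreasing size (ties by smallest gene
identifier) for reproducibility.

**Shifted log instead of rlog.** The regularized-log transform of dedicated
DE packages shrinks per-gene scatter with an empirical-Bayes prior. Here
log₂(count/size factor + 1) is used instead: the transform only feeds PCA,
correlation and visualization-style summaries, where the shifted log
preserves the needed structure, and it keeps the pipeline free of iterative
fitting. This is a known, deliberate simplification.

## Co-expression modules

Pairwise Spearman correlation (average ranks for ties, p from the
t-approximation) over the RBP-restricted expression matrix; constant genes
get ρ = 0 against everything and are flagged. Modules are the k branches of
an average-linkage tree on distance 1 − ρ; the cut height is reported
alongside. k defaults to 4 for the normal-differentiation design and 2 for
the leukemic design — in the source analysis module boundaries were chosen
visually from a clustered heat map, so exact module membership is not a
reproduction target; the tree cut makes the choice explicit and testable.
Correlation p-values are computed but modules are defined by clustering
alone.

Per-module cell-state contrasts pool all (gene, sample-in-group) values and
use the two-sided Wilcoxon rank-sum test: exact enumeration when the pooled
size is ≤ 20 and tie-free, the tie-corrected normal approximation
otherwise (the two routes agree within 0.01 around the switchover in the
test suite). Sample-level structure is a full PCA on gene-centered data
with samples as observations (variance ratios sum to 1) and a sample ×
sample Spearman matrix in dendrogram leaf order. UpSet-style set summaries
report the size of every exclusive membership region, which sum exactly to
the union size.

## Shortest-path PPI network and hubs

The PPI is built from a STRING-dialect edge list after canonicalization
(undirected, self-edges dropped, duplicate records collapsed keeping the
maximum combined score — an edge passes the filter if any record passes)
and filtered to combined score ≥ 500. Expression lives on genes and the
graph on proteins; the gene↔protein map is an explicit input, never
inferred. A gene stamps its DE record onto all of its proteins; when
several genes map to one protein the smallest adjusted p wins (conservative
for path retention; conflicts are logged). Unmapped proteins are marked
non-significant and can never survive path filtering.

Paths are *hop-count* shortest paths between every unordered pair of RBP
proteins, enumerated from BFS predecessor maps on the **full** filtered
graph; the significance filter (every node padj ≤ α, endpoints and
intermediates alike, RBP or not) is applied **afterwards** — the two orders
differ, and this is the order implemented. "All shortest paths" can explode
combinatorially, so enumeration per pair is capped (default 100, `None`
for exhaustive; truncations are counted and reported). Path output is
canonicalized (smaller endpoint first, sorted list), making results
independent of graph build order.

The union of retained paths defines the analysis network. Hubs are nodes
with degree at or above the nearest-rank 90th percentile of the union
network's degree multiset (the ⌈0.9·n⌉-th smallest degree; all ties at the
threshold included). Non-RBP intermediates are eligible as hubs and are
reported separately in the class breakdown. The low/high expression split
of hub genes uses the first/third quartiles (linear interpolation,
boundaries inclusive) of per-gene mean expression across the contrast's
samples, with a per-gene Wilcoxon rank-sum test flagged at p < 0.05.

The whole chain is verified against an exhaustive oracle that enumerates
all simple paths of minimum length on small random graphs and agrees
exactly (node sets, edge sets, degrees) on hundreds of cases.

## Synthetic data generator

The generator emulates the study design the pipeline targets: six cell
states (HSC, CMP, GMP, monocyte n = 4 each; LSC n = 8; blast n = 11), a
2,000-gene universe with a 400-gene RBP subset (classes assigned
round-robin over the nine-class vocabulary), log-normal baseline means
(meanlog 4, sdlog 1 — median ≈ 55 normalized counts with a long right
tail), NB dispersion 0.1, and uniform library-size factors on [0.5, 2].
Planted fold changes multiply the test group's mean by 2^β.

Within-module correlation is induced by a shared per-module, per-sample
log-normal latent factor exp(σZ − σ²/2) multiplying the NB mean. Because
count sampling attenuates latent correlation, the mapping from σ to the
realized within-module Spearman ρ was calibrated once by Monte Carlo at
the generator defaults and frozen as an interpolation table; ρ saturates
near 0.88 at dispersion 0.1 (NB noise is irreducible), and higher targets
are clamped with a warning. A latent factor was chosen over a Gaussian
copula for simplicity and because it composes naturally with planted fold
changes.

The PPI generator draws a Barabási–Albert background graph (attachment 2)
over 500 gene-proteins, shuffles labels so the early high-degree-prone
nodes are not systematically the designated genes, then wires each of k
planted hubs to ≥ d_min nodes drawn from a designated (differentially
expressed) gene set. Background scores are uniform on [500, 1000] with a
configurable fraction forced to [400, 499] to exercise the confidence
filter; planted hub edges always score ≥ 500 so the planted structure is
present in the filtered graph. One protein per gene (`_P` suffix) by
default; the ID map is still an explicit artifact so many-to-many cases
can be injected in tests.

**What passing these checks shows — and does not.** The generator matches
the analysis' own assumptions (NB counts, multiplicative size factors,
block-structured correlation, scale-free-ish PPI). Real RNA-seq adds
features it does not emulate: gene-length and GC effects, mapping
ambiguity, count outliers, dispersion–mean trends, batch structure, and a
PPI whose confidence scores correlate with biology rather than being
independent noise. Recovery results here therefore validate the
*implementation* of each stage under its stated model, not the biological
fidelity of the upstream assumptions.

## Problem sizes and numerical conventions

Verification runs use 20 seeds per stochastic check, 2,000 genes for DE
calibration/recovery (4 vs 4), 300 genes / 24 samples for module recovery,
200 random ≤ 12-node graphs for the shortest-path oracle, and 500-node
PPIs (2 hubs, d_min = 15) for hub recovery — sizes at which every planted
structure is comfortably identifiable while a full run stays in seconds.
Other conventions: dispersion floor 10⁻⁸; fold-change pseudocount 0.5 and
transform pseudocount 1.0 (both surfaced as parameters and recorded in run
configs); all threshold comparisons inclusive; tables written with floats
at 6 significant digits and rows sorted by primary key; all randomness
derived from a single seed through named substreams, giving byte-identical
reruns.

## Known limitations

- The Wald test is a simplified DESeq2 analogue: no dispersion–mean trend,
  no independent filtering, no LFC shrinkage, no outlier handling. Absolute
  DE gene counts on real data will differ from dedicated packages even when
  the ranking largely agrees.
- Two-group contrasts only; no multi-factor designs or likelihood-ratio
  tests.
- Module detection is a plain tree cut on 1 − ρ; no WGCNA-style soft
  thresholding or topological overlap.
- The per-pair shortest-path cap (default 100) can bias degree counts on
  graphs with massive path multiplicity; set it to `None` for exhaustive
  enumeration on small graphs (truncation counts are always reported).
- Exact Wilcoxon p-values are only used for tie-free pooled samples ≤ 20;
  with ties the tie-corrected normal approximation is used at any size.
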