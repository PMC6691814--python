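# rbpnet

Expression analysis of RNA-binding proteins (RBPs) across normal myeloid and
leukemic cell states, for computational biologists studying how
post-transcriptional regulators behave during hematopoietic differentiation
(HSC → CMP → GMP → monocyte) and leukemic transformation (HSC → LSC → blast).

The package implements four connected analyses over a gene × sample read-count
matrix and a STRING-style protein–protein interaction (PPI) network:

1. **Differential expression.** Genes with counts < 10 in every sample are
   removed; samples are normalized by median-of-ratios size factors
   (s_j = median_g c_gj / (∏_j c_gj)^(1/n), over genes positive in all
   samples). Counts are modelled as negative binomial, Var = μ + αμ², with
   per-gene method-of-moments dispersion moderated toward the across-gene
   mean. For a contrast (reference, test) the Wald statistic is
   z = log₂((m_test + ½)/(m_ref + ½)) / SE on normalized group means, with
   the delta-method SE and Benjamini–Hochberg FDR control. DE genes satisfy
   |log₂FC| ≥ 1.5 and padj ≤ 0.05; z-scored DE profiles are cut into
   expression-pattern clusters by average-linkage hierarchical clustering.
2. **Co-expression modules.** Pairwise Spearman correlation between RBP
   genes, average-linkage clustering of 1 − ρ, and a cut into k modules
   (k = 4 for the normal-myelopoiesis design, 2 for the AML design).
   Modules are contrasted between cell states by Wilcoxon rank-sum tests and
   broken down by RBP class (mRBP, rRBP, rrRBP, tRBP, snRBP, snoRBP, ncRBP,
   diverse, unknown).
3. **Shortest-path PPI network.** The PPI is filtered to combined score
   ≥ 500; every protein is stamped with its mapped gene's DE record; all
   hop-count shortest paths between RBP pairs are enumerated on the full
   filtered graph; paths in which every node is significant (padj ≤ 0.05)
   are retained; their union forms a new network in which **hub** genes are
   the nodes in the top 10 degree percentile (nearest-rank, ties included).
   Hubs are summarized by RBP class and split into low/high expression
   groups by the interquartile rule.
4. **Synthetic data with planted truth.** NB counts with group-specific
   fold changes, latent-factor-induced correlation blocks, library-size
   variation, and a preferential-attachment PPI with planted dense hubs —
   so every stage above is verifiable against known ground truth.

## Worked example

```python
from rbpnet import NBDifferentialExpression
from rbpnet.simulate import default_study_config, simulate_counts

cfg = default_study_config(seed=1)          # 6 cell states, 35 samples
counts, samples, annotation, truth = simulate_counts(cfg)

model = NBDifferentialExpression(counts, samples)
print(model.fit(("HSC", "LSC")).summary())
```

prints (first lines):

```
NB Wald differential expression
===============================
contrast:         LSC vs HSC
genes tested:     1997
selected (|log2FC| >= 1.5, padj <= 0.05): 187
  up in LSC:   99
  down in LSC: 88
```

1,997 of 2,000 simulated genes survive the low-count filter and 187 are
called differentially expressed between leukemic and normal stem cells —
close to the 200 genes planted at |log₂FC| = 2 (the shortfall is genes whose
baseline expression is too low to reach significance at n = 4 vs 8).

The same run end to end, from the shell:

```bash
rbpnet all --seed 1 --out run1
```

writes every intermediate table plus `run1/report.txt`:

```
rbpnet pipeline report
======================
seed: 1
simulated_genes: 2000
simulated_samples: 35
simulated_edges: 1026
genes_after_low_count_filter: 1997
de_selected: 187
rbp_genes_clustered: 400
module_sizes: {1: 117, 2: 99, 3: 97, 4: 87}
pca_top3_cumulative_variance: 0.639986
ppi_nodes: 495
ppi_edges: 860
paths_computed: 23042
paths_truncated_pairs: 0
paths_retained: 556
network_nodes: 74
network_edges: 88
hubs: 12
planted_hubs_recovered: 2
```

Reading the tail: of 23,042 shortest paths between RBP proteins on the
495-node confidence-filtered PPI, 556 consist entirely of significantly
differentially expressed nodes; their union is a 74-node network whose top
degree decile contains 12 hubs — including both planted ones.

Individual stages are also available as subcommands (`simulate`, `dge`,
`coexpress`, `structure`, `network`); run `rbpnet --help`.

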