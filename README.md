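# memlin — cell lineage inference from gene-expression memory

Small cell lineages (roughly 2–5 cells descended from a recent common
ancestor) retain correlated transcriptomes, because the expression level of
many genes is heritable across cell divisions.  `memlin` exploits this
*gene-expression memory* to reconstruct lineages directly from a scRNA-seq
count matrix — no barcoding, no mitochondrial variants — and to identify
and characterize the memory genes themselves.  It is aimed at anyone with a
10x-style UMI count matrix who wants clonal structure (sister/cousin cells)
or heritable-expression gene lists, and at method developers who need a
fully synthetic, truth-annotated test bed for lineage inference.

## Method

Counts are depth-normalized to a fixed total per cell (default 40,000,
RPM-style).  The pipeline then has three stages:

1. **Gene selection.**  For each gene compute the mean expression m_g and
   the squared coefficient of variation CV²_g = Var_g / m_g².  The
   *variability* of a gene is the residual of log₁₀ CV² to an OLS fit of
   log₁₀ CV² on log₁₀ mean (mean-corrected CV²).  With percentile ranks
   Q_mean and Q_var over expressed genes, a gene is selected iff

       (Q_mean ≥ 98) ∨ (Q_mean ≥ 90 ∧ Q_var ≥ 40) ∨ (Q_mean ≥ 60 ∧ Q_var ≥ 90)

   i.e. the 2% highest expressed genes, the 60% most variable of the 10%
   highest expressed, and the 10% most variable of the 40% highest
   expressed.  This set is strongly enriched for memory genes.

2. **Consensus lineage prediction.**  Repeat R = 100 times: draw 75% of the
   selected genes at random; cluster cells on the correlation distance
   d(i,j) = 1 − Pearson(x_i, x_j) with agglomerative Ward linkage (the
   squared-distance "ward.D2" variant); cut the tree into 2 clusters;
   re-cluster each cluster the same way (distances recomputed over its
   cells) until clusters reach the terminal lineage size (2–3 cells); every
   terminal cluster emits its within-cluster cell pairs.  Summing the pair
   indicators over repetitions gives a symmetric cell×cell **confidence
   matrix** with entries in 0..R.  Lineages at confidence level X are the
   connected components (size ≥ 2) of the graph with edges where
   confidence ≥ X; the headline operating point is X = 50.

3. **Memory genes.**  Given lineages (ground truth or predicted), a gene's
   cross-lineage variability is the CV² of its per-lineage mean expression.
   It is compared to 20 random, disjoint, size-matched cell groupings; the
   permutation p-value is (1 + #{null ≥ observed}) / 21 and genes with
   p ≤ 0.05 are memory genes.  Memory genes with sample skewness < 3 are
   *quantitative* (broadly expressed, lineage-specific level), those with
   skewness ≥ 3 are *qualitative* (on/off in a subset of lineages).  A
   linear model of total CV² on cross-lineage CV², applied to permuted
   (mock) lineages, estimates the percent inflation of cell-to-cell
   variation attributable to lineage.

Predictions are scored on unordered cell pairs against a (possibly
partial) ground truth: precision TP/(TP+FP), sensitivity TP/(TP+FN), FPR
FP/(FP+TN) per confidence threshold, and a rank-based ROC AUC using
confidence as the score, with stratification by cell-type symmetry or by
true lineage size.

The `simulate` module generates Poisson–log-normal count matrices with
planted quantitative/qualitative memory genes, lineage annotations,
optional cell-type programs with asymmetric lineages, library-size
variation, exact read-level downsampling and lineage-preserving cell
subsampling — so the whole pipeline is testable without external data.

## Worked example

```sh
$ memlin simulate --seed 7 --out-dir fixture
simulated 2000 genes x 212 cells (57 lineages) -> fixture

$ memlin pipeline --matrix fixture --truth fixture/lineages.tsv \
    --seed 1 --out-dir run
selected 193 genes
70 lineages covering 185 cells at confidence >= 50
537 memory genes called
```

`run/eval.tsv` holds the pair-level scores per confidence threshold; at the
headline threshold of 50:

```
stratum  threshold  tp   fp  fn   tn     precision  sensitivity  fpr  auc
all      50.0       149  0   176  22041  1.0        0.458        0.0  0.977
```

Of the 325 truly related cell pairs, 149 are recovered at confidence ≥ 50
with no false positives (precision 1.0, FPR 0.0): on strongly
memory-structured data the predictor is conservative — it misses pairs
(sensitivity 0.46) rather than inventing them.  `run/memory_genes.tsv`
lists each gene's cross-lineage CV², permutation p-value, skewness and
category.  The same steps are available as library calls
(`memlin.simulate`, `gene_stats` / `select_genes`, `predict` /
`assign_lineages`, `evaluate`, `call_memory_genes`), and every CLI run
writes a JSON manifest sufficient to replay it bit-for-bit.

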