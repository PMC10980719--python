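# Methods

This note documents the models, defaults and numerical choices behind
`memlin`, and what the synthetic test bed does and does not show.

## Data model and normalization

The substrate is a genes × cells matrix of UMI counts.  Each cell is
scaled to a fixed total (`target_depth`, default 40,000 — the RPM-style
convention under which one normalized count is on the order of one read).
Cells with zero total are kept, left all-zero and flagged; downstream
statistics exclude them instead of dropping columns, so annotations never
desynchronize from the matrix.  Matrices are stored sparse (CSR) below 50%
density and dense above, with value-identical behavior.  Dense CSV input
is always interpreted genes × rows / cells × columns; orientation is never
guessed.

## Gene statistics and selection

Per gene: mean over cells (zero-depth cells excluded), CV² = s²/m̄² with
the unbiased variance (ddof 1), and *variability* = residual of log₁₀ CV²
to an ordinary-least-squares fit of log₁₀ CV² on log₁₀ mean across
expressed genes with CV² > 0.  The log–log space is the default because
the CV²–mean relation of count data (Poisson floor CV² ≈ 1/mean plus a
biological plateau) is near-linear there; a raw-space fit is available via
`fit_space="raw"` for sensitivity analysis.

Percentile ranks are 100·(rank − 0.5)/n with mean ranks for ties, over
expressed genes.  Residuals are rounded to 1e−12 before ranking: residual
differences at float-noise level are ties, not order — this makes the
exactly-collinear case (all residuals 0 → all ranks 50) well defined.
Genes with zero CV² or zero mean are excluded from the fit and given
variability rank 0; they carry no lineage signal.  The selection rule is
the three-gate disjunction on (mean rank, variability rank): (98, 0),
(90, 40), (60, 90).  Variability ranks are computed over all expressed
genes, not within each mean band; the gates are therefore independent
filters whose union is taken.

## Consensus prediction

One repetition: sample ⌈0.75·n⌉ of the selected genes without
replacement; compute the correlation distance 1 − Pearson between cells
over the subsample; cluster with Ward linkage in its squared-distance
(ward.D2) form — scipy's `linkage(..., "ward")` on the condensed distance
matrix implements exactly this Lance–Williams recurrence — and cut the
tree into exactly 2 groups (`cut_tree`, the exact-k cut).  Each group of
size above the terminal lineage size (default max 3) is re-clustered the
same way with distances recomputed over its own cells; terminal groups of
≥ 2 cells emit all their unordered pairs, singletons emit none (the
conservative reading of a stranded cell).  A cell whose subsampled profile
has zero variance has undefined correlations; it participates at distance
1 to everyone rather than being dropped mid-repetition.

The default 100 repetitions are summed into the confidence matrix.  Each
repetition draws its genes from an RNG substream keyed by (seed,
repetition index) (`SeedSequence(seed, spawn_key=(r,))`), so the result is
bit-identical regardless of the order — or parallelism — in which
repetitions execute.  Lineage assignment at threshold X takes connected
components of the confidence ≥ X graph with ≥ 2 members; components may
exceed the terminal cluster size, since size restriction applies to the
per-repetition clusters, not the consensus.  Component ids are ordered by
smallest member index for determinism.

Distances are computed on normalized (not log) expression by default,
matching the correlation-distance definition on normalized counts; a log
transform is a per-call option, not part of normalization.

## Memory-gene statistics

Cross-lineage variability of a gene is the CV² of its per-lineage mean
expression over lineages in the configured size range (default 2–5), each
lineage one unweighted observation.  The null distribution re-draws the
exact lineage-size multiset as disjoint random groups from the whole
annotated cell pool, 20 times by default; p = (1 + #{null ≥ observed}) /
(1 + 20), so p ≤ 0.05 iff the observed value beats every replicate — the
granularity intended by the 20-replicate design; `n_null` can be raised
for finer resolution.  Ties count toward the null, so constant genes get
p = 1.  Skewness is the biased third standardized sample moment m₃/m₂^3/2
over the cells of the lineages used for calling (switchable to all
cells); < 3 → quantitative, ≥ 3 → qualitative (inclusive threshold on the
qualitative side).  Zero-variance genes have undefined skewness and are
forced quantitative with a warning; they cannot be memory genes anyway.

Variance inflation assumes within-lineage variation independent of
cross-lineage effects: OLS of total CV² on cross-lineage CV² across genes,
mock lineages by permuting cell→lineage labels (default 10 permutations,
control statistic averaged per gene), control total CV² predicted from the
model and clipped at 0, and the reported inflation is the percent
difference of the median per-gene SD (mean·√CV²), real vs control, overall
and for the top decile by mean.

## The simulator

The generator is a Poisson–log-normal count model with planted memory:

* base means μ_g ~ LogNormal(1, 1) (natural-log loc/scale) — a right-
  skewed gene-mean distribution spanning ~3 orders of magnitude;
* memory genes (12% quantitative + 8% qualitative of 2000 genes by
  default, echoing the observed ~20% split in real datasets) have base
  means shifted by +1 log unit: heritable-expression genes are enriched
  among highly expressed genes, which is the premise of the mean-quantile
  selection gates;
* quantitative memory: per-lineage multiplier LogNormal(0, σ_lineage =
  0.6) shared by lineage members, per-cell noise LogNormal(0, 0.15).
  σ_lineage = 0.6 keeps the marginal distribution's skewness below the
  categorization threshold of 3 (a log-normal with σ ≈ 1 would exceed it,
  mislabeling the planted class);
* qualitative memory: active per lineage with probability 0.08; active
  lineages express at (μ_g/0.08)·LogNormal(0, σ_lineage), inactive at 0.
  The on-level conserves the population mean so qualitative genes share
  the transcriptome-wide mean distribution; the activation probability is
  set so a gene is typically active in a handful of the 57 lineages —
  rarely zero (undetectable) and rarely so many that its expression stops
  being minority-restricted (sample skewness must be ≥ 3, the class
  definition);
* non-memory genes: iid per-cell noise LogNormal(0, 0.3);
* optional cell types: marker genes ×4 in their type; asymmetric lineages
  split members across two types;
* counts: per-cell rates normalized to shares, multiplied by
  depth (40,000) × library factor LogNormal(−σ²/2, σ = 0.25) (unit-mean,
  so expected depth matches), then Poisson-sampled.  The Poisson–log-normal
  mixture gives negative-binomial-like overdispersion with fewer knobs.

Default problem size — 57 lineages of 2–5 cells (~200 cells), 2000 genes —
is the package's standard desk-scale test bed; all simulation-based checks
and the acceptance script run on it in seconds.

What the simulator does *not* emulate: batch effects, doublets, ambient
RNA, cell-cycle structure, and any specific real dataset's empirical
distributions.  Its planted memory signal is strong and clean (per-gene
intraclass correlation ≈ 0.7 on memory genes), so passing tests show the
pipeline is correct and calibrated, not that real tissues will yield the
same precision/sensitivity; on real data the operating characteristics
depend on how much genuine expression memory the system has.  One notable
consequence: because counts are compositional (shares of a fixed depth),
strong lineage structure in memory genes induces weak anti-correlated
lineage structure in all other genes, so the fraction of genes called as
memory on structured simulations exceeds the planted 20% — as in real
data, "memory gene" is a property of the measured, depth-limited
transcriptome.

Read downsampling vectorizes each cell's reads and draws a fixed fraction
without replacement (multivariate hypergeometric) — an exact emulation of
shallower sequencing.  On the default simulation the planted signal
saturates: sensitivity stays ~flat down to 10% of reads (~4000
reads/cell) and precision stays at 1.0, so depth-robustness tests check
non-increase within Monte-Carlo jitter rather than a strict decline.
Cell subsampling keeps lineages whole, so pair-level scoring remains
meaningful after subsampling.

## Numerical and degenerate-case choices

* Correlations are clipped to [−1, 1]; distance diagonal forced to 0.
* Ward merges on exact ties follow scipy's deterministic nearest-neighbor
  chain; test oracles use continuous random data where ties have
  probability zero.
* `cut_tree` guarantees exactly k groups, so every recursion strictly
  shrinks cluster sizes — no special-casing of identical cells is needed
  for termination.
* Precision is reported as NaN when nothing is predicted positive; AUC is
  NaN when either pair class is empty; empty evaluation strata are
  reported as empty, not as zeros.
* p-values never reach 0 by construction ((1+b)/(1+n)).
* All public entry points that consume randomness take an explicit seed;
  nothing reads global RNG state.

## Known limitations

* The recursive splitter recomputes a full linkage per cluster per
  repetition: fine for 10²–10³ cells, not engineered for 10⁵.
* Quantile-gate selection assumes enough genes (~hundreds) for stable
  ranks; tiny panels should use an explicit gene list.
* The variance-inflation model is a between/total decomposition on CV²
  via a single linear fit; it is a summary, not a per-gene variance
  component estimate.
* Lineages larger than the terminal cluster size are recovered only
  through the connected-component closure, which requires their pairs to
  co-cluster in enough repetitions; very large clones need a larger
  terminal size parameter.
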