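"""Memory-gene identification, categorization, and lineage-variance estimates.

A memory gene is a gene whose expression level is conserved within cell
lineages: the variability (CV² = variance / mean²) of its per-lineage mean
expression is higher than expected for random groups of cells.  Given a
lineage annotation (ground truth or predicted), each gene's cross-lineage
CV² of lineage means is compared to the same statistic on repeated
(default 20x) random, disjoint, size-matched cell groupings; the one-sided
permutation p-value is (1 + #{null >= observed}) / (1 + n_null) and genes
with p <= 0.05 are called memory genes.

Memory genes are categorized by the sample skewness of their expression
across the cells used for calling: skewness < 3 -> quantitative (broadly
expressed, lineage-specific level), >= 3 -> qualitative (on/off in a
subset of lineages).

`variance_inflation` quantifies how much total cell-to-cell variation is
attributable to lineage: a linear model of total CV² on cross-lineage CV²
across genes is used to predict the total variation expected under
permuted (mock) lineages, and the percent difference of the median
per-gene standard deviation, real vs. control, is reported overall and
for the top decile of genes by mean expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from memlin.data_io import (
    ExpressionMatrix,
    LineagePartition,
    MemlinError,
    ParameterError,
)
from memlin.lineage_inference import _pearson_distance

__all__ = [
    "MemoryGeneTable",
    "VariancePartitionResult",
    "call_memory_genes",
    "categorize",
    "variance_inflation",
    "similarity_report",
]

SKEWNESS_CUTOFF = 3.0  # quantitative (<) vs qualitative (>=)


@dataclass
class MemoryGeneTable:
    """Per-gene memory statistics; arrays aligned with gene_ids."""

    gene_ids: np.ndarray
    cv2_lineage_means: np.ndarray
    null_cv2: np.ndarray  # shape (n_genes, n_null)
    p_value: np.ndarray
    is_memory: np.ndarray
    skewness: np.ndarray  # NaN until `categorize` is applied
    category: np.ndarray  # {"quantitative", "qualitative", "none"}
    alpha: float
    size_range: tuple[int, int]
    lineage_cells: np.ndarray  # cell ids of the lineages used for calling

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "cv2_lineage_means": self.cv2_lineage_means,
                "p_value": self.p_value,
                "is_memory": self.is_memory,
                "skewness": self.skewness,
                "category": self.category,
            }
        )


@dataclass
class VariancePartitionResult:
    """Lineage-mediated variance estimate from the total~across-lineage fit."""

    gene_ids: np.ndarray
    total_cv2: np.ndarray
    across_lineage_cv2: np.ndarray
    control_total_cv2: np.ndarray
    intercept: float
    slope: float
    inflation_pct: float
    inflation_pct_high_expr: float
    n_permutations: int


def _group_mean_cv2(
    X: np.ndarray, group_sizes: np.ndarray, order: np.ndarray
) -> np.ndarray:
    """CV² across group means for each gene (row of X).

    ``order`` lists cell columns; consecutive runs of ``group_sizes`` form
    the groups.  Groups are unweighted: each contributes one mean.
    """
    boundaries = np.concatenate([[0], np.cumsum(group_sizes)])
    means = np.empty((X.shape[0], len(group_sizes)))
    for k in range(len(group_sizes)):
        cols = order[boundaries[k] : boundaries[k + 1]]
        means[:, k] = X[:, cols].mean(axis=1)
    mu = means.mean(axis=1)
    var = means.var(axis=1, ddof=1)
    cv2 = np.zeros(X.shape[0])
    pos = mu > 0
    cv2[pos] = var[pos] / mu[pos] ** 2
    return cv2


def _lineage_layout(
    m: ExpressionMatrix, lp: LineagePartition, size_range: tuple[int, int]
):
    """Cell columns and group sizes for lineages within size_range."""
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ParameterError(f"invalid size_range {size_range}")
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}
    in_range = []
    for lin, members in sorted(lp.lineages().items()):
        if lo <= len(members) <= hi:
            in_range.append([cell_pos[c] for c in sorted(members, key=cell_pos.get)])
    if len(in_range) < 2:
        raise MemlinError(
            f"need >= 2 lineages with size in {size_range}, found {len(in_range)}"
        )
    sizes = np.array([len(g) for g in in_range])
    order = np.concatenate([np.asarray(g) for g in in_range])
    pool = np.array(
        sorted(cell_pos[c] for c in lp.assignments if c in cell_pos), dtype=int
    )
    return order, sizes, pool


def call_memory_genes(
    m: ExpressionMatrix,
    lp: LineagePartition,
    size_range: tuple[int, int] = (2, 5),
    n_null: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> MemoryGeneTable:
    """Call memory genes against a lineage annotation.

    For each gene the CV² of per-lineage mean expression (lineages with
    size in ``size_range``, each lineage one unweighted observation) is
    compared to ``n_null`` random groupings that match the lineage-size
    multiset exactly, drawn disjointly (without replacement within a
    replicate) from the whole annotated cell pool.  One-sided test for
    HIGHER cross-lineage variability; ties count toward the null.
    """
    if not (0 < alpha <= 1):
        raise ParameterError("alpha must be in (0, 1]")
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    order, sizes, pool = _lineage_layout(m, lp, size_range)
    if sizes.sum() > len(pool):  # pragma: no cover - defensive
        raise MemlinError("annotated cell pool smaller than lineage-size multiset")
    X = m.dense()
    observed = _group_mean_cv2(X, sizes, order)

    rng = np.random.default_rng(seed)
    null = np.empty((m.n_genes, n_null))
    for r in range(n_null):
        perm = rng.permutation(pool)
        null[:, r] = _group_mean_cv2(X, sizes, perm)

    exceed = (null >= observed[:, np.newaxis]).sum(axis=1)
    p_value = (1.0 + exceed) / (1.0 + n_null)
    is_memory = p_value <= alpha

    return MemoryGeneTable(
        gene_ids=m.gene_ids,
        cv2_lineage_means=observed,
        null_cv2=null,
        p_value=p_value,
        is_memory=is_memory,
        skewness=np.full(m.n_genes, np.nan),
        category=np.array(["none"] * m.n_genes, dtype=object),
        alpha=alpha,
        size_range=tuple(size_range),
        lineage_cells=m.cell_ids[np.sort(order)],
    )


def categorize(
    table: MemoryGeneTable,
    m: ExpressionMatrix,
    population: str = "lineage_cells",
) -> MemoryGeneTable:
    """Split memory genes into quantitative (skewness < 3) vs qualitative.

    Skewness is the third standardized sample moment m3 / m2^{3/2} over the
    cells of the lineages used for calling (``population="all_cells"``
    switches to every cell in the matrix).  Genes with zero variance have
    undefined skewness; they are forced quantitative with a warning (such
    genes cannot be memory genes anyway).
    """
    if population == "lineage_cells":
        cols = m.cell_index(table.lineage_cells)
    elif population == "all_cells":
        cols = np.arange(m.n_cells)
    else:
        raise ParameterError(f"unknown skewness population {population!r}")
    X = m.dense()[:, cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = scipy.stats.skew(X, axis=1, bias=True)
    degenerate = X.var(axis=1) == 0
    if (degenerate & table.is_memory).any():  # pragma: no cover - defensive
        warnings.warn("zero-variance memory gene: skewness undefined, "
                      "forced quantitative", stacklevel=2)
    skew = np.where(degenerate, 0.0, skew)

    category = np.array(["none"] * len(table.gene_ids), dtype=object)
    category[table.is_memory & (skew < SKEWNESS_CUTOFF)] = "quantitative"
    category[table.is_memory & (skew >= SKEWNESS_CUTOFF)] = "qualitative"

    table.skewness = skew
    table.category = category
    return table


def variance_inflation(
    m: ExpressionMatrix,
    lp: LineagePartition,
    size_range: tuple[int, int] = (2, 5),
    n_perm: int = 10,
    seed: int = 0,
) -> VariancePartitionResult:
    """Estimate the share of expression variation mediated by lineage.

    Assumes within-lineage variation is independent of cross-lineage
    effects.  Fits total CV² (across all lineage cells) ~ intercept +
    slope x cross-lineage CV² (of lineage means) across genes by OLS, then
    permutes the cell -> lineage labels to build mock lineages, predicts
    each gene's control total CV² from the model, and reports the percent
    difference of the median per-gene standard deviation (real vs control),
    overall and for the top decile of genes by mean expression.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if m.n_genes < 10:
        raise ParameterError("variance_inflation needs >= 10 genes")
    order, sizes, _pool = _lineage_layout(m, lp, size_range)
    X = m.dense()[:, np.sort(order)]
    # positions of the ordered lineage cells within the restricted matrix
    rank_of = {c: i for i, c in enumerate(np.sort(order))}
    order_local = np.array([rank_of[c] for c in order], dtype=int)

    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    expressed = mean > 0
    total_cv2 = np.zeros(m.n_genes)
    total_cv2[expressed] = var[expressed] / mean[expressed] ** 2
    across = _group_mean_cv2(X, sizes, order_local)

    fit_mask = expressed
    if np.var(across[fit_mask]) == 0:
        raise MemlinError("degenerate fit: cross-lineage CV2 has zero variance")
    slope, intercept = np.polyfit(across[fit_mask], total_cv2[fit_mask], 1)

    rng = np.random.default_rng(seed)
    control_across = np.zeros(m.n_genes)
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[1])
        control_across += _group_mean_cv2(X, sizes, perm)
    control_across /= n_perm
    control_total = np.clip(intercept + slope * control_across, 0.0, None)

    def _inflation(mask: np.ndarray) -> float:
        real_sd = mean[mask] * np.sqrt(total_cv2[mask])
        ctrl_sd = mean[mask] * np.sqrt(control_total[mask])
        med_ctrl = np.median(ctrl_sd)
        if med_ctrl == 0:
            return float("nan")
        return 100.0 * (np.median(real_sd) - med_ctrl) / med_ctrl

    high = expressed & (mean >= np.quantile(mean[expressed], 0.9))
    return VariancePartitionResult(
        gene_ids=m.gene_ids,
        total_cv2=total_cv2,
        across_lineage_cv2=across,
        control_total_cv2=control_total,
        intercept=float(intercept),
        slope=float(slope),
        inflation_pct=_inflation(expressed),
        inflation_pct_high_expr=_inflation(high),
        n_permutations=n_perm,
    )


def similarity_report(
    m: ExpressionMatrix,
    lp: LineagePartition,
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Within-lineage vs random-group correlation-distance summary.

    Pools pairwise correlation distances (whole transcriptome) between
    cells of the same lineage (all multi-cell lineages) and compares them
    to ``n_random`` replicates of random cell groups matching the lineage
    sizes.  Returns medians and quartiles plus the raw distance arrays.
    """
    if n_random < 1:
        raise ParameterError("n_random must be >= 1")
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}
    groups = [
        np.array([cell_pos[c] for c in members], dtype=int)
        for _, members in sorted(lp.lineages().items())
        if len(members) >= 2
    ]
    if not groups:
        raise MemlinError("no multi-cell lineages to report on")
    keep = np.flatnonzero(~m.zero_depth_cells())
    D = _pearson_distance(m.dense()[:, keep], warn=False)
    pos_of = {int(c): k for k, c in enumerate(keep)}

    def _within(group_list) -> np.ndarray:
        vals = []
        for g in group_list:
            g = [pos_of[int(i)] for i in g if int(i) in pos_of]
            for a in range(len(g)):
                for b in range(a + 1, len(g)):
                    vals.append(D[g[a], g[b]])
        return np.asarray(vals)

    within = _within(groups)
    sizes = [len(g) for g in groups]
    rng = np.random.default_rng(seed)
    random_vals = []
    for _ in range(n_random):
        perm = rng.permutation(len(keep))
        start, rand_groups = 0, []
        for s in sizes:
            rand_groups.append(keep[perm[start : start + s]])
            start += s
        random_vals.append(_within(rand_groups))
    random_all = np.concatenate(random_vals)

    def _summary(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"q1": float(q1), "median": float(med), "q3": float(q3)}

    return {
        "within_lineage": _summary(within),
        "random_groups": _summary(random_all),
        "within_values": within,
        "random_values": random_all,
        "n_random": n_random,
    }
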