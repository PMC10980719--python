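"""Per-gene mean/variability statistics and memory-gene-enriched selection.

Genes whose expression is heritable across cell divisions (memory genes)
tend to sit among the highly expressed and/or highly variable genes of a
dataset.  The selection used for lineage prediction therefore keys on two
per-gene quantile ranks:

* ``mean_quantile`` — percentile rank of mean normalized expression;
* ``variability_quantile`` — percentile rank of the mean-corrected CV²,
  i.e. the residual of each gene's squared coefficient of variation
  (variance / mean²) to a fit of CV² against mean expression.

The default rule keeps the 2% highest-expressed genes, the 60% most
variable among the 10% highest expressed, and the 10% most variable among
the 40% highest expressed:

    (mean_q >= 98) or (mean_q >= 90 and var_q >= 40)
                   or (mean_q >= 60 and var_q >= 90)

The CV²-vs-mean fit is ordinary least squares in log10-log10 space by
default (the CV²-mean relation of count data is near-linear there); a
raw-space fit is available behind ``fit_space="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from memlin.data_io import ExpressionMatrix, MemlinError, ParameterError

__all__ = ["GeneStats", "SelectionRule", "gene_stats", "select_genes", "DEFAULT_RULE"]


@dataclass
class SelectionRule:
    """Disjunction of (mean_quantile_min, variability_quantile_min) gates.

    A gene is selected iff it satisfies *any* pair: mean_quantile >= a and
    variability_quantile >= b.
    """

    thresholds: list[tuple[float, float]] = field(
        default_factory=lambda: [(98.0, 0.0), (90.0, 40.0), (60.0, 90.0)]
    )

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ParameterError("selection rule needs at least one threshold pair")
        for a, b in self.thresholds:
            if not (0 <= a <= 100 and 0 <= b <= 100):
                raise ParameterError(f"quantile thresholds ({a},{b}) outside [0,100]")


DEFAULT_RULE = SelectionRule()


@dataclass
class GeneStats:
    """Per-gene expression statistics over cells.

    All arrays are aligned with the source matrix's gene order.  Entries
    for unexpressed genes (mean 0) are NaN except ``mean_expr``; genes with
    zero variance have ``variability`` NaN and variability quantile 0 (they
    carry no lineage signal).
    """

    gene_ids: np.ndarray
    mean_expr: np.ndarray
    cv2: np.ndarray
    variability: np.ndarray
    mean_quantile: np.ndarray
    variability_quantile: np.ndarray
    fit_intercept: float
    fit_slope: float
    fit_space: str


def _percentile_rank(x: np.ndarray) -> np.ndarray:
    """Percentile rank 100*(rank-0.5)/n with mean rank for ties."""
    ranks = scipy.stats.rankdata(x, method="average")
    return 100.0 * (ranks - 0.5) / len(x)


def gene_stats(m: ExpressionMatrix, fit_space: str = "log") -> GeneStats:
    """Compute per-gene mean, CV², mean-corrected CV² and quantile ranks.

    Cells flagged as zero-depth are excluded.  The CV²-vs-mean trend is fit
    by OLS over expressed genes with positive CV², and ``variability`` is
    the per-gene residual to that fit (in log10 units for the default log
    fit).  Quantile ranks are percentile ranks over expressed genes
    (``100 * (rank - 0.5) / n``, ties at the mean rank).
    """
    if fit_space not in ("log", "raw"):
        raise ParameterError(f"fit_space must be 'log' or 'raw', got {fit_space!r}")
    if not m.normalized:
        raise ParameterError("gene_stats requires a depth-normalized matrix")
    if m.n_cells < 2:
        raise ParameterError("gene_stats requires at least 2 cells")

    keep = ~m.zero_depth_cells()
    X = m.dense()[:, keep]
    if X.shape[1] < 2:
        raise ParameterError("fewer than 2 cells with nonzero depth")

    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    expressed = mean > 0

    cv2 = np.full(m.n_genes, np.nan)
    cv2[expressed] = var[expressed] / mean[expressed] ** 2

    fit_mask = expressed & (cv2 > 0) & np.isfinite(cv2)
    if fit_mask.sum() < 2:
        raise MemlinError(
            "fewer than 2 expressed genes with positive CV2: cannot fit the "
            "CV2-mean trend"
        )
    if fit_space == "log":
        fx = np.log10(mean[fit_mask])
        fy = np.log10(cv2[fit_mask])
    else:
        fx = mean[fit_mask]
        fy = cv2[fit_mask]
    slope, intercept = np.polyfit(fx, fy, 1)

    variability = np.full(m.n_genes, np.nan)
    variability[fit_mask] = fy - (intercept + slope * fx)

    mean_q = np.full(m.n_genes, np.nan)
    mean_q[expressed] = _percentile_rank(mean[expressed])

    var_q = np.full(m.n_genes, np.nan)
    # residual differences at float-noise level are ties, not order
    var_q[fit_mask] = _percentile_rank(np.round(variability[fit_mask], 12))
    # zero-variance / zero-CV2 expressed genes: no lineage signal, rank 0
    var_q[expressed & ~fit_mask] = 0.0

    return GeneStats(
        gene_ids=m.gene_ids,
        mean_expr=mean,
        cv2=cv2,
        variability=variability,
        mean_quantile=mean_q,
        variability_quantile=var_q,
        fit_intercept=float(intercept),
        fit_slope=float(slope),
        fit_space=fit_space,
    )


def select_genes(stats: GeneStats, rule: SelectionRule = DEFAULT_RULE) -> np.ndarray:
    """Select memory-gene-enriched genes by the quantile-gate disjunction.

    Returns the selected gene ids in input gene order.  Raises if the rule
    selects nothing (relax the thresholds in that case).
    """
    selected = np.zeros(len(stats.gene_ids), dtype=bool)
    for mean_min, var_min in rule.thresholds:
        gate = (stats.mean_quantile >= mean_min) & (
            stats.variability_quantile >= var_min
        )
        selected |= np.where(np.isnan(stats.mean_quantile), False, gate)
    if not selected.any():
        raise MemlinError(
            "selection rule matched no genes; relax the quantile thresholds"
        )
    return stats.gene_ids[selected]
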