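"""Lineage-structured scRNA-seq count simulation with planted memory genes.

The generative model emulates the expression-memory structure the
predictor exploits, on top of a standard Poisson-log-normal count model:

* every gene g has a base mean ``mu_g ~ LogNormal(loc, scale)``;
* a *quantitative memory gene* carries a lineage-specific level: each
  lineage l draws a multiplier ``a_{g,l} ~ LogNormal(0, sigma_lineage)``
  shared by its cells, on top of small per-cell noise
  ``LogNormal(0, sigma_cell_memory)``;
* a *qualitative memory gene* is active in a random subset of lineages
  (probability ``qual_on_fraction`` each); active lineages express at
  ``mu_g / qual_on_fraction`` times their own LogNormal(0, sigma_lineage)
  level, inactive lineages not at all — so the population mean stays on
  the same scale as other genes while the on/off pattern makes the
  distribution strongly right-skewed;
* non-memory genes fluctuate per cell with ``LogNormal(0, sigma_cell)``;
* memory genes' base means are shifted by ``mean_shift_memory`` log units,
  reflecting that heritable-expression genes are enriched among highly
  expressed genes (the premise of the mean-quantile selection gates);
* optional cell-type programs multiply marker-gene rates by
  ``marker_strength`` in cells of the marked type; a fraction of lineages
  is asymmetric, splitting its members across two types;
* observed counts are ``Poisson(depth * libsize_c * rate_share)``, with
  per-cell library-size factors ``LogNormal(-sigma_library^2/2,
  sigma_library)`` so the expected depth matches the configured value.

`downsample_reads` thins counts exactly as a read-level subsample: each
cell's reads are vectorized and a fixed fraction is drawn without
replacement (multivariate hypergeometric).  `subsample_cells` removes
cells while keeping lineage members together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from memlin.data_io import (
    CellTypeAnnotation,
    ExpressionMatrix,
    LineagePartition,
    ParameterError,
    write_annotation,
    write_matrix,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "write_fixture",
    "downsample_reads",
    "subsample_cells",
]


@dataclass
class SimulationConfig:
    """Parameters of the lineage-structured count generator.

    Defaults describe a small, strongly memory-structured dataset of about
    200 cells (57 lineages of 2-5 cells) and 2000 genes at 40,000 reads
    per cell, with 12% quantitative and 8% qualitative memory genes.
    """

    n_lineages: int = 57
    lineage_sizes: tuple[int, int] | list[int] = (2, 5)
    n_genes: int = 2000
    frac_quant_memory: float = 0.12
    frac_qual_memory: float = 0.08
    base_mean_logdist: tuple[float, float] = (1.0, 1.0)  # natural-log loc/scale
    mean_shift_memory: float = 1.0  # log-units added to memory genes' base mean
    sigma_lineage: float = 0.6  # between-lineage log-SD for memory genes
    sigma_cell: float = 0.3  # per-cell log-SD, non-memory genes
    sigma_cell_memory: float = 0.15  # per-cell log-SD within lineages
    qual_on_fraction: float = 0.08  # per-lineage activation probability
    sigma_library: float = 0.25  # log-SD of per-cell library size
    depth: float = 40_000.0  # expected reads per cell
    n_celltypes: int = 1
    frac_asymmetric: float = 0.0
    n_marker_genes: int = 0
    marker_strength: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_quant_memory + self.frac_qual_memory > 1:
            raise ParameterError("memory-gene fractions sum above 1")
        if min(self.sigma_lineage, self.sigma_cell, self.sigma_cell_memory,
               self.sigma_library) < 0:
            raise ParameterError("noise SDs must be >= 0")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if not (0 < self.qual_on_fraction <= 1):
            raise ParameterError("qual_on_fraction must be in (0, 1]")
        if self.n_celltypes < 1:
            raise ParameterError("n_celltypes must be >= 1")
        if not (0 <= self.frac_asymmetric <= 1):
            raise ParameterError("frac_asymmetric must be in [0, 1]")
        if self.n_celltypes * self.n_marker_genes > self.n_genes:
            raise ParameterError("marker genes exceed n_genes")
        if self.n_celltypes == 1 and self.frac_asymmetric > 0:
            raise ParameterError("asymmetric lineages need n_celltypes >= 2")


@dataclass
class SimulatedDataset:
    """Raw counts plus the planted truth used to score every module."""

    counts: ExpressionMatrix
    truth_lineages: LineagePartition
    truth_celltypes: CellTypeAnnotation
    truth_memory: dict[str, str]  # gene_id -> {quantitative, qualitative, none}
    config: SimulationConfig = field(repr=False, default=None)


def _draw_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.lineage_sizes, tuple) and len(cfg.lineage_sizes) == 2:
        lo, hi = cfg.lineage_sizes
        return rng.integers(lo, hi + 1, size=cfg.n_lineages)
    sizes = np.asarray(list(cfg.lineage_sizes), dtype=int)
    if len(sizes) != cfg.n_lineages:
        raise ParameterError(
            "explicit lineage_sizes list must have n_lineages entries"
        )
    return sizes


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a lineage-annotated raw count matrix with planted truth.

    Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    sizes = _draw_sizes(cfg, rng)
    n_cells = int(sizes.sum())
    lineage_of = np.repeat(np.arange(cfg.n_lineages), sizes)

    gene_ids = np.array(
        [f"gene_{i + 1:05d}" for i in range(cfg.n_genes)], dtype=object
    )
    cell_ids = np.array(
        [f"cell_{i + 1:05d}" for i in range(n_cells)], dtype=object
    )
    lineage_ids = np.array(
        [f"lin_{k + 1:04d}" for k in range(cfg.n_lineages)], dtype=object
    )

    # gene roles
    n_quant = int(round(cfg.frac_quant_memory * cfg.n_genes))
    n_qual = int(round(cfg.frac_qual_memory * cfg.n_genes))
    roles = np.array(["none"] * cfg.n_genes, dtype=object)
    memory_idx = rng.choice(cfg.n_genes, size=n_quant + n_qual, replace=False)
    roles[memory_idx[:n_quant]] = "quantitative"
    roles[memory_idx[n_quant:]] = "qualitative"
    quant = roles == "quantitative"
    qual = roles == "qualitative"
    is_memory = quant | qual

    # base means (memory genes shifted toward high expression)
    loc, scale = cfg.base_mean_logdist
    log_mu = rng.normal(loc, scale, size=cfg.n_genes)
    log_mu[is_memory] += cfg.mean_shift_memory
    mu = np.exp(log_mu)

    # expected expression rate per gene x cell
    rate = np.tile(mu[:, np.newaxis], (1, n_cells))

    if quant.any():
        lin_mult = np.exp(
            rng.normal(0.0, cfg.sigma_lineage, size=(quant.sum(), cfg.n_lineages))
        )
        cell_eps = np.exp(
            rng.normal(0.0, cfg.sigma_cell_memory, size=(quant.sum(), n_cells))
        )
        rate[quant, :] *= lin_mult[:, lineage_of] * cell_eps

    if qual.any():
        active = rng.random((qual.sum(), cfg.n_lineages)) < cfg.qual_on_fraction
        on_level = np.exp(
            rng.normal(0.0, cfg.sigma_lineage, size=(qual.sum(), cfg.n_lineages))
        ) / cfg.qual_on_fraction
        cell_eps = np.exp(
            rng.normal(0.0, cfg.sigma_cell_memory, size=(qual.sum(), n_cells))
        )
        rate[qual, :] *= (active * on_level)[:, lineage_of] * cell_eps

    nonmem = ~is_memory
    if nonmem.any():
        rate[nonmem, :] *= np.exp(
            rng.normal(0.0, cfg.sigma_cell, size=(nonmem.sum(), n_cells))
        )

    # cell types and markers
    celltype_labels = [f"type_{t + 1}" for t in range(cfg.n_celltypes)]
    lineage_type = rng.integers(0, cfg.n_celltypes, size=cfg.n_lineages)
    cell_type = lineage_type[lineage_of].copy()
    if cfg.frac_asymmetric > 0:
        asym = rng.random(cfg.n_lineages) < cfg.frac_asymmetric
        for k in np.flatnonzero(asym):
            members = np.flatnonzero(lineage_of == k)
            if len(members) < 2:
                continue
            other = (lineage_type[k] + 1 + rng.integers(cfg.n_celltypes - 1)) % (
                cfg.n_celltypes
            )
            n_switch = rng.integers(1, len(members))
            switch = rng.choice(members, size=n_switch, replace=False)
            cell_type[switch] = other
    if cfg.n_marker_genes > 0 and cfg.n_celltypes > 1:
        nonmem_pool = np.flatnonzero(nonmem)
        markers = rng.choice(
            nonmem_pool,
            size=cfg.n_celltypes * cfg.n_marker_genes,
            replace=False,
        ).reshape(cfg.n_celltypes, cfg.n_marker_genes)
        for t in range(cfg.n_celltypes):
            in_type = cell_type == t
            rate[np.ix_(markers[t], in_type)] *= cfg.marker_strength

    # library size and Poisson sampling
    libsize = np.exp(
        rng.normal(-cfg.sigma_library**2 / 2, cfg.sigma_library, size=n_cells)
    )
    share = rate / rate.sum(axis=0, keepdims=True)
    lam = share * (cfg.depth * libsize)[np.newaxis, :]
    counts = rng.poisson(lam).astype(float)

    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, normalized=False)
    truth_lineages = LineagePartition(
        {cell_ids[i]: lineage_ids[lineage_of[i]] for i in range(n_cells)},
        source="ground_truth",
    )
    truth_celltypes = CellTypeAnnotation(
        {cell_ids[i]: celltype_labels[cell_type[i]] for i in range(n_cells)}
    )
    truth_memory = {gene_ids[g]: roles[g] for g in range(cfg.n_genes)}
    return SimulatedDataset(
        matrix, truth_lineages, truth_celltypes, truth_memory, cfg
    )


def write_fixture(ds: SimulatedDataset, path) -> None:
    """Write a dataset as an MTX triple plus truth TSVs.

    Emits ``matrix.mtx``/``features.tsv``/``barcodes.tsv``,
    ``lineages.tsv``, ``celltypes.tsv`` and ``memory_genes.tsv`` under
    ``path``; reading them back reproduces the dataset.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.counts, path, format="mtx_triple")
    write_annotation(ds.truth_lineages, path / "lineages.tsv")
    write_annotation(ds.truth_celltypes, path / "celltypes.tsv")
    lines = ["gene_id\tmemory_category"]
    lines += [f"{g}\t{cat}" for g, cat in ds.truth_memory.items()]
    (path / "memory_genes.tsv").write_text("\n".join(lines) + "\n", "utf-8")


def downsample_reads(
    m: ExpressionMatrix, fraction: float, seed: int = 0
) -> ExpressionMatrix:
    """Subsample a fixed fraction of each cell's reads without replacement.

    All reads of a cell are vectorized and ``floor(fraction * total)`` of
    them are drawn (multivariate hypergeometric), exactly emulating a
    shallower sequencing run.  Requires integer raw counts.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    if m.normalized:
        raise ParameterError("read downsampling applies to raw counts")
    X = m.dense()
    if not np.allclose(X, np.round(X)):
        raise ParameterError("read downsampling requires integer counts")
    X = np.round(X).astype(np.int64)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(X)
    for c in range(X.shape[1]):
        total = int(X[:, c].sum())
        take = int(np.floor(fraction * total))
        if take == 0:
            continue
        out[:, c] = rng.multivariate_hypergeometric(
            X[:, c], take, method="marginals"
        )
    return ExpressionMatrix(
        out.astype(float), m.gene_ids, m.cell_ids, normalized=False
    )


def subsample_cells(
    ds: SimulatedDataset, fraction: float, seed: int = 0
) -> SimulatedDataset:
    """Keep roughly a fraction of cells, preserving whole lineages.

    Multi-member lineages are kept or dropped as units; cells without a
    lineage (or sole members) are subsampled directly, so surviving
    lineages remain intact for pair-level scoring.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = ds.counts
    lineages = ds.truth_lineages.lineages()
    multi = sorted(lin for lin, mem in lineages.items() if len(mem) >= 2)
    single_cells = sorted(
        set(m.cell_ids)
        - {c for lin in multi for c in lineages[lin]}
    )
    keep: set[str] = set()
    for lin in multi:
        if rng.random() < fraction:
            keep.update(lineages[lin])
    for c in single_cells:
        if rng.random() < fraction:
            keep.add(c)
    keep_idx = [i for i, c in enumerate(m.cell_ids) if c in keep]
    if len(keep_idx) < 2:
        raise ParameterError("fraction too small: fewer than 2 cells kept")
    cells = m.cell_ids[keep_idx]
    matrix = ExpressionMatrix(
        m.dense()[:, keep_idx], m.gene_ids, cells, normalized=m.normalized,
        target_depth=m.target_depth,
    )
    return SimulatedDataset(
        matrix,
        LineagePartition(
            {c: l for c, l in ds.truth_lineages.assignments.items() if c in keep},
            source="ground_truth",
        ),
        CellTypeAnnotation(
            {c: t for c, t in ds.truth_celltypes.types.items() if c in keep}
        ),
        ds.truth_memory,
        ds.config,
    )
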