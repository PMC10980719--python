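"""Consensus lineage prediction by repeated iterative Ward clustering.

One prediction works on a random subsample (default 75%) of the selected
gene set: cells are clustered by correlation distance (1 - Pearson) with
agglomerative hierarchical clustering, Ward linkage in its squared-distance
("ward.D2") variant, the tree is cut into ``cluster_cut`` groups (default
2), and each group is re-clustered the same way — recomputing the distance
over the group's cells — until a group reaches the terminal lineage size
(default 2-3 cells).  Terminal groups of >= 2 cells emit all their
unordered cell pairs; singletons emit nothing.

Repeating this ``n_repetitions`` times (default 100) with fresh gene
subsamples and summing the emitted pair indicators yields the confidence
matrix: entry (i, j) counts the repetitions in which cells i and j ended in
the same terminal cluster.  Thresholding the confidence matrix and taking
connected components of size >= 2 assigns lineages; these may exceed the
terminal size since components are not size-restricted.

Each repetition draws its random gene subsample from an independent RNG
substream keyed by (seed, repetition index), so results are identical
regardless of the order in which repetitions are executed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
import scipy.spatial.distance as ssd
from scipy.sparse.csgraph import connected_components

from memlin.data_io import (
    ExpressionMatrix,
    LineagePartition,
    ParameterError,
    ValidationError,
)

__all__ = [
    "PredictionParams",
    "ConfidenceMatrix",
    "correlation_distance",
    "one_prediction",
    "predict",
    "assign_lineages",
]


@dataclass
class PredictionParams:
    """Tunables of the consensus predictor.

    sampling_fraction
        Fraction of the input gene set drawn (without replacement) per
        repetition.
    n_repetitions
        Number of consensus repetitions; the confidence scale is 0..R.
    cluster_cut
        Number of groups each non-terminal cluster is split into.
    lineage_size_min, lineage_size_max
        Terminal cluster size range at which iteration stops; clusters of
        size <= lineage_size_max are terminal.  ``lineage_size_min`` is
        used for reporting/validation only.
    seed
        Root seed for all gene subsampling.
    """

    sampling_fraction: float = 0.75
    n_repetitions: int = 100
    cluster_cut: int = 2
    lineage_size_min: int = 2
    lineage_size_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sampling_fraction <= 1):
            raise ParameterError("sampling_fraction must be in (0, 1]")
        if self.n_repetitions < 1:
            raise ParameterError("n_repetitions must be >= 1")
        if self.cluster_cut < 2:
            raise ParameterError("cluster_cut must be >= 2")
        if self.lineage_size_min < 2:
            raise ParameterError("lineage_size_min must be >= 2")
        if self.lineage_size_max < self.lineage_size_min:
            raise ParameterError("lineage_size_max must be >= lineage_size_min")


@dataclass
class ConfidenceMatrix:
    """Symmetric cell x cell co-clustering counts in 0..n_repetitions."""

    counts: np.ndarray
    n_repetitions: int
    cell_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValidationError("confidence matrix must be square")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length does not match matrix")
        if (self.counts != self.counts.T).any():
            raise ValidationError("confidence matrix must be symmetric")
        off = self.counts[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > self.n_repetitions):
            raise ValidationError("confidence counts outside [0, n_repetitions]")

    def to_pairs(self) -> pd.DataFrame:
        """Long format: one row (cell_a, cell_b, confidence) per pair > 0."""
        i, j = np.nonzero(np.triu(self.counts, k=1))
        return pd.DataFrame(
            {
                "cell_a": self.cell_ids[i],
                "cell_b": self.cell_ids[j],
                "confidence": self.counts[i, j].astype(int),
            }
        )

    @classmethod
    def from_pairs(
        cls, pairs: pd.DataFrame, cell_ids, n_repetitions: int
    ) -> "ConfidenceMatrix":
        cell_ids = np.asarray(cell_ids, dtype=object)
        idx = {c: k for k, c in enumerate(cell_ids)}
        counts = np.zeros((len(cell_ids), len(cell_ids)), dtype=int)
        for a, b, c in zip(pairs["cell_a"], pairs["cell_b"], pairs["confidence"]):
            counts[idx[a], idx[b]] = counts[idx[b], idx[a]] = int(c)
        np.fill_diagonal(counts, n_repetitions)
        return cls(counts, n_repetitions, cell_ids)


# ---------------------------------------------------------------------------
# distances


def _pearson_distance(X: np.ndarray, warn: bool = True) -> np.ndarray:
    """1 - Pearson between columns of X; zero-variance columns -> r = 0."""
    n = X.shape[1]
    centered = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    degenerate = norms == 0
    if degenerate.any() and warn:
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) with zero variance over the "
            "gene subset; their correlations are undefined and set to 0",
            stacklevel=3,
        )
    safe = np.where(degenerate, 1.0, norms)
    R = (centered.T @ centered) / np.outer(safe, safe)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return D


def correlation_distance(
    m: ExpressionMatrix, gene_subset=None, cells=None
) -> np.ndarray:
    """Pairwise correlation distance (1 - Pearson) between cells.

    Distances are computed over ``gene_subset`` (default: all genes)
    restricted to ``cells`` (default: all cells); values lie in [0, 2] with
    a zero diagonal.  A cell with zero variance over the subset has
    undefined correlations; these are set to 0 (distance 1) with a warning.
    """
    X = m.dense()
    if gene_subset is not None:
        gene_subset = np.asarray(gene_subset, dtype=object)
        if gene_subset.size == 0:
            raise ParameterError("gene_subset must be non-empty")
        X = X[m.gene_index(gene_subset), :]
    if cells is not None:
        X = X[:, m.cell_index(cells)]
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 cells")
    return _pearson_distance(X)


# ---------------------------------------------------------------------------
# one consensus repetition


def _ward_split(D: np.ndarray, k: int) -> list[np.ndarray]:
    """Cut a Ward (ward.D2) tree over distance matrix D into k groups."""
    condensed = ssd.squareform(D, checks=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sch.ClusterWarning)
        Z = sch.linkage(condensed, method="ward")
    labels = sch.cut_tree(Z, n_clusters=k).ravel()
    return [np.flatnonzero(labels == lab) for lab in range(labels.max() + 1)]


def _recursive_pairs(
    X: np.ndarray,
    cell_idx: np.ndarray,
    cluster_cut: int,
    size_max: int,
) -> set[tuple[int, int]]:
    """Emit within-terminal-cluster pairs for the cells in ``cell_idx``.

    ``X`` is the (subsampled genes) x (all cells) matrix; distances are
    recomputed over the member cells at every recursion level.
    """
    n = len(cell_idx)
    if n <= size_max:
        if n >= 2:
            return {
                (int(cell_idx[a]), int(cell_idx[b]))
                for a in range(n)
                for b in range(a + 1, n)
            }
        return set()
    D = _pearson_distance(X[:, cell_idx], warn=False)
    pairs: set[tuple[int, int]] = set()
    for group in _ward_split(D, min(cluster_cut, n)):
        pairs |= _recursive_pairs(X, cell_idx[group], cluster_cut, size_max)
    return pairs


def _subsample_genes(
    selected_genes: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(selected_genes)
    k = int(np.ceil(fraction * n))
    if k < 2:
        raise ParameterError(
            f"gene subsample of size {k} is too small (need >= 2 genes)"
        )
    pick = rng.choice(n, size=k, replace=False)
    return np.asarray(selected_genes, dtype=object)[np.sort(pick)]


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # substream keyed by (seed, repetition): order/parallelism independent
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def one_prediction(
    m: ExpressionMatrix,
    selected_genes,
    params: PredictionParams,
    rng: np.random.Generator | None = None,
) -> set[tuple[str, str]]:
    """Run a single consensus repetition; return co-clustered cell pairs.

    Subsamples ``ceil(sampling_fraction * n)`` genes without replacement,
    then applies the recursive Ward splitting until terminal cluster size.
    Pairs are unordered (cell_id, cell_id) tuples with the pair ordered by
    matrix cell order.
    """
    selected_genes = np.asarray(selected_genes, dtype=object)
    if len(selected_genes) < 2:
        raise ParameterError("need at least 2 selected genes")
    if m.n_cells < 2:
        raise ParameterError("need at least 2 cells")
    if rng is None:
        rng = _rep_rng(params.seed, 0)
    subsample = _subsample_genes(selected_genes, params.sampling_fraction, rng)
    X = m.dense()[m.gene_index(subsample), :]
    idx_pairs = _recursive_pairs(
        X, np.arange(m.n_cells), params.cluster_cut, params.lineage_size_max
    )
    return {(m.cell_ids[i], m.cell_ids[j]) for i, j in idx_pairs}


def predict(
    m: ExpressionMatrix, selected_genes, params: PredictionParams
) -> ConfidenceMatrix:
    """Run all repetitions and sum pair indicators into a confidence matrix.

    Deterministic given ``params.seed``; repetition r uses the RNG
    substream (seed, r), so the result does not depend on execution order.
    """
    selected_genes = np.asarray(selected_genes, dtype=object)
    if len(selected_genes) < 2:
        raise ParameterError("need at least 2 selected genes")
    if m.n_cells < 2:
        raise ParameterError("need at least 2 cells")
    X_all = m.dense()
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    counts = np.zeros((m.n_cells, m.n_cells), dtype=int)
    for rep in range(params.n_repetitions):
        rng = _rep_rng(params.seed, rep)
        sub = _subsample_genes(selected_genes, params.sampling_fraction, rng)
        sub_idx = np.array([gene_pos[g] for g in sub], dtype=int)
        idx_pairs = _recursive_pairs(
            X_all[sub_idx, :],
            np.arange(m.n_cells),
            params.cluster_cut,
            params.lineage_size_max,
        )
        for i, j in idx_pairs:
            counts[i, j] += 1
            counts[j, i] += 1
    np.fill_diagonal(counts, params.n_repetitions)
    return ConfidenceMatrix(counts, params.n_repetitions, m.cell_ids)


# ---------------------------------------------------------------------------
# lineage assignment


def assign_lineages(cm: ConfidenceMatrix, threshold: int) -> LineagePartition:
    """Call lineages as connected components above a confidence threshold.

    Cells i, j are linked when counts[i, j] >= threshold; lineages are the
    connected components with >= 2 members (note they may exceed the
    terminal cluster size).  Lineage ids are ``L1, L2, ...`` ordered by the
    smallest member cell index; singletons remain unassigned.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    n = cm.counts.shape[0]
    adj = cm.counts >= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        sp.csr_matrix(adj), directed=False, connection="weak"
    )
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    multi = sorted(
        (members for members in comps.values() if len(members) >= 2),
        key=lambda members: members[0],
    )
    assignments: dict[str, str] = {}
    for k, members in enumerate(multi, start=1):
        for i in members:
            assignments[cm.cell_ids[i]] = f"L{k}"
    return LineagePartition(assignments, source="predicted")
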