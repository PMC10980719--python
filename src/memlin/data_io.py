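"""Count-matrix and annotation I/O, core data model, depth normalization.

The substrate of every downstream computation is a genes x cells matrix of
UMI counts (or depth-normalized counts).  Two on-disk layouts are supported:
the 10x-style MatrixMarket triple (matrix.mtx + features.tsv + barcodes.tsv,
gzip-tolerant) and a dense CSV/TSV with gene ids in the first column and
cell ids in the header row.  Annotations (cell -> lineage, cell -> cell
type) are two-column TSVs with a header.

Counts are stored sparse (CSR) when density is below 50% and dense
otherwise; every operation is value-identical either way.  Per-cell depth
normalization scales each cell's column to a fixed total (default 40,000,
an RPM-style normalization in which one normalized count is on the order of
one read).  Cells with zero total are retained, left all-zero, and flagged
so downstream code can exclude them rather than silently dropping cells and
desynchronizing annotations.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "MemlinError",
    "FormatError",
    "ValidationError",
    "ParameterError",
    "ExpressionMatrix",
    "LineagePartition",
    "CellTypeAnnotation",
    "read_matrix",
    "write_matrix",
    "normalize_depth",
    "read_annotation",
    "write_annotation",
]

#: default per-cell total after depth normalization (reads per cell)
DEFAULT_TARGET_DEPTH = 40_000.0

#: store counts sparse below this density
_SPARSE_DENSITY_CUTOFF = 0.5


class MemlinError(Exception):
    """Base class for all memlin errors."""


class FormatError(MemlinError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(MemlinError):
    """Input data violates a documented invariant (duplicate ids, ...)."""


class ParameterError(MemlinError):
    """A parameter is outside its documented domain."""


def _as_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with id metadata.

    Parameters
    ----------
    values
        Non-negative matrix, shape ``(n_genes, n_cells)``; dense ndarray or
        scipy sparse.
    gene_ids, cell_ids
        Ordered unique identifiers for rows / columns.
    normalized
        Whether per-cell depth normalization has been applied.
    target_depth
        Per-cell total after normalization (meaningful when ``normalized``).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalized: bool = False
    target_depth: float = DEFAULT_TARGET_DEPTH

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        mn = self.values.min() if self.values.size else 0.0
        if mn < 0:
            raise ValidationError("negative entries in expression matrix")

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        """Values as a dense float ndarray (copy only if stored sparse)."""
        return _as_dense(self.values)

    def cell_totals(self) -> np.ndarray:
        """Per-cell column sums."""
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def zero_depth_cells(self) -> np.ndarray:
        """Boolean mask of cells whose raw column total is zero."""
        return self.cell_totals() == 0

    def gene_index(self, gene_ids) -> np.ndarray:
        """Positions of the given gene ids in matrix row order."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise ValidationError(f"unknown gene id {exc.args[0]!r}") from exc

    def cell_index(self, cell_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise ValidationError(f"unknown cell id {exc.args[0]!r}") from exc


@dataclass
class LineagePartition:
    """Partial map cell_id -> lineage_id (ground truth or predicted)."""

    assignments: dict[str, str]
    source: str = "ground_truth"  # {"ground_truth", "predicted"}

    def __post_init__(self) -> None:
        if self.source not in ("ground_truth", "predicted"):
            raise ValidationError(f"unknown partition source {self.source!r}")

    def lineages(self) -> dict[str, list[str]]:
        """lineage_id -> member cell_ids, members in insertion order."""
        out: dict[str, list[str]] = {}
        for cell, lin in self.assignments.items():
            out.setdefault(lin, []).append(cell)
        return out

    def sizes(self) -> dict[str, int]:
        return {lin: len(members) for lin, members in self.lineages().items()}

    def restrict_sizes(self, size_min: int, size_max: int) -> "LineagePartition":
        """Keep only lineages whose size is within [size_min, size_max]."""
        keep = {
            lin for lin, n in self.sizes().items() if size_min <= n <= size_max
        }
        return replace(
            self,
            assignments={
                c: l for c, l in self.assignments.items() if l in keep
            },
        )

    def validate_against(self, m: ExpressionMatrix) -> None:
        known = set(m.cell_ids)
        missing = [c for c in self.assignments if c not in known]
        if missing:
            raise ValidationError(
                f"{len(missing)} annotated cells absent from matrix "
                f"(first: {missing[0]!r})"
            )


@dataclass
class CellTypeAnnotation:
    """Partial map cell_id -> cell-type label."""

    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, label in self.types.items():
            if not isinstance(label, str) or not label:
                raise ValidationError(
                    f"empty cell-type label for cell {cell!r}"
                )


# ---------------------------------------------------------------------------
# matrix I/O


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(dirpath: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dirpath / name
            if p.exists():
                return p
    raise FormatError(
        f"none of {stems} found in {dirpath} (plain or .gz)"
    )


def _read_id_column(path: Path) -> np.ndarray:
    """First tab-separated field per line (10x features/barcodes files)."""
    with _open_maybe_gz(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def read_matrix(path, format: str = "mtx_triple") -> ExpressionMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        For ``mtx_triple``: a directory holding ``matrix.mtx``,
        ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``, each
        optionally gzipped.  For ``dense_csv``: a CSV/TSV file, genes in
        rows (first column = gene id), cells in columns (header = cell id).
    format
        ``"mtx_triple"`` or ``"dense_csv"``.
    """
    path = Path(path)
    if format == "mtx_triple":
        matrix_file = _find(path, ("matrix.mtx",))
        features_file = _find(path, ("features.tsv", "genes.tsv"))
        barcodes_file = _find(path, ("barcodes.tsv",))
        try:
            with _open_maybe_gz(matrix_file) as fh:
                mat = scipy.io.mmread(fh)
        except Exception as exc:
            raise FormatError(f"cannot parse {matrix_file}: {exc}") from exc
        gene_ids = _read_id_column(features_file)
        cell_ids = _read_id_column(barcodes_file)
        if mat.shape[0] != len(gene_ids):
            raise FormatError(
                f"{matrix_file} has {mat.shape[0]} rows but "
                f"{features_file} lists {len(gene_ids)} features"
            )
        if mat.shape[1] != len(cell_ids):
            raise FormatError(
                f"{matrix_file} has {mat.shape[1]} columns but "
                f"{barcodes_file} lists {len(cell_ids)} barcodes"
            )
        values = sp.csr_matrix(mat, dtype=float)
        density = values.nnz / max(1, values.shape[0] * values.shape[1])
        if density >= _SPARSE_DENSITY_CUTOFF:
            values = _as_dense(values)
    elif format == "dense_csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
        values = df.to_numpy(dtype=float)
    else:
        raise ParameterError(f"unknown matrix format {format!r}")
    return ExpressionMatrix(values, gene_ids, cell_ids, normalized=False)


def write_matrix(m: ExpressionMatrix, path, format: str = "mtx_triple") -> None:
    """Write a matrix in the layout `read_matrix` understands.

    Integer-valued matrices round-trip bit-for-bit.  Output is plain text,
    UTF-8, deterministic row order.
    """
    path = Path(path)
    if format == "mtx_triple":
        path.mkdir(parents=True, exist_ok=True)
        coo = sp.coo_matrix(m.values)
        is_int = np.allclose(coo.data, np.round(coo.data))
        scipy.io.mmwrite(
            path / "matrix.mtx",
            coo.astype(int) if is_int else coo,
            field="integer" if is_int else "real",
        )
        (path / "features.tsv").write_text(
            "".join(f"{g}\n" for g in m.gene_ids), encoding="utf-8"
        )
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in m.cell_ids), encoding="utf-8"
        )
    elif format == "dense_csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        dense = m.dense()
        if np.allclose(dense, np.round(dense)):
            dense = dense.astype(int)
        df = pd.DataFrame(dense, index=m.gene_ids, columns=m.cell_ids)
        df.to_csv(path, sep=sep)
    else:
        raise ParameterError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# normalization


def normalize_depth(
    m: ExpressionMatrix, target_depth: float = DEFAULT_TARGET_DEPTH
) -> ExpressionMatrix:
    """Scale every cell's counts to a fixed total (RPM-style).

    Each column is multiplied by ``target_depth / column_total``.  Columns
    whose total is zero are left all-zero and reported with a warning; they
    stay flagged via :meth:`ExpressionMatrix.zero_depth_cells`.
    """
    if target_depth <= 0:
        raise ParameterError("target_depth must be positive")
    if m.normalized:
        raise ParameterError("matrix is already depth-normalized")
    totals = m.cell_totals()
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero total count left all-zero",
            stacklevel=2,
        )
    scale = np.where(zero, 0.0, target_depth / np.where(zero, 1.0, totals))
    if sp.issparse(m.values):
        values = m.values @ sp.diags(scale)
        values = sp.csr_matrix(values)
    else:
        values = m.values * scale[np.newaxis, :]
    return ExpressionMatrix(
        values, m.gene_ids, m.cell_ids, normalized=True, target_depth=target_depth
    )


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation(path, kind: str = "lineage"):
    """Read a 2-column TSV (header + `cell_id<TAB>label` rows).

    ``kind="lineage"`` returns a :class:`LineagePartition` (ground truth);
    ``kind="cell_type"`` returns a :class:`CellTypeAnnotation`.  Cells not
    listed are simply unannotated.  Duplicate cell rows are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 tab-separated columns")
    cells = df.iloc[:, 0].to_numpy()
    labels = df.iloc[:, 1].to_numpy()
    mapping: dict[str, str] = {}
    for cell, label in zip(cells, labels):
        if cell in mapping:
            if mapping[cell] != label:
                raise ValidationError(
                    f"{path}: cell {cell!r} listed with conflicting labels "
                    f"{mapping[cell]!r} and {label!r}"
                )
            raise ValidationError(f"{path}: duplicate row for cell {cell!r}")
        mapping[cell] = label
    if kind == "lineage":
        return LineagePartition(mapping, source="ground_truth")
    if kind == "cell_type":
        return CellTypeAnnotation(mapping)
    raise ParameterError(f"unknown annotation kind {kind!r}")


def write_annotation(ann, path, header: tuple[str, str] | None = None) -> None:
    """Write a LineagePartition or CellTypeAnnotation as a 2-column TSV."""
    path = Path(path)
    if isinstance(ann, LineagePartition):
        mapping = ann.assignments
        head = header or ("cell_id", "lineage_id")
    elif isinstance(ann, CellTypeAnnotation):
        mapping = ann.types
        head = header or ("cell_id", "cell_type")
    else:
        raise ParameterError(f"cannot write annotation of type {type(ann)}")
    lines = [f"{head[0]}\t{head[1]}"]
    lines += [f"{cell}\t{label}" for cell, label in mapping.items()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
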