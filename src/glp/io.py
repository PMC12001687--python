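"""Count-matrix input and ranked-result output.

Reads raw count matrices either from a 10x-style Matrix Market directory
(``matrix.mtx`` plus ``features.tsv``/``genes.tsv`` and ``barcodes.tsv``)
or from a dense delimited text file with gene row labels, and writes the
per-gene score table produced by the selection pipeline as TSV.

Counts are held genes x cells in memory regardless of the on-disk layout;
an explicit orientation flag covers transposed files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import InputError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .core import GLPScores

__all__ = ["CountMatrix", "read_counts", "write_ranking"]


@dataclass
class CountMatrix:
    """A genes x cells matrix of raw, nonnegative integer counts.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Cell/barcode identifiers, one per column.
    counts
        Sparse (CSR) genes x cells count matrix.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} matrix rows"
            )
        if len(self.cell_ids) != c:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {c} matrix columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique()[:5])
            raise ValidationError(f"duplicate gene ids (e.g. {dupes})")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts are not allowed")
            if not np.all(data == np.floor(data)):
                raise ValidationError("non-integral counts are not allowed")
        # store integral values as integers
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)
        self.counts.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def _find_sidecar(directory: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise InputError(f"none of {names} found in {directory}")


def _read_mtx_dir(directory: Path) -> tuple[sp.coo_matrix, list[str], list[str]]:
    mtx_candidates = sorted(directory.glob("*.mtx"))
    if not mtx_candidates:
        raise InputError(f"no .mtx file in {directory}")
    mat = scipy.io.mmread(str(mtx_candidates[0]))
    gene_path = _find_sidecar(directory, ("features.tsv", "genes.tsv", "features.txt", "genes.txt"))
    barcode_path = _find_sidecar(directory, ("barcodes.tsv", "barcodes.txt"))
    # 10x features.tsv may carry (id, symbol, type); column 1 is the identifier
    genes = pd.read_csv(gene_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    barcodes = pd.read_csv(barcode_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    return sp.coo_matrix(mat), genes, barcodes


def _read_dense(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric entries in {path}")
    return values, [str(g) for g in df.index], [str(c) for c in df.columns]


def read_counts(
    path: str | os.PathLike,
    format: str = "auto",
    orientation: str = "genes_x_cells",
) -> CountMatrix:
    """Read a count matrix from disk into genes x cells orientation.

    Parameters
    ----------
    path
        Matrix Market directory (``format="mtx_dir"``) or dense delimited
        file (``format="dense_delim"``). ``"auto"`` picks by whether the
        path is a directory.
    format
        ``{"auto", "mtx_dir", "dense_delim"}``.
    orientation
        On-disk layout: ``"genes_x_cells"`` (default, 10x convention) or
        ``"cells_x_genes"`` (the matrix is transposed after reading).

    Returns
    -------
    CountMatrix
        Validated sparse counts, always genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    if orientation not in ("genes_x_cells", "cells_x_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if format == "auto":
        format = "mtx_dir" if path.is_dir() else "dense_delim"

    if format == "mtx_dir":
        mat, row_labels, col_labels = _read_mtx_dir(path)
    elif format == "dense_delim":
        mat, row_labels, col_labels = _read_dense(path)
    else:
        raise ValidationError(f"unknown format {format!r}")

    if orientation == "cells_x_genes":
        mat = mat.T
        row_labels, col_labels = col_labels, row_labels

    if sp.issparse(mat):
        if mat.shape[0] != len(row_labels) or mat.shape[1] != len(col_labels):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(row_labels)} genes, {len(col_labels)} cells)"
            )
        data = mat.data
        if data.size and (np.any(data < 0) or not np.all(data == np.floor(data))):
            raise ValidationError("matrix entries must be nonnegative integers")
    return CountMatrix(gene_ids=row_labels, cell_ids=col_labels, counts=sp.csr_matrix(mat))


def write_counts_mtx(m: CountMatrix, directory: str | os.PathLike) -> None:
    """Write a CountMatrix as matrix.mtx + features.tsv + barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.counts))
    (directory / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))


RANKING_COLUMNS = [
    "gene", "positive_ratio", "mean_expr", "fitted", "residual",
    "z_score", "outlier", "rank",
]


def write_ranking(
    scores: "GLPScores",
    path: str | os.PathLike,
    top_path: str | os.PathLike | None = None,
) -> None:
    """Write the full rank-ordered score table as TSV.

    The table has one row per scored gene, ordered by rank, with columns
    ``gene, positive_ratio, mean_expr, fitted, residual, z_score, outlier,
    rank``. If *top_path* is given, the selected top-N subset is written
    there in the same format.
    """
    table = scores.table
    if len(table) == 0:
        raise ValidationError("no scored genes to write")
    out = table[RANKING_COLUMNS]
    try:
        out.to_csv(path, sep="\t", index=False)
        if top_path is not None:
            scores.selected[RANKING_COLUMNS].to_csv(top_path, sep="\t", index=False)
    except OSError as exc:
        raise InputError(f"cannot write ranking: {exc}") from exc
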