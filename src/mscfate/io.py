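"""Count-matrix container and on-disk formats.

Orientation contract: on disk and in :class:`CountMatrix`, genes are rows
and cells are columns (10x convention: ``matrix.mtx`` + ``genes.tsv`` +
``barcodes.tsv``).  Every analysis routine in this package works on the
transposed cells x genes array, obtained once via
:meth:`CountMatrix.to_cells_by_genes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "FormatError", "read_counts", "write_counts", "read_cell_table"]


class FormatError(ValueError):
    """Malformed input file or violated matrix invariant."""


@dataclass
class CountMatrix:
    """Gene x cell non-negative integer counts with identifiers."""

    values: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = pd.Series(ids)
            dup = dup[dup.duplicated()]
            if not dup.empty:
                raise FormatError(f"duplicate {kind} id: {dup.iloc[0]!r}")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative count entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_cells_by_genes(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.values.T)


def read_counts(path: str | Path, fmt: str = "mtx_dir") -> CountMatrix:
    """Read counts from a 10x-style Matrix Market directory or a dense CSV.

    ``mtx_dir`` expects ``matrix.mtx`` (genes x cells), ``genes.tsv`` and
    ``barcodes.tsv`` (one id per line) under ``path``.  ``csv`` expects a
    dense table with gene ids in the first column and cell ids as header.
    """
    path = Path(path)
    if fmt == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes_f, cells_f = path / "genes.tsv", path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FormatError(f"missing file: {f}")
        try:
            values = scipy.io.mmread(mtx)
        except Exception as exc:  # scipy raises bare ValueError on bad entries
            raise FormatError(f"cannot parse {mtx}: {exc}") from exc
        gene_ids = genes_f.read_text().split()
        cell_ids = cells_f.read_text().split()
        return CountMatrix(sp.csr_matrix(values), gene_ids, cell_ids)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id in {path}: {dup[0]!r}")
        return CountMatrix(
            sp.csr_matrix(df.to_numpy()), [str(g) for g in df.index], [str(c) for c in df.columns]
        )
    raise FormatError(f"unknown format {fmt!r} (expected 'mtx_dir' or 'csv')")


def write_counts(path: str | Path, matrix: CountMatrix) -> None:
    """Write a 10x-style Matrix Market directory (round-trips bit-exactly)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.values), field="integer")
    (path / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata table (cell_id, day, matrix, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = {"cell_id", "day", "matrix"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cell table {path} lacks columns: {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"duplicate cell id in {path}: {dup!r}")
    bad_day = set(df["day"]) - {"D0", "D3", "D6"}
    if bad_day:
        raise FormatError(f"unknown day labels: {sorted(bad_day)}")
    bad_matrix = set(df["matrix"]) - {"PS", "soft", "stiff"}
    if bad_matrix:
        raise FormatError(f"unknown matrix labels: {sorted(bad_matrix)}")
    return df
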