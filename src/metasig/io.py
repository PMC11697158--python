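"""Count-matrix containers, format I/O, quality control and normalisation.

The two in-memory containers used throughout the package are
:class:`CountMatrix` (genes x cells raw UMI counts, sparse) and
:class:`LogNormMatrix` (genes x cells log library-size-normalised
expression).  Readers and writers cover the MatrixMarket triplet layout
(matrix.mtx + genes.tsv + barcodes.tsv + cells.tsv metadata) and a dense
TSV layout, both plain text so simulated cohorts round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("metasig")

#: prefix identifying mitochondrial genes in QC
MITO_PREFIX = "MT-"

#: QC defaults: strictly more than 200 detected genes per cell, a gene seen
#: in at least 3 cells, and at most 20% mitochondrial UMIs.
MIN_GENES_PER_CELL = 200
MIN_CELLS_PER_GENE = 3
MAX_MITO_FRAC = 0.20

#: library-size scale factor for log-normalisation
LOGNORM_SCALE = 10_000.0

CELL_META_COLUMNS = ["cell_id", "patient_id", "sample_id", "cancer_type", "cell_type"]


class FormatError(ValueError):
    """Raised when an on-disk matrix fails structural validation."""


class EmptyResultError(RuntimeError):
    """Raised when a filter removes every cell."""


@dataclass
class CountMatrix:
    """Genes x cells integer UMI counts with per-cell metadata.

    ``counts`` is stored as CSR so iteration over non-zeros is cheap;
    ``cell_meta`` is indexed by cell id and carries at least patient_id,
    sample_id and cancer_type (cell_type optional).
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        data = self.counts.data
        if data.size and (data < 0).any():
            raise FormatError("negative count entry")
        if data.size and np.any(data != np.round(data)):
            raise FormatError("non-integer count entry")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cells, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.loc[self.cells]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset(self, gene_mask: np.ndarray, cell_mask: np.ndarray) -> "CountMatrix":
        genes = [g for g, k in zip(self.genes, gene_mask) if k]
        cells = [c for c, k in zip(self.cells, cell_mask) if k]
        return CountMatrix(
            genes,
            cells,
            self.counts[gene_mask][:, cell_mask],
            self.cell_meta.loc[cells],
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class LogNormMatrix:
    """Genes x cells log(1 + scale * count / library_size) expression."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    scale: float = LOGNORM_SCALE

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise FormatError("values shape does not match gene/cell lists")
        if self.values.data.size and not np.all(np.isfinite(self.values.data)):
            raise FormatError("non-finite normalised value")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cells, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.loc[self.cells]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_one_column(path: Path, what: str) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate {what} ids in {path}")
    return ids


def read_counts(path: str | Path, fmt: str = "mtx") -> CountMatrix:
    """Read a count matrix from ``path``.

    ``fmt="mtx"`` expects a directory with matrix.mtx, genes.tsv,
    barcodes.tsv and optionally cells.tsv (metadata).  ``fmt="dense_tsv"``
    expects a single TSV with gene ids in the first column and cell ids in
    the header.
    """
    path = Path(path)
    if fmt == "mtx":
        mtx_path = path / "matrix.mtx"
        if not mtx_path.exists():
            raise FileNotFoundError(mtx_path)
        mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
        genes = _read_one_column(path / "genes.tsv", "gene")
        cells = _read_one_column(path / "barcodes.tsv", "cell")
        if mat.shape[0] != len(genes):
            raise FormatError(
                f"matrix.mtx declares {mat.shape[0]} genes but genes.tsv lists {len(genes)}"
            )
        if mat.shape[1] != len(cells):
            raise FormatError(
                f"matrix.mtx declares {mat.shape[1]} cells but barcodes.tsv lists {len(cells)}"
            )
        meta_path = path / "cells.tsv"
        meta = None
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
            meta.index = meta.index.astype(str)
        return CountMatrix(genes, cells, mat, meta)
    if fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise FormatError("duplicate gene ids in dense TSV")
        return CountMatrix(
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
            sp.csr_matrix(df.to_numpy()),
        )
    raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'dense_tsv'")


def write_counts(m: CountMatrix, path: str | Path, fmt: str = "mtx") -> None:
    """Write ``m`` so that :func:`read_counts` round-trips it bit-exactly."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
        pd.Series(m.genes).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(m.cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        meta = m.cell_meta.reset_index()
        if "index" in meta.columns:
            meta = meta.rename(columns={"index": "cell_id"})
        meta.to_csv(path / "cells.tsv", sep="\t", index=False)
    elif fmt == "dense_tsv":
        df = pd.DataFrame(m.dense().astype(int), index=m.genes, columns=m.cells)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one symbol per line, '#' comments."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# quality control and normalisation
# ---------------------------------------------------------------------------

def qc_filter(
    m: CountMatrix,
    min_genes_per_cell: int = MIN_GENES_PER_CELL,
    min_cells_per_gene: int = MIN_CELLS_PER_GENE,
    max_mito_frac: float = MAX_MITO_FRAC,
    mito_prefix: str = MITO_PREFIX,
) -> CountMatrix:
    """Standard scRNA-seq QC: keep cells with strictly more than
    ``min_genes_per_cell`` detected genes (count > 0) and mitochondrial UMI
    fraction at most ``max_mito_frac``; then keep genes detected in at least
    ``min_cells_per_gene`` of the retained cells.

    Gene filtering is recomputed after cell removal, so the operation is
    idempotent.
    """
    counts = m.counts
    detected = counts.copy()
    detected.data = np.ones_like(detected.data)
    genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()

    mito_mask = np.array([g.startswith(mito_prefix) for g in m.genes])
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1.0), 0.0)

    cell_keep = (genes_per_cell > min_genes_per_cell) & (mito_frac <= max_mito_frac)
    if not cell_keep.any():
        raise EmptyResultError("qc_filter removed every cell")

    cells_per_gene = np.asarray(detected[:, cell_keep].sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= min_cells_per_gene

    out = m.subset(gene_keep, cell_keep)
    logger.info(
        "qc_filter: kept %d/%d cells, %d/%d genes "
        "(min_genes>%d, min_cells>=%d, mito<=%.0f%%)",
        cell_keep.sum(), len(m.cells), gene_keep.sum(), len(m.genes),
        min_genes_per_cell, min_cells_per_gene, 100 * max_mito_frac,
    )
    return out


def lognorm(m: CountMatrix, scale: float = LOGNORM_SCALE) -> LogNormMatrix:
    """Library-size normalise to ``scale`` counts per cell and log-transform.

    value(g, c) = log(1 + scale * count(g, c) / total(c)), natural log.
    Zero counts stay exactly zero, so sparsity is preserved.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"cells with zero total counts (run qc_filter first): "
            f"{[m.cells[i] for i in zero[:5]]}"
        )
    mat = sp.csc_matrix(m.counts, dtype=float)
    # scale columns in place on the CSC representation
    for j in range(mat.shape[1]):
        sl = slice(mat.indptr[j], mat.indptr[j + 1])
        mat.data[sl] = np.log1p(scale * mat.data[sl] / totals[j])
    return LogNormMatrix(list(m.genes), list(m.cells), sp.csr_matrix(mat), m.cell_meta, scale)
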