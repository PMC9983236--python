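"""Reading/writing standard formats, QC filtering and normalization.

Single-cell matrices are exchanged as MatrixMarket ``.mtx`` (genes x cells,
1-based per the standard) with sidecar ``genes.tsv`` / ``barcodes.tsv`` /
``labels.tsv``, or as dense TSV. Bulk matrices are genes x samples TSV.

QC follows the common droplet workflow: discard low-complexity and
high-mitochondrial cells first, then rarely detected genes. Single-cell
normalization is counts-per-``scale`` followed by ln(1 + x). Bulk
normalization uses median-of-ratios size factors (the DESeq-style estimator):
the per-gene reference is the geometric mean across samples over genes with
no zero, and a sample's factor is the median ratio of its values to that
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import BulkMatrix, CellMatrix


@dataclass
class QCReport:
    """Counts of cells/genes removed per QC rule."""

    cells_low_genes: int = 0
    cells_high_mito: int = 0
    genes_low_cells: int = 0
    n_cells_before: int = 0
    n_cells_after: int = 0
    n_genes_before: int = 0
    n_genes_after: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class EmptyMatrixError(ValueError):
    """Raised when QC removes every cell or every gene."""

    def __init__(self, message: str, report: QCReport):
        super().__init__(message)
        self.report = report


def qc_filter(
    cm: CellMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 10,
    max_mito_frac: float = 0.10,
) -> tuple[CellMatrix, QCReport]:
    """Remove poor-quality cells, then rarely detected genes.

    A cell is dropped if it expresses fewer than ``min_genes_per_cell`` genes
    (strictly less) or its mitochondrial count fraction exceeds
    ``max_mito_frac`` (strictly greater). Afterwards genes detected in fewer
    than ``min_cells_per_gene`` of the surviving cells are dropped.
    """
    counts = cm.counts
    report = QCReport(n_cells_before=cm.n_cells, n_genes_before=cm.n_genes)

    detected = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0).astype(float)
    mito = counts[cm.mito_mask].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)

    low_genes = detected < min_genes_per_cell
    high_mito = mito_frac > max_mito_frac
    keep_cells = ~(low_genes | high_mito)
    report.cells_low_genes = int(low_genes.sum())
    report.cells_high_mito = int((high_mito & ~low_genes).sum())

    sub = counts[:, keep_cells]
    gene_cells = (sub > 0).sum(axis=1)
    keep_genes = gene_cells >= min_cells_per_gene
    report.genes_low_cells = int((~keep_genes).sum())
    report.n_cells_after = int(keep_cells.sum())
    report.n_genes_after = int(keep_genes.sum())

    if report.n_cells_after == 0 or report.n_genes_after == 0:
        raise EmptyMatrixError("QC filtering removed all cells or genes", report)

    out = cm.subset(
        gene_idx=np.flatnonzero(keep_genes), cell_idx=np.flatnonzero(keep_cells)
    )
    out.lognorm = None  # counts changed; normalization must be redone
    return out, report


def lognormalize(cm: CellMatrix, scale: float = 1e4) -> CellMatrix:
    """Fill ``lognorm`` with ln(1 + scale * count / cell_total).

    Counts are left untouched. Cells with zero total counts are an error —
    they should have been removed by :func:`qc_filter`.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = cm.cell_ids[totals == 0]
        raise ValueError(f"cells with zero total counts: {list(bad[:5])}")
    out = cm.copy()
    out.lognorm = np.log1p(scale * cm.counts / totals)
    return out


def size_factors_median_ratio(raw_bulk: BulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one per sample.

    Reference = per-gene geometric mean over samples, computed over genes
    nonzero in every sample; factor_s = median_g(values[g, s] / reference[g]).
    """
    v = raw_bulk.values
    all_nonzero = np.all(v > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError("no gene is nonzero in all samples; cannot form reference")
    sub = v[all_nonzero]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    return np.exp(np.median(ratios, axis=0))


def normalize_bulk(raw_bulk: BulkMatrix) -> tuple[BulkMatrix, np.ndarray]:
    """Divide each sample by its median-of-ratios size factor."""
    factors = size_factors_median_ratio(raw_bulk)
    return (
        BulkMatrix(
            values=raw_bulk.values / factors[None, :],
            gene_ids=raw_bulk.gene_ids,
            sample_ids=raw_bulk.sample_ids,
            normalized=True,
        ),
        factors,
    )


# ---------------------------------------------------------------------------
# readers / writers


def write_sc_dir(cm: CellMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(cm.counts))
    pd.Series(cm.gene_ids.astype(str)).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(cm.cell_ids.astype(str)).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if cm.labels is not None:
        pd.DataFrame({"cell_id": cm.cell_ids.astype(str), "label": cm.labels}).to_csv(
            outdir / "labels.tsv", sep="\t", index=False
        )


def read_sc_dir(indir: str | Path) -> CellMatrix:
    indir = Path(indir)
    counts = scipy.io.mmread(indir / "matrix.mtx")
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    labels = None
    labels_path = indir / "labels.tsv"
    if labels_path.exists():
        lab = pd.read_csv(labels_path, sep="\t").set_index("cell_id")["label"]
        labels = lab.reindex(cells.astype(str)).to_numpy()
    return CellMatrix(counts=counts, gene_ids=genes, cell_ids=cells, labels=labels)


def read_sc_tsv(path: str | Path, labels_path: str | Path | None = None) -> CellMatrix:
    """Dense TSV fallback: genes as rows, cells as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t").set_index("cell_id")["label"]
        labels = lab.reindex(df.columns).to_numpy()
    return CellMatrix(
        counts=df.to_numpy(),
        gene_ids=df.index.to_numpy(),
        cell_ids=df.columns.to_numpy(),
        labels=labels,
    )


def write_bulk_tsv(bulk: BulkMatrix, path: str | Path) -> None:
    bulk.to_frame().to_csv(path, sep="\t")


def read_bulk_tsv(path: str | Path, normalized: bool = False) -> BulkMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BulkMatrix(
        values=df.to_numpy(),
        gene_ids=df.index.to_numpy(),
        sample_ids=df.columns.to_numpy(),
        normalized=normalized,
    )
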