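"""In-memory containers for single-cell and bulk expression data.

Both containers are thin, genes-x-observations dataclasses. ``CellMatrix``
holds raw counts plus (optionally) log-normalized values, per-cell cluster
labels and a mitochondrial gene mask; ``BulkMatrix`` holds a genes-x-samples
expression table. Conversion to :class:`anndata.AnnData` is provided for
interoperability with the scanpy ecosystem (AnnData is cells x genes, i.e.
the transpose of these containers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _as_dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")


@dataclass
class CellMatrix:
    """Genes x cells expression with per-cell labels.

    Parameters
    ----------
    counts
        Raw counts, shape (n_genes, n_cells). Sparse input is densified.
    gene_ids, cell_ids
        Unique string identifiers.
    labels
        Per-cell cluster/cell-type labels, or None if unannotated.
    mito_mask
        Per-gene boolean; defaults to ``gene_ids`` starting with ``"MT-"``.
    lognorm
        Log-normalized values, same shape as counts; filled by
        :func:`tmex.io_norm.lognormalize`.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: np.ndarray | None = None
    mito_mask: np.ndarray | None = None
    lognorm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != c:
            raise ValueError("cell_ids length does not match counts columns")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != c:
                raise ValueError("labels length does not match cell count")
        if self.mito_mask is None:
            self.mito_mask = np.array(
                [str(gid).startswith("MT-") for gid in self.gene_ids]
            )
        else:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
            if len(self.mito_mask) != g:
                raise ValueError("mito_mask length does not match gene count")
        if self.lognorm is not None:
            self.lognorm = _as_dense(self.lognorm).astype(float)
            if self.lognorm.shape != self.counts.shape:
                raise ValueError("lognorm shape differs from counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cluster_names(self) -> list[str]:
        if self.labels is None:
            raise ValueError("CellMatrix has no labels")
        return sorted(set(self.labels))

    def cells_of(self, cluster: str) -> np.ndarray:
        """Column indices of cells belonging to ``cluster``."""
        if self.labels is None:
            raise ValueError("CellMatrix has no labels")
        idx = np.flatnonzero(self.labels == cluster)
        if idx.size == 0:
            raise KeyError(f"unknown cluster {cluster!r}")
        return idx

    def subset(self, gene_idx=None, cell_idx=None) -> "CellMatrix":
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CellMatrix(
            counts=self.counts[np.ix_(gi, ci)],
            gene_ids=self.gene_ids[gi],
            cell_ids=self.cell_ids[ci],
            labels=None if self.labels is None else self.labels[ci],
            mito_mask=self.mito_mask[gi],
            lognorm=None if self.lognorm is None else self.lognorm[np.ix_(gi, ci)],
        )

    def copy(self) -> "CellMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            lognorm=None if self.lognorm is None else self.lognorm.copy(),
        )

    def to_anndata(self):
        """Return an AnnData view (cells x genes) with counts in ``layers``."""
        import anndata as ad

        X = self.counts.T if self.lognorm is None else self.lognorm.T
        adata = ad.AnnData(
            X=np.asarray(X, dtype=float),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell")),
            var=pd.DataFrame(
                {"mito": self.mito_mask},
                index=pd.Index(self.gene_ids.astype(str), name="gene"),
            ),
            layers={"counts": np.asarray(self.counts.T, dtype=float)},
        )
        if self.labels is not None:
            adata.obs["cluster"] = pd.Categorical(self.labels.astype(str))
        return adata


@dataclass
class BulkMatrix:
    """Genes x samples bulk expression table."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = _as_dense(self.values).astype(float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match rows")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match columns")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if np.any(self.values < 0):
            raise ValueError("bulk values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids.astype(str), name="gene"),
            columns=pd.Index(self.sample_ids.astype(str), name="sample"),
        )

    def log2p1(self) -> np.ndarray:
        """log2(x + 1) of the values; the scale used for all correlation work."""
        return np.log2(self.values + 1.0)
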