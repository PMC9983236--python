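"""Per-cluster marker detection and signature assembly.

Markers are found one-vs-rest per cluster with a Wilcoxon rank-sum test
(normal approximation, tie-corrected) on log-normalized values. Genes are
pre-filtered on the fraction of expressing cells (``pct_in >= min_pct``,
"expressing" meaning lognorm > 0) and on log2 fold-change before testing;
p-values are BH-adjusted within each cluster's tested set.

log2FC convention: ``log2((mean(expm1(lognorm_in)) + 1) /
(mean(expm1(lognorm_out)) + 1))`` — cluster mean vs rest on the
de-logged scale with a pseudocount of 1.

Signatures keep, per cell type, the genes with ``pct_in`` strictly over 25%
and log2FC strictly greater than 0.5 (both thresholds exposed), ordered by
log2FC descending.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import CellMatrix

MARKER_COLUMNS = ["gene", "cluster", "log2fc", "pct_in", "pct_out", "p", "p_adj"]


@dataclass
class SignatureSet:
    """Per-cell-type marker-gene lists plus the records that admitted them."""

    genes: dict[str, list[str]]
    records: pd.DataFrame
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, gs in self.genes.items():
            if len(set(gs)) != len(gs):
                raise ValueError(f"duplicate signature genes for {t}")

    def cell_types(self) -> list[str]:
        return sorted(self.genes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"genes": self.genes, "thresholds": self.thresholds}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            genes=obj["genes"],
            records=pd.DataFrame(columns=MARKER_COLUMNS),
            thresholds=obj.get("thresholds", {}),
        )


def _log2fc(lognorm: np.ndarray, in_idx: np.ndarray, out_idx: np.ndarray):
    mean_in = np.expm1(lognorm[:, in_idx]).mean(axis=1)
    mean_out = np.expm1(lognorm[:, out_idx]).mean(axis=1)
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def find_markers(
    cm: CellMatrix, min_pct: float = 0.10, min_log2fc: float = 0.5
) -> pd.DataFrame:
    """One-vs-rest marker table for every cluster.

    Returns a DataFrame with columns gene, cluster, log2fc, pct_in, pct_out,
    p, p_adj. Clusters with fewer than 3 cells are skipped with a warning.
    """
    if cm.lognorm is None:
        raise ValueError("lognormalize the matrix before marker detection")
    if cm.labels is None:
        raise ValueError("cell labels required for marker detection")
    clusters = cm.cluster_names()
    if len(clusters) < 2:
        raise ValueError("marker detection needs at least 2 clusters")

    x = cm.lognorm
    expressed = x > 0
    rows = []
    for cl in clusters:
        in_idx = cm.cells_of(cl)
        if in_idx.size < 3:
            warnings.warn(f"cluster {cl!r} has <3 cells; skipped", stacklevel=2)
            continue
        out_idx = np.setdiff1d(np.arange(cm.n_cells), in_idx)
        pct_in = expressed[:, in_idx].mean(axis=1)
        pct_out = expressed[:, out_idx].mean(axis=1)
        lfc = _log2fc(x, in_idx, out_idx)
        tested = np.flatnonzero((pct_in >= min_pct) & (lfc >= min_log2fc))
        if tested.size == 0:
            continue
        res = mannwhitneyu(
            x[np.ix_(tested, in_idx)],
            x[np.ix_(tested, out_idx)],
            alternative="two-sided",
            method="asymptotic",
            use_continuity=False,
            axis=1,
        )
        p = np.atleast_1d(res.pvalue)
        p_adj = multipletests(p, method="fdr_bh")[1]
        for k, gi in enumerate(tested):
            rows.append(
                (
                    str(cm.gene_ids[gi]),
                    cl,
                    float(lfc[gi]),
                    float(pct_in[gi]),
                    float(pct_out[gi]),
                    float(p[k]),
                    float(p_adj[k]),
                )
            )
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def build_signatures(
    markers: pd.DataFrame,
    min_pct: float = 0.25,
    min_log2fc: float = 0.5,
    max_genes: int | None = None,
) -> SignatureSet:
    """Assemble per-type signatures from a marker table.

    Both thresholds are strict inequalities: a gene qualifies if its
    expressing fraction is over ``min_pct`` and its log2FC greater than
    ``min_log2fc``. Genes are ordered by log2FC descending, truncated to
    ``max_genes`` if given. A cell type with no passing gene is an error.
    """
    genes: dict[str, list[str]] = {}
    kept_records = []
    for cl, sub in markers.groupby("cluster", sort=True):
        passing = sub[(sub["pct_in"] > min_pct) & (sub["log2fc"] > min_log2fc)]
        passing = passing.sort_values(
            ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
        )
        if max_genes is not None:
            passing = passing.head(max_genes)
        if passing.empty:
            raise ValueError(f"no signature genes pass thresholds for {cl!r}")
        genes[str(cl)] = passing["gene"].tolist()
        kept_records.append(passing)
    if not genes:
        raise ValueError("marker table is empty")
    return SignatureSet(
        genes=genes,
        records=pd.concat(kept_records, ignore_index=True),
        thresholds={"min_pct": min_pct, "min_log2fc": min_log2fc},
    )
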