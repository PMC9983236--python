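"""Gene-set scoring: binned-control module scores and single-sample GSEA.

``module_score`` is the Tirosh-style per-cell score: the mean expression of
the set minus the mean of control genes sampled, with replacement, from
expression-matched bins (genes binned by their average expression across
cells). It is shift-invariant by construction and centered near zero on
exchangeable data.

``ssgsea`` is the rank-based single-sample enrichment score: genes are
ranked by expression descending (ties broken by gene id for determinism);
the score is the sum over ranks of the difference between the weighted
in-set ECDF (weights = rank-value ** alpha, normalized) and the out-set
ECDF, divided by the number of genes to bound the scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellMatrix


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, source, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], genes=parts[2:], source=parts[1]))
    return sets


def module_score(
    cm: CellMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score with bin-matched control genes.

    Genes are cut into ``n_bins`` equal-size bins of average expression; for
    each gene-set gene, ``n_ctrl`` controls are sampled with replacement from
    its bin. Score = mean(set expression) - mean(control expression) per
    cell. Deterministic given ``seed``. Gene-set genes absent from the
    matrix are dropped with a warning.
    """
    if cm.lognorm is None:
        raise ValueError("lognormalized values required")
    if cm.n_genes < n_bins:
        raise ValueError("fewer genes than bins")
    gene_ids = cm.gene_ids.astype(str)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in gs.genes if g in gene_pos]
    if not present:
        raise ValueError(f"no gene of set {gs.name!r} present in the matrix")
    if len(present) < len(gs.genes):
        warnings.warn(
            f"{len(gs.genes) - len(present)} genes of {gs.name!r} absent; dropped",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    avg = cm.lognorm.mean(axis=1)
    # equal-size bins on the rank of average expression (ties split stably)
    order = pd.Series(avg, index=gene_ids).rank(method="first")
    bins = pd.qcut(order, q=n_bins, labels=False, duplicates="drop")
    bin_members = {b: np.flatnonzero(bins.to_numpy() == b) for b in np.unique(bins)}

    set_idx = np.array([gene_pos[g] for g in present])
    ctrl_rows = []
    for gi in set_idx:
        pool = bin_members[int(bins.iloc[gi])]
        ctrl_rows.append(pool[rng.integers(0, len(pool), size=n_ctrl)])
    ctrl_idx = np.concatenate(ctrl_rows)

    score = cm.lognorm[set_idx].mean(axis=0) - cm.lognorm[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=cm.cell_ids.astype(str), name=gs.name)


def ssgsea(values: pd.Series, gs: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of ``gs`` in one expression profile.

    ``values`` maps gene id -> expression. The gene set must be a strict,
    nonempty subset of the profiled genes.
    """
    values = values.sort_index(kind="mergesort")  # stable tie-break by gene id
    n = len(values)
    in_set = values.index.isin(gs.genes)
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("gene set must be a strict, nonempty subset of the genes")
    # descending expression; mergesort keeps the gene-id order among ties
    order = np.argsort(-values.to_numpy(), kind="mergesort")
    in_ordered = in_set[order]
    rank_value = np.arange(n, 0, -1, dtype=float)  # top gene gets n
    w = np.where(in_ordered, rank_value**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ordered) / (n - n_in)
    return float(np.sum(p_in - p_out) / n)


def ssgsea_matrix(
    cm: CellMatrix,
    sets: list[GeneSet],
    alpha: float = 0.25,
    group_by: bool = False,
) -> pd.DataFrame:
    """ssGSEA per cell, or per cluster pseudobulk when ``group_by`` is set."""
    if cm.lognorm is None:
        raise ValueError("lognormalized values required")
    gene_ids = cm.gene_ids.astype(str)
    if group_by:
        cols = {
            t: pd.Series(cm.lognorm[:, cm.cells_of(t)].mean(axis=1), index=gene_ids)
            for t in cm.cluster_names()
        }
    else:
        cols = {
            str(cid): pd.Series(cm.lognorm[:, i], index=gene_ids)
            for i, cid in enumerate(cm.cell_ids)
        }
    return pd.DataFrame(
        {name: {gs.name: ssgsea(vals, gs, alpha=alpha) for gs in sets}
         for name, vals in cols.items()}
    )


def zscore_across_groups(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize each gene set (row) across groups (columns), sample sd.

    Rows with zero variance are returned as all zeros (degenerate).
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 groups to z-normalize")
    m = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    z = scores.sub(m, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return z.fillna(0.0)
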