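"""Cell-type co-occurrence network from paired bulk and single-cell data.

The procedure infers which cell types tend to co-occur across a bulk cohort:

1. Estimate each cell type's relative abundance per bulk sample as the mean
   log2(x+1) expression of its signature genes.
2. Correlate every gene's bulk profile (log2(x+1)) with each type's
   abundance (Pearson, across samples).
3. For a focal type, drop its self-expressed genes (mean lognorm over the
   type's cells > ``expr_min`` AND expressing fraction > ``freq_min`` in the
   single-cell data) and keep the top-k remaining genes by signed
   correlation — the type's candidate co-occurrence program.
4. Score the candidate program against every cell type in the single-cell
   data: mean lognorm of the candidate genes per type, z-scored across types
   (sample sd, T-1 denominator).
5. A directed hit i->j exists when z[i][j] strictly exceeds the threshold
   (default 1.28, the one-sided 90% normal point); an undirected edge takes
   the maximum of the two directed scores when both pass, else the single
   passing score.

Hub types are ranked by undirected degree, then weighted degree, then id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BulkMatrix, CellMatrix
from .markers import SignatureSet


@dataclass
class AbundanceMatrix:
    """Cell type x bulk sample relative-abundance scores."""

    scores: pd.DataFrame
    provenance: str = ""


@dataclass
class CorrelationTable:
    """Gene x cell type Pearson correlations across bulk samples."""

    r: pd.DataFrame
    n_samples: int
    undefined: pd.Index = field(default_factory=lambda: pd.Index([]))


@dataclass
class CooccurrenceNetwork:
    """Directed enrichment z-scores and the derived undirected edges."""

    z: pd.DataFrame  # z.loc[i, j] = enrichment of type j on i's candidates
    threshold: float
    edges: list[tuple[str, str, float]]
    candidate_genes: dict[str, list[str]] = field(default_factory=dict)
    self_excluded: dict[str, set[str]] = field(default_factory=dict)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.z.index)
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=float(w))
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, w, float(self.z.loc[i, j]), float(self.z.loc[j, i]))
            for i, j, w in self.edges
        ]
        return pd.DataFrame(rows, columns=["type_i", "type_j", "weight", "z_ij", "z_ji"])


def estimate_abundance(bulk: BulkMatrix, signatures: SignatureSet) -> AbundanceMatrix:
    """Mean log2(x+1) signature-gene expression per type and sample."""
    if not bulk.normalized:
        warnings.warn("bulk matrix is not flagged as normalized", stacklevel=2)
    logb = pd.DataFrame(
        bulk.log2p1(), index=bulk.gene_ids.astype(str), columns=bulk.sample_ids
    )
    rows = {}
    for t in signatures.cell_types():
        genes = [g for g in signatures.genes[t] if g in logb.index]
        missing = len(signatures.genes[t]) - len(genes)
        if not genes:
            raise ValueError(f"no signature genes of {t!r} found in bulk matrix")
        if missing:
            warnings.warn(
                f"{missing} signature genes of {t!r} missing from bulk", stacklevel=2
            )
        rows[t] = logb.loc[genes].mean(axis=0)
    return AbundanceMatrix(scores=pd.DataFrame(rows).T, provenance="signature-mean")


def correlate_genes(bulk: BulkMatrix, abundance: AbundanceMatrix) -> CorrelationTable:
    """Pearson r between every gene's log2(x+1) profile and each abundance row.

    Zero-variance genes get r = 0 and are flagged undefined.
    """
    n = bulk.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to correlate")
    x = bulk.log2p1()
    a = abundance.scores.to_numpy()
    if np.any(a.std(axis=1) == 0):
        raise ValueError("abundance row with zero variance")

    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc.std(axis=1)
    ac = a - a.mean(axis=1, keepdims=True)
    as_ = a.std(axis=1)
    undefined = xs == 0
    denom = np.where(undefined, 1.0, xs)
    r = (xc @ ac.T) / n / (denom[:, None] * as_[None, :])
    r[undefined, :] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return CorrelationTable(
        r=pd.DataFrame(
            r, index=bulk.gene_ids.astype(str), columns=abundance.scores.index
        ),
        n_samples=n,
        undefined=pd.Index(bulk.gene_ids.astype(str)[undefined]),
    )


def self_expressed_genes(
    cm: CellMatrix, cell_type: str, expr_min: float = 1.0, freq_min: float = 0.20
) -> set[str]:
    """Genes the focal type expresses itself (mean lognorm > expr_min AND
    expressing-cell fraction > freq_min; both strict)."""
    if cm.lognorm is None:
        raise ValueError("lognormalized values required")
    idx = cm.cells_of(cell_type)
    mean_expr = cm.lognorm[:, idx].mean(axis=1)
    freq = (cm.lognorm[:, idx] > 0).mean(axis=1)
    mask = (mean_expr > expr_min) & (freq > freq_min)
    return {str(g) for g in cm.gene_ids[mask]}


def select_candidate_genes(
    corr: CorrelationTable,
    cm: CellMatrix,
    cell_type: str,
    expr_min: float = 1.0,
    freq_min: float = 0.20,
    k: int = 20,
    abs_corr: bool = False,
) -> tuple[list[str], set[str]]:
    """Top-k correlated non-self-expressed genes for a cell type.

    Ranking uses signed r descending by default (``abs_corr`` switches to
    magnitude). Genes flagged undefined never enter the list. Returns the
    candidate list and the excluded self-expressed set.
    """
    if cell_type not in corr.r.columns:
        raise KeyError(f"cell type {cell_type!r} absent from correlation table")
    excluded = self_expressed_genes(cm, cell_type, expr_min, freq_min)
    shared = [g for g in corr.r.index if g not in excluded and g not in corr.undefined]
    r = corr.r.loc[shared, cell_type]
    key = r.abs() if abs_corr else r
    ranked = key.sort_values(ascending=False, kind="mergesort")
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} candidates available for {cell_type!r} (k={k})",
            stacklevel=2,
        )
    return list(ranked.index[:k]), excluded


def enrichment_zscores(cm: CellMatrix, gene_list: list[str]) -> pd.Series:
    """Mean candidate-gene expression per cell type, z-scored across types.

    Uses sample sd (T-1). If every type scores identically the result is all
    zeros (degenerate; no type can pass any positive threshold).
    """
    if not gene_list:
        raise ValueError("gene_list is empty")
    if cm.lognorm is None:
        raise ValueError("lognormalized values required")
    types = cm.cluster_names()
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    gene_pos = {str(g): i for i, g in enumerate(cm.gene_ids)}
    idx = [gene_pos[g] for g in gene_list if g in gene_pos]
    if not idx:
        raise ValueError("no gene of gene_list present in the cell matrix")
    e = np.array(
        [cm.lognorm[np.ix_(idx, cm.cells_of(t))].mean() for t in types]
    )
    sd = e.std(ddof=1)
    z = np.zeros_like(e) if sd == 0 else (e - e.mean()) / sd
    return pd.Series(z, index=types)


def build_network(
    z: pd.DataFrame, threshold: float = 1.28, mutual_only: bool = False
) -> CooccurrenceNetwork:
    """Derive the undirected edge set from the directed z matrix.

    A direction hits iff z > threshold (strict). By default one passing
    direction suffices for an edge; ``mutual_only`` requires both. Edge
    weight = max of the passing scores. Self-pairs are never evaluated.
    """
    types = list(z.index)
    edges = []
    for a in range(len(types)):
        for b in range(a + 1, len(types)):
            i, j = types[a], types[b]
            hit_ij = z.loc[i, j] > threshold
            hit_ji = z.loc[j, i] > threshold
            if hit_ij and hit_ji:
                edges.append((i, j, float(max(z.loc[i, j], z.loc[j, i]))))
            elif (hit_ij or hit_ji) and not mutual_only:
                edges.append((i, j, float(z.loc[i, j] if hit_ij else z.loc[j, i])))
    return CooccurrenceNetwork(z=z, threshold=threshold, edges=edges)


def infer_cooccurrence(
    bulk: BulkMatrix,
    cm: CellMatrix,
    signatures: SignatureSet,
    expr_min: float = 1.0,
    freq_min: float = 0.20,
    k: int = 20,
    threshold: float = 1.28,
    abs_corr: bool = False,
    mutual_only: bool = False,
) -> CooccurrenceNetwork:
    """Run the full five-step procedure and return the network."""
    abundance = estimate_abundance(bulk, signatures)
    corr = correlate_genes(bulk, abundance)
    types = list(abundance.scores.index)
    z = pd.DataFrame(0.0, index=types, columns=types)
    candidates, excluded = {}, {}
    for t in types:
        cand, excl = select_candidate_genes(
            corr, cm, t, expr_min=expr_min, freq_min=freq_min, k=k, abs_corr=abs_corr
        )
        candidates[t], excluded[t] = cand, excl
        z.loc[t, :] = enrichment_zscores(cm, cand).reindex(z.columns).to_numpy()
    net = build_network(z, threshold=threshold, mutual_only=mutual_only)
    net.candidate_genes = candidates
    net.self_excluded = excluded
    return net


def hub_ranking(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Cell types ranked by degree, then weighted degree, then id."""
    types = list(net.z.index)
    degree = {t: 0 for t in types}
    wdegree = {t: 0.0 for t in types}
    for i, j, w in net.edges:
        degree[i] += 1
        degree[j] += 1
        wdegree[i] += w
        wdegree[j] += w
    df = pd.DataFrame(
        {
            "cell_type": types,
            "degree": [degree[t] for t in types],
            "weighted_degree": [wdegree[t] for t in types],
        }
    )
    return df.sort_values(
        ["degree", "weighted_degree", "cell_type"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
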