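"""Permutation-based ligand-receptor interaction scoring between clusters.

For every ordered cluster pair (donor A, acceptor B) and database pair, the
test statistic is the mean of the ligand's cluster-A mean and the receptor's
cluster-B mean (log-normalized scale). A null distribution is built by
shuffling cell labels (preserving the label multiset) and recomputing; the
p-value is the plain proportion of null statistics >= the observed one, so
that exhaustive enumeration and the sampling estimate agree exactly on tiny
instances (a ``plus_one`` flag gives the conservative (k+1)/(n+1) variant).

Genes expressed in less than ``min_expr_frac`` of a cluster's cells are
masked there; a pair whose ligand or receptor is masked for a cluster pair
is skipped, never scored as zero. Significance follows the secreted-ligand
filter: p < alpha AND secreted.

The display statistic reported alongside is sqrt(mean(ligand x receptor) + 1)
over a resampled cell pairing, the convention used for interaction dot plots.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellMatrix
from .simulate import LRDatabase

RESULT_COLUMNS = [
    "cluster_a",
    "cluster_b",
    "pair_id",
    "ligand",
    "receptor",
    "mean_stat",
    "display_stat",
    "p",
    "secreted",
    "significant",
]


def cluster_means(
    cm: CellMatrix, min_expr_frac: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean lognorm, expressing fraction, and mask.

    Returns (means, fractions, masked) gene x cluster frames; ``masked`` is
    True where the expressing fraction is below ``min_expr_frac`` (the gene
    is treated as not expressed in that cluster).
    """
    if cm.lognorm is None:
        raise ValueError("lognormalized values required")
    if cm.labels is None:
        raise ValueError("cell labels required")
    clusters = cm.cluster_names()
    means, fracs = {}, {}
    for cl in clusters:
        idx = cm.cells_of(cl)
        if idx.size == 0:
            raise ValueError(f"empty cluster {cl!r}")
        means[cl] = cm.lognorm[:, idx].mean(axis=1)
        fracs[cl] = (cm.lognorm[:, idx] > 0).mean(axis=1)
    gene_index = pd.Index(cm.gene_ids.astype(str), name="gene")
    means = pd.DataFrame(means, index=gene_index)
    fracs = pd.DataFrame(fracs, index=gene_index)
    return means, fracs, fracs < min_expr_frac


def lr_mean_stat(ligand_mean: float, receptor_mean: float) -> float:
    """Arithmetic mean of the two cluster means."""
    return 0.5 * (ligand_mean + receptor_mean)


def lr_display_stat(
    ligand_cells: np.ndarray,
    receptor_cells: np.ndarray,
    rng: np.random.Generator | None = None,
) -> float:
    """sqrt(mean(ligand x receptor) + 1) over a resampled cell pairing.

    Cells from both clusters are independently resampled to a common length
    max(|A|, |B|) (the full cross product is quadratic); with equal-length
    inputs and no rng the given pairing is used as-is.
    """
    lig = np.asarray(ligand_cells, dtype=float)
    rec = np.asarray(receptor_cells, dtype=float)
    if lig.size == 0 or rec.size == 0:
        raise ValueError("empty cell vector")
    n = max(lig.size, rec.size)
    if rng is None:
        if lig.size != rec.size:
            raise ValueError("unequal lengths require an rng for resampling")
    else:
        lig = lig[rng.integers(0, lig.size, size=n)]
        rec = rec[rng.integers(0, rec.size, size=n)]
    return float(math.sqrt(np.mean(lig * rec) + 1.0))


def _distinct_label_assignments(labels: np.ndarray):
    """All distinct arrangements of the label multiset (tiny n only)."""
    seen = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm, dtype=object)


def permutation_test(
    cm: CellMatrix,
    db: LRDatabase,
    n_perm: int = 1000,
    seed: int = 0,
    min_expr_frac: float = 0.10,
    alpha: float = 0.05,
    require_secreted: bool = True,
    exhaustive: bool = False,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Score every ordered cluster pair against every database pair.

    Returns the result table (one row per unmasked combination) with the
    observed mean statistic, display statistic, permutation p-value, and the
    significance flag (p < alpha AND secreted, unless ``require_secreted``
    is off). ``exhaustive`` enumerates every distinct label assignment
    instead of sampling; only feasible for very small matrices.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    clusters = cm.cluster_names()
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)

    means, _, masked = cluster_means(cm, min_expr_frac=min_expr_frac)
    genes_needed = sorted(
        set(db.pairs["ligand"].astype(str)) | set(db.pairs["receptor"].astype(str))
    )
    present = [g for g in genes_needed if g in means.index]
    gene_pos = {g: i for i, g in enumerate(present)}
    full_pos = {str(g): i for i, g in enumerate(cm.gene_ids)}
    x = cm.lognorm[[full_pos[g] for g in present], :]  # genes_db x cells

    # observed statistic per (pair, A, B); skip masked/absent combinations
    tasks = []  # (row_dict, ligand_pos, receptor_pos, a_idx, b_idx)
    for rec in db.pairs.itertuples(index=False):
        lig, recp = str(rec.ligand), str(rec.receptor)
        if lig not in gene_pos or recp not in gene_pos:
            continue
        for a in clusters:
            for b in clusters:
                if masked.loc[lig, a] or masked.loc[recp, b]:
                    continue
                obs = lr_mean_stat(means.loc[lig, a], means.loc[recp, b])
                disp = lr_display_stat(
                    x[gene_pos[lig], cm.cells_of(a)],
                    x[gene_pos[recp], cm.cells_of(b)],
                    rng=rng,
                )
                tasks.append(
                    (
                        {
                            "cluster_a": a,
                            "cluster_b": b,
                            "pair_id": rec.pair_id,
                            "ligand": lig,
                            "receptor": recp,
                            "mean_stat": obs,
                            "display_stat": disp,
                            "secreted": bool(rec.secreted),
                        },
                        gene_pos[lig],
                        gene_pos[recp],
                        a,
                        b,
                    )
                )
    if not tasks:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    cl_index = {c: k for k, c in enumerate(clusters)}
    labels = cm.labels

    def null_means(perm_labels: np.ndarray) -> np.ndarray:
        """gene x cluster mean matrix under a label assignment."""
        out = np.empty((x.shape[0], len(clusters)))
        for c, k in cl_index.items():
            out[:, k] = x[:, perm_labels == c].mean(axis=1)
        return out

    exceed = np.zeros(len(tasks), dtype=np.int64)
    obs_vec = np.array([t[0]["mean_stat"] for t in tasks])
    lig_idx = np.array([t[1] for t in tasks])
    rec_idx = np.array([t[2] for t in tasks])
    a_idx = np.array([cl_index[t[3]] for t in tasks])
    b_idx = np.array([cl_index[t[4]] for t in tasks])

    if exhaustive:
        n_done = 0
        for perm_labels in _distinct_label_assignments(labels):
            nm = null_means(perm_labels)
            stat = 0.5 * (nm[lig_idx, a_idx] + nm[rec_idx, b_idx])
            exceed += stat >= obs_vec
            n_done += 1
        denom = n_done
    else:
        for _ in range(n_perm):
            perm_labels = labels[rng.permutation(len(labels))]
            nm = null_means(perm_labels)
            stat = 0.5 * (nm[lig_idx, a_idx] + nm[rec_idx, b_idx])
            exceed += stat >= obs_vec
        denom = n_perm

    if plus_one:
        p = (exceed + 1) / (denom + 1)
    else:
        p = exceed / denom

    rows = []
    for t, pv in zip(tasks, p):
        row = dict(t[0])
        row["p"] = float(pv)
        row["significant"] = bool(
            pv < alpha and (row["secreted"] or not require_secreted)
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def filter_significant(
    results: pd.DataFrame, alpha: float = 0.05, require_secreted: bool = True
) -> pd.DataFrame:
    """Keep rows with p < alpha (strict) and, optionally, a secreted ligand."""
    keep = results["p"] < alpha
    if require_secreted:
        keep &= results["secreted"].astype(bool)
    out = results.loc[keep].copy()
    out["significant"] = True
    return out.reset_index(drop=True)


def interaction_strength(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count significant pairs per ordered cluster pair.

    Returns (strength, symmetric) where strength[A, B] counts significant
    pairs with donor A and acceptor B, and symmetric = strength + transpose.
    """
    clusters = sorted(
        set(results["cluster_a"].astype(str)) | set(results["cluster_b"].astype(str))
    )
    strength = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    sig = results[results["significant"].astype(bool)]
    for a, b in zip(sig["cluster_a"], sig["cluster_b"]):
        strength.loc[str(a), str(b)] += 1
    return strength, strength + strength.T
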