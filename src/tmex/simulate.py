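"""Synthetic paired single-cell / bulk data with planted ground truth.

The generator emulates the structure of a tumor-microenvironment study:
an annotated single-cell count matrix with marker-gene structure, bulk
samples that are noisy mixtures of the cell-type mean profiles with a
user-specified correlation structure on the mixing proportions, a
ligand-receptor pair database with cluster-specific planted pairs, and
exponential survival times with a planted gene-signature hazard effect.

Counts are negative-binomial with a dispersion shared across genes. Mixing
proportions follow a logistic-normal: latent Gaussians with the requested
correlation matrix are pushed through a softmax, so realized simplex
correlations are attenuated relative to the latent target. The first 5% of
genes are named ``MT-*`` so mitochondrial QC is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BulkMatrix, CellMatrix


class ConfigError(ValueError):
    """A SimConfig field failed validation; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Defaults describe a desk-scale cohort: 6 cell types of 80 cells over
    1500 genes with 20 four-fold markers each, 200 bulk samples mixed with
    20% multiplicative noise, and a logistic-normal on the mixing-proportion
    logits with scale 0.4 (chosen so a latent correlation of 0.8 realizes
    near 0.65 on the simplex after softmax closure).
    """

    n_genes: int = 1500
    n_cell_types: int = 6
    cells_per_type: int = 80
    markers_per_type: int = 20
    marker_fold: float = 4.0
    nb_dispersion: float = 0.3
    n_bulk_samples: int = 200
    proportion_corr: np.ndarray | None = None  # identity if None
    proportion_sigma: float = 0.4
    bulk_noise_cv: float = 0.2
    lr_pairs: int = 30
    planted_lr: list[tuple[int, int]] = field(default_factory=list)
    secreted_frac: float = 0.5
    survival_effect_genes: list[str] = field(default_factory=list)
    survival_log_hazard_ratio: float = 0.0
    edge_corr_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_types", "cells_per_type",
                     "markers_per_type", "n_bulk_samples"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("marker_fold", "nb_dispersion", "proportion_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.bulk_noise_cv < 0:
            raise ConfigError("bulk_noise_cv must be nonnegative")
        if self.lr_pairs < 0:
            raise ConfigError("lr_pairs must be a nonnegative count")
        if not 0 <= self.secreted_frac <= 1:
            raise ConfigError("secreted_frac must be in [0, 1]")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ConfigError(
                "markers_per_type x n_cell_types exceeds n_genes"
            )
        if self.proportion_corr is not None:
            c = np.asarray(self.proportion_corr, dtype=float)
            t = self.n_cell_types
            if c.shape != (t, t):
                raise ConfigError("proportion_corr must be n_cell_types square")
            if not np.allclose(c, c.T):
                raise ConfigError("proportion_corr must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ConfigError("proportion_corr must have unit diagonal")
            if np.any(np.abs(c) > 1 + 1e-12):
                raise ConfigError("proportion_corr entries must be in [-1, 1]")
            self.proportion_corr = c
        for pair in self.planted_lr:
            a, b = pair
            if not (0 <= a < self.n_cell_types and 0 <= b < self.n_cell_types):
                raise ConfigError("planted_lr references a nonexistent cluster")

    def corr_matrix(self) -> np.ndarray:
        if self.proportion_corr is None:
            return np.eye(self.n_cell_types)
        return np.asarray(self.proportion_corr, dtype=float)

    def type_names(self) -> list[str]:
        return [f"type{t}" for t in range(self.n_cell_types)]


@dataclass
class LRDatabase:
    """Ligand-receptor pair records: (pair_id, ligand, receptor, secreted)."""

    pairs: pd.DataFrame  # columns: pair_id, ligand, receptor, secreted

    def __post_init__(self) -> None:
        required = {"pair_id", "ligand", "receptor", "secreted"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"LRDatabase needs columns {sorted(required)}")
        if self.pairs["pair_id"].duplicated().any():
            raise ValueError("pair_ids must be unique")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        out = self.pairs[["ligand", "receptor", "secreted"]].copy()
        out["secreted"] = out["secreted"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LRDatabase":
        df = pd.read_csv(path)
        df["secreted"] = df["secreted"].astype(bool)
        df["pair_id"] = df["ligand"].astype(str) + "_" + df["receptor"].astype(str)
        return cls(pairs=df[["pair_id", "ligand", "receptor", "secreted"]])


@dataclass
class GroundTruth:
    """Planted structure recorded alongside the simulated data."""

    true_labels: np.ndarray | None = None
    true_markers: dict[str, list[str]] = field(default_factory=dict)
    true_proportions: pd.DataFrame | None = None  # types x samples
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_lr_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    survival_groups: np.ndarray | None = None

    def to_json(self, path) -> None:
        obj = {
            "true_markers": self.true_markers,
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "planted_lr_pairs": [list(p) for p in self.planted_lr_pairs],
        }
        if self.true_labels is not None:
            obj["true_labels"] = [str(x) for x in self.true_labels]
        if self.true_proportions is not None:
            obj["true_proportions"] = {
                t: [float(v) for v in row]
                for t, row in self.true_proportions.iterrows()
            }
        if self.survival_groups is not None:
            obj["survival_groups"] = [int(x) for x in self.survival_groups]
        Path(path).write_text(json.dumps(obj, indent=1))


def nearest_psd(corr: np.ndarray, clip: float = 1e-8, repair_limit: float = 0.3):
    """Eigenvalue-clipping nearest-PSD repair of a correlation matrix.

    Eigenvalues in ``(-repair_limit, clip)`` are lifted to ``clip`` and the
    matrix is rescaled back to unit diagonal; anything below ``-repair_limit``
    is treated as a genuinely infeasible target and raises.
    """
    w, v = np.linalg.eigh(corr)
    if w.min() >= clip:
        return corr
    if w.min() < -repair_limit:
        raise ValueError(
            f"proportion_corr is non-PSD beyond repair (min eigenvalue {w.min():.3g})"
        )
    w = np.clip(w, clip, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    lam = rng.gamma(shape=size, scale=np.maximum(mu, 1e-300) / size)
    return rng.poisson(lam).astype(np.int64)


def _gene_ids(n_genes: int) -> np.ndarray:
    n_mito = max(1, int(round(0.05 * n_genes)))
    ids = [f"MT-{i:04d}" for i in range(n_mito)]
    ids += [f"G{i:05d}" for i in range(n_genes - n_mito)]
    return np.asarray(ids, dtype=object)


def simulate_sc(config: SimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Negative-binomial counts with per-type marker structure.

    Marker blocks are laid out after the mitochondrial block; each type's
    markers have mean ``marker_fold`` x baseline in that type only.
    """
    rng = np.random.default_rng(config.seed)
    g, t, c = config.n_genes, config.n_cell_types, config.cells_per_type
    gene_ids = _gene_ids(g)
    n_mito = int(np.sum([str(x).startswith("MT-") for x in gene_ids]))
    if n_mito + config.markers_per_type * t > g:
        raise ConfigError(
            "markers_per_type x n_cell_types leaves no room after the mito block"
        )

    baseline = rng.lognormal(mean=0.0, sigma=0.5, size=g)
    mean_profiles = np.tile(baseline[:, None], (1, t))
    true_markers: dict[str, list[str]] = {}
    type_names = config.type_names()
    for k, name in enumerate(type_names):
        lo = n_mito + k * config.markers_per_type
        hi = lo + config.markers_per_type
        mean_profiles[lo:hi, k] *= config.marker_fold
        true_markers[name] = [str(x) for x in gene_ids[lo:hi]]

    labels = np.repeat(type_names, c)
    counts = np.empty((g, t * c), dtype=np.int64)
    for k in range(t):
        mu = np.tile(mean_profiles[:, k][:, None], (1, c))
        counts[:, k * c : (k + 1) * c] = _nb_draw(rng, mu, config.nb_dispersion)

    cm = CellMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=np.asarray([f"cell{i:05d}" for i in range(t * c)], dtype=object),
        labels=labels,
    )
    truth = GroundTruth(true_labels=labels.copy(), true_markers=true_markers)
    return cm, truth


def _type_mean_profiles(cm: CellMatrix) -> pd.DataFrame:
    types = cm.cluster_names()
    prof = np.column_stack(
        [cm.counts[:, cm.cells_of(t)].mean(axis=1) for t in types]
    )
    return pd.DataFrame(prof, index=cm.gene_ids.astype(str), columns=types)


def simulate_bulk(
    cm: CellMatrix,
    truth: GroundTruth,
    config: SimConfig,
    proportions: pd.DataFrame | None = None,
) -> tuple[BulkMatrix, GroundTruth]:
    """Bulk samples as noisy mixtures of the cell-type mean profiles.

    Proportions are logistic-normal: latent Gaussian logits with correlation
    ``proportion_corr`` (nearest-PSD repaired) scaled by ``proportion_sigma``,
    softmaxed per sample. Expression = profiles @ proportions, times
    lognormal noise with coefficient of variation ``bulk_noise_cv``.
    ``proportions`` overrides the draw (rows = cell types, columns sum to 1).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    profiles = _type_mean_profiles(cm)
    types = list(profiles.columns)
    t, n = len(types), config.n_bulk_samples

    if proportions is None:
        corr = nearest_psd(config.corr_matrix())
        chol = np.linalg.cholesky(corr)
        z = chol @ rng.standard_normal((t, n))
        logits = config.proportion_sigma * z
        expz = np.exp(logits - logits.max(axis=0, keepdims=True))
        props = expz / expz.sum(axis=0, keepdims=True)
        proportions = pd.DataFrame(
            props, index=types, columns=[f"S{i:04d}" for i in range(n)]
        )
    else:
        if list(proportions.index) != types:
            raise ValueError("proportions rows must match cell types")
        colsums = proportions.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("proportions columns must sum to 1")

    clean = profiles.to_numpy() @ proportions.to_numpy()
    if config.bulk_noise_cv > 0:
        sigma2 = np.log1p(config.bulk_noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=clean.shape)
    else:
        noise = 1.0
    bulk = BulkMatrix(
        values=clean * noise,
        gene_ids=profiles.index.to_numpy(),
        sample_ids=proportions.columns.to_numpy(),
        normalized=False,
    )
    truth.true_proportions = proportions
    corr = config.corr_matrix()
    truth.planted_edges = {
        (types[i], types[j])
        for i in range(t)
        for j in range(i + 1, t)
        if abs(corr[i, j]) > config.edge_corr_threshold
    }
    return bulk, truth


def simulate_lr_db(
    config: SimConfig, cm: CellMatrix, truth: GroundTruth
) -> LRDatabase:
    """Ligand-receptor database with planted cluster-specific pairs.

    A planted pair ``(a, b)`` takes its ligand from cluster a's marker genes
    and its receptor from cluster b's (genes not already used by another
    pair), so the ligand is up-regulated in the donor and the receptor in the
    acceptor. Decoys draw from uniformly expressed non-marker genes. The
    secreted fraction is exact: planted pairs are always secreted, decoys
    fill the remainder.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    type_names = config.type_names()
    if len(config.planted_lr) > config.lr_pairs:
        raise ConfigError("more planted_lr pairs than lr_pairs")

    marker_pool = {t: list(genes) for t, genes in truth.true_markers.items()}
    all_markers = {g for genes in truth.true_markers.values() for g in genes}
    decoy_pool = [
        str(g)
        for g in cm.gene_ids
        if str(g) not in all_markers and not str(g).startswith("MT-")
    ]
    n_decoys = config.lr_pairs - len(config.planted_lr)
    if 2 * n_decoys > len(decoy_pool):
        raise ConfigError("lr_pairs requires more decoy genes than available")

    records = []
    for a, b in config.planted_lr:
        ta, tb = type_names[a], type_names[b]
        if not marker_pool[ta] or not marker_pool[tb]:
            raise ConfigError("not enough marker genes to plant lr pairs")
        lig = marker_pool[ta].pop(0)
        rec = marker_pool[tb].pop(0)
        records.append((f"{lig}_{rec}", lig, rec, True))
        truth.planted_lr_pairs.append((ta, tb, f"{lig}_{rec}"))

    decoy_genes = rng.choice(len(decoy_pool), size=2 * n_decoys, replace=False)
    for i in range(n_decoys):
        lig = decoy_pool[decoy_genes[2 * i]]
        rec = decoy_pool[decoy_genes[2 * i + 1]]
        records.append((f"{lig}_{rec}", lig, rec, False))
    df = pd.DataFrame(records, columns=["pair_id", "ligand", "receptor", "secreted"])
    # planted pairs (first rows) are always secreted; decoys fill up to the
    # exact configured fraction
    n_secreted = int(round(config.secreted_frac * config.lr_pairs))
    n_planted = len(config.planted_lr)
    df["secreted"] = df.index < max(n_secreted, n_planted)
    return LRDatabase(pairs=df)


@dataclass
class SurvivalTable:
    """Sample survival records: time (nonnegative) and event (0/1)."""

    data: pd.DataFrame  # columns: sample, time, event

    def __post_init__(self) -> None:
        required = {"sample", "time", "event"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"SurvivalTable needs columns {sorted(required)}")
        if (self.data["time"] < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not set(self.data["event"].unique()).issubset({0, 1}):
            raise ValueError("event must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalTable":
        return cls(data=pd.read_csv(path))


def simulate_survival(
    bulk: BulkMatrix,
    config: SimConfig,
    truth: GroundTruth | None = None,
    baseline_hazard: float = 0.1,
    censor_max: float = 30.0,
) -> SurvivalTable:
    """Exponential survival with a planted gene-signature hazard effect.

    log-hazard = ``survival_log_hazard_ratio`` x the standardized per-sample
    mean log2(x+1) expression of ``survival_effect_genes``; censoring is
    independent Uniform(0, ``censor_max``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = list(config.survival_effect_genes)
    gene_index = {str(g): i for i, g in enumerate(bulk.gene_ids)}
    missing = [g for g in genes if g not in gene_index]
    if missing:
        raise ValueError(f"survival effect gene absent from bulk: {missing[0]}")
    if genes and config.survival_log_hazard_ratio != 0.0:
        idx = [gene_index[g] for g in genes]
        score = bulk.log2p1()[idx].mean(axis=0)
        sd = score.std(ddof=1)
        z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    else:
        z = np.zeros(bulk.n_samples)
    hazard = baseline_hazard * np.exp(config.survival_log_hazard_ratio * z)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.uniform(0, censor_max, size=bulk.n_samples)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    if truth is not None:
        truth.survival_groups = (z > np.median(z)).astype(int)
    return SurvivalTable(
        data=pd.DataFrame(
            {
                "sample": bulk.sample_ids.astype(str),
                "time": time,
                "event": event,
            }
        )
    )
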