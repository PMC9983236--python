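"""Kaplan-Meier estimation, log-rank testing, and median-split stratification.

Estimation and testing are delegated to ``lifelines``; this module fixes the
conventions used throughout: the High group is strictly above the median
(ties go Low), and a ligand-receptor pair stratifies samples by the mean of
the z-scored log2(x+1) expression of the two genes (the ``both-high`` rule —
High = above median on BOTH genes — is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import BulkMatrix
from .simulate import SurvivalTable


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray  # ascending, including 0
    survival: np.ndarray
    at_risk: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def median_split(values: pd.Series) -> pd.Series:
    """High/Low split at the median; ties at the median go Low."""
    if len(values) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(np.median(values))
    if np.all(values == values.iloc[0]):
        raise ValueError("all values identical; no split possible")
    return pd.Series(
        np.where(values > med, "High", "Low"), index=values.index, name="group"
    )


def km_estimate(surv: SurvivalTable, group: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate."""
    if len(surv) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.data["time"], surv.data["event"])
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    )
    return KMCurve(
        times=times, survival=sf.to_numpy(dtype=float), at_risk=at_risk, group=group
    )


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable):
    """Two-group log-rank test; returns (chi2, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    total_events = int(group_a.data["event"].sum() + group_b.data["event"].sum())
    if total_events == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(
        group_a.data["time"],
        group_b.data["time"],
        event_observed_A=group_a.data["event"],
        event_observed_B=group_b.data["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def split_survival(
    surv: SurvivalTable, groups: pd.Series
) -> dict[str, SurvivalTable]:
    """Partition a survival table by a sample -> group mapping."""
    df = surv.data.set_index("sample")
    out = {}
    for g in sorted(groups.unique()):
        samples = groups.index[groups == g]
        missing = [s for s in samples if s not in df.index]
        if missing:
            raise ValueError(f"samples absent from survival table: {missing[:5]}")
        out[g] = SurvivalTable(
            data=df.loc[samples].rename_axis("sample").reset_index()
        )
    return out


def gene_survival(
    bulk: BulkMatrix, surv: SurvivalTable, gene: str
) -> tuple[KMCurve, KMCurve, float]:
    """Median-split stratification of a single gene; returns (High, Low, p)."""
    return lr_pair_survival(bulk, surv, gene, gene)


def lr_pair_survival(
    bulk: BulkMatrix,
    surv: SurvivalTable,
    ligand: str,
    receptor: str,
    rule: str = "mean-z",
) -> tuple[KMCurve, KMCurve, float]:
    """Stratify samples by joint ligand/receptor expression, then KM + log-rank.

    ``mean-z``: per-sample score = mean of the z-scored log2(x+1) expression
    of the two genes, median-split into High/Low. ``both-high``: High =
    strictly above median on both genes, Low = everyone else. With
    ligand == receptor both rules reduce to single-gene stratification.
    """
    gene_pos = {str(g): i for i, g in enumerate(bulk.gene_ids)}
    for g in (ligand, receptor):
        if g not in gene_pos:
            raise KeyError(f"gene {g!r} absent from bulk matrix")
    samples = pd.Index(bulk.sample_ids.astype(str))
    missing = samples.difference(pd.Index(surv.data["sample"].astype(str)))
    if len(missing):
        raise ValueError(f"bulk samples absent from survival table: {list(missing[:5])}")

    logb = bulk.log2p1()
    lig = pd.Series(logb[gene_pos[ligand]], index=samples)
    rec = pd.Series(logb[gene_pos[receptor]], index=samples)

    def zscore(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    if rule == "mean-z":
        score = (zscore(lig) + zscore(rec)) / 2.0
        groups = median_split(score)
    elif rule == "both-high":
        high = (lig > lig.median()) & (rec > rec.median())
        if high.all() or not high.any():
            raise ValueError("both-high rule produced a single group")
        groups = pd.Series(
            np.where(high, "High", "Low"), index=samples, name="group"
        )
    else:
        raise ValueError(f"unknown rule {rule!r}")

    parts = split_survival(surv, groups)
    _, p = logrank_test(parts["High"], parts["Low"])
    return (
        km_estimate(parts["High"], group="High"),
        km_estimate(parts["Low"], group="Low"),
        p,
    )
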