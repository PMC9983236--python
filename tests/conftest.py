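import numpy as np
import pytest

import tmex


def make_cell_matrix(lognorm, labels=None, gene_ids=None, cell_ids=None):
    """CellMatrix from an explicit lognorm array (counts backfilled)."""
    x = np.asarray(lognorm, dtype=float)
    g, c = x.shape
    return tmex.CellMatrix(
        counts=np.rint(np.expm1(x)).astype(np.int64),
        gene_ids=gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)],
        cell_ids=cell_ids if cell_ids is not None else [f"c{i}" for i in range(c)],
        labels=labels,
        lognorm=x,
    )


@pytest.fixture(scope="session")
def small_world():
    """Default-sized simulated world, QC'd and log-normalized."""
    cfg = tmex.SimConfig(
        n_genes=600, n_cell_types=4, cells_per_type=60, seed=11
    )
    cm, truth = tmex.simulate_sc(cfg)
    cm, _ = tmex.qc_filter(cm)
    cm = tmex.lognormalize(cm)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def small_markers(small_world):
    _, cm, _ = small_world
    return tmex.find_markers(cm)
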