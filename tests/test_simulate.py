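"""Synthetic-data generator: bookkeeping, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

import tmex
from tmex.simulate import ConfigError, nearest_psd


class TestSimConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("cells_per_type", -1),
            ("marker_fold", 0.0),
            ("nb_dispersion", -0.5),
            ("bulk_noise_cv", -0.1),
            ("secreted_frac", 1.5),
        ],
    )
    def test_invalid_fields_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            tmex.SimConfig(**{field: value})

    def test_marker_budget_checked(self):
        with pytest.raises(ConfigError):
            tmex.SimConfig(n_genes=50, n_cell_types=5, markers_per_type=20)

    def test_corr_must_be_symmetric_unit_diagonal(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ConfigError, match="symmetric"):
            tmex.SimConfig(n_cell_types=2, proportion_corr=bad)


class TestNearestPSD:
    def test_psd_matrix_untouched(self):
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.array_equal(nearest_psd(c), c)

    def test_mild_violation_repaired_to_unit_diagonal(self):
        # three mutually 0.8-anticorrelated variables: min eigenvalue < 0
        c = np.full((3, 3), -0.55)
        np.fill_diagonal(c, 1.0)
        fixed = nearest_psd(c, repair_limit=0.2)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_gross_violation_errors(self):
        c = np.array([[1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        with pytest.raises(ValueError, match="non-PSD"):
            nearest_psd(c)


class TestSimulateSC:
    def test_cell_bookkeeping(self):
        cfg = tmex.SimConfig(n_genes=200, n_cell_types=3, cells_per_type=50, seed=0)
        cm, truth = tmex.simulate_sc(cfg)
        assert cm.n_cells == 150
        counts = pd.Series(cm.labels).value_counts()
        assert (counts == 50).all()
        assert set(truth.true_markers) == {"type0", "type1", "type2"}

    def test_determinism_byte_identical(self):
        cfg = tmex.SimConfig(n_genes=200, n_cell_types=3, cells_per_type=20, seed=42)
        a, _ = tmex.simulate_sc(cfg)
        b, _ = tmex.simulate_sc(cfg)
        assert a.counts.tobytes() == b.counts.tobytes()

    def test_null_fold_means_no_marker_structure(self):
        # marker_fold=1: expected expression identical across types, so the
        # planted "marker" genes are no higher in their own type
        cfg = tmex.SimConfig(
            n_genes=400, n_cell_types=3, cells_per_type=100, marker_fold=1.0, seed=5
        )
        cm, truth = tmex.simulate_sc(cfg)
        m0 = truth.true_markers["type0"]
        idx = [list(cm.gene_ids).index(g) for g in m0]
        own = cm.counts[np.ix_(idx, cm.cells_of("type0"))].mean()
        rest = cm.counts[np.ix_(idx, np.flatnonzero(cm.labels != "type0"))].mean()
        assert abs(own - rest) / rest < 0.15

    def test_mito_block_present(self):
        cfg = tmex.SimConfig(n_genes=200, seed=0)
        cm, _ = tmex.simulate_sc(cfg)
        assert cm.mito_mask.sum() == 10  # 5% of 200


class TestSimulateBulk:
    def test_proportions_columns_sum_to_one(self, small_world):
        cfg, cm, truth = small_world
        _, truth = tmex.simulate_bulk(cm, truth, cfg)
        sums = truth.true_proportions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_identity_corr_rows_nearly_uncorrelated(self):
        # softmax closure induces r = -1/(T-1) = -0.2 between independent
        # logits at T=6; averaged over seeds every pair stays inside the
        # |r| < 0.3 sampling-noise bound
        acc = np.zeros((6, 6))
        for seed in range(20):
            cfg = tmex.SimConfig(
                n_genes=120, n_cell_types=6, cells_per_type=20,
                markers_per_type=10, n_bulk_samples=200, seed=seed,
            )
            cm, truth = tmex.simulate_sc(cfg)
            _, truth = tmex.simulate_bulk(cm, truth, cfg)
            acc += np.abs(np.corrcoef(truth.true_proportions.to_numpy()))
        acc /= 20
        off = acc[~np.eye(6, dtype=bool)]
        assert off.max() < 0.3

    def test_planted_correlation_realized_in_band(self):
        corr = np.eye(6)
        corr[0, 1] = corr[1, 0] = 0.8
        rs = []
        for seed in range(20):
            cfg = tmex.SimConfig(
                n_genes=120, n_cell_types=6, cells_per_type=20,
                markers_per_type=10, n_bulk_samples=200,
                proportion_corr=corr, seed=seed,
            )
            cm, truth = tmex.simulate_sc(cfg)
            _, truth = tmex.simulate_bulk(cm, truth, cfg)
            p = truth.true_proportions
            rs.append(np.corrcoef(p.iloc[0], p.iloc[1])[0, 1])
        assert 0.6 <= np.mean(rs) <= 0.95

    def test_pure_mixture_reproduces_profile(self, small_world):
        cfg, cm, truth = small_world
        types = sorted(set(cm.labels))
        props = pd.DataFrame(
            0.0, index=types, columns=[f"S{i}" for i in range(3)]
        )
        props.loc[types[0]] = 1.0
        cfg_clean = tmex.SimConfig(
            n_genes=cfg.n_genes, n_cell_types=cfg.n_cell_types,
            cells_per_type=cfg.cells_per_type, n_bulk_samples=3,
            bulk_noise_cv=0.0, seed=cfg.seed,
        )
        bulk, _ = tmex.simulate_bulk(cm, truth, cfg_clean, proportions=props)
        profile = cm.counts[:, cm.cells_of(types[0])].mean(axis=1)
        assert np.allclose(bulk.values[:, 0], profile, rtol=1e-12)


class TestSimulateLRDB:
    def test_secreted_fraction_exact_and_planted_specific(self):
        cfg = tmex.SimConfig(
            n_genes=400, n_cell_types=3, cells_per_type=30,
            lr_pairs=20, secreted_frac=0.4, planted_lr=[(0, 1)], seed=2,
        )
        cm, truth = tmex.simulate_sc(cfg)
        db = tmex.simulate_lr_db(cfg, cm, truth)
        assert len(db) == 20
        assert db.pairs["secreted"].sum() == 8
        ta, tb, pid = truth.planted_lr_pairs[0]
        lig = db.pairs.loc[db.pairs.pair_id == pid, "ligand"].item()
        gi = list(cm.gene_ids).index(lig)
        per_type = {
            t: cm.counts[gi, cm.cells_of(t)].mean() for t in sorted(set(cm.labels))
        }
        assert max(per_type, key=per_type.get) == ta

    def test_too_many_pairs_errors(self):
        cfg = tmex.SimConfig(n_genes=130, n_cell_types=3, cells_per_type=10,
                             markers_per_type=10, lr_pairs=60, seed=0)
        cm, truth = tmex.simulate_sc(cfg)
        with pytest.raises(ConfigError):
            tmex.simulate_lr_db(cfg, cm, truth)


class TestSimulateSurvival:
    def test_missing_effect_gene_named(self, small_world):
        cfg, cm, truth = small_world
        bulk, truth = tmex.simulate_bulk(cm, truth, cfg)
        bad = tmex.SimConfig(
            n_genes=cfg.n_genes, n_cell_types=cfg.n_cell_types,
            cells_per_type=cfg.cells_per_type,
            survival_effect_genes=["NOPE"], survival_log_hazard_ratio=1.0,
        )
        with pytest.raises(ValueError, match="NOPE"):
            tmex.simulate_survival(bulk, bad)

    def test_all_censored_km_stays_at_one(self, small_world):
        cfg, cm, truth = small_world
        bulk, truth = tmex.simulate_bulk(cm, truth, cfg)
        surv = tmex.simulate_survival(bulk, cfg, censor_max=1e-6)
        assert surv.data["event"].sum() == 0
        km = tmex.km_estimate(surv)
        assert np.all(km.survival == 1.0)
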