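"""Co-occurrence network: abundance, correlation, candidates, z-scores, edges."""

import numpy as np
import pandas as pd
import pytest

import tmex
from conftest import make_cell_matrix
from tmex.containers import BulkMatrix
from tmex.cooccurrence import AbundanceMatrix, CorrelationTable
from tmex.markers import SignatureSet


def bulk_from(values, gene_ids=None, normalized=True):
    values = np.asarray(values, dtype=float)
    return BulkMatrix(
        values=values,
        gene_ids=gene_ids or [f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        normalized=normalized,
    )


def sigset(genes: dict) -> SignatureSet:
    return SignatureSet(genes=genes, records=pd.DataFrame(), thresholds={})


class TestEstimateAbundance:
    def test_constant_signature_gives_log2_of_4(self):
        bulk = bulk_from(np.full((3, 2), 3.0))
        ab = tmex.estimate_abundance(bulk, sigset({"T": ["g0", "g1", "g2"]}))
        assert np.allclose(ab.scores.loc["T"], 2.0, atol=1e-12)  # log2(3+1)

    def test_empty_intersection_errors(self):
        bulk = bulk_from(np.ones((2, 2)))
        with pytest.raises(ValueError, match="X"):
            tmex.estimate_abundance(bulk, sigset({"X": ["absent"]}))

    def test_missing_genes_dropped_with_warning(self):
        bulk = bulk_from(np.ones((2, 2)))
        with pytest.warns(UserWarning, match="missing"):
            ab = tmex.estimate_abundance(bulk, sigset({"T": ["g0", "nope"]}))
        assert np.allclose(ab.scores.loc["T"], 1.0)

    @pytest.mark.filterwarnings("ignore:bulk matrix is not flagged")
    def test_pure_mixture_sample_maximal_for_its_type(self, small_world):
        cfg, cm, truth = small_world
        types = sorted(set(cm.labels))
        props = pd.DataFrame(np.eye(len(types)), index=types,
                             columns=[f"S{i}" for i in range(len(types))])
        clean = tmex.SimConfig(
            n_genes=cfg.n_genes, n_cell_types=cfg.n_cell_types,
            cells_per_type=cfg.cells_per_type, n_bulk_samples=len(types),
            bulk_noise_cv=0.0, seed=cfg.seed,
        )
        bulk, _ = tmex.simulate_bulk(cm, truth, clean, proportions=props)
        sigs = tmex.build_signatures(tmex.find_markers(cm))
        ab = tmex.estimate_abundance(bulk, sigs)
        for k, t in enumerate(types):
            assert ab.scores.iloc[:, k].idxmax() == t


class TestCorrelateGenes:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 5, size=10)
        values = np.vstack([a, a.max() + 1 - a, rng.uniform(1, 5, size=10)])
        bulk = bulk_from(values)
        # abundance row exactly equal to gene 0's log2 profile
        ab = AbundanceMatrix(scores=pd.DataFrame({"T": np.log2(a + 1)}).T)
        corr = tmex.correlate_genes(bulk, ab)
        assert corr.r.loc["g0", "T"] == pytest.approx(1.0, abs=1e-12)
        assert corr.r.loc["g1", "T"] < 0

    def test_constant_gene_flagged_zero(self):
        values = np.vstack([np.arange(1.0, 6.0), np.full(5, 2.0)])
        bulk = bulk_from(values)
        ab = AbundanceMatrix(scores=pd.DataFrame({"T": np.arange(5.0)}).T)
        corr = tmex.correlate_genes(bulk, ab)
        assert corr.r.loc["g1", "T"] == 0.0
        assert "g1" in corr.undefined

    def test_too_few_samples_errors(self):
        bulk = bulk_from(np.ones((2, 2)))
        ab = AbundanceMatrix(scores=pd.DataFrame({"T": [1.0, 2.0]}).T)
        with pytest.raises(ValueError, match="3 samples"):
            tmex.correlate_genes(bulk, ab)


class TestSelectCandidates:
    def make_corr_cm(self):
        # 30 genes, 2 types; genes g0..g4 self-expressed in A
        rng = np.random.default_rng(1)
        x = rng.uniform(0.0, 0.5, size=(30, 40))
        x[:5, :20] = 2.0  # A cells express g0-g4 at mean 2, freq 1
        labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        cm = make_cell_matrix(x, labels=labels)
        r = pd.DataFrame(
            {"A": np.linspace(1.0, -1.0, 30), "B": np.linspace(-1.0, 1.0, 30)},
            index=[f"g{i}" for i in range(30)],
        )
        return CorrelationTable(r=r, n_samples=50), cm

    def test_topk_and_self_exclusion(self):
        corr, cm = self.make_corr_cm()
        cand, excluded = tmex.select_candidate_genes(corr, cm, "A", k=20)
        assert len(cand) == 20
        assert excluded.issuperset({"g0", "g1", "g2", "g3", "g4"})
        assert not set(cand) & excluded
        # ranked by signed r descending: first non-self gene is g5
        assert cand[0] == "g5"

    def test_expr_boundary_not_excluded_at_exactly_one(self):
        corr, cm = self.make_corr_cm()
        cm.lognorm[:5, :20] = 1.0  # mean exactly 1.0: NOT self-expressed (> is strict)
        cand, excluded = tmex.select_candidate_genes(corr, cm, "A", k=20)
        assert "g0" in cand
        assert not excluded

    def test_unknown_type_errors(self):
        corr, cm = self.make_corr_cm()
        with pytest.raises(KeyError, match="Z"):
            tmex.select_candidate_genes(corr, cm, "Z")

    def test_own_signature_genes_never_candidates(self, small_world):
        cfg, cm, truth = small_world
        sigs = tmex.build_signatures(tmex.find_markers(cm))
        bulk, _ = tmex.simulate_bulk(cm, truth, cfg)
        nb, _ = tmex.normalize_bulk(bulk)
        net = tmex.infer_cooccurrence(nb, cm, sigs)
        for t in sigs.cell_types():
            assert not set(net.candidate_genes[t]) & net.self_excluded[t]
            assert not set(net.candidate_genes[t]) & set(sigs.genes[t])


class TestEnrichmentZ:
    def cm_with_type_means(self, means):
        # one gene; each type's cells at the given constant value
        x = np.concatenate([[m] * 10 for m in means])[None, :]
        labels = np.concatenate(
            [[f"t{i}"] * 10 for i in range(len(means))]
        ).astype(object)
        return make_cell_matrix(x, labels=labels)

    def test_hand_computed_z(self):
        # e = (2,0,0,0,0): mean 0.4, sample sd sqrt(0.8); z0 = 1.6/0.8944 = 1.7889
        cm = self.cm_with_type_means([2.0, 0.0, 0.0, 0.0, 0.0])
        z = tmex.enrichment_zscores(cm, ["g0"])
        assert z["t0"] == pytest.approx(1.6 / np.sqrt(0.8), abs=1e-12)
        assert z["t0"] > 1.28

    def test_degenerate_all_equal_is_zero(self):
        cm = self.cm_with_type_means([1.0, 1.0, 1.0])
        z = tmex.enrichment_zscores(cm, ["g0"])
        assert np.all(z.to_numpy() == 0.0)

    def test_rows_standardized(self, small_world):
        _, cm, _ = small_world
        z = tmex.enrichment_zscores(cm, [str(g) for g in cm.gene_ids[:15]])
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10


class TestBuildNetwork:
    def zmat(self, entries, types=("A", "B")):
        z = pd.DataFrame(0.0, index=list(types), columns=list(types))
        for (i, j), v in entries.items():
            z.loc[i, j] = v
        return z

    def test_mutual_hit_takes_maximum(self):
        net = tmex.build_network(self.zmat({("A", "B"): 1.5, ("B", "A"): 2.0}))
        assert net.edges == [("A", "B", 2.0)]

    def test_threshold_strictly_over(self):
        net = tmex.build_network(self.zmat({("A", "B"): 1.28}))
        assert net.edges == []

    def test_one_directional_hit_creates_edge(self):
        net = tmex.build_network(self.zmat({("A", "B"): 1.5, ("B", "A"): 0.2}))
        assert net.edges == [("A", "B", 1.5)]

    def test_mutual_only_drops_one_directional(self):
        z = self.zmat({("A", "B"): 1.5, ("B", "A"): 0.2})
        assert tmex.build_network(z, mutual_only=True).edges == []


class TestHubRanking:
    def star(self):
        types = ["A", "B", "C", "D"]
        z = pd.DataFrame(0.0, index=types, columns=types)
        net = tmex.build_network(z)
        net.edges = [("A", "B", 2.0), ("A", "C", 1.5), ("A", "D", 1.4)]
        return net

    def test_star_center_first(self):
        ranked = tmex.hub_ranking(self.star())
        assert ranked.iloc[0].cell_type == "A"
        assert ranked.iloc[0].degree == 3

    def test_empty_network_lexical(self):
        types = ["B", "A"]
        z = pd.DataFrame(0.0, index=types, columns=types)
        ranked = tmex.hub_ranking(tmex.build_network(z))
        assert list(ranked.cell_type) == ["A", "B"]
        assert (ranked.degree == 0).all()

    def test_planted_hub_recovered(self):
        # A correlated with both B and C: A should be the top hub usually
        wins = 0
        for seed in range(10):
            corr = np.eye(5)
            corr[0, 1] = corr[1, 0] = 0.8
            corr[0, 2] = corr[2, 0] = 0.8
            cfg = tmex.SimConfig(
                n_genes=800, n_cell_types=5, cells_per_type=60,
                proportion_corr=corr, seed=seed,
            )
            cm, truth = tmex.simulate_sc(cfg)
            cm = tmex.lognormalize(cm)
            sigs = tmex.build_signatures(tmex.find_markers(cm))
            bulk, _ = tmex.simulate_bulk(cm, truth, cfg)
            nb, _ = tmex.normalize_bulk(bulk)
            net = tmex.infer_cooccurrence(nb, cm, sigs)
            if tmex.hub_ranking(net).iloc[0].cell_type == "type0":
                wins += 1
        assert wins >= 8
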