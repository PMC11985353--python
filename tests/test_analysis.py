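"""Activities, importances, differential testing, communication, niches."""

import numpy as np
import pandas as pd
import pytest

from nichegp.analysis import (LOG_K_THRESHOLD, ProgramActivities,
                              compute_activities,
                              compute_communication_potentials,
                              compute_communication_strengths,
                              compute_importances, cluster_to_n_niches,
                              identify_niches, select_characterizing_programs)
from nichegp.analysis import test_differential_activity as differential_test
from nichegp.model import ModelConfig, NicheVGAE
from nichegp.programs import GeneProgram, build_masks
from nichegp.spatial_graph import NeighborGraph
import scipy.sparse as sp


def tiny_model(source=("L",), target=("T1", "T2"), genes=("L", "T1", "T2", "X")):
    labels = {g: "ligand" for g in source}
    labels.update({g: "target_gene" for g in target})
    progs = [GeneProgram(name="GP", category="ligand-receptor",
                         source_genes=source, target_genes=target,
                         gene_labels=labels)]
    masks = build_masks(progs, list(genes), n_denovo=1)
    return NicheVGAE(masks, {}, ModelConfig(), rng=np.random.default_rng(0))


class TestComputeActivities:
    def set_weights(self, model, src_sum, tgt_sum=1.0):
        m = model.masks
        wn = model.params["dec.rna.neigh.Wpr"]
        wn.data[:] = 0
        src_idx = np.flatnonzero(m.neigh_rna[0])
        if len(src_idx):
            wn.data[src_idx[0], 0] = src_sum
        ws = model.params["dec.rna.self.Wpr"]
        ws.data[:] = 0
        ws.data[np.flatnonzero(m.self_rna[0])[0], 0] = tgt_sum

    def test_positive_source_sum_keeps_sign(self):
        model = tiny_model()
        self.set_weights(model, +0.7)
        mu = np.array([[1.0, 2.0], [-1.0, 0.5]])
        act = compute_activities(mu, model)
        assert np.array_equal(act.values[:, 0], mu[:, 0])

    def test_negative_source_sum_flips_column(self):
        model = tiny_model()
        self.set_weights(model, -0.7)
        mu = np.array([[1.0, 2.0], [-1.0, 0.5]])
        act = compute_activities(mu, model)
        assert np.array_equal(act.values[:, 0], -mu[:, 0])

    def test_no_source_genes_falls_back_to_targets(self):
        model = tiny_model()
        # zero out the neighborhood mask row: transcriptional-regulation
        # style program with self component only
        model.masks.neigh_rna[0] = 0
        model._mask_arrays[("rna", "neigh", "pr")][:, 0] = 0
        ws = model.params["dec.rna.self.Wpr"]
        ws.data[:] = 0
        ws.data[np.flatnonzero(model.masks.self_rna[0])[0], 0] = -2.0
        mu = np.array([[1.0, 0.0]])
        act = compute_activities(mu, model)
        assert act.values[0, 0] == -1.0

    def test_magnitudes_preserved(self):
        model = tiny_model()
        mu = np.random.default_rng(0).normal(size=(5, model.n_gp))
        act = compute_activities(mu, model)
        assert np.allclose(np.abs(act.values),
                           np.abs(mu[:, act.program_index]))


class TestComputeImportances:
    def test_hand_normalization(self):
        model = tiny_model()
        m = model.masks
        model.params["dec.rna.neigh.Wpr"].data[:] = 0
        model.params["dec.rna.neigh.Wpr"].data[
            np.flatnonzero(m.neigh_rna[0])[0], 0] = 2.0
        ws = model.params["dec.rna.self.Wpr"]
        ws.data[:] = 0
        t1, t2 = np.flatnonzero(m.self_rna[0])
        ws.data[t1, 0], ws.data[t2, 0] = -1.0, 1.0
        imp = compute_importances(model)
        gp = imp[imp["program"] == "GP"].set_index("feature")
        assert gp.loc["L", "importance"] == pytest.approx(0.5)
        assert gp.loc["T1", "importance"] == pytest.approx(0.25)
        assert gp.loc["T2", "importance"] == pytest.approx(0.25)

    def test_sums_to_one_per_program_and_modality(self, trained_small):
        imp = compute_importances(trained_small["model"])
        sums = imp.groupby(["program", "modality"])["importance"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_single_member_program_importance_one(self):
        model = tiny_model(source=("L",), target=("T1",),
                           genes=("L", "T1"))
        model.masks.neigh_rna[0] = 0
        model._mask_arrays[("rna", "neigh", "pr")][:, 0] = 0
        model.params["dec.rna.neigh.Wpr"].data[:, 0] = 0.0
        imp = compute_importances(model)
        gp = imp[imp["program"] == "GP"]
        assert len(gp) == 1 and gp["importance"].iloc[0] == 1.0


class TestDifferentialActivity:
    def test_identical_distributions_not_flagged(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(200, 3))
        logsig = np.full((200, 3), -1.0)
        res = differential_test(mu, logsig, np.arange(100),
                                         np.arange(100, 200), n_mc=20000,
                                         seed=1)
        assert (np.abs(res["log_k"]) < 1.0).all()
        assert not res["differential"].any()

    def test_log_k_is_log_odds_of_p0(self):
        rng = np.random.default_rng(2)
        mu = np.vstack([rng.normal(1.0, 0.1, size=(50, 1)),
                        rng.normal(0.0, 0.1, size=(50, 1))])
        logsig = np.full((100, 1), -3.0)
        res = differential_test(mu, logsig, np.arange(50),
                                         np.arange(50, 100), n_mc=5000,
                                         seed=0)
        p0 = res["p_h0"].iloc[0]
        assert res["log_k"].iloc[0] == pytest.approx(np.log(p0 / (1 - p0)))
        assert res["differential"].iloc[0]

    def test_threshold_on_borderline_probability(self):
        # p0 = 0.9 -> log K = log 9 = 2.197 < 2.3: not differential
        assert np.log(0.9 / 0.1) < LOG_K_THRESHOLD
        assert np.log(0.92 / 0.08) > LOG_K_THRESHOLD

    def test_swapping_groups_negates_log_k(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(size=(80, 2))
        mu[:40] += 0.8
        logsig = np.full((80, 2), -1.0)
        n_mc = 40000
        a, b = np.arange(40), np.arange(40, 80)
        r1 = differential_test(mu, logsig, a, b, n_mc=n_mc, seed=3)
        r2 = differential_test(mu, logsig, b, a, n_mc=n_mc, seed=4)
        assert np.abs(r1["log_k"].to_numpy()
                      + r2["log_k"].to_numpy()).max() < 10 / np.sqrt(n_mc)

    def test_probability_clipping_bounds_log_k(self):
        mu = np.vstack([np.full((30, 1), 10.0), np.zeros((30, 1))])
        logsig = np.full((60, 1), -5.0)
        res = differential_test(mu, logsig, np.arange(30),
                                         np.arange(30, 60), n_mc=1000,
                                         seed=0)
        assert res["log_k"].iloc[0] == pytest.approx(np.log(999))

    def test_overlapping_groups_rejected(self):
        mu = np.zeros((10, 1))
        with pytest.raises(ValueError, match="overlap"):
            differential_test(mu, mu, np.arange(5), np.arange(4, 8))

    def test_empty_group_rejected(self):
        mu = np.zeros((10, 1))
        with pytest.raises(ValueError, match="non-empty"):
            differential_test(mu, mu, np.array([]), np.arange(5))


class TestCommunicationPotentials:
    def build(self, weights_self=1.0, weights_neigh=0.5, activity=2.0):
        import pandas as pd
        from nichegp.spatial_graph import SpatialDataset
        model = tiny_model(source=("L",), target=("T1",),
                           genes=("L", "T1"))
        model.params["dec.rna.neigh.Wpr"].data[:] = 0
        model.params["dec.rna.neigh.Wpr"].data[0, 0] = weights_neigh
        model.params["dec.rna.self.Wpr"].data[:] = 0
        model.params["dec.rna.self.Wpr"].data[1, 0] = weights_self
        counts = np.array([[2, 1], [0, 0], [1, 2]])
        dataset = SpatialDataset(
            counts_rna=sp.csr_matrix(counts),
            coords=np.array([[0, 0], [1, 0], [2, 0.0]]),
            covariates=pd.DataFrame({"sample": ["s"] * 3}),
            gene_names=["L", "T1"])
        act = ProgramActivities(
            values=np.array([[activity], [activity], [activity]]),
            program_names=["GP"], signs=np.ones(1),
            program_index=np.array([0]))
        return model, dataset, act

    def test_hand_pipeline_example(self):
        # cell 0: scaled L = 1, weight 0.5 -> pre-source 0.5; x activity 2 = 1
        # scaled T1 = 0.5, weight 1 -> pre-target 0.5; x activity 2 = 1
        model, dataset, act = self.build()
        pot = compute_communication_potentials(dataset, model, act, "GP")
        assert pot["source_potential"].iloc[0] == pytest.approx(1.0)
        assert pot["target_potential"].iloc[0] == pytest.approx(1.0)

    def test_zero_activity_zero_potentials(self):
        model, dataset, act = self.build(activity=0.0)
        pot = compute_communication_potentials(dataset, model, act, "GP")
        assert (pot.to_numpy() == 0).all()

    def test_negative_scores_clamped_to_zero(self):
        model, dataset, act = self.build(weights_self=-1.0,
                                         weights_neigh=-1.0)
        pot = compute_communication_potentials(dataset, model, act, "GP")
        assert (pot.to_numpy() >= 0).all()
        assert pot["target_potential"].iloc[2] == 0.0


class TestCommunicationStrengths:
    def graph_from_edges(self, n, edges):
        a = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            a[i, j] = a[j, i] = 1
        return NeighborGraph(adjacency=sp.csr_matrix(a), k=1)

    def test_two_cell_directed_pair(self):
        pot = pd.DataFrame({"source_potential": [1.0, 0.0],
                            "target_potential": [0.0, 1.0]})
        graph = self.graph_from_edges(2, [(0, 1)])
        niches = np.array(["n0", "n1"])
        out = compute_communication_strengths(pot, graph, niches)
        m = out["niche_matrix"]
        assert m.loc["n0", "n1"] == 1.0
        assert m.loc["n1", "n0"] == 0.0

    def test_zero_source_zeroes_outgoing(self):
        rng = np.random.default_rng(0)
        pot = pd.DataFrame({"source_potential": rng.random(5),
                            "target_potential": rng.random(5)})
        pot.loc[2, "source_potential"] = 0.0
        graph = self.graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        src = pot["source_potential"].to_numpy()
        tgt = pot["target_potential"].to_numpy()
        a = graph.adjacency.toarray()
        outgoing2 = sum(src[2] * tgt[j] for j in range(5) if a[2, j])
        assert outgoing2 == 0.0

    def test_niche_matrix_matches_brute_force(self):
        rng = np.random.default_rng(1)
        n = 30
        coords = rng.random((n, 2))
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if np.linalg.norm(coords[i] - coords[j]) < 0.3]
        graph = self.graph_from_edges(n, edges)
        pot = pd.DataFrame({"source_potential": rng.random(n),
                            "target_potential": rng.random(n)})
        niches = rng.choice(["a", "b", "c"], size=n)
        out = compute_communication_strengths(pot, graph, niches)
        a = graph.adjacency.toarray()
        src = pot["source_potential"].to_numpy()
        tgt = pot["target_potential"].to_numpy()
        brute = pd.DataFrame(0.0, index=["a", "b", "c"],
                             columns=["a", "b", "c"])
        for i in range(n):
            for j in range(n):
                if a[i, j]:
                    brute.loc[niches[i], niches[j]] += src[i] * tgt[j]
        b = brute.to_numpy()
        b = (b - b.min()) / (b.max() - b.min())
        assert np.allclose(out["niche_matrix"].to_numpy(), b)

    def test_normalized_to_unit_interval(self):
        rng = np.random.default_rng(2)
        pot = pd.DataFrame({"source_potential": rng.random(10),
                            "target_potential": rng.random(10)})
        graph = self.graph_from_edges(10, [(i, i + 1) for i in range(9)])
        out = compute_communication_strengths(pot, graph,
                                              np.repeat(["a", "b"], 5))
        m = out["niche_matrix"].to_numpy()
        assert m.min() >= 0 and m.max() == pytest.approx(1.0)


class TestIdentifyNiches:
    def test_two_separated_blobs_two_niches(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.1, size=(60, 4)),
                         rng.normal(5, 0.1, size=(60, 4))])
        labels, linkage = identify_niches(emb, resolution=0.5, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:60])) == 1
        assert len(np.unique(labels[60:])) == 1

    def test_dendrogram_leaf_count_equals_niche_count(self):
        rng = np.random.default_rng(1)
        emb = np.vstack([rng.normal(c, 0.1, size=(40, 3))
                         for c in (0, 4, 8)])
        labels, linkage = identify_niches(emb, resolution=0.5, seed=0)
        k = len(np.unique(labels))
        assert linkage.shape[0] == k - 1  # Ward linkage over k leaves

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(100, 5))
        l1, _ = identify_niches(emb, resolution=1.0, seed=11)
        l2, _ = identify_niches(emb, resolution=1.0, seed=11)
        assert np.array_equal(l1, l2)

    def test_single_observation_single_niche(self):
        labels, linkage = identify_niches(np.zeros((1, 3)))
        assert labels.tolist() == [0] and linkage is None

    def test_resolution_search_hits_target(self):
        rng = np.random.default_rng(4)
        emb = np.vstack([rng.normal(4 * c, 0.1, size=(30, 3))
                         for c in range(4)])
        labels, res = cluster_to_n_niches(emb, 4, seed=0)
        assert len(np.unique(labels)) == 4


class TestSubclusterNiche:
    def test_relabels_only_target_niche(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.1, size=(40, 3)),
                         rng.normal(6, 0.1, size=(40, 3)),
                         rng.normal(12, 0.1, size=(40, 3))])
        # niche 0 actually holds two separated blobs
        emb[:20] += 3
        labels = np.repeat([0, 0, 1], [20, 20, 80])
        from nichegp.analysis import subcluster_niche
        out = subcluster_niche(emb, labels, 0, resolution=0.5, seed=0)
        assert set(out[80:]) == {1}
        assert all(str(v).startswith("0.") for v in out[:40])
        assert len(set(out[:40])) == 2


class TestSelectCharacterizingPrograms:
    def test_correlated_program_ranked_first(self, trained_small):
        """On the trained toy, selection returns at most two programs per
        niche, each enriched, with finite correlation scores."""
        d = trained_small
        act = compute_activities(d["mu"], d["model"])
        imp = compute_importances(d["model"])
        sel = select_characterizing_programs(
            act, d["dataset"], imp, d["truth"].niche, d["mu"], d["logsig"],
            d["model"], n_per_niche=2, n_mc=2000, seed=0)
        if not sel.empty:
            assert (sel.groupby("niche").size() <= 2).all()
            assert (sel["log_k"] >= LOG_K_THRESHOLD).all()

    def test_constructed_correlation_ranking(self):
        """Between two enriched programs, the one whose member-gene
        expression tracks its activity is ranked first."""
        import pandas as pd
        from nichegp.spatial_graph import SpatialDataset
        rng = np.random.default_rng(0)
        n = 120
        labels_half = np.repeat([0, 1], n // 2)
        progs = []
        for name, src, tgt in (("corr", ("L1",), ("T1",)),
                               ("uncorr", ("L2",), ("T2",))):
            progs.append(GeneProgram(
                name=name, category="ligand-receptor", source_genes=src,
                target_genes=tgt,
                gene_labels={src[0]: "ligand", tgt[0]: "target_gene"}))
        genes = ["L1", "T1", "L2", "T2"]
        masks = build_masks(progs, genes, n_denovo=1)
        model = NicheVGAE(masks, {}, ModelConfig(),
                          rng=np.random.default_rng(1))
        # both programs active in niche 0, but only "corr" member genes
        # track the activity column
        mu = np.zeros((n, model.n_gp))
        mu[labels_half == 0, 0] = 2.0 + rng.normal(0, 0.1, n // 2)
        mu[labels_half == 0, 1] = 2.0 + rng.normal(0, 0.1, n // 2)
        logsig = np.full((n, model.n_gp), -3.0)
        counts = rng.poisson(1.0, size=(n, 4))
        counts[:, 0] = np.maximum(0, (mu[:, 0] * 3)).astype(int)
        counts[:, 1] = np.maximum(0, (mu[:, 0] * 3)).astype(int)
        dataset = SpatialDataset(
            counts_rna=sp.csr_matrix(counts),
            coords=rng.random((n, 2)),
            covariates=pd.DataFrame({"sample": ["s"] * n}),
            gene_names=genes)
        for comp in ("self", "neigh"):
            w = model.params[f"dec.rna.{comp}.Wpr"]
            w.data[:] = np.abs(w.data)  # keep signs positive
        act = compute_activities(mu, model)
        imp = compute_importances(model)
        sel = select_characterizing_programs(
            act, dataset, imp, labels_half, mu, logsig, model,
            n_per_niche=2, n_mc=4000, seed=0)
        first = sel[(sel["niche"] == 0) & (sel["rank"] == 0)]
        assert first["program"].iloc[0] == "corr"
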