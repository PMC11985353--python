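"""Edge batching, loss assembly, pruning and the training loop."""

import numpy as np
import pytest

from nichegp.autodiff import Tensor
from nichegp.model import ModelConfig, NicheVGAE
from nichegp.programs import build_masks
from nichegp.spatial_graph import build_neighbor_graph
from nichegp.training import (PruningState, TrainConfig,
                              edge_reconstruction_loss, l1_penalty,
                              sample_edge_batch, total_loss, train,
                              update_pruning)
from conftest import two_sample_dataset


class TestSampleEdgeBatch:
    def test_single_sample_all_negatives_valid(self):
        ds = two_sample_dataset(n_per_sample=40)
        ds.covariates["sample"] = "a"  # collapse to one sample
        graph = build_neighbor_graph(ds, k=3)
        rng = np.random.default_rng(0)
        edges = graph.edge_list()
        batch = sample_edge_batch(graph, ds.pure_codes(), edges[:20], rng)
        assert len(batch.neg_pairs) == len(batch.pos_pairs)
        assert batch.omega_pos == 1.0

    def test_two_samples_no_cross_sample_negatives_over_seeds(self):
        ds = two_sample_dataset(n_per_sample=25)
        graph = build_neighbor_graph(ds, k=3)
        pure = ds.pure_codes()
        edges = graph.edge_list()
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            batch = sample_edge_batch(graph, pure, edges[:8], rng)
            if len(batch.neg_pairs):
                assert (pure[batch.neg_pairs[:, 0]]
                        == pure[batch.neg_pairs[:, 1]]).all()
            # filtering can only shrink the negative set
            assert len(batch.neg_pairs) <= len(batch.pos_pairs)
            assert batch.omega_pos <= 1.0

    def test_negatives_are_non_edges(self):
        ds = two_sample_dataset(n_per_sample=30)
        graph = build_neighbor_graph(ds, k=4)
        rng = np.random.default_rng(5)
        batch = sample_edge_batch(graph, ds.pure_codes(),
                                  graph.edge_list()[:30], rng)
        adj = graph.adjacency
        for i, j in batch.cand_neg_pairs:
            assert adj[i, j] == 0 and i != j


class TestEdgeReconstructionLoss:
    def test_confident_logits_near_zero_loss(self):
        logits = Tensor(np.array([10.0, -10.0]))
        loss = edge_reconstruction_loss(logits, np.array([1.0, 0.0]), 1.0)
        assert loss.data == pytest.approx(4.5398e-5, rel=1e-3)

    def test_zero_logits_give_log_two(self):
        logits = Tensor(np.zeros(6))
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        loss = edge_reconstruction_loss(logits, labels, 1.0)
        assert loss.data == pytest.approx(np.log(2.0), rel=1e-12)

    def test_omega_balances_classes_for_constant_logits(self):
        # omega_pos * |pos| = |neg|: the class contributions match
        logits = Tensor(np.zeros(6))
        labels = np.array([1, 1, 1, 1, 0, 0], dtype=float)
        omega = 2 / 4
        loss = edge_reconstruction_loss(logits, labels, omega)
        pos_part = omega * 4 * np.log(2)
        neg_part = 2 * np.log(2)
        assert loss.data == pytest.approx((pos_part + neg_part) / 6)


class TestL1Penalty:
    @pytest.fixture
    def masked_model(self):
        from nichegp.programs import GeneProgram
        p = GeneProgram(name="GP", category="ligand-receptor",
                        source_genes=("L",), target_genes=("T",),
                        gene_labels={"L": "ligand", "T": "target_gene"})
        masks = build_masks([p], ["L", "T", "X"], n_denovo=1)
        return NicheVGAE(masks, {}, ModelConfig(),
                         rng=np.random.default_rng(0))

    def test_zero_weights_zero_penalties(self, masked_model):
        for comp in ("self", "neigh"):
            masked_model.params[f"dec.rna.{comp}.Wpr"].data[:] = 0
            masked_model.params[f"dec.rna.{comp}.Wnv"].data[:] = 0
        prior, denovo = l1_penalty(masked_model)
        assert prior.data == 0.0 and denovo.data == 0.0

    def test_prior_penalty_counts_only_indicated_categories(self, masked_model):
        m = masked_model
        # ligand weight 3 (neighborhood), target weight -2 (self);
        # indicator marks targets only -> penalty 2
        m.params["dec.rna.neigh.Wpr"].data[:] = 0
        m.params["dec.rna.neigh.Wpr"].data[0, 0] = 3.0
        m.params["dec.rna.self.Wpr"].data[:] = 0
        m.params["dec.rna.self.Wpr"].data[1, 0] = -2.0
        m.params["dec.rna.self.Wnv"].data[:] = 0
        m.params["dec.rna.neigh.Wnv"].data[:] = 0
        prior, _ = l1_penalty(m)
        assert prior.data == pytest.approx(2.0)

    def test_denovo_penalty_sums_all_absolutes(self, masked_model):
        m = masked_model
        for comp in ("self", "neigh"):
            m.params[f"dec.rna.{comp}.Wpr"].data[:] = 0
            m.params[f"dec.rna.{comp}.Wnv"].data[:] = 0
        m.params["dec.rna.self.Wnv"].data[2, 0] = 1.0
        m.params["dec.rna.neigh.Wnv"].data[2, 0] = -1.0
        _, denovo = l1_penalty(m)
        assert denovo.data == pytest.approx(2.0)


class TestTotalLoss:
    def test_zero_lambdas_leave_kl_only(self):
        terms = {"kl": Tensor(3.0), "edge": Tensor(100.0),
                 "rna": Tensor(50.0)}
        cfg = TrainConfig(lambda_edge=0.0, lambda_rna=0.0)
        assert total_loss(terms, cfg).data == 3.0

    def test_additivity(self):
        terms = {"kl": Tensor(1.0), "edge": Tensor(2.0), "rna": Tensor(3.0),
                 "l1_prior": Tensor(4.0), "l1_denovo": Tensor(5.0)}
        cfg = TrainConfig(lambda_edge=2.0, lambda_rna=0.5,
                          lambda_l1_prior=0.1, lambda_l1_denovo=0.2)
        expected = 1.0 + 2.0 * 2.0 + 0.5 * 3.0 + 0.1 * 4.0 + 0.2 * 5.0
        assert total_loss(terms, cfg).data == pytest.approx(expected, abs=1e-10)

    def test_doubling_edge_weight_adds_one_edge_loss(self):
        terms = {"kl": Tensor(1.0), "edge": Tensor(2.5)}
        lo = total_loss(terms, TrainConfig(lambda_edge=1.0)).data
        hi = total_loss(terms, TrainConfig(lambda_edge=2.0)).data
        assert hi - lo == pytest.approx(2.5, abs=1e-12)


class TestPruning:
    def make_model(self, n_priors=3):
        from nichegp.programs import GeneProgram
        progs = [GeneProgram(name=f"P{i}", category="ligand-receptor",
                             source_genes=(f"L{i}",), target_genes=(f"T{i}",),
                             gene_labels={f"L{i}": "ligand",
                                          f"T{i}": "target_gene"})
                 for i in range(n_priors)]
        genes = [g for i in range(n_priors) for g in (f"L{i}", f"T{i}")]
        masks = build_masks(progs, genes + ["extra"], n_denovo=2)
        return NicheVGAE(masks, {}, ModelConfig(),
                         rng=np.random.default_rng(0))

    def test_zero_weight_program_pruned_after_warmup(self):
        model = self.make_model()
        for comp in ("self", "neigh"):
            model.params[f"dec.rna.{comp}.Wpr"].data[:, 1] = 0.0
        state = PruningState(ema=np.zeros(model.n_gp), decay=0.5, tau=0.05,
                             warmup_steps=1)
        mu = np.ones((4, model.n_gp))
        state = update_pruning(state, model, mu)   # warm-up step
        assert model.active_prior.all()
        state = update_pruning(state, model, mu)
        assert not model.active_prior[1]
        assert model.active_prior[[0, 2]].all()

    def test_argmax_program_never_pruned(self):
        model = self.make_model()
        state = PruningState(ema=np.zeros(model.n_gp), decay=0.5, tau=1.0,
                             warmup_steps=0)
        for _ in range(3):
            state = update_pruning(state, model, np.ones((2, model.n_gp)))
        deltas = state.contributions(model)["sum"][:model.n_pr]
        assert model.active_prior[deltas.argmax()]

    def test_both_variants_must_agree(self):
        # tau=0.1; program 2 below threshold under both variants -> pruned
        model = self.make_model(n_priors=2)
        state = PruningState(ema=np.ones(model.n_gp), decay=1.0, tau=0.1,
                             warmup_steps=0, initialized=True)
        for comp in ("self", "neigh"):
            w = model.params[f"dec.rna.{comp}.Wpr"]
            w.data[:] = 0
            w.data[model.masks.self_rna[0] == 1
                   if comp == "self" else model.masks.neigh_rna[0] == 1, 0] = 0.5
            w.data[model.masks.self_rna[1] == 1
                   if comp == "self" else model.masks.neigh_rna[1] == 1, 1] = 0.02
        state = update_pruning(state, model, np.ones((1, model.n_gp)))
        assert model.active_prior[0] and not model.active_prior[1]

    def test_lower_tau_never_prunes_more(self):
        rng = np.random.default_rng(0)
        results = {}
        for tau in (0.3, 0.05):
            model = self.make_model()
            for comp in ("self", "neigh"):
                for pool in ("Wpr", "Wnv"):
                    w = model.params[f"dec.rna.{comp}.{pool}"]
                    w.data *= rng.random(w.data.shape)
            state = PruningState(ema=np.ones(model.n_gp), decay=1.0, tau=tau,
                                 warmup_steps=0, initialized=True)
            update_pruning(state, model, np.ones((1, model.n_gp)))
            results[tau] = model.active_prior.copy()
        assert (results[0.05] | results[0.3] == results[0.05]).all()


class TestTrainLoop:
    def test_loss_decreases_and_masks_stay_exact(self, trained_small):
        log = trained_small["log"]
        assert log["total"].iloc[-1] < log["total"].iloc[0]
        model = trained_small["model"]
        m = model.masks
        assert np.all(model.params["dec.rna.self.Wpr"].data[m.self_rna.T == 0]
                      == 0.0)
        assert np.all(model.params["dec.rna.neigh.Wpr"].data[m.neigh_rna.T == 0]
                      == 0.0)
        assert np.all(model.params["dec.rna.self.Wnv"].data[
            m.self_rna_nv.T == 0] == 0.0)

    def test_seeded_runs_are_bitwise_identical(self, small_tissue,
                                               small_graph, small_masks):
        dataset, _ = small_tissue
        cfg = TrainConfig(epochs=2, warmup_epochs=1, n_node_batch=128,
                          n_edge_batch=64)
        m1, log1, _ = train(dataset, small_graph, small_masks, cfg, seed=7)
        m2, log2, _ = train(dataset, small_graph, small_masks, cfg, seed=7)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data), k
        assert np.array_equal(log1["total"], log2["total"])

    def test_multimodal_training_includes_atac_loss(self):
        """With paired peak counts, the ATAC reconstruction term is
        computed and optimized alongside the RNA terms."""
        from nichegp.programs import build_masks, link_peaks_to_genes
        from nichegp.simulation import simulate_multiome
        from nichegp.spatial_graph import build_neighbor_graph
        from conftest import small_sim_config
        cfg = small_sim_config(seed=8, n_cells=200, n_genes=30,
                               n_injected=2, n_decoys=1,
                               n_markers_per_type=1)
        dataset, truth, links, peaks, annotation = simulate_multiome(
            cfg, peaks_per_gene=1)
        rediscovered = link_peaks_to_genes(peaks, annotation)
        masks = build_masks(truth.programs, dataset.gene_names,
                            peak_links=rediscovered,
                            peak_index=dataset.peak_names, n_denovo=3)
        graph = build_neighbor_graph(dataset, k=3)
        config = TrainConfig(epochs=3, warmup_epochs=5, n_node_batch=100,
                             n_edge_batch=32)
        model, log, _ = train(dataset, graph, masks, config, seed=0)
        assert "atac" in log.columns
        assert np.isfinite(log["atac"]).all()
        assert log["total"].iloc[-1] < log["total"].iloc[0]
        # ATAC decoder masks hold exactly like RNA masks
        w = model.params["dec.atac.self.Wpr"].data
        assert np.all(w[masks.self_atac.T == 0] == 0.0)

    def test_loss_term_isolation(self, small_tissue, small_graph,
                                 small_masks):
        """Zeroing a lambda removes exactly that term from the total."""
        dataset, _ = small_tissue
        # one step per run (full-batch) so both runs compare the same
        # initial weights and sampled batches
        base = TrainConfig(epochs=1, warmup_epochs=5, n_node_batch=800,
                           n_edge_batch=64, lambda_edge=500.0)
        off = TrainConfig(epochs=1, warmup_epochs=5, n_node_batch=800,
                          n_edge_batch=64, lambda_edge=0.0)
        _, log1, _ = train(dataset, small_graph, small_masks, base, seed=3)
        _, log2, _ = train(dataset, small_graph, small_masks, off, seed=3)
        assert log1["edge"].iloc[0] == pytest.approx(log2["edge"].iloc[0])
        assert (log1["total"].iloc[0] - log2["total"].iloc[0]
                == pytest.approx(500.0 * log1["edge"].iloc[0], rel=1e-6))
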