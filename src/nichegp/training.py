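"""Mini-batch multi-task training with dual neighbor-sampling loaders.

Each optimization step runs two forward passes — a node-level pass that
reconstructs self and neighborhood counts for a batch of nodes, and an
edge-level pass that reconstructs adjacency for a batch of positive
pairs plus uniformly sampled negative pairs — followed by one joint
backward pass.  Negative pairs whose endpoints differ in any pure
covariate are discarded (never resampled), and the surviving imbalance
is compensated by the positive-pair weight ``omega_pos``.

A dropout-style pruning mechanism tracks each program's contribution to
gene-expression reconstruction (decoder weight mass times an
exponential moving average of absolute embeddings) and deactivates
programs that fall below a fraction ``tau`` of the strongest program
under both a sum-based and a nonzero-mean-based aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import AdamW, Tensor, logsigmoid
from .model import (ModelConfig, NicheVGAE, build_subgraph,
                    kl_divergence, nb_negative_log_likelihood)
from .programs import ProgramMasks
from .spatial_graph import NeighborGraph, SpatialDataset, aggregate_neighborhood

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "BatchSpec", "PruningState", "sample_edge_batch",
           "edge_reconstruction_loss", "l1_penalty", "total_loss",
           "update_pruning", "train", "fit", "encode_all"]


@dataclass
class TrainConfig:
    """Loss weights, batch shapes and pruning schedule."""

    lambda_edge: float = 500.0
    lambda_rna: float = 1.0
    lambda_atac: float = 1.0
    lambda_l1_prior: float = 0.0
    lambda_l1_denovo: float = 0.0
    lr: float = 2e-3
    weight_decay: float = 0.0
    n_node_batch: int = 256
    n_edge_batch: int = 128
    n_sampled_neighbors: int = 4
    epochs: int = 50
    prune: bool = True
    tau: float = 0.05
    warmup_epochs: int = 40
    ema_decay: float = 0.99
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class BatchSpec:
    """One edge-loader batch after negative sampling and filtering."""

    pos_pairs: np.ndarray          # (n_pos, 2) with A_ij = 1
    neg_pairs: np.ndarray          # valid negatives (pure covariates match)
    cand_neg_pairs: np.ndarray     # all sampled negatives, pre-filtering
    omega_pos: float

    @property
    def rec_pairs(self) -> np.ndarray:
        if len(self.neg_pairs) == 0:
            return self.pos_pairs
        return np.vstack([self.pos_pairs, self.neg_pairs])

    @property
    def rec_labels(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.pos_pairs)),
                               np.zeros(len(self.neg_pairs))])


def sample_edge_batch(graph: NeighborGraph, pure_codes: np.ndarray,
                      positives: np.ndarray,
                      rng: np.random.Generator) -> BatchSpec:
    """Sample negative pairs for a chunk of positive edges.

    Candidate negatives are drawn uniformly among non-edges (rejection
    sampling over ordered pairs); candidates whose endpoints differ in
    pure covariates are discarded without resampling, so
    ``len(neg_pairs) <= len(pos_pairs)``.
    """
    n = graph.n_obs
    n_pos = len(positives)
    adj = graph.adjacency
    cand = np.empty((0, 2), dtype=np.intp)
    needed = n_pos
    for _ in range(50):
        if needed <= 0:
            break
        i = rng.integers(0, n, size=2 * needed)
        j = rng.integers(0, n, size=2 * needed)
        ok = i != j
        i, j = i[ok], j[ok]
        is_edge = np.asarray(adj[i, j]).ravel() > 0
        i, j = i[~is_edge], j[~is_edge]
        take = min(needed, len(i))
        cand = np.vstack([cand, np.column_stack([i[:take], j[:take]])])
        needed = n_pos - len(cand)
    valid = cand[pure_codes[cand[:, 0]] == pure_codes[cand[:, 1]]]
    if len(valid) == 0:
        logger.info("edge batch has no valid negatives; omega_pos = 1")
        omega = 1.0
    else:
        omega = len(valid) / n_pos
    return BatchSpec(pos_pairs=np.asarray(positives, dtype=np.intp),
                     neg_pairs=valid, cand_neg_pairs=cand, omega_pos=omega)


def edge_reconstruction_loss(logits: Tensor, labels: np.ndarray,
                             omega_pos: float) -> Tensor:
    """Class-weighted binary cross-entropy on edge logits.

    mean over pairs of -[omega_pos * y * log sigma(l)
                         + (1 - y) * log(1 - sigma(l))].
    """
    y = np.asarray(labels, dtype=np.float64)
    log_p = logsigmoid(logits)
    log_q = logsigmoid(-logits)
    per_pair = -(Tensor(omega_pos * y) * log_p + Tensor(1.0 - y) * log_q)
    return per_pair.mean()


def l1_penalty(model: NicheVGAE) -> tuple[Tensor, Tensor]:
    """Selective L1 on gene-expression decoder weights.

    Prior penalty sums |W| over positions flagged by the regularization
    indicator (default: target genes), across self and neighborhood
    components; the de novo penalty sums |W| over all de novo weights.
    """
    m = model.masks
    prior = Tensor(0.0)
    denovo = Tensor(0.0)
    for comp, reg in (("self", m.reg_self), ("neigh", m.reg_neigh)):
        wpr = model.params[f"dec.rna.{comp}.Wpr"]
        wnv = model.params[f"dec.rna.{comp}.Wnv"]
        prior = prior + (wpr.abs() * Tensor(reg.T.astype(float))).sum()
        denovo = denovo + wnv.abs().sum()
    return prior, denovo


def total_loss(terms: dict[str, Tensor], cfg: TrainConfig) -> Tensor:
    """λ-weighted sum of the loss components.

    Expected keys: ``kl``, ``edge``, ``rna`` (and optionally ``atac``,
    ``l1_prior``, ``l1_denovo``).  Missing keys contribute nothing.
    """
    total = terms["kl"]
    weights = {"edge": cfg.lambda_edge, "rna": cfg.lambda_rna,
               "atac": cfg.lambda_atac, "l1_prior": cfg.lambda_l1_prior,
               "l1_denovo": cfg.lambda_l1_denovo}
    for key, lam in weights.items():
        if key in terms and lam != 0.0:
            total = total + lam * terms[key]
    return total


@dataclass
class PruningState:
    """EMA of absolute embeddings and active-program flags."""

    ema: np.ndarray                # (n_programs,)
    decay: float
    tau: float
    warmup_steps: int
    step: int = 0
    initialized: bool = False

    def contributions(self, model: NicheVGAE) -> dict[str, np.ndarray]:
        """Per-program delta under both aggregations (gene expression)."""
        w_abs = np.zeros(model.n_gp)
        nz = np.zeros(model.n_gp)
        for comp in ("self", "neigh"):
            wpr = np.abs(model.params[f"dec.rna.{comp}.Wpr"].data)
            wnv = np.abs(model.params[f"dec.rna.{comp}.Wnv"].data)
            w_abs[:model.n_pr] += wpr.sum(axis=0)
            w_abs[model.n_pr:] += wnv.sum(axis=0)
            mp, mn = model._masks_for("rna", comp)
            nz[:model.n_pr] += mp.sum(axis=1)
            nz[model.n_pr:] += mn.sum(axis=1)
        delta_sum = w_abs * self.ema
        delta_nzm = (w_abs / np.maximum(nz, 1.0)) * self.ema
        return {"sum": delta_sum, "nonzero_mean": delta_nzm}


def update_pruning(state: PruningState, model: NicheVGAE,
                   mu_batch: np.ndarray) -> PruningState:
    """EMA update plus (after warm-up) a pruning decision.

    A program is deactivated iff its contribution falls below
    ``tau * delta_max`` under *both* aggregation variants; the maxima
    are taken over currently active programs, separately for prior and
    de novo pools.
    """
    batch_abs = np.abs(mu_batch).mean(axis=0)
    if not state.initialized:
        state.ema = batch_abs
        state.initialized = True
    else:
        state.ema = state.decay * state.ema + (1 - state.decay) * batch_abs
    state.step += 1
    if state.step <= state.warmup_steps:
        return state
    deltas = state.contributions(model)
    for pool, sl in (("prior", slice(0, model.n_pr)),
                     ("denovo", slice(model.n_pr, model.n_gp))):
        active = model.active_prior if pool == "prior" else model.active_denovo
        if active.sum() == 0:
            continue
        below_both = np.ones(sl.stop - sl.start, dtype=bool)
        for variant, delta in deltas.items():
            d = delta[sl]
            ref = d[active].max()
            below_both &= d < state.tau * ref
        new_active = active & ~below_both
        if pool == "prior":
            model.active_prior = new_active
        else:
            model.active_denovo = new_active
    return state


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _prepare_arrays(dataset: SpatialDataset, graph: NeighborGraph):
    labels = aggregate_neighborhood(dataset, graph)
    mods = list(dataset.modalities())
    x_self = {m: np.asarray(labels.self_labels[m].todense(), dtype=np.float64)
              for m in mods}
    x_neigh = {m: labels.neighborhood_labels[m] for m in mods}
    features = np.hstack([x_self[m] for m in mods])
    log_lib = {}
    for m in mods:
        for comp, x in (("self", x_self[m]), ("neigh", x_neigh[m])):
            tot = x.sum(axis=1)
            zero = tot <= 0
            if zero.any():
                logger.info("%d observations with zero %s %s library excluded "
                            "from that loss", int(zero.sum()), m, comp)
            log_lib[(m, comp)] = (np.log(np.where(zero, 1.0, tot)), ~zero)
    return mods, x_self, x_neigh, features, log_lib


def _covariate_codes(dataset: SpatialDataset,
                     vocab: dict[str, list[str]]) -> np.ndarray:
    cols = []
    for l, cats in vocab.items():
        lut = {c: i for i, c in enumerate(cats)}
        vals = dataset.covariates[l].astype(str)
        unseen = set(vals) - set(lut)
        if unseen:
            raise ValueError(f"unseen categories for covariate {l!r}: {unseen}")
        cols.append(vals.map(lut).to_numpy(dtype=np.intp))
    if not cols:
        return np.zeros((dataset.n_obs, 0), dtype=np.intp)
    return np.column_stack(cols)


def fit(model: NicheVGAE, dataset: SpatialDataset, graph: NeighborGraph,
        config: TrainConfig, seed: int,
        trainable: tuple[str, ...] | None = None,
        pruning_state: PruningState | None = None,
        ) -> tuple[NicheVGAE, pd.DataFrame, PruningState]:
    """Run the optimization loop on an initialized model.

    ``trainable`` restricts gradient updates to parameters whose names
    start with the given prefixes (used for query fine-tuning, where
    only covariate embeddings move).
    """
    rng = np.random.default_rng(seed)
    mods, x_self, x_neigh, features, log_lib = _prepare_arrays(dataset, graph)
    codes = _covariate_codes(dataset, model.covariate_categories)
    pure = dataset.pure_codes()
    neighbor_lists = graph.neighbor_lists()
    edges = graph.edge_list()
    if len(edges) == 0:
        raise ValueError("graph has no edges")
    features = model._encoder_features(features)
    params = model.parameters(only=trainable)
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    n_obs = dataset.n_obs
    steps_per_epoch = max(1, int(np.ceil(n_obs / config.n_node_batch)))
    if pruning_state is None:
        pruning_state = PruningState(
            ema=np.zeros(model.n_gp), decay=config.ema_decay, tau=config.tau,
            warmup_steps=config.warmup_epochs * steps_per_epoch)
    records = []
    edge_perm = rng.permutation(len(edges))
    edge_ptr = 0
    n_smp = config.n_sampled_neighbors
    for epoch in range(config.epochs):
        node_perm = rng.permutation(n_obs)
        epoch_terms: dict[str, list[float]] = {}
        for step in range(steps_per_epoch):
            vb = node_perm[step * config.n_node_batch:
                           (step + 1) * config.n_node_batch]
            if len(vb) == 0:
                continue
            # ---- edge batch (positives without replacement per epoch) ----
            if edge_ptr >= len(edge_perm):
                edge_perm = rng.permutation(len(edges))
                edge_ptr = 0
            take = edge_perm[edge_ptr:edge_ptr + config.n_edge_batch]
            edge_ptr += config.n_edge_batch
            batch = sample_edge_batch(graph, pure, edges[take], rng)

            terms: dict[str, Tensor] = {}
            # ---- node-level forward ----
            sub = build_subgraph(vb, neighbor_lists, n_sample=n_smp, rng=rng)
            mu, logsig = model.encode(features[sub.node_ids], sub,
                                      transformed=True)
            z = model.sample_latent(mu, logsig, rng)
            e = model.embed_covariates(codes[vb]) if model.n_cov else None
            for m in mods:
                nb_total = Tensor(0.0)
                for comp, target in (("self", x_self[m]), ("neigh", x_neigh[m])):
                    ll, valid_mask = log_lib[(m, comp)]
                    valid = valid_mask[vb]
                    if not valid.any():
                        continue
                    phi = model.decode_omics(z, e, comp, m, ll[vb])
                    nll = nb_negative_log_likelihood(
                        target[vb], phi, model.theta(comp, m))
                    nb_total = nb_total + (nll * Tensor(valid.astype(float))
                                           ).sum() * (1.0 / max(valid.sum(), 1))
                terms[m] = nb_total
            kl_node = kl_divergence(mu, logsig).mean()

            # ---- edge-level forward ----
            pair_nodes = np.unique(np.concatenate(
                [batch.pos_pairs.ravel(), batch.cand_neg_pairs.ravel()]))
            sub_e = build_subgraph(pair_nodes, neighbor_lists,
                                   n_sample=n_smp, rng=rng)
            local = {g: i for i, g in enumerate(pair_nodes)}
            mu_e, logsig_e = model.encode(features[sub_e.node_ids], sub_e,
                                          transformed=True)
            z_e = model.sample_latent(mu_e, logsig_e, rng)
            rec = batch.rec_pairs
            li = np.array([local[v] for v in rec[:, 0]], dtype=np.intp)
            lj = np.array([local[v] for v in rec[:, 1]], dtype=np.intp)
            logits = model.decode_edges(z_e, li, lj)
            terms["edge"] = edge_reconstruction_loss(
                logits, batch.rec_labels, batch.omega_pos)
            # KL: node-level mean plus edge-level endpoint term
            kl_e = kl_divergence(mu_e, logsig_e)
            eb = np.vstack([batch.pos_pairs, batch.cand_neg_pairs])
            ei = np.array([local[v] for v in eb[:, 0]], dtype=np.intp)
            ej = np.array([local[v] for v in eb[:, 1]], dtype=np.intp)
            n_eb = max(len(batch.pos_pairs), 1)
            kl_edge = (kl_e.take_rows(ei).sum() + kl_e.take_rows(ej).sum()
                       ) * (1.0 / (4.0 * n_eb))
            terms["kl"] = kl_node + kl_edge

            if config.lambda_l1_prior or config.lambda_l1_denovo:
                pr, nv = l1_penalty(model)
                terms["l1_prior"] = pr
                terms["l1_denovo"] = nv

            loss = total_loss(terms, config)
            if not np.isfinite(loss.data):
                bad = [k for k, t in terms.items()
                       if not np.all(np.isfinite(np.asarray(t.data)))]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; offending terms: {bad}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if config.prune:
                pruning_state = update_pruning(pruning_state, model, mu.data)
            for k, t in {**terms, "total": loss}.items():
                epoch_terms.setdefault(k, []).append(float(np.asarray(t.data)))
        rec = {"epoch": epoch}
        rec.update({k: float(np.mean(v)) for k, v in epoch_terms.items()})
        records.append(rec)
        logger.info("epoch %d: total=%.3f", epoch, rec.get("total", np.nan))
    return model, pd.DataFrame(records), pruning_state


def train(dataset: SpatialDataset, graph: NeighborGraph, masks: ProgramMasks,
          config: TrainConfig, seed: int,
          ) -> tuple[NicheVGAE, pd.DataFrame, PruningState]:
    """Initialize and train a model on a dataset (fully seeded)."""
    vocab = {l: sorted(dataset.covariates[l].astype(str).unique())
             for l in dataset.covariates.columns}
    rng = np.random.default_rng(seed)
    model = NicheVGAE(masks, vocab, config.model, rng=rng)
    return fit(model, dataset, graph, config, seed=int(
        rng.integers(0, 2**31 - 1)))


def encode_all(model: NicheVGAE, dataset: SpatialDataset,
               graph: NeighborGraph,
               chunk: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Full-neighborhood posterior (mu, log sigma) for every observation.

    Inference is deterministic and batch-independent: each node's
    one-hop neighborhood is fixed, so chunking cannot change results.
    """
    mods, x_self, x_neigh, features, _ = _prepare_arrays(dataset, graph)
    features = model._encoder_features(features)
    neighbor_lists = graph.neighbor_lists()
    mus, logs = [], []
    for start in range(0, dataset.n_obs, chunk):
        ids = np.arange(start, min(start + chunk, dataset.n_obs))
        sub = build_subgraph(ids, neighbor_lists, n_sample=None)
        mu, logsig = model.encode(features[sub.node_ids], sub,
                                  transformed=True)
        mus.append(mu.data)
        logs.append(logsig.data)
    mu = np.vstack(mus) * model.active_mask[None, :]
    return mu, np.vstack(logs)
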