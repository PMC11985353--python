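"""Downstream interpretation of a trained model.

Covers sign-corrected program activities, per-program feature
importances, Bayesian differential activity testing via log Bayes
factors, selection of niche-characterizing programs, cell-cell
communication potentials and strengths, and Leiden-based niche
identification with a Ward dendrogram over niche centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from sklearn.neighbors import NearestNeighbors

from .model import NicheVGAE
from .spatial_graph import NeighborGraph, SpatialDataset

logger = logging.getLogger(__name__)

__all__ = ["ProgramActivities", "compute_activities", "compute_importances",
           "test_differential_activity", "select_characterizing_programs",
           "compute_communication_potentials",
           "compute_communication_strengths", "identify_niches",
           "cluster_to_n_niches", "LOG_K_THRESHOLD"]

#: |log K| at or above which a program counts as differentially active;
#: corresponds to a posterior probability ratio of exp(2.3) ~ 10.
LOG_K_THRESHOLD = 2.3


# ---------------------------------------------------------------------------
# activities and importances
# ---------------------------------------------------------------------------

@dataclass
class ProgramActivities:
    """Sign-corrected embeddings restricted to active programs."""

    values: np.ndarray             # (n_obs, n_active)
    program_names: list[str]
    signs: np.ndarray              # +1/-1 per active program
    program_index: np.ndarray      # columns of the latent space retained

    def frame(self, obs_names=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.program_names,
                            index=obs_names)


def _program_signs(model: NicheVGAE) -> np.ndarray:
    """Sign-correction factor per program from decoder weight sums.

    Prior programs flip when the aggregated gene-expression weight of
    their source genes (target genes if no source genes exist) is
    negative; de novo programs flip when the sum over all member genes
    is negative.
    """
    w_self = model.params["dec.rna.self.Wpr"].data
    w_neigh = model.params["dec.rna.neigh.Wpr"].data
    signs = np.ones(model.n_gp)
    m = model.masks
    for u in range(model.n_pr):
        src_sum = w_neigh[m.neigh_rna[u] == 1, u].sum()
        if m.neigh_rna[u].sum() > 0:
            agg = src_sum
        else:
            agg = w_self[m.self_rna[u] == 1, u].sum()
        if agg < 0:
            signs[u] = -1.0
    wn_self = model.params["dec.rna.self.Wnv"].data
    wn_neigh = model.params["dec.rna.neigh.Wnv"].data
    for v in range(model.n_nv):
        agg = (wn_self[m.self_rna_nv[v] == 1, v].sum()
               + wn_neigh[m.neigh_rna_nv[v] == 1, v].sum())
        if agg < 0:
            signs[model.n_pr + v] = -1.0
    return signs


def compute_activities(mu: np.ndarray, model: NicheVGAE) -> ProgramActivities:
    """Sign-corrected activities for every active program."""
    signs = _program_signs(model)
    active = model.active_mask.astype(bool)
    idx = np.flatnonzero(active)
    names = [model.masks.all_names[i] for i in idx]
    return ProgramActivities(values=mu[:, idx] * signs[idx][None, :],
                             program_names=names, signs=signs[idx],
                             program_index=idx)


def compute_importances(model: NicheVGAE) -> pd.DataFrame:
    """Normalized |weight| importances per program and modality.

    Importances are normalized over the union of self- and
    neighborhood-component member features, so they sum to 1 per
    (program, modality); fully pruned programs are excluded.
    """
    rows = []
    names = model.masks.all_names
    active = model.active_mask.astype(bool)
    for mod, feats in (("rna", model.masks.gene_names),
                       ("atac", model.masks.peak_names or [])):
        if not feats:
            continue
        for pool, offset in (("pr", 0), ("nv", model.n_pr)):
            w_self = model.params[f"dec.{mod}.self.W{pool}"].data
            w_neigh = model.params[f"dec.{mod}.neigh.W{pool}"].data
            m_self = model._mask_arrays[(mod, "self", pool)]
            m_neigh = model._mask_arrays[(mod, "neigh", pool)]
            n_cols = w_self.shape[1]
            for u in range(n_cols):
                if not active[offset + u]:
                    continue
                entries = []
                for comp, w, msk in (("self", w_self, m_self),
                                     ("neigh", w_neigh, m_neigh)):
                    for f in np.flatnonzero(msk[:, u]):
                        entries.append((comp, f, w[f, u]))
                total = sum(abs(w) for _, _, w in entries)
                if total == 0:
                    continue
                for comp, f, w in entries:
                    rows.append({"program": names[offset + u], "modality": mod,
                                 "component": comp, "feature": feats[f],
                                 "weight": w, "importance": abs(w) / total})
    return pd.DataFrame(rows, columns=["program", "modality", "component",
                                       "feature", "weight", "importance"])


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

def test_differential_activity(mu: np.ndarray, logsig: np.ndarray,
                               group_a: np.ndarray, group_b: np.ndarray,
                               model: NicheVGAE | None = None,
                               signs: np.ndarray | None = None,
                               n_mc: int = 10_000, seed: int = 0,
                               threshold: float = LOG_K_THRESHOLD,
                               program_names: list[str] | None = None,
                               ) -> pd.DataFrame:
    """Log-Bayes-factor test of program activity between two groups.

    ``p(H0) = P(Z_u^(a) > Z_u^(b))`` is estimated by Monte Carlo over
    ``n_mc`` random cross-group pairs of reparameterized posterior
    samples; probabilities are clipped to ``[1/n_mc, 1 - 1/n_mc]``
    before ``log K = log(p / (1 - p))``.  Programs with
    ``|log K| >= threshold`` are flagged.
    """
    group_a = np.asarray(group_a, dtype=np.intp)
    group_b = np.asarray(group_b, dtype=np.intp)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups overlap")
    rng = np.random.default_rng(seed)
    if model is not None:
        signs = _program_signs(model)[model.active_mask.astype(bool)]
        idx = np.flatnonzero(model.active_mask)
        mu = mu[:, idx]
        logsig = logsig[:, idx]
        program_names = [model.masks.all_names[i] for i in idx]
    if signs is None:
        signs = np.ones(mu.shape[1])
    ia = rng.choice(group_a, size=n_mc, replace=True)
    ib = rng.choice(group_b, size=n_mc, replace=True)
    za = mu[ia] + np.exp(logsig[ia]) * rng.standard_normal((n_mc, mu.shape[1]))
    zb = mu[ib] + np.exp(logsig[ib]) * rng.standard_normal((n_mc, mu.shape[1]))
    za *= signs[None, :]
    zb *= signs[None, :]
    p0 = (za > zb).mean(axis=0)
    p0 = np.clip(p0, 1.0 / n_mc, 1.0 - 1.0 / n_mc)
    log_k = np.log(p0 / (1.0 - p0))
    if program_names is None:
        program_names = [f"program_{u}" for u in range(mu.shape[1])]
    return pd.DataFrame({
        "program": program_names, "p_h0": p0, "log_k": log_k,
        "n_a": len(group_a), "n_b": len(group_b),
        "differential": np.abs(log_k) >= threshold,
    })


def select_characterizing_programs(activities: ProgramActivities,
                                   dataset: SpatialDataset,
                                   importances: pd.DataFrame,
                                   niche_labels: np.ndarray,
                                   mu: np.ndarray, logsig: np.ndarray,
                                   model: NicheVGAE,
                                   n_per_niche: int = 2, n_mc: int = 10_000,
                                   seed: int = 0) -> pd.DataFrame:
    """Pick the programs that best characterize each niche.

    Per niche a one-vs-rest differential test selects enriched programs
    (``log K >= threshold``); among them programs are ranked by the
    importance-weighted mean Pearson correlation between the activity
    column and member-gene expression, ties broken by |log K|.
    """
    x = np.asarray(dataset.counts_rna.todense(), dtype=np.float64)
    gene_pos = {g: i for i, g in enumerate(dataset.gene_names)}
    rows = []
    for niche in np.unique(niche_labels):
        in_n = np.flatnonzero(niche_labels == niche)
        out_n = np.flatnonzero(niche_labels != niche)
        res = test_differential_activity(mu, logsig, in_n, out_n, model=model,
                                         n_mc=n_mc, seed=seed)
        enriched = res[res["log_k"] >= LOG_K_THRESHOLD]
        if enriched.empty:
            logger.info("niche %s: no enriched programs", niche)
            continue
        scored = []
        for _, r in enriched.iterrows():
            prog = r["program"]
            col = activities.program_names.index(prog)
            act = activities.values[:, col]
            imp = importances[(importances["program"] == prog)
                              & (importances["modality"] == "rna")]
            cors, weights = [], []
            for _, g in imp.iterrows():
                gi = gene_pos.get(g["feature"])
                if gi is None:
                    continue
                expr = x[:, gi]
                if expr.std() == 0 or act.std() == 0:
                    continue
                cors.append(np.corrcoef(act, expr)[0, 1])
                weights.append(g["importance"])
            score = (np.average(cors, weights=weights)
                     if cors else -np.inf)
            scored.append((prog, score, r["log_k"]))
        scored.sort(key=lambda t: (-t[1], -t[2]))
        if len(scored) < n_per_niche:
            logger.info("niche %s: only %d enriched programs available",
                        niche, len(scored))
        for rank, (prog, score, log_k) in enumerate(scored[:n_per_niche]):
            rows.append({"niche": niche, "rank": rank, "program": prog,
                         "correlation": score, "log_k": log_k})
    return pd.DataFrame(rows, columns=["niche", "rank", "program",
                                       "correlation", "log_k"])


# ---------------------------------------------------------------------------
# communication scoring
# ---------------------------------------------------------------------------

def compute_communication_potentials(dataset: SpatialDataset,
                                     model: NicheVGAE,
                                     activities: ProgramActivities,
                                     program: str) -> pd.DataFrame:
    """Per-cell source and target communication potentials for a program.

    Gene expression is min-max scaled per gene, multiplied by the
    decoder weight of the gene in the relevant component, averaged over
    member genes, multiplied by the cell's program activity, and
    clamped at zero.
    """
    names = model.masks.all_names
    u_global = names.index(program)
    col = activities.program_names.index(program)
    act = activities.values[:, col]
    x = np.asarray(dataset.counts_rna.todense(), dtype=np.float64)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.info("%d constant genes scaled to 0", int(const.sum()))
    scaled = np.where(const[None, :], 0.0, (x - lo[None, :])
                      / np.where(const, 1.0, span)[None, :])
    out = {}
    for comp, key in (("target", "self"), ("source", "neigh")):
        if u_global < model.n_pr:
            w = model.params[f"dec.rna.{key}.Wpr"].data[:, u_global]
            mask = (model.masks.self_rna if key == "self"
                    else model.masks.neigh_rna)[u_global]
        else:
            v = u_global - model.n_pr
            w = model.params[f"dec.rna.{key}.Wnv"].data[:, v]
            mask = (model.masks.self_rna_nv if key == "self"
                    else model.masks.neigh_rna_nv)[v]
        members = np.flatnonzero(mask)
        if len(members) == 0:
            out[comp] = np.zeros(dataset.n_obs)
            continue
        pre = (scaled[:, members] * w[members][None, :]).mean(axis=1)
        out[comp] = np.maximum(pre * act, 0.0)
    return pd.DataFrame({"source_potential": out["source"],
                         "target_potential": out["target"]})


def compute_communication_strengths(potentials: pd.DataFrame,
                                    graph: NeighborGraph,
                                    niche_labels: np.ndarray | None = None,
                                    ) -> dict[str, object]:
    """Directed communication strengths over neighboring cell pairs.

    For every ordered neighbor pair (i -> j), strength is
    ``source_i * target_j``; non-neighbors are implicitly 0.  Cell-level
    aggregates sum outgoing and incoming strengths; the niche-level
    matrix sums over ordered pairs grouped by (niche_i, niche_j).  All
    reported matrices are min-max normalized to [0, 1].
    """
    src = potentials["source_potential"].to_numpy()
    tgt = potentials["target_potential"].to_numpy()
    a = graph.adjacency.tocoo()
    s = src[a.row] * tgt[a.col]
    pair = sp.csr_matrix((s, (a.row, a.col)), shape=a.shape)
    out = {
        "cell_outgoing": np.asarray(pair.sum(axis=1)).ravel(),
        "cell_incoming": np.asarray(pair.sum(axis=0)).ravel(),
    }
    if niche_labels is not None:
        niches = np.unique(niche_labels)
        k = len(niches)
        pos = {n: i for i, n in enumerate(niches)}
        m = np.zeros((k, k))
        np.add.at(m, (np.vectorize(pos.get)(niche_labels[a.row]),
                      np.vectorize(pos.get)(niche_labels[a.col])), s)
        if m.max() > 0:
            m = (m - m.min()) / (m.max() - m.min())
        out["niche_matrix"] = pd.DataFrame(m, index=niches, columns=niches)
    for key in ("cell_outgoing", "cell_incoming"):
        v = out[key]
        if v.max() > v.min():
            out[key] = (v - v.min()) / (v.max() - v.min())
    return out


# ---------------------------------------------------------------------------
# niche identification
# ---------------------------------------------------------------------------

def _leiden(embeddings: np.ndarray, resolution: float, seed: int,
            n_neighbors: int) -> np.ndarray:
    import igraph
    import leidenalg
    n = embeddings.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embeddings)
    _, idx = nn.kneighbors(embeddings)
    src = np.repeat(np.arange(n), k)
    dst = idx.ravel()
    edges = {(min(i, j), max(i, j)) for i, j in zip(src, dst) if i != j}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return np.asarray(part.membership)


def identify_niches(embeddings: np.ndarray, resolution: float = 1.0,
                    seed: int = 0, n_neighbors: int = 15,
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """Leiden clustering of embeddings plus a Ward dendrogram.

    Returns integer niche labels and a scipy linkage matrix over the
    per-niche mean embeddings (None when a single niche is found).
    """
    labels = _leiden(embeddings, resolution, seed, n_neighbors)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return labels, None
    centroids = np.vstack([embeddings[labels == u].mean(axis=0)
                           for u in uniq])
    linkage = hierarchy.linkage(centroids, method="ward")
    return labels, linkage


def subcluster_niche(embeddings: np.ndarray, niche_labels: np.ndarray,
                     niche, resolution: float = 1.0, seed: int = 0,
                     n_neighbors: int = 15) -> np.ndarray:
    """Re-cluster one niche into sub-niches.

    Returns the full label vector with the selected niche's cells
    relabeled as ``"<niche>.<k>"``; other cells keep their labels.
    """
    mask = niche_labels == niche
    if mask.sum() < 2:
        return niche_labels.astype(object)
    sub = _leiden(embeddings[mask], resolution, seed, n_neighbors)
    out = niche_labels.astype(object).copy()
    out[mask] = [f"{niche}.{k}" for k in sub]
    return out


def cluster_to_n_niches(embeddings: np.ndarray, n_target: int, seed: int = 0,
                        n_neighbors: int = 15, max_iter: int = 20,
                        ) -> tuple[np.ndarray, float]:
    """Search the Leiden resolution that yields ``n_target`` niches.

    Bisection on the resolution parameter; returns the labels of the
    closest match and the resolution used.
    """
    lo, hi = 0.01, 4.0
    best_labels, best_res, best_gap = None, None, np.inf
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        labels = _leiden(embeddings, mid, seed, n_neighbors)
        k = len(np.unique(labels))
        gap = abs(k - n_target)
        if gap < best_gap:
            best_labels, best_res, best_gap = labels, mid, gap
        if k == n_target:
            break
        if k < n_target:
            lo = mid
        else:
            hi = mid
    return best_labels, best_res
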