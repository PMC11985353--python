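"""Spatial neighborhood graphs and neighborhood-aggregated node labels.

A spatial omics dataset is a set of observations (cells or spots) with
raw counts, 2D coordinates and categorical covariates.  Tissue structure
is modeled by a disconnected graph of per-sample symmetric k-NN
subgraphs built on Euclidean distances.  Each observation's
reconstruction target concatenates its own feature vector with a
GCN-normalized aggregate over its neighborhood, so that a downstream
decoder can separate cell-intrinsic from microenvironment signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["SpatialDataset", "NeighborGraph", "NodeLabels",
           "build_neighbor_graph", "aggregate_neighborhood"]


@dataclass
class SpatialDataset:
    """Observation-level spatial omics data.

    Parameters
    ----------
    counts_rna
        ``(n_obs, n_genes)`` non-negative integer count matrix
        (dense array or scipy sparse).
    coords
        ``(n_obs, 2)`` spatial coordinates, same length unit per sample.
    covariates
        ``(n_obs, n_cov)`` categorical labels as a DataFrame.  The column
        named by ``sample_key`` identifies the sample; covariates listed
        in ``pure_covariates`` are constant within graph components.
    counts_atac
        Optional ``(n_obs, n_peaks)`` peak count matrix.
    """

    counts_rna: sp.spmatrix | np.ndarray
    coords: np.ndarray
    covariates: pd.DataFrame
    gene_names: list[str]
    counts_atac: sp.spmatrix | np.ndarray | None = None
    peak_names: list[str] | None = None
    obs_names: list[str] | None = None
    sample_key: str | None = None
    pure_covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts_rna = sp.csr_matrix(self.counts_rna)
        if self.counts_atac is not None:
            self.counts_atac = sp.csr_matrix(self.counts_atac)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have exactly 2 columns")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.counts_rna.shape[0]
        if self.coords.shape[0] != n:
            raise ValueError("coords and counts_rna disagree on n_obs")
        if len(self.covariates) != n:
            raise ValueError("covariates and counts_rna disagree on n_obs")
        if self.covariates.isna().any().any():
            raise ValueError("every observation needs a value for every covariate")
        if self.counts_rna.size and self.counts_rna.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(self.gene_names) != self.counts_rna.shape[1]:
            raise ValueError("gene_names length does not match counts_rna")
        if self.counts_atac is not None:
            if self.counts_atac.shape[0] != n:
                raise ValueError("counts_atac and counts_rna disagree on n_obs")
            if self.peak_names is None or len(self.peak_names) != self.counts_atac.shape[1]:
                raise ValueError("peak_names must match counts_atac columns")
        if self.obs_names is None:
            self.obs_names = [f"obs{i}" for i in range(n)]
        if self.sample_key is None and len(self.covariates.columns):
            self.sample_key = self.covariates.columns[0]
        if self.sample_key is not None and self.sample_key not in self.pure_covariates:
            self.pure_covariates = [self.sample_key] + list(self.pure_covariates)
        # multi-sample data must designate the sample covariate
        if self.sample_key is not None:
            n_samples = self.covariates[self.sample_key].nunique()
            if n_samples < 1:
                raise ValueError("sample covariate has no categories")

    @property
    def n_obs(self) -> int:
        return self.counts_rna.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts_rna.shape[1]

    @property
    def n_peaks(self) -> int:
        return 0 if self.counts_atac is None else self.counts_atac.shape[1]

    def sample_ids(self) -> np.ndarray:
        """Per-observation sample labels (single pseudo-sample if absent)."""
        if self.sample_key is None:
            return np.zeros(self.n_obs, dtype=object)
        return self.covariates[self.sample_key].to_numpy()

    def pure_codes(self) -> np.ndarray:
        """Integer code combining all pure covariates per observation."""
        if not self.pure_covariates:
            return np.zeros(self.n_obs, dtype=np.int64)
        key = self.covariates[self.pure_covariates].astype(str).agg("|".join, axis=1)
        return pd.factorize(key)[0]

    def modalities(self) -> dict[str, sp.csr_matrix]:
        out = {"rna": self.counts_rna}
        if self.counts_atac is not None:
            out["atac"] = self.counts_atac
        return out


@dataclass
class NeighborGraph:
    """Symmetric spatial adjacency (no stored self-loops).

    ``degrees[i]`` counts the neighbors of ``i`` plus a self-loop, as
    used by the GCN normalization of the neighborhood aggregation.
    """

    adjacency: sp.csr_matrix
    k: int
    strategy: str = "knn"

    def __post_init__(self):
        self.adjacency = sp.csr_matrix(self.adjacency)
        self.adjacency.setdiag(0)
        self.adjacency.eliminate_zeros()

    @property
    def n_obs(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64) + 1

    def edge_list(self) -> np.ndarray:
        """Undirected edges as an ``(n_edges, 2)`` array with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    def neighbor_lists(self) -> list[np.ndarray]:
        indptr, indices = self.adjacency.indptr, self.adjacency.indices
        return [indices[indptr[i]:indptr[i + 1]] for i in range(self.n_obs)]


@dataclass
class NodeLabels:
    """Self and GCN-aggregated neighborhood features per modality."""

    self_labels: dict[str, sp.csr_matrix]
    neighborhood_labels: dict[str, np.ndarray]

    def concatenated(self, modality: str) -> np.ndarray:
        return np.hstack([np.asarray(self.self_labels[modality].todense()),
                          self.neighborhood_labels[modality]])


def _knn_edges_one_sample(coords: np.ndarray, k: int,
                          chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Directed k-NN edges within one sample.

    Ties at rank k are broken by ascending observation index: a stable
    argsort on exact Euclidean distances preserves index order among
    equal keys, which makes the graph deterministic across platforms.
    """
    n = coords.shape[0]
    rows, cols = [], []
    sq = (coords**2).sum(axis=1)
    for start in range(0, n, chunk):
        block = coords[start:start + chunk]
        d2 = sq[start:start + chunk, None] - 2.0 * block @ coords.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        idx = np.arange(start, min(start + chunk, n))
        d2[np.arange(len(idx)), idx] = -1.0  # self always ranked first
        order = np.argsort(d2, axis=1, kind="stable")[:, 1:k + 1]
        rows.append(np.repeat(idx, k))
        cols.append(order.ravel())
    return np.concatenate(rows), np.concatenate(cols)


def _radius_edges_one_sample(coords: np.ndarray, radius: float,
                             chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    n = coords.shape[0]
    rows, cols = [], []
    sq = (coords**2).sum(axis=1)
    r2 = radius**2
    for start in range(0, n, chunk):
        block = coords[start:start + chunk]
        d2 = sq[start:start + chunk, None] - 2.0 * block @ coords.T + sq[None, :]
        idx = np.arange(start, min(start + chunk, n))
        d2[np.arange(len(idx)), idx] = np.inf
        r, c = np.nonzero(d2 <= r2)
        rows.append(r + start)
        cols.append(c)
    return np.concatenate(rows), np.concatenate(cols)


def build_neighbor_graph(dataset: SpatialDataset, k: int, *,
                         strategy: str = "knn",
                         radius: float | None = None) -> NeighborGraph:
    """Build the sample-wise symmetric spatial neighbor graph.

    Per sample, each node is connected to its ``k`` Euclidean nearest
    neighbors; the directed relation is symmetrized by union (an edge
    exists if either direction is a k-NN).  No cross-sample edges exist.
    With ``strategy="radius"`` a fixed-radius graph is built instead.
    """
    if strategy not in ("knn", "radius"):
        raise ValueError(f"unknown graph strategy {strategy!r}")
    if strategy == "knn" and k < 1:
        raise ValueError("k must be a positive integer")
    if strategy == "radius" and (radius is None or radius <= 0):
        raise ValueError("radius strategy needs a positive radius")
    n = dataset.n_obs
    samples = dataset.sample_ids()
    rows_all, cols_all = [], []
    for s in pd.unique(samples):
        mask = np.flatnonzero(samples == s)
        if strategy == "knn":
            if len(mask) < k + 1:
                raise ValueError(
                    f"sample {s!r} has {len(mask)} observations, "
                    f"fewer than k+1={k + 1}")
            r, c = _knn_edges_one_sample(dataset.coords[mask], k)
        else:
            r, c = _radius_edges_one_sample(dataset.coords[mask], radius)
        rows_all.append(mask[r])
        cols_all.append(mask[c])
    rows = np.concatenate(rows_all) if rows_all else np.empty(0, dtype=np.intp)
    cols = np.concatenate(cols_all) if cols_all else np.empty(0, dtype=np.intp)
    directed = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    symmetric = ((directed + directed.T) > 0).astype(np.int8)
    return NeighborGraph(adjacency=symmetric, k=k, strategy=strategy)


def normalized_adjacency(graph: NeighborGraph) -> sp.csr_matrix:
    """GCN-normalized adjacency with self-loops: D^{-1/2}(A+I)D^{-1/2}."""
    a_hat = graph.adjacency.astype(np.float64) + sp.eye(graph.n_obs, format="csr")
    inv_sqrt = 1.0 / np.sqrt(graph.degrees.astype(np.float64))
    d = sp.diags(inv_sqrt)
    return (d @ a_hat @ d).tocsr()


def aggregate_neighborhood(dataset: SpatialDataset,
                           graph: NeighborGraph) -> NodeLabels:
    """Aggregate features over neighborhoods with the GCN norm.

    For every observation i,

        x'_i = sum_{j in N(i) ∪ {i}}  x_j / sqrt(d_j d_i)

    computed per modality.  An isolated node (self-loop only) keeps
    x'_i = x_i.
    """
    if graph.n_obs != dataset.n_obs:
        raise ValueError("graph and dataset refer to different observations")
    norm = normalized_adjacency(graph)
    self_labels: dict[str, sp.csr_matrix] = {}
    neigh_labels: dict[str, np.ndarray] = {}
    for mod, x in dataset.modalities().items():
        self_labels[mod] = x
        neigh_labels[mod] = np.asarray((norm @ x.astype(np.float64)).todense())
    return NodeLabels(self_labels=self_labels, neighborhood_labels=neigh_labels)
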