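"""Shared fixtures: small synthetic tissues and a trained toy model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nichegp.programs import build_masks
from nichegp.simulation import SimulationConfig, simulate_tissue
from nichegp.spatial_graph import SpatialDataset, build_neighbor_graph
from nichegp.training import TrainConfig, encode_all, train


def small_sim_config(seed: int = 1, **kw) -> SimulationConfig:
    defaults = dict(n_cells=800, n_genes=120, n_injected=4, n_decoys=4,
                    n_markers_per_type=6, n_source_genes=2, n_target_genes=4,
                    seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_tissue():
    return simulate_tissue(small_sim_config())


@pytest.fixture(scope="session")
def small_graph(small_tissue):
    dataset, _ = small_tissue
    return build_neighbor_graph(dataset, k=4)


@pytest.fixture(scope="session")
def small_masks(small_tissue):
    dataset, truth = small_tissue
    return build_masks(truth.programs, dataset.gene_names, n_denovo=10)


@pytest.fixture(scope="session")
def trained_small(small_tissue, small_graph, small_masks):
    """A model trained briefly on the small tissue, with embeddings."""
    dataset, truth = small_tissue
    config = TrainConfig(epochs=12, warmup_epochs=4, n_node_batch=128,
                         n_edge_batch=64)
    model, log, pruning = train(dataset, small_graph, small_masks, config,
                                seed=0)
    mu, logsig = encode_all(model, dataset, small_graph)
    return {"model": model, "log": log, "pruning": pruning, "mu": mu,
            "logsig": logsig, "dataset": dataset, "truth": truth,
            "graph": small_graph, "masks": small_masks, "config": config}


def two_sample_dataset(n_per_sample: int = 30, n_genes: int = 5,
                       seed: int = 0) -> SpatialDataset:
    rng = np.random.default_rng(seed)
    n = 2 * n_per_sample
    counts = rng.poisson(2.0, size=(n, n_genes))
    coords = rng.uniform(0, 1, size=(n, 2))
    cov = pd.DataFrame({"sample": ["a"] * n_per_sample + ["b"] * n_per_sample})
    return SpatialDataset(counts_rna=sp.csr_matrix(counts), coords=coords,
                          covariates=cov,
                          gene_names=[f"g{i}" for i in range(n_genes)],
                          sample_key="sample")
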