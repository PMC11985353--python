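"""Run configuration: defaults, YAML loading and override handling."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run.

    Every parameter has a default; the effective configuration (after
    file values and flag overrides) is serialized next to the outputs.
    """

    # graph
    k: int = 4
    graph_strategy: str = "knn"
    radius: float | None = None
    # model
    n_emb: int = 10
    n_heads: int = 4
    encoder: str = "gat"
    n_denovo: int = 100
    # training
    lambda_edge: float = 500.0
    lambda_rna: float = 1.0
    lambda_atac: float = 1.0
    lambda_l1_prior: float = 0.0
    lambda_l1_denovo: float = 0.0
    lr: float = 2e-3
    n_node_batch: int = 256
    n_edge_batch: int = 128
    n_sampled_neighbors: int = 4
    epochs: int = 50
    prune: bool = True
    tau: float = 0.05
    warmup_epochs: int = 40
    ema_decay: float = 0.99
    seed: int = 0
    # analysis
    resolution: float = 1.0
    n_mc: int = 10_000
    log_k_threshold: float = 2.3
    cluster_neighbors: int = 15

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            lambda_edge=self.lambda_edge, lambda_rna=self.lambda_rna,
            lambda_atac=self.lambda_atac,
            lambda_l1_prior=self.lambda_l1_prior,
            lambda_l1_denovo=self.lambda_l1_denovo, lr=self.lr,
            n_node_batch=self.n_node_batch, n_edge_batch=self.n_edge_batch,
            n_sampled_neighbors=self.n_sampled_neighbors, epochs=self.epochs,
            prune=self.prune, tau=self.tau,
            warmup_epochs=self.warmup_epochs, ema_decay=self.ema_decay,
            model=ModelConfig(n_emb=self.n_emb, n_heads=self.n_heads,
                              encoder=self.encoder))

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
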