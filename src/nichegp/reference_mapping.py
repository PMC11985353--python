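"""Map query datasets onto a trained reference model.

Query integration uses weight-restricted fine-tuning: every weight of
the reference model is frozen except the covariate embedding matrices,
which are extended with freshly initialized rows for categories unseen
during reference training (new rows start at the mean of the existing
rows of that covariate).  Niche labels are transferred from reference to
query cells with a k-NN classifier in embedding space.
"""

from __future__ import annotations

import copy
import logging

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .model import NicheVGAE
from .spatial_graph import NeighborGraph, SpatialDataset
from .training import PruningState, TrainConfig, encode_all, fit

logger = logging.getLogger(__name__)

__all__ = ["extend_covariates", "fine_tune_query", "transfer_labels"]


def extend_covariates(model: NicheVGAE, query: SpatialDataset) -> NicheVGAE:
    """Copy the model and add embedding rows for unseen query categories."""
    out = copy.deepcopy(model)
    for l in out.covariate_categories:
        if l not in query.covariates.columns:
            raise ValueError(f"query lacks covariate {l!r}")
        seen = out.covariate_categories[l]
        new = [c for c in sorted(query.covariates[l].astype(str).unique())
               if c not in seen]
        if not new:
            continue
        w = out.params[f"cov.{l}"]
        mean_row = w.data.mean(axis=0, keepdims=True)
        w.data = np.vstack([w.data] + [mean_row.copy() for _ in new])
        out.covariate_categories[l] = seen + new
        logger.info("covariate %s: added %d query categories", l, len(new))
    return out


def fine_tune_query(reference: NicheVGAE, query: SpatialDataset,
                    graph: NeighborGraph, config: TrainConfig, seed: int,
                    pruning_state: PruningState | None = None,
                    ) -> tuple[NicheVGAE, pd.DataFrame, np.ndarray]:
    """Fine-tune covariate embeddings on a query dataset.

    The query feature panel must match the reference panel exactly.
    Gradients flow only into covariate embedding matrices; pruning EMAs
    continue updating and may deactivate further programs.  Returns the
    extended model, the training log and the query embeddings computed
    with the (frozen) encoder.
    """
    if list(query.gene_names) != list(reference.masks.gene_names):
        missing = set(reference.masks.gene_names) - set(query.gene_names)
        raise ValueError(
            f"query gene panel differs from reference; missing {sorted(missing)[:5]}")
    if reference.masks.peak_names and (
            query.peak_names is None
            or list(query.peak_names) != list(reference.masks.peak_names)):
        raise ValueError("query peak panel differs from reference")
    model = extend_covariates(reference, query)
    if config.epochs > 0:
        model, log, _ = fit(model, query, graph, config, seed,
                            trainable=("cov.",), pruning_state=pruning_state)
    else:
        log = pd.DataFrame()
    mu, _ = encode_all(model, query, graph)
    return model, log, mu


def transfer_labels(reference_embeddings: np.ndarray,
                    reference_labels: np.ndarray,
                    query_embeddings: np.ndarray,
                    k: int = 15) -> pd.DataFrame:
    """k-NN majority-vote label transfer in embedding space.

    Per query cell, the majority label among its ``k`` Euclidean
    nearest reference cells, with probability equal to the vote
    fraction.  Neighbor ties are broken by distance then reference
    index; vote ties go to the label of the nearest tied neighbor.
    Low-probability assignments flag candidate novel niches.
    """
    if k > len(reference_embeddings):
        raise ValueError("k exceeds the reference size")
    reference_labels = np.asarray(reference_labels)
    nn = NearestNeighbors(n_neighbors=k).fit(reference_embeddings)
    dist, idx = nn.kneighbors(query_embeddings)
    # deterministic ordering: distance, then reference index
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    labels, probs = [], []
    for row in idx:
        votes = reference_labels[row]
        uniq, counts = np.unique(votes, return_counts=True)
        top = counts.max()
        tied = set(uniq[counts == top])
        if len(tied) == 1:
            win = uniq[counts.argmax()]
        else:  # nearest neighbor holding a tied label decides
            win = next(v for v in votes if v in tied)
        labels.append(win)
        probs.append(top / k)
    return pd.DataFrame({"label": labels, "probability": probs})
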