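"""Conditional variational graph autoencoder with masked linear decoders.

The encoder maps each observation's omics feature vector through a fully
connected layer of width equal to the number of gene programs, then
through two parallel message-passing layers (dynamic graph attention by
default, graph convolution in light mode) that produce the mean and log
standard deviation of the variational posterior.  Per-covariate
embedding matrices capture confounders and are injected into the omics
decoders only, so latent embeddings stay covariate-free.

The decoder has three parts: a cosine-similarity graph decoder that
reconstructs adjacency between nodes with identical pure covariates, and
per modality a *self* and a *neighborhood* omics decoder — single linear
layers whose weights are elementwise-masked by the binary program
matrices, followed by a softmax across features scaled by the empirical
library size.  Counts are modeled as negative binomial with
feature-specific inverse dispersions.  Each latent dimension is thereby
tied to one gene program and is directly interpretable as that program's
activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import scipy.sparse as sp

from .autodiff import (Parameter, Tensor, concat, gammaln, log_softmax,
                       segment_softmax, sparse_matmul)
from .programs import ProgramMasks

__all__ = ["ModelConfig", "NicheVGAE", "nb_negative_log_likelihood",
           "kl_divergence", "cosine_edge_logits"]

EPS = 1e-12


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    n_emb:
        embedding width per categorical covariate.
    n_heads:
        attention heads in the message-passing layers (head outputs are
        averaged so the latent width stays at the number of programs).
    encoder:
        ``"gat"`` for dynamic graph attention, ``"gcn"`` for the light
        graph-convolution variant.
    encoder_input:
        ``"log1p"`` (default) feeds log(1+x) to the first layer; raw
        counts are available via ``"raw"``.
    """

    n_emb: int = 10
    n_heads: int = 4
    encoder: str = "gat"
    encoder_input: str = "log1p"
    logvar_clamp: float = 5.0
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.encoder not in ("gat", "gcn"):
            raise ValueError(f"unknown encoder mode {self.encoder!r}")
        if self.encoder_input not in ("log1p", "raw"):
            raise ValueError(f"unknown encoder input {self.encoder_input!r}")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


@dataclass
class Subgraph:
    """A node-induced subgraph prepared for one encoder forward pass.

    ``edges`` run source -> destination and include a self-loop for
    every output node; ``out_index`` locates the nodes whose posteriors
    are needed within the subgraph's local ordering.
    """

    node_ids: np.ndarray           # global ids, local order
    edge_src: np.ndarray           # local indices
    edge_dst: np.ndarray
    edge_coef: np.ndarray          # GCN normalization per edge
    out_index: np.ndarray          # local indices of output nodes


def build_subgraph(seed_nodes: np.ndarray,
                   neighbor_lists: list[np.ndarray],
                   n_sample: int | None = None,
                   rng: np.random.Generator | None = None) -> Subgraph:
    """One-hop subgraph around ``seed_nodes``.

    With ``n_sample`` set, at most that many neighbors per seed are
    drawn without replacement (inductive neighbor sampling); otherwise
    the full neighborhood is used.
    """
    seed_nodes = np.asarray(seed_nodes, dtype=np.intp)
    chosen: list[np.ndarray] = []
    for v in seed_nodes:
        nb = neighbor_lists[v]
        if n_sample is not None and len(nb) > n_sample:
            nb = rng.choice(nb, size=n_sample, replace=False)
        chosen.append(np.sort(nb))
    all_nodes = np.unique(np.concatenate([seed_nodes] + chosen))
    local = {g: i for i, g in enumerate(all_nodes)}
    src, dst = [], []
    for v, nb in zip(seed_nodes, chosen):
        lv = local[v]
        src.append(lv)  # self-loop
        dst.append(lv)
        for u in nb:
            src.append(local[u])
            dst.append(lv)
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    # degrees within the (sampled) subgraph: 1 (self) + incoming edges
    deg = np.ones(len(all_nodes))
    nonself = src != dst
    np.add.at(deg, dst[nonself], 1.0)
    coef = 1.0 / np.sqrt(deg[src] * deg[dst])
    out_index = np.array([local[v] for v in seed_nodes], dtype=np.intp)
    return Subgraph(node_ids=all_nodes, edge_src=src, edge_dst=dst,
                    edge_coef=coef, out_index=out_index)


class NicheVGAE:
    """The conditional variational graph autoencoder."""

    def __init__(self, masks: ProgramMasks,
                 covariate_categories: dict[str, list[str]],
                 config: ModelConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.masks = masks
        self.config = config or ModelConfig()
        self.covariate_categories = {k: list(v)
                                     for k, v in covariate_categories.items()}
        rng = rng or np.random.default_rng(0)
        cfg = self.config
        self.n_genes = len(masks.gene_names)
        self.n_peaks = len(masks.peak_names) if masks.peak_names else 0
        self.n_fts = self.n_genes + self.n_peaks
        self.n_pr = masks.n_prior
        self.n_nv = masks.n_denovo
        self.n_gp = self.n_pr + self.n_nv
        self.n_cov = len(self.covariate_categories)
        self.n_emb_total = cfg.n_emb * self.n_cov

        p: dict[str, Parameter] = {}
        p["enc.fc.W"] = Parameter(_glorot(rng, (self.n_fts, self.n_gp)))
        p["enc.fc.b"] = Parameter(np.zeros(self.n_gp))
        for head in ("mu", "logsig"):
            if cfg.encoder == "gat":
                p[f"enc.{head}.Wl"] = Parameter(_glorot(rng, (self.n_gp, self.n_gp)))
                p[f"enc.{head}.Wr"] = Parameter(_glorot(rng, (self.n_gp, self.n_gp)))
                p[f"enc.{head}.attn"] = Parameter(
                    _glorot(rng, (cfg.n_heads, self.n_gp)))
            else:
                p[f"enc.{head}.W"] = Parameter(_glorot(rng, (self.n_gp, self.n_gp)))
        for l, cats in self.covariate_categories.items():
            p[f"cov.{l}"] = Parameter(
                rng.normal(0.0, 0.1, size=(len(cats), cfg.n_emb)))
        self._mask_arrays: dict[tuple[str, str, str], np.ndarray] = {}
        for mod, n_feat in self._modality_sizes().items():
            for comp in ("self", "neigh"):
                mp, mn = self._masks_for(mod, comp)
                self._mask_arrays[(mod, comp, "pr")] = mp.T.astype(float)
                self._mask_arrays[(mod, comp, "nv")] = mn.T.astype(float)
                key = f"dec.{mod}.{comp}"
                # masked positions start (and stay) exactly zero
                p[f"{key}.Wpr"] = Parameter(
                    _glorot(rng, (n_feat, self.n_pr)) * mp.T)
                p[f"{key}.Wnv"] = Parameter(
                    _glorot(rng, (n_feat, self.n_nv)) * mn.T)
                if self.n_emb_total:
                    p[f"{key}.Wemb"] = Parameter(
                        _glorot(rng, (n_feat, self.n_emb_total)))
                p[f"{key}.log_theta"] = Parameter(np.zeros(n_feat))
        self.params = p
        self.active_prior = np.ones(self.n_pr, dtype=bool)
        self.active_denovo = np.ones(self.n_nv, dtype=bool)

    # -- bookkeeping ----------------------------------------------------------
    def _modality_sizes(self) -> dict[str, int]:
        out = {"rna": self.n_genes}
        if self.n_peaks:
            out["atac"] = self.n_peaks
        return out

    def _masks_for(self, mod: str, comp: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.masks
        table = {
            ("rna", "self"): (m.self_rna, m.self_rna_nv),
            ("rna", "neigh"): (m.neigh_rna, m.neigh_rna_nv),
            ("atac", "self"): (m.self_atac, m.self_atac_nv),
            ("atac", "neigh"): (m.neigh_atac, m.neigh_atac_nv),
        }
        return table[(mod, comp)]

    @property
    def active_mask(self) -> np.ndarray:
        return np.concatenate([self.active_prior,
                               self.active_denovo]).astype(float)

    def parameters(self, only: tuple[str, ...] | None = None) -> list[Parameter]:
        if only is None:
            return list(self.params.values())
        return [v for k, v in self.params.items()
                if any(k.startswith(pfx) for pfx in only)]

    # -- encoder --------------------------------------------------------------
    def _encoder_features(self, x: np.ndarray) -> np.ndarray:
        if self.config.encoder_input == "log1p":
            return np.log1p(x)
        return x

    def encode(self, features: np.ndarray, sub: Subgraph,
               transformed: bool = False) -> tuple[Tensor, Tensor]:
        """Posterior mean and log-sigma for the subgraph's output nodes.

        ``features`` are the raw feature rows for ``sub.node_ids`` in
        local order (``transformed=True`` skips the input transform when
        the caller pre-applied it).
        """
        if features.shape[1] != self.n_fts:
            raise ValueError(
                f"feature dimension {features.shape[1]} != model {self.n_fts}")
        x = Tensor(features if transformed
                   else self._encoder_features(features))
        h = (x @ self.params["enc.fc.W"] + self.params["enc.fc.b"])
        h = h.layer_norm().relu()
        n_nodes = features.shape[0]
        n_edges = len(sub.edge_src)
        ones = np.ones(n_edges)
        gather_src = sp.csr_matrix(
            (ones, (np.arange(n_edges), sub.edge_src)), shape=(n_edges, n_nodes))
        gather_dst = sp.csr_matrix(
            (ones, (np.arange(n_edges), sub.edge_dst)), shape=(n_edges, n_nodes))
        scatter_dst = gather_dst.T.tocsr()
        outs = []
        for head in ("mu", "logsig"):
            if self.config.encoder == "gcn":
                hw = h @ self.params[f"enc.{head}.W"]
                msg = sparse_matmul(gather_src, hw) * Tensor(
                    sub.edge_coef[:, None])
                out = sparse_matmul(scatter_dst, msg)
            else:
                hl = h @ self.params[f"enc.{head}.Wl"]
                hr = h @ self.params[f"enc.{head}.Wr"]
                msgs = sparse_matmul(gather_src, hr)
                pair = (sparse_matmul(gather_dst, hl) + msgs).leaky_relu(
                    self.config.leaky_slope)
                # head outputs share the message transform, so averaging
                # the per-head attention weights first is equivalent to
                # averaging the head outputs
                alpha_mean = None
                attn = self.params[f"enc.{head}.attn"]
                for hd in range(self.config.n_heads):
                    a = attn.take_rows(np.array([hd])).reshape(-1, 1)
                    e = (pair @ a).reshape(-1)
                    alpha = segment_softmax(e, sub.edge_dst, n_nodes)
                    alpha_mean = alpha if alpha_mean is None \
                        else alpha_mean + alpha
                alpha_mean = alpha_mean * (1.0 / self.config.n_heads)
                out = sparse_matmul(scatter_dst,
                                    msgs * alpha_mean.reshape(-1, 1))
            outs.append(out.take_rows(sub.out_index))
        mu, logsig = outs
        c = self.config.logvar_clamp
        return mu, logsig.clamp(-c, c)

    def sample_latent(self, mu: Tensor, logsig: Tensor,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Reparameterized draw (posterior mean at inference)."""
        if rng is None:
            z = mu
        else:
            eps = rng.standard_normal(mu.shape)
            z = mu + logsig.exp() * Tensor(eps)
        return z * Tensor(self.active_mask[None, :])

    def embed_covariates(self, codes: np.ndarray) -> Tensor | None:
        """Concatenated covariate embeddings for integer category codes."""
        if self.n_cov == 0:
            return None
        parts = []
        for j, l in enumerate(self.covariate_categories):
            idx = codes[:, j]
            n_cat = len(self.covariate_categories[l])
            if idx.max(initial=-1) >= n_cat or idx.min(initial=0) < 0:
                raise ValueError(f"unseen category code for covariate {l!r}")
            parts.append(self.params[f"cov.{l}"].take_rows(idx))
        return concat(parts, axis=1)

    # -- decoders -------------------------------------------------------------
    def decode_edges(self, z: Tensor, pair_i: np.ndarray,
                     pair_j: np.ndarray) -> Tensor:
        """Cosine-similarity logits for node pairs (in z's row order)."""
        zi = z.take_rows(pair_i)
        zj = z.take_rows(pair_j)
        num = (zi * zj).sum(axis=1)
        ni = ((zi * zi).sum(axis=1) + EPS).sqrt()
        nj = ((zj * zj).sum(axis=1) + EPS).sqrt()
        return num / (ni * nj)

    def decode_omics(self, z: Tensor, e: Tensor | None, component: str,
                     modality: str, log_library: np.ndarray) -> Tensor:
        """Negative-binomial mean parameters for one component/modality.

        Softmax across features times the empirical library size, so the
        reconstructed means sum to each observation's total counts.
        """
        key = f"dec.{modality}.{component}"
        wpr = self.params[f"{key}.Wpr"] * Tensor(
            self._mask_arrays[(modality, component, "pr")])
        wnv = self.params[f"{key}.Wnv"] * Tensor(
            self._mask_arrays[(modality, component, "nv")])
        act = self.active_mask
        z_pr = z.take_cols(np.arange(self.n_pr)) * Tensor(act[None, :self.n_pr])
        z_nv = z.take_cols(np.arange(self.n_pr, self.n_gp)) * Tensor(
            act[None, self.n_pr:])
        logits = z_pr @ wpr.T + z_nv @ wnv.T
        if e is not None and self.n_emb_total:
            logits = logits + e @ self.params[f"{key}.Wemb"].T
        log_prop = log_softmax(logits, axis=1)
        return (log_prop + Tensor(np.asarray(log_library)[:, None])).exp()

    def theta(self, component: str, modality: str) -> Tensor:
        return self.params[f"dec.{modality}.{component}.log_theta"].exp()

    # -- checkpoint serialization --------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param.{k}": v.data.copy() for k, v in self.params.items()}
        out["active_prior"] = self.active_prior.copy()
        out["active_denovo"] = self.active_denovo.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(state[f"param.{k}"], dtype=np.float64)
        self.active_prior = np.array(state["active_prior"], dtype=bool)
        self.active_denovo = np.array(state["active_denovo"], dtype=bool)


# ---------------------------------------------------------------------------
# likelihood / divergence primitives
# ---------------------------------------------------------------------------

def nb_negative_log_likelihood(x, phi, theta) -> Tensor:
    """Per-observation negative binomial NLL, summed over features.

    Mean parameterization: mean ``phi`` (>=0) and feature-specific
    inverse dispersion ``theta`` (>0), variance phi + phi^2/theta.
    Returns a tensor of shape ``(n_obs,)``.
    """
    x_arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    if np.any(x_arr < 0):
        raise ValueError("negative counts are not allowed")
    x = Tensor(x_arr)
    phi = phi if isinstance(phi, Tensor) else Tensor(phi)
    theta = theta if isinstance(theta, Tensor) else Tensor(theta)
    log_theta_phi = (theta + phi + EPS).log()
    ll = (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
          + theta * ((theta + EPS).log() - log_theta_phi)
          + x * ((phi + EPS).log() - log_theta_phi))
    return -ll.sum(axis=-1)


def kl_divergence(mu, logsig) -> Tensor:
    """KL(q || N(0, I)) per observation: -1/2 Σ(1 + log σ² - μ² - σ²)."""
    mu = mu if isinstance(mu, Tensor) else Tensor(mu)
    logsig = logsig if isinstance(logsig, Tensor) else Tensor(logsig)
    sig2 = (logsig * 2.0).exp()
    return ((mu * mu + sig2 - logsig * 2.0 - 1.0) * 0.5).sum(axis=-1)


def cosine_edge_logits(z: np.ndarray, pair_i: np.ndarray,
                       pair_j: np.ndarray) -> np.ndarray:
    """Plain-array cosine logits (inference convenience)."""
    zi, zj = z[pair_i], z[pair_j]
    num = (zi * zj).sum(axis=1)
    den = np.sqrt(((zi**2).sum(axis=1) + EPS) * ((zj**2).sum(axis=1) + EPS))
    return num / den
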