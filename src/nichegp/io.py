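"""File bundle readers/writers and single-file model checkpoints.

A dataset bundle is a directory of plain-text files: counts in
MatrixMarket (``counts_rna.mtx``) or dense delimited text, feature and
observation name lists, a coordinates table and a covariates table.
Optional files add ATAC counts, peak intervals (BED), gene annotations
and a program-definition table.  Checkpoints are single ``.npz``
archives holding all weights, masks, configuration, covariate
vocabularies and pruning state under a versioned schema.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .model import ModelConfig, NicheVGAE
from .programs import ProgramMasks, load_programs
from .spatial_graph import SpatialDataset
from .training import PruningState

logger = logging.getLogger(__name__)

__all__ = ["read_bundle", "write_bundle", "save_checkpoint",
           "load_checkpoint", "CHECKPOINT_SCHEMA"]

CHECKPOINT_SCHEMA = 1


def _read_names(path: Path) -> list[str]:
    return path.read_text().splitlines()


def _read_counts(dirpath: Path, stem: str) -> sp.csr_matrix | None:
    mtx = dirpath / f"{stem}.mtx"
    txt = dirpath / f"{stem}.tsv"
    if mtx.exists():
        return sp.csr_matrix(sio.mmread(mtx))
    if txt.exists():
        return sp.csr_matrix(
            pd.read_csv(txt, sep="\t", header=None).to_numpy())
    return None


def read_bundle(dirpath) -> dict:
    """Read a dataset bundle directory into a :class:`SpatialDataset`.

    Returns a dict with keys ``dataset`` and, when present, ``programs``,
    ``peaks``, ``annotation`` and ``ground_truth``.
    """
    d = Path(dirpath)
    counts = _read_counts(d, "counts_rna")
    if counts is None:
        raise FileNotFoundError(f"no counts_rna.mtx or counts_rna.tsv in {d}")
    data = counts.data
    if not np.allclose(data, np.round(data)):
        raise ValueError("counts_rna contains non-integer values")
    genes = _read_names(d / "genes.txt")
    obs = _read_names(d / "observations.txt")
    coords = pd.read_csv(d / "coords.tsv", sep="\t")
    cov = pd.read_csv(d / "covariates.tsv", sep="\t", dtype=str)
    for name, n in (("coords.tsv", len(coords)), ("covariates.tsv", len(cov)),
                    ("observations.txt", len(obs))):
        if n != counts.shape[0]:
            raise ValueError(
                f"{name} has {n} rows but counts_rna has {counts.shape[0]}")
    atac = _read_counts(d, "counts_atac")
    peaks = None
    if atac is not None:
        peaks = _read_names(d / "peaks.txt")
    meta = {}
    meta_path = d / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    dataset = SpatialDataset(
        counts_rna=counts.astype(np.int64),
        coords=coords[["x", "y"]].to_numpy(),
        covariates=cov, gene_names=genes, obs_names=obs,
        counts_atac=None if atac is None else atac.astype(np.int64),
        peak_names=peaks,
        sample_key=meta.get("sample_key"),
        pure_covariates=meta.get("pure_covariates", []))
    out = {"dataset": dataset}
    if (d / "programs.tsv").exists():
        progs = load_programs(d / "programs.tsv")
        panel = set(genes)
        n_prog_genes = {g for p in progs
                        for g in p.source_genes + p.target_genes}
        frac = (len(n_prog_genes & panel) / len(n_prog_genes)
                if n_prog_genes else 1.0)
        logger.info("%.0f%% of program genes present on the panel",
                    100 * frac)
        out["programs"] = progs
    if (d / "peaks.bed").exists():
        out["peaks"] = pd.read_csv(
            d / "peaks.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "name"])
    if (d / "annotation.tsv").exists():
        out["annotation"] = pd.read_csv(d / "annotation.tsv", sep="\t")
    if (d / "ground_truth.tsv").exists():
        out["ground_truth"] = pd.read_csv(d / "ground_truth.tsv", sep="\t")
    return out


def _atomic_write(path: Path, writer) -> None:
    tmp = tempfile.NamedTemporaryFile(
        dir=path.parent, prefix=f".{path.name}.", delete=False)
    tmp.close()
    try:
        writer(tmp.name)
        os.replace(tmp.name, path)
    except BaseException:
        os.unlink(tmp.name)
        raise


def write_bundle(dirpath, dataset: SpatialDataset,
                 ground_truth: pd.DataFrame | None = None,
                 programs_path_rows: pd.DataFrame | None = None,
                 peaks: pd.DataFrame | None = None,
                 annotation: pd.DataFrame | None = None) -> None:
    """Write a dataset (and companions) as a plain-text bundle."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    # pass a file object: mmwrite would append ".mtx" to a bare temp path
    _atomic_write(d / "counts_rna.mtx",
                  lambda p: sio.mmwrite(open(p, "wb"), dataset.counts_rna,
                                        field="integer"))
    (d / "genes.txt").write_text("\n".join(dataset.gene_names) + "\n")
    (d / "observations.txt").write_text("\n".join(dataset.obs_names) + "\n")
    pd.DataFrame({"x": dataset.coords[:, 0], "y": dataset.coords[:, 1]}
                 ).to_csv(d / "coords.tsv", sep="\t", index=False)
    dataset.covariates.to_csv(d / "covariates.tsv", sep="\t", index=False)
    json.dump({"sample_key": dataset.sample_key,
               "pure_covariates": dataset.pure_covariates},
              open(d / "meta.json", "w"))
    if dataset.counts_atac is not None:
        _atomic_write(d / "counts_atac.mtx",
                      lambda p: sio.mmwrite(open(p, "wb"),
                                            dataset.counts_atac,
                                            field="integer"))
        (d / "peaks.txt").write_text("\n".join(dataset.peak_names) + "\n")
    if ground_truth is not None:
        ground_truth.to_csv(d / "ground_truth.tsv", sep="\t", index=False)
    if peaks is not None:
        peaks.to_csv(d / "peaks.bed", sep="\t", index=False, header=False)
    if annotation is not None:
        annotation.to_csv(d / "annotation.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _masks_to_arrays(m: ProgramMasks) -> dict[str, np.ndarray]:
    out = {"mask.self_rna": m.self_rna, "mask.neigh_rna": m.neigh_rna,
           "mask.self_rna_nv": m.self_rna_nv,
           "mask.neigh_rna_nv": m.neigh_rna_nv,
           "mask.reg_self": m.reg_self, "mask.reg_neigh": m.reg_neigh}
    for key in ("self_atac", "neigh_atac", "self_atac_nv", "neigh_atac_nv"):
        arr = getattr(m, key)
        if arr is not None:
            out[f"mask.{key}"] = arr
    return out


def save_checkpoint(path, model: NicheVGAE,
                    pruning_state: PruningState | None = None) -> None:
    """Serialize model weights, masks, config and pruning state."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "model_config": asdict(model.config),
        "covariate_categories": model.covariate_categories,
        "program_names": model.masks.program_names,
        "denovo_names": model.masks.denovo_names,
        "gene_names": model.masks.gene_names,
        "peak_names": model.masks.peak_names,
    }
    arrays = dict(model.state_dict())
    arrays.update(_masks_to_arrays(model.masks))
    if pruning_state is not None:
        arrays["prune.ema"] = pruning_state.ema
        meta["pruning"] = {"decay": pruning_state.decay,
                           "tau": pruning_state.tau,
                           "warmup_steps": pruning_state.warmup_steps,
                           "step": pruning_state.step,
                           "initialized": pruning_state.initialized}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _atomic_write(path, lambda p: np.savez(open(p, "wb"), **arrays))


def load_checkpoint(path) -> tuple[NicheVGAE, PruningState | None]:
    with np.load(path) as zf:
        arrays = {k: zf[k] for k in zf.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    if meta["schema"] != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
    masks = ProgramMasks(
        program_names=meta["program_names"],
        denovo_names=meta["denovo_names"],
        gene_names=meta["gene_names"],
        self_rna=arrays["mask.self_rna"], neigh_rna=arrays["mask.neigh_rna"],
        self_rna_nv=arrays["mask.self_rna_nv"],
        neigh_rna_nv=arrays["mask.neigh_rna_nv"],
        reg_self=arrays["mask.reg_self"], reg_neigh=arrays["mask.reg_neigh"],
        peak_names=meta["peak_names"],
        self_atac=arrays.get("mask.self_atac"),
        neigh_atac=arrays.get("mask.neigh_atac"),
        self_atac_nv=arrays.get("mask.self_atac_nv"),
        neigh_atac_nv=arrays.get("mask.neigh_atac_nv"))
    model = NicheVGAE(masks, meta["covariate_categories"],
                      ModelConfig(**meta["model_config"]))
    model.load_state_dict(arrays)
    pruning = None
    if "prune.ema" in arrays:
        p = meta["pruning"]
        pruning = PruningState(ema=arrays["prune.ema"], decay=p["decay"],
                               tau=p["tau"], warmup_steps=p["warmup_steps"],
                               step=p["step"], initialized=p["initialized"])
    return model, pruning
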