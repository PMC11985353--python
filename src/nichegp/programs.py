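"""Gene programs: loading, filtering, merging, peak linking and masks.

A gene program (GP) names a set of genes split into a *neighborhood
component* (interaction-source genes: ligands, enzymes, transcription
factors expressed by neighboring cells) and a *self component*
(interaction-target genes: receptors, sensors and downstream targets
expressed by the cell itself).  Programs constrain the decoder of the
model through binary masks over the measured gene (and, for multimodal
data, peak) panel.  De novo programs cover the panel complement of all
prior programs and are shaped by L1 sparsity during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneProgram", "ProgramMasks", "PeakGeneLinks",
    "load_programs", "save_programs", "cap_target_genes",
    "merge_redundant", "link_peaks_to_genes", "build_masks",
    "CATEGORIES", "GENE_LABELS",
]

CATEGORIES = ("ligand-receptor", "metabolite-sensor", "combined-interaction",
              "transcriptional-regulation", "de-novo")
GENE_LABELS = ("ligand", "receptor", "transcription_factor", "sensor",
               "target_gene")
INTERACTION_CATEGORIES = ("ligand-receptor", "metabolite-sensor",
                          "combined-interaction")


@dataclass
class GeneProgram:
    """A named prior (or de novo) gene program.

    ``source_genes`` form the neighborhood component, ``target_genes``
    the self component.  ``gene_labels`` assigns each gene a functional
    label from the closed set; ``scores`` optionally carries per-target
    regulatory scores used when capping large programs.
    """

    name: str
    category: str
    source_genes: tuple[str, ...]
    target_genes: tuple[str, ...]
    gene_labels: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown program category {self.category!r}")
        for g, lab in self.gene_labels.items():
            if lab not in GENE_LABELS:
                raise ValueError(f"unknown gene label {lab!r} for gene {g!r}")
        if self.category in INTERACTION_CATEGORIES:
            if not self.source_genes or not self.target_genes:
                raise ValueError(
                    f"program {self.name!r}: interaction categories require "
                    "non-empty source and target gene sets")
        self.source_genes = tuple(dict.fromkeys(self.source_genes))
        self.target_genes = tuple(dict.fromkeys(self.target_genes))


@dataclass
class PeakGeneLinks:
    """Mapping peak -> linked genes, with the rule deriving each link."""

    links: dict[str, set[str]]
    rules: dict[tuple[str, str], str]  # (peak, gene) -> "gene_body" | "promoter"

    def genes_for(self, peak: str) -> set[str]:
        return self.links.get(peak, set())

    def peaks_for_genes(self, genes: set[str]) -> set[str]:
        return {p for p, gs in self.links.items() if gs & genes}


@dataclass
class ProgramMasks:
    """Binary self/neighborhood program masks per modality.

    Rows index programs, columns genes (or peaks).  ``self_*`` masks
    mark target genes; ``neigh_*`` masks mark source genes.  The
    regularization indicators are 1 only where the corresponding RNA
    mask is 1 and the gene belongs to a regularized functional category.
    """

    program_names: list[str]
    denovo_names: list[str]
    gene_names: list[str]
    self_rna: np.ndarray          # (n_prior, n_genes)
    neigh_rna: np.ndarray
    self_rna_nv: np.ndarray       # (n_denovo, n_genes)
    neigh_rna_nv: np.ndarray
    reg_self: np.ndarray          # indicator I, aligned with self_rna
    reg_neigh: np.ndarray
    peak_names: list[str] | None = None
    self_atac: np.ndarray | None = None
    neigh_atac: np.ndarray | None = None
    self_atac_nv: np.ndarray | None = None
    neigh_atac_nv: np.ndarray | None = None

    @property
    def n_prior(self) -> int:
        return len(self.program_names)

    @property
    def n_denovo(self) -> int:
        return len(self.denovo_names)

    @property
    def n_programs(self) -> int:
        return self.n_prior + self.n_denovo

    @property
    def all_names(self) -> list[str]:
        return list(self.program_names) + list(self.denovo_names)

    def export_mtx(self, dirpath) -> None:
        """Write every mask as a MatrixMarket file plus name lists."""
        import scipy.io as sio
        import scipy.sparse as sp
        from pathlib import Path
        d = Path(dirpath)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {"self_rna": self.self_rna, "neigh_rna": self.neigh_rna,
                  "self_rna_denovo": self.self_rna_nv,
                  "neigh_rna_denovo": self.neigh_rna_nv}
        for key in ("self_atac", "neigh_atac"):
            if getattr(self, key) is not None:
                arrays[key] = getattr(self, key)
                arrays[key + "_denovo"] = getattr(self, key + "_nv")
        for name, arr in arrays.items():
            sio.mmwrite(open(d / f"{name}.mtx", "wb"), sp.csr_matrix(arr),
                        field="integer")
        (d / "programs.txt").write_text("\n".join(self.program_names) + "\n")
        (d / "denovo.txt").write_text("\n".join(self.denovo_names) + "\n")
        (d / "genes.txt").write_text("\n".join(self.gene_names) + "\n")
        if self.peak_names:
            (d / "peaks.txt").write_text("\n".join(self.peak_names) + "\n")


# ---------------------------------------------------------------------------
# program file I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["program", "category", "gene", "gene_label", "component", "score"]


def load_programs(path) -> list[GeneProgram]:
    """Load gene programs from a delimited definition file.

    The file is tab-separated with header columns ``program, category,
    gene, gene_label, component, score`` — one row per (program, gene)
    membership, ``component`` being ``source`` or ``target``.  Duplicate
    program names spread over non-contiguous blocks are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        logger.warning("program file %s is empty", path)
        return []
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"program file missing columns: {missing}")
    programs: list[GeneProgram] = []
    for name, grp in df.groupby("program", sort=False):
        # a later block re-defining an earlier program is a duplicate
        idx = grp.index.to_numpy()
        if len(idx) and (np.diff(idx) != 1).any():
            raise ValueError(f"duplicate program name {name!r}")
        cats = grp["category"].unique()
        if len(cats) != 1:
            raise ValueError(f"program {name!r} has inconsistent categories")
        src, tgt, labels, scores = [], [], {}, {}
        for row in grp.itertuples():
            line = row.Index + 2  # header + 1-based
            gene = row.gene.strip()
            if not gene:
                raise ValueError(f"line {line}: empty gene symbol")
            if row.gene_label not in GENE_LABELS:
                raise ValueError(
                    f"line {line}: unknown gene label {row.gene_label!r}")
            if row.component == "source":
                src.append(gene)
            elif row.component == "target":
                tgt.append(gene)
            else:
                raise ValueError(
                    f"line {line}: component must be source|target, "
                    f"got {row.component!r}")
            labels[gene] = row.gene_label
            sc = getattr(row, "score", "")
            if sc not in ("", None) and not (isinstance(sc, float) and np.isnan(sc)):
                scores[gene] = float(sc)
        if cats[0] not in CATEGORIES:
            raise ValueError(f"unknown category {cats[0]!r} in program {name!r}")
        programs.append(GeneProgram(name=name, category=cats[0],
                                    source_genes=tuple(src),
                                    target_genes=tuple(tgt),
                                    gene_labels=labels, scores=scores))
    return programs


def save_programs(programs: list[GeneProgram], path) -> None:
    rows = []
    for p in programs:
        for comp, genes in (("source", p.source_genes), ("target", p.target_genes)):
            for g in genes:
                rows.append({
                    "program": p.name, "category": p.category, "gene": g,
                    "gene_label": p.gene_labels.get(
                        g, "target_gene" if comp == "target" else "ligand"),
                    "component": comp,
                    "score": p.scores.get(g, ""),
                })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------

def cap_target_genes(program: GeneProgram,
                     max_targets: int = 250) -> GeneProgram:
    """Keep at most ``max_targets`` target genes, ranked by score.

    Ties at the cap boundary are broken alphabetically by gene name.
    """
    if len(program.target_genes) <= max_targets:
        return program
    missing = [g for g in program.target_genes if g not in program.scores]
    if missing:
        raise ValueError(
            f"program {program.name!r} exceeds {max_targets} targets but "
            f"lacks regulatory scores for {missing[:3]}...")
    ranked = sorted(program.target_genes,
                    key=lambda g: (-program.scores[g], g))
    kept = tuple(sorted(ranked[:max_targets],
                        key=program.target_genes.index))
    return GeneProgram(name=program.name, category=program.category,
                       source_genes=program.source_genes, target_genes=kept,
                       gene_labels=program.gene_labels, scores=program.scores)


def _shared_fraction(a: set, b: set) -> float:
    """Fraction of the smaller set shared with the other."""
    if not a or not b:
        return 1.0 if (not a and not b) else 0.0
    return len(a & b) / min(len(a), len(b))


def merge_redundant(programs: list[GeneProgram],
                    overlap_threshold: float = 0.9) -> list[GeneProgram]:
    """Drop subset programs, then merge near-duplicate programs.

    A program that is a (source and target) subset of another is removed
    first.  Two programs are merged when both the source-gene and the
    target-gene shared fraction (relative to the smaller set) reach the
    threshold; merged programs take the union of genes and concatenated
    names.  The operation is idempotent.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    # remove strict subsets
    keep = []
    for i, p in enumerate(programs):
        ps, pt = set(p.source_genes), set(p.target_genes)
        subset = False
        for j, q in enumerate(programs):
            if i == j:
                continue
            qs, qt = set(q.source_genes), set(q.target_genes)
            if ps <= qs and pt <= qt and (ps, pt) != (qs, qt):
                subset = True
                break
            if (ps, pt) == (qs, qt) and j < i:
                subset = True  # exact duplicates: keep the first
                break
        if not subset:
            keep.append(p)
    # union-find merge to a fixpoint
    merged = list(keep)
    changed = True
    while changed:
        changed = False
        out: list[GeneProgram] = []
        used = [False] * len(merged)
        for i, p in enumerate(merged):
            if used[i]:
                continue
            acc = p
            for j in range(i + 1, len(merged)):
                if used[j]:
                    continue
                q = merged[j]
                if (_shared_fraction(set(acc.source_genes), set(q.source_genes))
                        >= overlap_threshold
                        and _shared_fraction(set(acc.target_genes),
                                             set(q.target_genes))
                        >= overlap_threshold):
                    labels = {**q.gene_labels, **acc.gene_labels}
                    scores = {**q.scores, **acc.scores}
                    acc = GeneProgram(
                        name=f"{acc.name}+{q.name}", category=acc.category,
                        source_genes=acc.source_genes + q.source_genes,
                        target_genes=acc.target_genes + q.target_genes,
                        gene_labels=labels, scores=scores)
                    used[j] = True
                    changed = True
            out.append(acc)
        merged = out
    return merged


# ---------------------------------------------------------------------------
# peak-gene linking
# ---------------------------------------------------------------------------

def link_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                        promoter_bp: int = 2000) -> PeakGeneLinks:
    """Link peaks to genes through gene-body overlap or promoters.

    ``peaks``: columns ``chrom, start, end, name`` (BED-style half-open,
    0-based).  ``genes``: columns ``gene, chrom, strand`` plus either
    ``start, end`` (gene body, half-open) or only ``tss``.  A peak links
    to a gene iff it overlaps the gene body or the window of
    ``promoter_bp`` bases upstream of the TSS (strand-aware); one peak
    may link to several genes.
    """
    peaks = peaks.copy()
    if (peaks["end"] <= peaks["start"]).any():
        bad = peaks[peaks["end"] <= peaks["start"]].iloc[0]
        raise ValueError(f"malformed interval for peak {bad['name']!r}: "
                         f"end <= start")
    genes = genes.copy()
    if "start" in genes.columns and "end" in genes.columns:
        has_body = True
        plus = genes["strand"] == "+"
        genes["tss"] = np.where(plus, genes["start"], genes["end"] - 1)
    else:
        has_body = False
        if "tss" not in genes.columns:
            raise ValueError("gene annotation needs start/end or tss")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strands must be '+' or '-'")

    links: dict[str, set[str]] = {}
    rules: dict[tuple[str, str], str] = {}
    for chrom, pk in peaks.groupby("chrom"):
        gn = genes[genes["chrom"] == chrom]
        if gn.empty:
            continue
        ps = pk["start"].to_numpy()[:, None]
        pe = pk["end"].to_numpy()[:, None]
        tss = gn["tss"].to_numpy()[None, :]
        plus = (gn["strand"] == "+").to_numpy()[None, :]
        # promoter window, half-open: + strand [tss-P, tss); - strand mirrored
        prom_lo = np.where(plus, tss - promoter_bp, tss + 1)
        prom_hi = np.where(plus, tss, tss + 1 + promoter_bp)
        prom = (ps < prom_hi) & (pe > prom_lo)
        if has_body:
            gs = gn["start"].to_numpy()[None, :]
            ge = gn["end"].to_numpy()[None, :]
            body = (ps < ge) & (pe > gs)
        else:
            body = np.zeros_like(prom)
        pnames = pk["name"].to_numpy()
        gnames = gn["gene"].to_numpy()
        for pi, gi in zip(*np.nonzero(body | prom)):
            p, g = pnames[pi], gnames[gi]
            links.setdefault(p, set()).add(g)
            # gene-body overlap takes precedence when both rules apply
            rules[(p, g)] = "gene_body" if body[pi, gi] else "promoter"
    return PeakGeneLinks(links=links, rules=rules)


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

def build_masks(programs: list[GeneProgram], gene_index: list[str],
                peak_links: PeakGeneLinks | None = None,
                peak_index: list[str] | None = None,
                n_denovo: int = 100,
                regularized_labels: tuple[str, ...] = ("target_gene",),
                ) -> ProgramMasks:
    """Construct binary decoder masks from program definitions.

    Prior RNA masks mark target genes in the self mask and source genes
    in the neighborhood mask; program genes absent from the panel are
    dropped (logged).  ATAC masks mark peaks linked to masked genes.
    De novo masks mark — identically in every de novo row — all panel
    genes absent from the corresponding component across all prior
    programs, plus their linked peaks.
    """
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    n_genes = len(gene_index)
    kept: list[GeneProgram] = []
    rows_self, rows_neigh, rows_rs, rows_rn = [], [], [], []
    for p in programs:
        src = [g for g in p.source_genes if g in gene_pos]
        tgt = [g for g in p.target_genes if g in gene_pos]
        n_dropped = (len(p.source_genes) - len(src)
                     + len(p.target_genes) - len(tgt))
        if n_dropped:
            logger.info("program %s: %d genes absent from panel dropped",
                        p.name, n_dropped)
        if not src and not tgt:
            logger.warning("program %s has no panel genes; dropped", p.name)
            continue
        s_row = np.zeros(n_genes, dtype=np.int8)
        n_row = np.zeros(n_genes, dtype=np.int8)
        rs_row = np.zeros(n_genes, dtype=np.int8)
        rn_row = np.zeros(n_genes, dtype=np.int8)
        for g in tgt:
            s_row[gene_pos[g]] = 1
            if p.gene_labels.get(g, "target_gene") in regularized_labels:
                rs_row[gene_pos[g]] = 1
        for g in src:
            n_row[gene_pos[g]] = 1
            if p.gene_labels.get(g, "ligand") in regularized_labels:
                rn_row[gene_pos[g]] = 1
        kept.append(p)
        rows_self.append(s_row)
        rows_neigh.append(n_row)
        rows_rs.append(rs_row)
        rows_rn.append(rn_row)
    if programs and not kept:
        raise ValueError("all programs were dropped: no genes on the panel")
    self_rna = np.array(rows_self, dtype=np.int8).reshape(len(kept), n_genes)
    neigh_rna = np.array(rows_neigh, dtype=np.int8).reshape(len(kept), n_genes)
    reg_self = np.array(rows_rs, dtype=np.int8).reshape(len(kept), n_genes)
    reg_neigh = np.array(rows_rn, dtype=np.int8).reshape(len(kept), n_genes)

    # de novo masks: complement of the prior component coverage
    cov_self = self_rna.any(axis=0) if len(kept) else np.zeros(n_genes, bool)
    cov_neigh = neigh_rna.any(axis=0) if len(kept) else np.zeros(n_genes, bool)
    nv_self_row = (~cov_self).astype(np.int8)
    nv_neigh_row = (~cov_neigh).astype(np.int8)
    self_nv = np.tile(nv_self_row, (n_denovo, 1))
    neigh_nv = np.tile(nv_neigh_row, (n_denovo, 1))

    masks = ProgramMasks(
        program_names=[p.name for p in kept],
        denovo_names=[f"de_novo_{i}" for i in range(n_denovo)],
        gene_names=list(gene_index),
        self_rna=self_rna, neigh_rna=neigh_rna,
        self_rna_nv=self_nv, neigh_rna_nv=neigh_nv,
        reg_self=reg_self, reg_neigh=reg_neigh)

    if peak_links is not None and peak_index is not None:
        peak_pos = {p: i for i, p in enumerate(peak_index)}
        n_peaks = len(peak_index)

        def peaks_row(gene_mask_row: np.ndarray) -> np.ndarray:
            genes = {gene_index[i] for i in np.flatnonzero(gene_mask_row)}
            row = np.zeros(n_peaks, dtype=np.int8)
            for pk in peak_links.peaks_for_genes(genes):
                if pk in peak_pos:
                    row[peak_pos[pk]] = 1
            return row

        masks.peak_names = list(peak_index)
        masks.self_atac = np.array(
            [peaks_row(r) for r in self_rna], dtype=np.int8
        ).reshape(len(kept), n_peaks)
        masks.neigh_atac = np.array(
            [peaks_row(r) for r in neigh_rna], dtype=np.int8
        ).reshape(len(kept), n_peaks)
        masks.self_atac_nv = np.tile(peaks_row(nv_self_row), (n_denovo, 1))
        masks.neigh_atac_nv = np.tile(peaks_row(nv_neigh_row), (n_denovo, 1))
    return masks
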