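# nichegp

Interpretable niche identification for spatial omics data.

Cells in tissue organize into *niches* — communities of spatially
colocalized cells with coordinated function, shaped by ligand–receptor,
metabolite–sensor and transcriptional interactions between neighbors.
`nichegp` learns a per-cell embedding in which **every latent dimension
is a gene program**: a named set of genes split into a *neighborhood
component* (interaction sources such as ligands, expressed by
neighboring cells) and a *self component* (receptors, sensors and
downstream targets, expressed by the cell itself). Clustering the
embedding yields niches; the same embedding directly quantifies which
signaling programs characterize each niche and how strongly neighboring
cells communicate through them.

It is intended for computational biologists working with
cell-resolution or spot-resolution spatial transcriptomics (optionally
paired with chromatin accessibility), who need niche assignments that
come with a mechanistic, program-level explanation rather than an
opaque latent space.

## Model

For observations with raw counts `x_i`, spatial coordinates `s_i` and
categorical covariates `c_i` (sample, donor, field of view), a
sample-wise symmetric k-NN graph defines neighborhoods. Each node
carries two reconstruction targets: its own counts `x_i` and the
GCN-normalized neighborhood aggregate

    x'_i = Σ_{j ∈ N(i) ∪ {i}}  x_j / sqrt(d_j d_i).

A conditional variational graph autoencoder embeds each cell as
`z_i ∈ R^{N_gp}` (one dimension per program, prior and de novo). The
encoder is a fully connected layer followed by two parallel
message-passing layers (dynamic graph attention; graph convolution in
light mode) producing the posterior mean and log-σ. The decoder has
three parts:

- a **graph decoder**: `Ã_ij = cos(z_i, z_j)`, the logit for edge
  reconstruction, restricted to node pairs with identical *pure*
  covariates (covariates constant within graph components);
- two **masked omics decoders** per modality (self and neighborhood):
  single linear layers whose weights are element-wise masked by binary
  program–gene matrices, followed by a softmax across features scaled
  by the observed library size, giving the mean of a negative binomial
  with feature-specific inverse dispersion θ_f;
- **covariate embeddings** injected into the omics decoders only, so
  embeddings stay batch-free.

The loss combines weighted edge cross-entropy (with a positive-pair
weight ω_pos = |E⁻|/|E⁺|), self and neighborhood NB likelihoods, the
closed-form KL to the standard-normal prior, and optional selective L1
penalties. Programs whose decoder contribution falls below a fraction
τ of the strongest program (under both a sum-based and a nonzero-mean
aggregation of |weights|, scaled by an EMA of |embeddings|) are pruned
after a warm-up. Downstream, embeddings are sign-corrected into
*program activities*, tested between groups with log Bayes factors
(|log K| ≥ 2.3 ⇔ posterior odds ≈ 10), and turned into per-cell
source/target *communication potentials* whose products over neighbor
pairs give directed *communication strengths*. Query datasets map onto
a trained reference by fine-tuning only the covariate embeddings.

No deep-learning framework is required: the model runs on NumPy through
a small reverse-mode autodiff engine included in the package, with
gradients verified against finite differences in the test suite.

## Worked example

The bundled generator simulates the package's reference tissue: 5,000
cells in eight rectangular niches with distinct cell-type compositions,
500 genes, NB counts, and ten ground-truth programs additively injected
into niches (target genes raised inside the niche, source genes raised
in cells adjacent to it), plus ten decoy programs that receive no
injection and one duplicated program:

```python
from nichegp.benchmark import (run_recovery_benchmark,
                               run_reference_mapping_benchmark)

run = run_recovery_benchmark(seed=0)
print(run.nmi, run.ari)                  # 0.986 0.990
print(run.injected_survived)             # 10   (all injected programs active)
print(run.decoys_survived)               # 0    (all decoys pruned)
print(run.duplicate_copies_active)       # 1    (redundant copy pruned)
print(run.f1_per_niche)                  # {0: 1.0, 1: 1.0, ..., 7: 1.0}

mapping = run_reference_mapping_benchmark(run, seed=0)
print(mapping["label_transfer_accuracy"])  # 0.9968
print(mapping["weights_frozen"])           # True
```

Reading: Leiden clustering of the learned embeddings recovers the eight
ground-truth niches almost exactly (NMI 0.986, ARI 0.990); pruning
keeps every injected program while discarding all decoys and one copy
of the duplicated pair; per-niche one-vs-rest log-Bayes-factor tests
flag exactly the injected programs (F1 = 1 in every niche); and a
held-out replicate sample, mapped with all weights frozen except
covariate embeddings, receives 99.7 % correct niche labels by k-NN
transfer.

The same pipeline is scriptable from the shell:

```bash
nichegp simulate --out run/sim --seed 7 --n-cells 5000 --n-genes 500
nichegp train    --bundle run/sim/bundle --out run/train
nichegp analyze  --bundle run/sim/bundle --checkpoint run/train/model.npz \
                 --out run/analysis
```

`analyze` writes activities, per-program gene importances, niche
labels, a dendrogram linkage, per-niche log Bayes factors and
niche-level communication strength matrices as TSV tables.

### Program definition files

Prior programs are supplied as a tab-separated file with one row per
(program, gene):

```text
program  category         gene  gene_label   component  score
SPP1     ligand-receptor  SPP1  ligand       source
SPP1     ligand-receptor  ITGAV receptor     target
SPP1     ligand-receptor  FN1   target_gene  target     0.82
```

Categories: `ligand-receptor`, `metabolite-sensor`,
`combined-interaction`, `transcriptional-regulation`. For multimodal
runs, supply peaks as BED and gene annotations as a table
(`gene, chrom, start, end, strand`); peaks link to genes through
gene-body overlap or promoters (2,000 bp upstream of the TSS).

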