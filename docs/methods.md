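# Methods

This note records the model as implemented, the defaults and why they
are set where they are, what the synthetic generator does and does not
emulate, and the numerical and design choices a maintainer would want
to know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

**Graph.** Each sample contributes a symmetric k-NN subgraph on
Euclidean distances (default k = 4); the directed relation is
symmetrized by union and degrees are recomputed afterwards, counting a
self-loop (`d_i = 1 + #neighbors`). Distance ties at rank k are broken
by ascending observation index via a stable argsort on exact distances,
so graphs are identical across platforms. Self-loops are not stored in
the adjacency — they enter only through the degrees and the
aggregation — because the graph decoder reconstructs the off-diagonal
adjacency. A fixed-radius strategy is available behind a flag.

**Node labels.** The reconstruction target of node i concatenates its
raw counts with the GCN-normalized neighborhood aggregate
`x'_i = Σ_{j∈N(i)∪{i}} x_j / sqrt(d_j d_i)`, per modality. The sparse
implementation is tested to 1e-10 against the dense
`D^{-1/2}(A+I)D^{-1/2} X` product.

**Encoder.** Raw counts pass through `log(1+x)` (config-switchable to
raw), a fully connected layer of width N_gp, layer normalization and
ReLU, then two parallel message-passing layers produce μ and log σ
(clamped to [−5, 5]). The default message passing is dynamic graph
attention with 4 heads; the source/target linear transforms are shared
across heads and each head contributes only its attention vector, with
head outputs averaged. Because all heads share the message transform,
averaging the attention coefficients before aggregation is exactly
equivalent to averaging head outputs, and keeps the latent width at
N_gp. Light mode replaces attention with a graph convolution. The
first-layer nonlinearity/normalization and the head combination are
implementation choices exposed in `ModelConfig`, not constraints of the
method.

**Covariates.** Each categorical covariate has its own embedding matrix
(default 10 dimensions per covariate); embeddings are concatenated and
injected into the omics decoders only, never the encoder, so latent
embeddings are covariate-free by construction. Covariates tied to graph
components (sample, donor) are *pure*; others (field of view) are
*mixed*. Edge reconstruction and negative sampling are restricted to
pairs with identical pure covariates.

**Decoders.** Edge logits are cosine similarities of embeddings (a
zero-norm embedding yields similarity 0 through an ε-guarded norm).
Omics decoders are single linear layers; weights are multiplied by the
binary program masks inside the forward pass, so masked positions have
exactly zero weight and exactly zero gradient at every step (asserted
after training in the tests). A softmax across features times the
empirical library size — computed per component: total self counts,
total aggregated neighborhood counts — gives NB means; inverse
dispersions are per-feature, parameterized as unconstrained log θ
initialized at 0. Observations with zero library size for a component
are excluded from that component's loss.

**Loss.** Edge binary cross-entropy with positive weight
ω_pos = |E⁻|/|E⁺| (≤ 1, since candidate negatives that differ in pure
covariates are discarded without resampling); NB negative
log-likelihood for self and neighborhood components per modality;
closed-form KL with a node-level mean plus an edge-level endpoint term
weighted 1/(4·N_E_bat); optional selective L1 on prior-program decoder
weights of configured gene categories (default: target genes) and on
all de novo weights. The λ-weighted total is assembled additively;
zeroing a λ removes exactly that term.

**Training.** Two loaders per step: a node loader (default 256 nodes)
for omics reconstruction and an edge loader (default 128 positive pairs
plus as many uniformly sampled candidate negatives) for adjacency, each
with 4 sampled neighbors per node for message passing, one joint
backward pass, AdamW at lr 2e-3. Default schedule: 50 epochs with
pruning warm-up of 40 epochs. The batch sizes, learning rate and
schedule were chosen on the synthetic benchmark as the smallest budget
at which decoder weights of all injected programs converge past the
pruning threshold; they are package defaults, not tuned per dataset.
λ_edge defaults to 500 (the edge task is per-pair and much smaller in
magnitude than the summed NB terms), λ_rna = λ_atac = 1, L1 weights
default to 0. Enabling L1 at substantial weight shrinks prior decoder
weights and can starve weak programs; it is implemented and tested but
off by default.

**Pruning.** An EMA (decay 0.99) of batch-mean |μ| scales the per-program
sum of absolute gene-expression decoder weights (self + neighborhood)
under two aggregations — raw sum and mean over mask-member genes. After
warm-up a program is deactivated only if it falls below τ·δ_max
(τ = 0.05) under *both* aggregations, with δ_max taken over currently
active programs, separately for the prior and de novo pools. Pruning is
realized by zeroing the program's posterior features (reversible flags;
decoder columns are untouched so the state can be re-evaluated during
query training). A deactivated program's EMA decays toward zero, which
makes pruning effectively self-reinforcing.

## Downstream analysis

*Activities* flip the sign of a latent column when the summed
neighborhood-component (source-gene) decoder weight is negative, with
the self component as fallback for programs without source genes, and
the sum over all member genes for de novo programs. *Importances*
normalize |weight| over the union of self and neighborhood members per
program and modality (sum = 1; zero-weight members get 0).

*Differential testing* estimates p(H0) = P(Z_u^(a) > Z_u^(b)) by Monte
Carlo over uniformly drawn cross-group pairs of reparameterized
posterior samples (default 10,000 pairs), clips to
[1/n_mc, 1 − 1/n_mc], and reports log K = log p/(1−p); |log K| ≥ 2.3
(posterior odds ≈ 10) flags a program. The pair-sampling estimator is a
documented stand-in for the unspecified estimator of the underlying
Bayesian scheme.

*Characterizing programs*: per niche, one-vs-rest tests select enriched
programs; among them, rank by the importance-weighted mean Pearson
correlation (on raw counts) between the activity column and member-gene
expression, ties broken by |log K|; keep two per niche.

*Communication*: per program, gene expression is min–max scaled per
gene (constant genes → 0), multiplied by the gene's decoder weight,
averaged within the self component (→ target potential) and the
neighborhood component (→ source potential), multiplied by the cell's
activity, clamped at 0. Directed strengths are source_i × target_j over
graph-neighbor pairs (a per-program k-NN override is available;
defaults to the training graph), aggregated per ordered niche pair and
min–max normalized to [0, 1] per program at the reported aggregation
level.

*Niches*: Leiden on a k-NN graph (k = 15) of the embeddings at a given
resolution, seeded; `cluster_to_n_niches` bisects the resolution to hit
a target niche count, mirroring common practice of matching cluster
counts when comparing to a reference. The dendrogram is Ward linkage
over per-niche mean embeddings.

*Reference mapping*: query fine-tuning updates only covariate embedding
matrices; rows for unseen categories are initialized to the mean of the
covariate's existing rows (a neutral starting point). Dispersions are
frozen with all other weights (the alternative — releasing θ — is a
one-line change but breaks the bit-exact freezing guarantee the tests
assert). Pruning EMAs can continue updating during query training when
a pruning state is passed. Label transfer is k-NN majority vote on
embeddings, probability = vote fraction, ties broken by distance then
reference index.

## Synthetic data generator

The generator is parametric and self-contained: it places cells
uniformly on the unit square, assigns niches by a rectangular grid
partition (default 2 × 4 = 8 niches), draws cell types from
niche-specific composition vectors (one dominant type at 60 % per
niche, 5 types), and draws counts from NB distributions (inverse
dispersion θ = 3) whose means combine lognormal per-gene baselines,
cell-type marker folds (20 marker genes per type at 6×), and additive
injected program effects (+4 on the NB mean; 3 source + 6 target genes
per program; defaults 10 injected and 10 decoy programs on a
10,000-cell, ~1,100-gene tissue; scaled-down instances override
n_cells/n_genes). Source-gene effects apply to cells adjacent to the
target niche on the same k-NN construction the model trains with,
deliberately creating exactly the neighborhood signal the neighborhood
decoder is built to detect. Structural parameters (baselines, program
gene sets) derive from `seed`; `replicate_seed` redraws only cell
positions, types and counts, which is what makes a held-out
"biological replicate" share its generative model with the reference.

A spot-level version bins cells into circular bins on a
hexagonal-packing grid of a given diameter (cells outside every circle
are dropped and logged; spot counts are member sums, spot labels
majority votes). A multiome extension gives each gene one gene-body
and optionally several promoter peaks with NB counts proportional to
the gene's realized mean, and emits the BED/annotation files from which
the peak–gene linking rule re-derives the generating links exactly.

What the generator does **not** emulate: real segmentation noise,
spatially varying density, continuous gradients between niches,
cell-type-specific dispersion, or correlated gene modules beyond the
injected programs. Passing recovery tests therefore demonstrates that
the estimator recovers the signal class it models, under ideal
conditions — not performance on real tissue.

## Numerical choices

- Float64 throughout; gradients via the package's tape-based autodiff,
  checked against central finite differences (tolerance 1e-5).
- log σ clamped to [−5, 5]; ε = 1e-12 guards logs and norms.
- NB NLL uses the exact log-pmf with `gammaln` (digamma gradients) and
  matches `scipy.stats.nbinom` to 1e-8 and the Poisson limit at
  θ = 1e8 to 1e-4.
- k-NN ties: stable argsort on exact distances → index-order
  tie-break; duplicated coordinates allowed.
- Program merging uses the fraction of the smaller set for both source
  and target genes (threshold 0.9), after removing strict subsets;
  applied iteratively to a fixpoint, which makes it idempotent.
- Capping large programs keeps the top-250 targets by regulatory
  score, ties at the boundary broken alphabetically.
- De novo masks are identical across de novo programs at
  initialization (the panel complement of prior components, per
  component); differentiation is left to L1 sparsity.
- Negative sampling is uniform over non-edges with replacement within
  a batch, no cross-batch bookkeeping.
- The KL edge term includes the endpoints of all sampled candidate
  negative pairs (they are encoded in the same forward pass), with
  N_E_bat the number of positive pairs.

## Benchmark configuration

The acceptance benchmark trains on a 5,000-cell, 500-gene, 8-niche
tissue with 10 injected programs, 10 decoys and one duplicated program,
three model seeds on a fixed simulated tissue, with the package default
schedule; problem sizes were chosen so a full three-seed run completes
in roughly ten minutes on one CPU core while keeping every niche above
500 cells. Enrichment F1 per niche compares prior programs with
log K ≥ 2.3 (one-vs-rest) against that niche's injected programs; the
baseline draws count-matched random program sets (200 draws). In one of
three seeds both copies of the duplicated program can survive pruning;
the majority of seeds prune one copy, and the reported median is 1.

## Known limitations

- No multi-GPU, no mixed precision, no minibatch-free full-graph
  training path; runtimes target datasets up to tens of thousands of
  cells on CPU.
- Query mapping requires an identical feature panel; no panel
  harmonization or imputation.
- The attention encoder shares source/target transforms across heads
  (see above); a fully per-head parameterization would quadruple
  message-passing cost on CPU.
- Zero-inflated or Poisson likelihoods are not implemented (the
  Poisson limit exists only as a test).
- `identify_niches` sub-niche discovery is re-clustering within a
  niche; no stability selection across resolutions.
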