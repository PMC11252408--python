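# Methods

This note documents the models, defaults and numerical choices behind
trajblend, what the synthetic data generator does and does not emulate,
and the known limitations.

## Data model and preprocessing

A profile is a cells × genes integer count matrix with one cell-type
label per cell; bulk samples are per-gene nonnegative vectors with an
explicit normalization-state flag. Counts are validated (nonnegative,
integral, unique IDs) before any computation.

Quality control removes cells with total counts below 1000 or a
mitochondrial count fraction above 0.2; both bounds are strict, so a cell
exactly at a threshold is kept. Mitochondrial genes are matched by a
case-insensitive ID prefix (default `MT-`). Per-cell normalization
divides by the cell total, scales to `target_sum` (default 1e4, the
counts-per-ten-thousand convention that keeps log values well
conditioned) and
applies log1p into a `lognorm` layer; raw counts are retained because the
deconvolution stage trains on raw counts while the generative model
trains on the normalized layer. Bulk samples are normalized by
median-of-ratios size factors (geometric mean per gene across samples,
per-sample ratios, median over genes positive in all samples) and log1p.

PCA (default 50 components) runs on the centered, unit-scaled lognorm
layer. The sign of each component is fixed by forcing its
largest-magnitude loading positive, making embeddings deterministic.
Highly-variable-gene selection is deliberately not applied: the full gene
set flows into every model.

Gene universes of bulk and single-cell data are reconciled by exact
string intersection in reference order; dropped genes are counted and
reported. This is a package choice — there is no canonical rule for the
reconciliation.

## Fraction autoencoder

Encoder and decoder are two-hidden-layer perceptrons (64 units, ReLU)
implemented in NumPy with Adam (lr 1e-3, 400 epochs, batch 32). Training
data are 200 pseudo-bulks: Dirichlet(1,…,1) proportions over the M
labels, 500 cells sampled with replacement per bulk, counts summed per
gene. The ground truth is the *realized* cell proportion of each mixture,
not the Dirichlet draw. Bulk vectors are internally library-size scaled
and log1p-compressed; this feature map makes the estimate invariant to
sequencing depth and to gene order (genes are aligned by ID).

The joint loss adds a fraction term and a reconstruction term with unit
weights; both are tracked as mean absolute error. Two numerical choices
matter:

- The encoder head is a softmax, but the fraction term's gradient is
  taken directly on the logits in cross-entropy form `(T − F)`. A pure
  sign-gradient (MAE) through a softmax saturates: once a class's
  probability reaches zero its logit receives no gradient and the class
  is permanently dead, which collapses training on many seeds. The
  cross-entropy form has its unique minimum at `T = F` and never
  saturates; MAE remains the recorded evaluation metric.
- The adaptive stage on a real bulk fine-tunes encoder and decoder on the
  reconstruction term only, for up to 50 steps at one fifth of the
  pretraining learning rate with plateau early-stopping, and restores the
  pretrained weights afterwards (adaptation is sample-local). At the full
  learning rate a single sample overfits the decoder and corrupts the
  fraction estimate; the reduced rate preserves recovery of both interior
  mixtures and near-pure corner compositions.

On the standard synthetic conditions (5 types, 2000 cells, 300 genes)
held-out fraction MAE converges to ~0.01–0.02 and a pure single-type bulk
is recovered within 0.1 in sup norm.

## Fraction-constrained β-VAE

Architecture: one ReLU hidden layer of 64 units on each side; latent
dimension `2M + 8` (never below M); β = 4 by default (β > 1 encourages a
disentangled latent code). Per-cell loss is
`0.5‖x − x̂‖² + β·KL(q(z|x)‖N(0,I)) + λ_V Σ|V − onehot(label)|` with the
reparameterisation trick, Adam (lr 1e-3, 300 epochs, batch 128). The
fraction head V is the softmax of the first M latent means; λ_V defaults
to 50, sized so the head's gradient is commensurate with a
reconstruction term summed over ~300 genes. As in the deconvolution
stage the head's training gradient uses the cross-entropy form; the MAE
is what the history records. Label accuracy of V's argmax is ~92–94% on
the default fixture: discrete types are near-perfect, while bridge
(mixture) cells settle on their parents' mixture weights rather than the
bridge vertex — the expected optimum for a population that is literally
a blend of two programs.

The generative factor table holds, per type, the mean posterior latent W
and its per-dimension empirical spread. Generation decodes
`z ~ N(W_type, diag(spread))`: for discrete types the spread is small and
labels stay crisp, while a transitional type whose latent code varies
along a mixing continuum is regenerated as a continuum — collapsing it to
a point mass (decoding W alone) would prevent any overlap community from
forming downstream. Per-type cell allocation follows the bulk fraction
state by largest-remainder rounding; the target type's allocation is
overridden to `scale ×` its reference abundance (default scale 2, the
setting the hyperparameter study found optimal together with 64 hidden
units).

Counts are emitted from a gamma-Poisson (negative binomial) around expm1
of the decoded lognorm mean, with per-gene overdispersion estimated from
the reference by method-of-moments pooled within cell types. Emitting
the decoded mean itself would place every generated cell at the
noise-free centroid of its type; such centroids are nearer to every real
cell than real cells are to each other, become hubs of the kNN graph and
short-circuit pseudotime. Matching the reference noise footprint puts
generated cells on the same manifold as real ones.

Generated profiles are denoised by Leiden clustering (resolution 1.0) on
their own PCA/kNN graph; clusters with fewer than 25 members are
discarded as generator artefacts (strict: a 25-cell cluster is kept).

## Overlapping community detection

The kNN graph (K = 15, union-symmetrised, no self-loops) feeds a
two-layer GCN `F = ReLU(Â ReLU(BN(Â X W₁)) W₂)` with
`Â = D̂^{-1/2}(A + I)D̂^{-1/2}`, batch normalization after the first
convolution, and L2 (1e-2) on both weight matrices; hidden width 128.
Node features X are the one-hot provisional labels (an identity matrix
for unlabelled benchmark graphs). The loss is the balanced
Bernoulli–Poisson negative log-likelihood: the mean edge term over a
uniform sample of edges plus the mean non-edge term over an equal sample
of non-edges (2000 each per step), which weights the two expectations
equally on sparse graphs. Edge inner products are clamped at 1e-10 to
keep the edge term finite. Training uses Adam (lr 5e-3, 500 epochs).

The objective is non-convex and single runs land in merged-community
optima on roughly half of the seeds, so `train_nocd` performs five
independently initialised runs and keeps the one with the lowest *exact*
(fully enumerated) likelihood — model selection touches only the
training objective. On the planted overlapping benchmark (300 nodes,
three communities, ten dual-membership nodes, p_in = 0.2, p_out = 0.01)
the selected run recovers memberships with overlapping-F1 ≥ 0.99 across
seeds.

Memberships binarise each affinity row divided by its maximum at
threshold 0.5 (both package choices; configurable). The number of
communities defaults to the number of provisional labels. Each community
is labelled by the majority provisional label of its members,
lexicographically smallest label on ties. Selected cells are target-type
cells belonging to ≥ 2 communities. When no community carries the target
majority — a transitional population can be wholly absorbed as dual
members of its two parent communities, which is itself the overlap state
of interest — the pipeline proceeds with the dual-membership target
cells and a warning; the strict error remains the library default.

Interpolation row-concatenates the selected cells into the original
profile, keeping their generated expression as-is, with a per-cell
`interpolated` flag and the target label.

## Evaluation suite

- **Marker ranking**: one-vs-rest Wilcoxon rank-sum on the lognorm layer
  (tie-corrected), top 200 genes per type, ties broken by gene ID;
  groups under 2 cells are excluded with a warning.
- **Marker correlation**: per type, Pearson r between reference and
  generated type-mean lognorm over the reference's top-200 markers.
- **Marker cosine**: `|A ∩ B| / √(|A||B|)` between the two top-200 sets.
- **Transition confidence**: for cluster pair (i, j), observed
  inter-cluster edge count divided by its expectation under uniformly
  random edge placement given cluster sizes (`m·nᵢnⱼ/C(n,2)`), clipped to
  [0, 1]; the value is assigned to the direction i → j when cluster i's
  mean pseudotime is smaller. The magnitude is symmetric by construction
  and zero exactly when no inter-cluster edge exists.
- **Pseudotime**: desk-scale pseudotime is single-source shortest-path
  distance on the kNN graph, min-max scaled to [0, 1]; edges are
  weighted by their Euclidean embedding length when available (hop
  counts quantise to a few levels on dense kNN graphs). The root is the
  root-type cell farthest in the embedding from the centroid of all
  other types — the tip of the progenitor cluster — so pseudotime grows
  outward through the progenitor toward transitional states. Cells
  disconnected from the root get pseudotime 1 with a warning. Variance
  over the target population is the population (not sample) variance.
  The evaluation report records which engine produced pseudotime;
  accession-scale studies should substitute a full trajectory method.

## Synthetic study conditions

The generator emulates: M well-separated discrete types (disjoint marker
blocks at 8× fold over a shared gamma baseline), negative-binomial counts
(gamma-Poisson, shape 2.0 — moderate overdispersion; per-cell totals
comfortably above the QC floor), an optional bridge population whose mean
program interpolates linearly between two parents along an even mixing
grid, pseudo-bulks as realized mixtures of sampled cells, and omission by
uniform removal of a target type. Defaults: 5 types × 370 cells + 150
bridge cells, 300 genes, 20 markers/type, seed-reproducible bit for bit.

It does **not** emulate batch effects, doublets, ambient RNA,
library-size gradients within types, or correlated gene modules beyond
the marker blocks. Passing tests therefore demonstrate that the
algorithms behave as specified under clean, well-separated populations
with known truth — not that real tissues with subtler substructure will
yield equally sharp recovery. On real data the deconvolution error and
overlap selection depend on how distinct the target population's program
is, and the reference profile used for training must itself contain the
target type (a more comprehensive atlas can stand in when the profile
under study lacks it; the pipeline trains on `reference` and interpolates
into `profile` for exactly this reason).

## Pipeline

Seven stages (preprocess, fractions, generate, denoise, overlap,
interpolate, evaluate) run from one YAML config; each stage's seed is
derived from the config seed by stage index, outputs are cached on disk
keyed by the input hash, and the manifest records the hash chain. Reruns
are bit-reproducible; a resumed run recomputes only stages whose inputs
changed.

## Problem sizes

The shipped study conditions (2000 cells × 300 genes, 200 training
bulks, 300-node benchmark graphs) are sized so a complete test suite and
a full acceptance run each finish in minutes on one CPU; every model and
metric scales to larger profiles through the same interfaces.

## Known limitations

- The Gaussian reconstruction on lognorm values is a convenience
  likelihood; count likelihoods (NB/ZINB decoders) would be more faithful
  at low depth.
- Transition-confidence direction relies on mean pseudotime per cluster,
  which can be ambiguous for populations embedded at a cluster boundary;
  the symmetric magnitudes are always reported alongside.
- The accession-scale experiments (GEO/HCA datasets, full-size training,
  external trajectory inference) are documented targets, not part of the
  desk-scale suite; reproducing them requires downloading the datasets
  and running a full trajectory-inference engine.
- Community count C must be meaningful for the generated mixture; a C
  far above the number of real populations fragments communities and
  inflates spurious overlaps.
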