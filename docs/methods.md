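# Methods

## Problem and model

Given an annotated scRNA-seq reference (genes × cells raw counts with per-cell
type labels) and an SRT sample (spots × genes raw counts with 2-D spot
coordinates), the package estimates each spot's cell-type proportion vector.
Supervision comes entirely from pseudo-spots sampled from the reference; the
SRT spots participate in training only through unsupervised terms
(reconstruction, domain adversarial), so held-out SRT labels are never seen.

### Pseudo-spot sampling

For each pseudo-spot: `nc = Poisson(λ) + 1` member cells (λ = 5 by default,
matching typical multi-cell spot occupancies of 1–16 cells), `nk ~ U{1, ...,
min(NK, CT)}` member types (NK = 4). The `nk` types are drawn uniformly
*without* replacement from the type vocabulary — uniformly rather than from the
reference's empirical composition, because the tissue's true composition is
unknown and the reference's is platform-biased. Each member cell picks one of
the `nk` types uniformly, then a cell uniformly *with* replacement within that
type (types can be small). Expression is the raw-count sum; the label is the
realized type-frequency vector, so a chosen type can realize zero cells.
A mean-matched normal sampler (`round(N(m, 1))`, floored at 1) is available via
`size_sampler="normal"` for comparison; Poisson/uniform is the default.

### Preprocessing

Both datasets are restricted to highly variable genes shared between the two
platforms: HVGs are computed per dataset (scanpy's mean–dispersion binning,
20 bins, mean in [0.0125, 3], normalized dispersion ≥ 0.5) on the gene
intersection, and the HVG intersection is used, falling back to the union and
then to all shared genes when fewer than `min_genes` (default 100) survive.
Each dataset — the pseudo-spot batch and the SRT sample separately — is then
library-size normalized to its median library size, log1p-transformed, and
gene-wise z-scored on its own statistics (population s.d.; columns with zero
range map to zero). Per-dataset standardization removes most of a gene-wise
multiplicative platform shift (after log1p such a shift is an additive gene
offset); the residual shift is left to the adversarial domain loss.

### Graphs

All graphs are mutual k-nearest-neighbor graphs (k = 6): an edge exists only
if each endpoint is in the other's k nearest neighbors, giving a symmetric
adjacency with zero diagonal. Distance ties break by ascending node index, so
construction is deterministic. The SRT sample yields a spatial graph
(Euclidean distance on coordinates) and an expression graph (cosine distance
on preprocessed profiles, zero vectors defined to have similarity 0); the
pseudo-spot batch is shuffled once per run (seeded) and chunked into
`n_graphs` disjoint expression graphs of `graph_size` nodes (defaults 250 ×
200) with edges built only inside each chunk. Isolated nodes are allowed; the
encoder adds self-loops so their features still propagate.

### Encoder and heads

Two graph-convolution layers with symmetric normalization
`D^{-1/2}(A + I)D^{-1/2}` and ELU activations produce a shared hidden state
(width 512). Three linear heads emit per-component means `μ_ik`, log-variances
(clamped to [-10, 10]; `σ = exp(logvar/2)`), and responsibility logits
(softmax over K = 8 components). The embedding is the responsibility-weighted
mixture `z_i = Σ_k r_ik (μ_ik + σ_ik ∘ ε_k)` with fresh `ε_k ~ N(0, I)` during
training and `z_i = Σ_k r_ik μ_ik` at inference, so inference is
deterministic. The soft mixture keeps the draw differentiable; a
straight-through hard-assignment mode (forward argmax, soft gradient) is
available behind `hard_assignment`. The proportion head is a 512→256→CT MLP
with ELU and softmax; the domain discriminator is a 512→256→1 MLP with sigmoid
behind a gradient-reversal layer (identity forward, gradient × −α backward,
α = 1 with no schedule).

### Losses and schedule

Pseudo-spot graphs: `L = L_recon + 1000·L_MSE + L_CE + 1000·L_sample +
10·L_entropy`; SRT graphs: `L = L_recon + L_CE`. `L_recon` is the summed
binary cross-entropy of `sigmoid(z_i·z_j)` against the adjacency over ordered
pairs i ≠ j (the diagonal is excluded by default — self inner products are
uninformative and would dominate; `include_diagonal` restores the literal
all-pairs sum). `L_sample` is computed as the squared distance between mean
predicted and mean true proportion vectors, the unweighted per-spot mean
(not cell-count-weighted). `L_entropy` adds the mean per-spot Shannon entropy
(natural log) and the entropy of the batch-mean prediction; both terms enter
with sign +1 by default. The second term slightly tensions with the sample
loss (it rewards a concentrated batch mean); an `entropy_sign=-1` mode that
instead rewards a spread batch mean is provided and exposed to ablation
configs. Probabilities are clamped to [1e-7, 1−1e-7] before logs (entropies
clamp only the lower bound so exact one-hot rows score exactly zero).

Training is Adam (lr 0.001, framework-default betas) for 20 epochs; each epoch
takes one optimizer step per pseudo-spot graph in fixed order (a seeded
shuffle per epoch is available), then one step on the SRT expression graph and
one on the SRT spatial graph. No validation split or early stopping is used.
A non-finite loss aborts training naming the offending component. At
inference the deterministic forward pass runs on both SRT graphs and the two
proportion matrices are averaged elementwise, which stays on the simplex by
convexity.

## Numerical choices

* The model runs on a small in-package reverse-mode autodiff engine over
  numpy (gradient-checked against central finite differences to ~1e-8);
  arithmetic is float32 for throughput on one CPU thread, float64 available
  via `ModelConfig.dtype`.
* Weights are Glorot-uniform; the log-variance head bias starts at −4
  (initial σ ≈ 0.14) because unit-scale latent noise at initialization is as
  large as the mixture means and swamps the supervised signal in the first
  epochs.
* Gradients are clipped to 3× an exponential moving average (decay 0.9) of
  the global gradient norm (`TrainConfig.clip_factor`, disable with `None`).
  The summed reconstruction term scales with n² and occasionally spikes late
  in training (observed norms 20–30k against a healthy 3–5k median), which
  can undo several epochs of supervised progress; clipping against the
  running norm is scale-free and leaves ordinary steps untouched.
* Adjacencies are stored dense; intended graph sizes are ≤ a few thousand
  nodes (the reconstruction loss is O(n²) regardless).
* One user-facing seed derives all stage seeds (sampling, partitioning,
  initialization, training noise, K-means) through a CRC-keyed splitter, so a
  run is bit-for-bit reproducible on one CPU thread and individual stages can
  be re-run in isolation.

## Synthetic data generator

`gmdecon.fixtures` generates the study used by the tests and the acceptance
script. The reference draws negative-binomial counts (var = μ + 0.3·μ²;
negative-binomial rather than Poisson so overdispersion and platform shift
remain separable) with baseline mean 0.5 and 8 disjoint marker genes per type
at 8× fold. The tissue lays spots on a rectangular lattice split into
contiguous horizontal band domains (mimicking cortical layers); each spot
draws `Poisson(5) + 1` cells from its domain's mixture (default: one dominant
type at 0.7 per domain, remainder uniform), sums resampled reference cells'
raw counts, and multiplies each gene by a shared log-normal platform factor
(σ = 0.3). This reproduces the qualitative structure the losses target —
dominant per-spot types (long-tailed proportions) and a multiplicative
platform shift — but not real platform chemistry (no dropout curves, no
segmentation error, no spot-size heterogeneity beyond the Poisson count), so
passing recovery tests demonstrates the machinery works, not field accuracy.

The standard study is 1000 reference cells × 200 genes × 5 types and 20 × 20
spots in 4 domains. Tests and the acceptance script train at a scaled-down
schedule — 4000 pseudo-spots in 40 graphs of 100 nodes, 10 epochs — chosen so
the whole study (including ablations and repeat seeds) runs in minutes on one
CPU; the package default remains the full 50 000 / 250 × 200 / 20-epoch
schedule.

## Evaluation conventions

Per-spot metrics treat each spot's predicted and true proportion vectors as
the comparison unit: Pearson correlation (defined 0 for constant vectors),
RMSE over cell types, Jensen–Shannon divergence with base-2 logs (range
[0, 1]), and SSIM over cell types with the standard constants C1 = 0.01²,
C2 = 0.03² after min-max scaling each matrix to [0, 1]. The rank-based
accuracy score ranks methods within each of PCC/SSIM (descending) and
RMSE/JSD (ascending), ties sharing the average rank, maps rank r of M methods
to (M − r + 1)/M, and averages the four. Sample-level fractions are column
means of proportion matrices, compared by OLS r² and RMSE. Spatial domains
are recovered by seeded K-means (10 restarts) on predicted proportions and
scored by ARI and purity. Platform mixing is the mean silhouette of pooled
SRT/pseudo embeddings labeled by platform (lower = better mixed), computed on
equal-sized groups. An exclusion list drops named cell types from both
matrices and renormalizes rows before scoring (for types absent from the
reference).

## Known limitations

* Dense adjacency and O(n²) reconstruction bound practical graph sizes.
* The mixture combination is the soft responsibility-weighted form; the hard
  per-component sampling semantics is approximated (straight-through mode
  available but off by default).
* Single-slice only; no hexagonal-lattice simulation; no image-based inputs.
* The entropy and domain losses have small effects under the synthetic
  conditions here. In particular, per-dataset standardization removes the
  simulated multiplicative platform shift almost exactly (the platform
  silhouette of the preprocessed inputs is already ≈ 0), so the adversarial
  domain loss has essentially nothing left to correct on this generator and
  ablating it changes embeddings only at noise level; on real data the
  platform effect is richer (depth, dropout, chemistry) and survives
  standardization. Effect magnitudes measured here should not be read as
  real-data effect sizes.
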