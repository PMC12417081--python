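# gmdecon

Cell-type deconvolution for spatially resolved transcriptomics (SRT) spots.

Sequencing-based SRT platforms (legacy ST, 10x Visium, Slide-seq, ...) capture
gene expression in spots that contain one to tens of cells, so downstream
analyses need an estimate of each spot's cell-type composition. `gmdecon`
estimates per-spot cell-type proportions from an annotated scRNA-seq reference
while correcting three systematic biases:

1. **Spot-level overbalance** — real spots have dominant cell types (long-tailed
   per-spot proportions), while naive estimators spread mass evenly.
2. **Sample-level fraction drift** — the tissue-wide average of predicted
   proportions should match the sample's cell-type fractions.
3. **Platform shift** — scRNA-seq and SRT measure expression on systematically
   different scales.

## Model

Training data are *pseudo-spots*: for each one, `nc = Poisson(λ) + 1` cells
(default λ = 5) from `nk ~ U{1, ..., NK}` cell types (default NK = 4) are drawn
uniformly from the reference and their raw counts summed, giving an expression
profile `x_i` with a known proportion vector `y_i`. 50 000 pseudo-spots are
sampled per run and chunked into 250 expression graphs of 200 nodes each
(mutual 6-nearest-neighbor by cosine similarity); the SRT sample contributes a
spatial graph (Euclidean, mutual 6-NN on coordinates) and an expression graph
over its spots.

A Gaussian-mixture graph convolutional encoder maps each graph `(X, A)` to
node embeddings `Z ∈ R^{n×512}`: two symmetric-normalized graph-convolution
layers produce per-node mixture parameters `(μ_ik, σ_ik)` and responsibilities
`r_ik` over K components, and `z_i = Σ_k r_ik (μ_ik + σ_ik ∘ ε)`, `ε ~ N(0, I)`
(means only at inference). A two-layer MLP head with softmax predicts
proportions; a discriminator behind a gradient-reversal layer predicts the
platform (pseudo vs SRT), training the encoder adversarially toward
platform-invariant embeddings.

Pseudo-spot graphs minimize

```
L = L_recon + 1000 · L_MSE + L_CE + 1000 · L_sample + 10 · L_entropy
```

where `L_recon` is the edge-wise cross-entropy of `sigmoid(z_i · z_j)` against
the adjacency, `L_MSE` the per-spot proportion error, `L_CE` the domain
cross-entropy, `L_sample` the squared distance between batch-mean predicted and
true proportions, and `L_entropy` penalizes high Shannon entropy of predictions
(per spot and for the batch mean). SRT graphs, whose proportions are never
supervised, use `L = L_recon + L_CE`. Training runs Adam (lr 0.001) for 20
epochs, visiting all pseudo-spot graphs and then the two SRT graphs each
epoch. The final prediction averages the proportion matrices inferred from the
SRT spatial and expression graphs.

## Worked example

Generate a synthetic study with known ground truth, deconvolve it, and score
the result:

```bash
gmdecon fixtures --preset standard --seed 1 --out demo/
gmdecon deconvolve \
    --ref demo/ref_counts.tsv --ref-labels demo/ref_labels.tsv \
    --srt demo/srt_counts.tsv --coords demo/srt_coords.tsv \
    --config demo_run.yaml --seed 1 --out demo/out/
gmdecon evaluate --pred demo/out/proportions.tsv \
    --truth demo/true_proportions.tsv --out demo/report.json
```

with `demo_run.yaml` holding a scaled-down schedule:

```yaml
n_pseudo: 4000
graph_size: 100
n_graphs: 40
epochs: 10
```

The evaluation report for this run contains

```
"median": {"pcc": 0.953, "ssim": 0.899, "rmse": 0.114, "jsd": 0.129},
"mean_entropy": 1.169,
"sample_level": {"r2": 0.978, "rmse": 0.0358, ...}
```

i.e. the predicted proportion vector of a typical spot correlates at 0.95 with
the truth, its root-mean-square proportion error is 0.11 (versus 0.28 for a
uniform prediction), and the tissue-wide cell-type fractions are recovered to
within 0.04. `mean_entropy` well below `ln 5 ≈ 1.61` (a fully balanced
prediction) reflects the entropy loss favoring dominant cell types.

The same pipeline is available as a library:

```python
from gmdecon import FixtureSpec, RunConfig, make_fixture, run_pipeline

ref, labels, tissue = make_fixture(FixtureSpec(seed=1))
cfg = RunConfig(n_pseudo=4000, graph_size=100, n_graphs=40, epochs=10, seed=1)
result = run_pipeline(cfg, ref, labels, tissue.counts, tissue.coords)
result.proportions  # spots x cell-types DataFrame on the simplex
```

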