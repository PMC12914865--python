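# copulagcn

Semi-supervised cell-type classification for single-cell RNA-seq that
couples a graph convolutional network (GCN) with a **Gaussian copula over
the cell–cell graph**, plus the count simulator used to benchmark it.

## Who this is for

Annotating cell types in scRNA-seq is usually treated as independent
per-cell classification, even though transcriptionally similar cells are
strongly dependent. `copulagcn` models that dependence explicitly: a GCN
produces per-cell *marginal* scores for each cell type, and a Gaussian
copula — whose precision matrix lives on the k-nearest-neighbor
cell–cell graph — captures the *joint* behavior of the labels. The
package is a library plus a small CLI for people who want to train the
model on labeled count matrices (or on fully synthetic data from the
built-in simulator) and evaluate it with cross-validation.

## The model

For cells with features **X** (CLR-normalized, highly-variable-gene
selected counts) and a k-NN graph *G*, the joint density of one-vs-rest
labels *y* factorizes through Sklar's theorem as

```
f(y; X, G) = c(u_1, …, u_n; Σ) · Π_i f_i(y_i; λ_i)
```

* **Marginals** — a two-layer GCN (`H¹ = relu(S X W⁰)`, `H² = S H¹ W¹`,
  with `S` the symmetric-normalized adjacency) and an MLP head give one
  raw score `s_i` per cell and label, read two ways: Bernoulli
  probability `σ(s_i)` for the cross-entropy term and Poisson rate
  `λ_i = softplus(s_i)` for the copula.
* **Dependence** — a Gaussian copula with precision matrix
  `K = I_n + D̂ − Â`, where `Â_ij = softplus(h(x_i, x_j))` on graph edges
  (h a small symmetrized MLP) and `D̂` the matching degree matrix.
  Because `D̂ − Â` is a weighted graph Laplacian, K is guaranteed
  symmetric positive definite with `min eig(K) ≥ 1` and `K·1 = 1`.
* **Discrete marginals** enter through the distributional transform
  `u_i = F(y_i − 1; λ_i) + v · p(y_i; λ_i)` (midpoint `v = ½` during
  training; `v ~ U(0,1)` is exactly uniform and is used for
  diagnostics).
* **Training** minimizes `L_total = w · L_copula + L_BCE` with full-batch
  Adam, where `L_copula = −log c(u_obs; Σ)` is the negative log copula
  density of the training-fold (observed) block of Σ = K⁻¹.

Two ablations are built in: `gcn_only` (copula weight 0 — a plain GCN
classifier) and `copula_only` (per-label intercepts instead of the GCN —
its constant scores put ranking metrics at the all-ties value 0.5).

The simulator draws latent expression `X_ij ~ Gamma(1/Φ_i, Z_i Φ_i)`
(per-group fold changes on disjoint marker genes) and sequences each
cell by a multivariate hypergeometric draw of exactly `L` reads from the
rounded latent pool, so library sizes are conserved exactly.

## Worked example

```bash
copulagcn simulate --genes 2000 --cells 800 --groups 4 \
    --marker-frac 0.05 --marker-fold 8 --libsize 5000 --seed 1 --out sim/
copulagcn preprocess --counts sim/matrix.mtx --hvg 300 --out feat/
copulagcn graph --features feat/features.csv --k 5 --out graph/
copulagcn train --features feat/features.csv --graph graph/graph.tsv \
    --labels sim/labels.tsv --mode full --folds 5 --epochs 200 \
    --seed 1 --out run/
```

The last step prints (and writes to `run/metrics.json`):

```
macro metrics: {'macro_accuracy': 1.0, 'macro_pr_auc': 1.0, 'macro_roc_auc': 1.0}
```

With four groups separated by 8-fold marker up-regulation the model
recovers the grouping essentially perfectly: macro ROC-AUC 1.0 means
every held-out cell ranks above every non-member for its own type, and
macro accuracy 1.0 means the thresholded one-vs-rest calls are all
correct. Re-running with `--mode copula_only` yields
`macro_roc_auc: 0.5` exactly — the dependence term alone carries no
per-cell discrimination, which is the designed behavior of that
ablation. Equivalent library calls: `simulate_dataset`,
`build_features`, `knn_graph`, `run_cv` (see docstrings).

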