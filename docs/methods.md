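# Methods

## Model

Cells are nodes of a k-nearest-neighbor graph built from normalized
expression profiles. Cell-type annotation is decomposed into one-vs-rest
binary tasks; for each task the joint label distribution is split into a
representational part (per-cell marginals from a GCN) and a
correlational part (a Gaussian copula over the graph):

    f(y; X, G) = c(u_1, …, u_n; Σ) Π_i f_i(y_i; λ_i).

**Marginals.** A two-layer GCN over the symmetric-normalized adjacency
S = D̃^(−1/2)(A + I)D̃^(−1/2), followed by a one-hidden-layer MLP head,
yields one raw score s per (cell, label). The score is read both as a
Bernoulli probability sigmoid(s) (for the cross-entropy loss) and as a
Poisson rate λ = softplus(s) (for the copula's discrete marginal). Using
a single shared score keeps the two readings monotonically linked; they
agree on ordering by construction.

**Dependence.** The copula's precision matrix is parameterized on the
graph: K = I_n + D̂ − Â with Â_ij = softplus(h(x_i, x_j)) for edges
(i, j) and zero otherwise, where h is a two-layer perceptron on the
concatenated feature pair, symmetrized by averaging both argument
orders. D̂ − Â is a weighted graph Laplacian, so K is symmetric positive
definite with min eig(K) ≥ 1 and K·1 = 1 regardless of the regressor's
parameters — properties the test suite asserts on random draws. The
number of parameters is independent of the number of cells.

**Discrete marginals.** Sklar's theorem gives a unique copula only for
continuous marginals. Labels are discrete, so the probability integral
transform is replaced by the distributional transform
u = F(y − 1; λ) + v·p(y; λ). During training v = ½ (deterministic, so
gradients are well defined); for diagnostics v ~ Uniform(0,1), which
makes u exactly uniform under a correctly specified rate — this is the
property the KS-based uniformity checks exercise. u is clamped to
[1e-12, 1 − 1e-12] and latent normal scores z = Φ⁻¹(u) to |z| ≤ 8
before quadratic forms (Φ⁻¹ overflows near 0/1); gradients are zeroed
where a clamp binds.

**Loss.** L_total = w·L_copula + L_BCE. The copula term is the negative
log Gaussian-copula density of the observed (training-fold) block:
Σ = K⁻¹ is marginalized by extracting the observed block Σ₀₀ and
re-standardizing it to a correlation matrix R₀₀ (the Gaussian copula of
a margin is the Gaussian copula of the sub-correlation). A single
dependence model is shared across all label tasks — dependence between
cells is a property of the graph and features, not of one label — and
the copula term is averaged over labels and divided by the number of
observed nodes so that the two loss terms stay on comparable scales.
The weight w defaults to 1 (an unweighted sum); w = 0 reproduces a
plain GCN classifier exactly.

**Prediction.** Default prediction uses the marginal probabilities.
Optionally (`conditional_prediction`), test cells are scored by
conditioning the latent Gaussian on the training labels: with
z_obs = Φ⁻¹(u_obs), m = R₁₀R₀₀⁻¹z_obs and
v = diag(R₁₁ − R₁₀R₀₀⁻¹R₀₁), the adjusted probability is
P(y=1) = 1 − Φ((Φ⁻¹(e^(−λ)) − m)/√v), using P(y=0) = e^(−λ) under the
Poisson marginal. This construction is principled but optional — it is
off by default because marginal prediction is the simpler reading and
the two coincide whenever the graph carries no dependence. Conditional
variances are clamped at 1e-10 with a warning if numerics drive them
non-positive.

## Preprocessing and graph

* **CLR normalization** per cell over the *full* gene set (rows sum to
  zero, preserving the compositional interpretation), with pseudocount
  ε = 1 by default (scRNA-seq zeros make one mandatory).
* **HVG selection** by Fano-factor dispersion (variance/mean) of raw
  counts — the classical criterion; zero-mean genes get dispersion 0 and
  ties break to the lower gene index for determinism. CLR is computed
  first, then subset to the selected genes.
* **Standardization** of the selected CLR features per gene (z-score) by
  default; this guards the pairwise regressor and the GCN against scale
  imbalance and can be disabled.
* **Graph**: Euclidean distances on the standardized features, directed
  k-NN (k = 5 by default) symmetrized by union, ties at the k-th
  neighbor broken toward the lower index. Union symmetrization
  guarantees at least k incident edges per node but no upper bound (a
  hub may be the near neighbor of many cells). Edge weights are binary
  by default; a heat-kernel option exp(−d²/σ²) with σ the median
  included-edge distance is available. No PCA step is applied before
  distances.

## Simulator

The generator separates biological from technical variability:
X_ij ~ Gamma(shape 1/Φ_i, scale Z_i·Φ_i) so that E[X] = Z and
Var[X] = Z²Φ (Φ is the squared coefficient of variation), then each cell
is sequenced by drawing exactly L reads without replacement from a pool
holding round-half-to-even(X_ij) copies of gene i (a multivariate
hypergeometric, realized by sequential conditional univariate draws).
Library sizes are therefore conserved exactly — a hard invariant the
tests assert cell by cell.

Templates are synthetic: Z is log-normal (σ = 1), rescaled so the
expected pool is `pool_factor` (default 10) times the library size —
the sequencing stage requires pool ≥ L, and a real cell's transcript
pool far exceeds its sequenced depth; Φ ~ Gamma with mean 0.5 (shape 2),
floored at 1e-3; each group receives a disjoint random marker set
(default 5% of genes) up-regulated by a constant fold (default 8).
Default benchmark dimensions are 2000 genes × 800 cells, 4 equally
likely groups, library size 5000.

What the simulator does *not* emulate: batch effects, zero-inflation
beyond what the hypergeometric induces, gene–gene co-expression modules,
continuous differentiation trajectories, or estimation of (Z, Φ, L)
from a real template dataset. Passing the recovery benchmark therefore
shows that the implementation learns strong, well-separated group
structure end to end — not that it matches performance on real tissue
atlases.

## Training and evaluation

Full-batch Adam (lr 0.01, β = (0.9, 0.999), weight decay 5e-4), 200
epochs by default. Architecture defaults: GCN hidden width 64, head
hidden width 32, pairwise regressor hidden width 32 (tanh), dropout 0.5
after the first GCN layer (training mode only). The pairwise regressor's
final layer initializes at zero so every edge starts at softplus(0) =
ln 2 — the initial K is a uniformly weighted Laplacian plus identity.
One master seed drives fold assignment, initialization, dropout and the
copula node subsample through named child streams; runs are bit-for-bit
reproducible, and `gcn_only` coincides exactly with `full` at copula
weight 0 (both skip the copula term and train the same parameter set).

Evaluation is stratified 5-fold cross-validation. Per label:
one-vs-rest accuracy at threshold 0.5, ROC-AUC by the Mann–Whitney rank
statistic with ties counted ½ (so constant scores give exactly 0.5), and
PR-AUC as average precision. Macro metrics average over labels and
folds; a label missing a class in a test fold is recorded as missing and
excluded with a warning. "Accuracy" is per-label binary accuracy, not
multiclass argmax accuracy — with four groups a constant "all negative"
scorer already reaches 0.75 per label, which is why accuracy and ROC-AUC
can diverge.

## Numerical implementation

No deep-learning framework is used: training gradients come from a
small reverse-mode autodiff module (`copulagcn.autodiff`) over NumPy,
with two custom operations. The distributional transform differentiates
through the Poisson CDF identity dF(k;λ)/dλ = −p(k;λ), giving
du/dλ = −(p(y−1;λ) + p(y;λ))/2 at the midpoint. The copula loss is a
single fused op: Σ₀₀⁻¹ is formed directly as the Schur complement
K₀₀ − K₀₁K₁₁⁻¹K₁₀ (so cost is cubic in the block sizes, not in n via a
full inverse), the log-determinant and diagonal come from a Cholesky
factorization, and the gradient with respect to the per-edge weights is
assembled in closed form — only the diagonal and the edge entries of
the dense gradient matrix are ever materialized. Both ops are verified
against a dense reference implementation and central finite differences
in the test suite.

The loss op's linear algebra runs in single precision by default during
training (the conventional choice for neural-network optimization; the
matrices involved have smallest eigenvalue ≥ 1, so Cholesky in float32
is well conditioned); all analysis-facing functions
(`build_precision`, `gaussian_copula_logdensity`,
`copula_nll_observed`, conditioning) compute in double precision.
Training with the full copula term is used up to 4000 observed nodes;
above that a random node subsample (default 2048) is drawn per epoch
for the copula term only.

## Benchmark scale

The acceptance study uses the defaults above (800 cells, 300 HVG
features, k = 5, 200 epochs) with one fixed simulation and ten training
seeds — large enough that the full model's macro ROC-AUC separates
cleanly from both ablations, small enough to run on a single CPU in
minutes. The three reference simulated-scenario sizes (6776 / 1694 /
3388 cells, four groups) are available as presets
(`simulate.SCENARIO_CELLS`) for larger runs.

## Known limitations

* The copula loss is dense in the observed block; quadratic memory and
  cubic time limit exact training to a few thousand cells (hence the
  subsampling fallback).
* The conditional-prediction path inverts the full covariance once per
  fold; it is intended for datasets of the same scale.
* One-vs-rest scores are not calibrated against each other; if a single
  hard label per cell is needed, take the argmax of the per-label
  probabilities, but the reported metrics deliberately stay per-label.
* The Gaussian copula captures only elliptical dependence; tail
  dependence between cells is not modeled.
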