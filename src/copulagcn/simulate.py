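"""Generative model for labeled scRNA-seq count matrices.

Two-stage sampling separating biological from technical variability:

1. latent expression  X_ij ~ Gamma(shape = 1/Phi_i, scale = Z_i * Phi_i)
   per gene i and cell j, so E[X] = Z and Var[X] = Z^2 * Phi (Phi is the
   squared coefficient of variation). Cell-type structure enters through
   per-group fold changes multiplying Z on disjoint marker gene sets.
2. sequencing  Y_j ~ MultivariateHypergeometric(n = L_j, m = round(X_j)):
   L_j reads drawn without replacement from a pool holding round(X_ij)
   copies of gene i, so each cell's total count equals its library size
   exactly and no gene exceeds its pool count.

Templates are synthetic (no external reference dataset is estimated):
gene intensities are log-normal, rescaled so the expected pre-sequencing
pool is a configurable multiple of the library size (the sequencing stage
requires pool >= L); variabilities are Gamma-distributed with mean 0.5.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import GeneExpressionDataset, ValidationError


@dataclasses.dataclass
class SimTemplate:
    """Gene-level and cell-level parameters of the generative model."""

    Z: np.ndarray             # per-gene expression intensity, > 0
    Phi: np.ndarray           # per-gene variability (CV^2), > 0
    library_size: int         # reads per cell L, >= 1
    fold_changes: np.ndarray  # groups x genes positive multipliers on Z
    group_probs: np.ndarray   # mixing proportions, sums to 1
    seed: int

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        self.Phi = np.asarray(self.Phi, dtype=np.float64)
        self.fold_changes = np.asarray(self.fold_changes, dtype=np.float64)
        self.group_probs = np.asarray(self.group_probs, dtype=np.float64)
        if np.any(self.Z <= 0) or np.any(self.Phi <= 0):
            raise ValidationError("Z and Phi must be positive")
        if np.any(self.fold_changes <= 0):
            raise ValidationError("fold changes must be positive")
        if self.library_size < 1:
            raise ValidationError("library size must be >= 1")
        if not np.isclose(self.group_probs.sum(), 1.0):
            raise ValidationError("group probabilities must sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.Z)

    @property
    def n_groups(self) -> int:
        return self.fold_changes.shape[0]


@dataclasses.dataclass
class SimOutput:
    dataset: GeneExpressionDataset
    latent_X: np.ndarray  # genes x cells pre-sequencing expression


def make_template(n_genes: int, n_groups: int, marker_fraction: float,
                  marker_fold: float, library_size: int, seed: int,
                  intensity_sigma: float = 1.0, phi_mean: float = 0.5,
                  pool_factor: float = 10.0) -> SimTemplate:
    """Draw a synthetic template with disjoint per-group marker genes.

    Z is log-normal (shape ``intensity_sigma``), rescaled so the expected
    pool sum(Z) equals ``pool_factor * library_size`` (the sequencing
    stage needs the pool to cover the library size). Phi is
    Gamma-distributed with mean ``phi_mean`` (shape 2). Each group gets a
    disjoint random ``marker_fraction`` of genes up-regulated by
    ``marker_fold``; all other fold changes are 1.
    """
    if not (0 < marker_fraction < 1):
        raise ValidationError("marker_fraction must be in (0, 1)")
    if marker_fold < 1:
        raise ValidationError("marker_fold must be >= 1")
    n_markers = int(marker_fraction * n_genes)
    if n_markers * n_groups > n_genes:
        raise ValidationError(
            f"cannot place {n_groups} disjoint marker sets of {n_markers} "
            f"genes among {n_genes} genes")
    rng = np.random.default_rng(seed)
    Z = rng.lognormal(mean=0.0, sigma=intensity_sigma, size=n_genes)
    Z *= pool_factor * library_size / Z.sum()
    Phi = rng.gamma(shape=2.0, scale=phi_mean / 2.0, size=n_genes)
    Phi = np.maximum(Phi, 1e-3)
    fold = np.ones((n_groups, n_genes))
    perm = rng.permutation(n_genes)
    for g in range(n_groups):
        fold[g, perm[g * n_markers:(g + 1) * n_markers]] = marker_fold
    return SimTemplate(Z=Z, Phi=Phi, library_size=library_size,
                       fold_changes=fold,
                       group_probs=np.full(n_groups, 1.0 / n_groups),
                       seed=seed)


def simulate_expression(template: SimTemplate, n_cells: int,
                        rng: np.random.Generator):
    """Latent Gamma expression matrix (genes x cells) and group labels."""
    groups = rng.choice(template.n_groups, size=n_cells, p=template.group_probs)
    shape = 1.0 / template.Phi                       # per gene
    scale = template.Z * template.Phi                # per gene, before FC
    # fold change multiplies the mean (scale), not the shape
    scale_cells = scale[:, None] * template.fold_changes[groups].T
    x = rng.gamma(shape=shape[:, None], scale=scale_cells)
    return x, groups


def simulate_reads(x_col: np.ndarray, library_size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sequence one cell: L draws without replacement from its latent pool.

    Pool counts are round-half-to-even of the latent expression. The
    result sums exactly to the library size and never exceeds the pool.
    """
    m = np.rint(np.asarray(x_col, dtype=np.float64)).astype(np.int64)
    m = np.maximum(m, 0)
    pool = int(m.sum())
    if pool < library_size:
        raise ValidationError(
            f"latent pool {pool} smaller than library size {library_size}; "
            "increase gene intensities Z or reduce the library size")
    # sequential conditional univariate hypergeometric sampling
    return rng.multivariate_hypergeometric(m, library_size, method="marginals")


def simulate_dataset(template: SimTemplate, n_cells: int,
                     seed: int | None = None) -> SimOutput:
    """Full generative pass: expression, sequencing, labels 'group_g'."""
    rng = np.random.default_rng(template.seed if seed is None else seed)
    x, groups = simulate_expression(template, n_cells, rng)
    counts = np.empty((template.n_genes, n_cells), dtype=np.int64)
    for j in range(n_cells):
        counts[:, j] = simulate_reads(x[:, j], template.library_size, rng)
    dataset = GeneExpressionDataset(
        counts=counts,
        gene_ids=[f"gene_{i}" for i in range(template.n_genes)],
        cell_ids=[f"cell_{j}" for j in range(n_cells)],
        labels=np.array([f"group_{g}" for g in groups], dtype=object),
    )
    return SimOutput(dataset=dataset, latent_X=x)


# cell counts of the three reference benchmark scenarios (4 groups each)
SCENARIO_CELLS = {"large": 6776, "small": 1694, "medium": 3388}
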