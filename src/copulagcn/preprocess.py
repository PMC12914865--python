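"""CLR normalization and highly-variable-gene selection.

Produces the node feature matrix fed to both the GCN trunk and the
pairwise precision-matrix regressor. The centered log-ratio transform is
computed per cell over the FULL gene set (so rows sum to zero and the
compositional interpretation holds) and only then subset to the selected
highly variable genes; selection itself ranks genes by Fano-factor
dispersion (variance / mean) of the raw counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import GeneExpressionDataset, ValidationError


@dataclasses.dataclass
class NormalizedMatrix:
    """Cells x selected-genes real-valued feature matrix."""

    values: np.ndarray
    selected_gene_ids: list[str]
    cell_ids: list[str]
    pseudocount: float
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized matrix contains NaN/Inf")
        if self.values.shape != (len(self.cell_ids), len(self.selected_gene_ids)):
            raise ValidationError("normalized matrix shape mismatch with ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def clr_normalize(dataset: GeneExpressionDataset,
                  pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio transform, one row per cell.

    For cell j with counts x_.j, output_ij = ln((x_ij + eps) / g_j) where
    g_j is the geometric mean of (x_.j + eps). Each row sums to zero (to
    1e-9) and the transform is invariant to positive rescaling of a cell's
    shifted count vector.
    """
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    if dataset.n_genes == 0:
        raise ValidationError("dataset has zero genes")
    # counts are genes x cells on disk; analysis orientation is cells x genes
    shifted = dataset.counts.T.astype(np.float64) + pseudocount
    log = np.log(shifted)
    values = log - log.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        values=values,
        selected_gene_ids=list(dataset.gene_ids),
        cell_ids=list(dataset.cell_ids),
        pseudocount=pseudocount,
    )


def gene_dispersion(counts: np.ndarray) -> np.ndarray:
    """Fano factor (variance / mean) per gene of a genes x cells count matrix.

    Genes with zero mean get dispersion 0.
    """
    mean = counts.mean(axis=1)
    var = counts.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return disp


def select_hvg(dataset: GeneExpressionDataset, n_genes: int,
               method: str = "dispersion") -> np.ndarray:
    """Indices of the ``n_genes`` most dispersed genes (raw-count Fano factor).

    Ties at the cutoff are broken toward the lower gene index; the returned
    index array is ordered by rank (highest dispersion first).
    """
    if method != "dispersion":
        raise ValueError(f"unknown HVG method {method!r}")
    total = dataset.n_genes
    if not (0 < n_genes <= total):
        raise ValidationError(
            f"n_genes must be in [1, {total}], got {n_genes}")
    disp = gene_dispersion(dataset.counts)
    # stable sort on (-dispersion, index): lexsort's last key is primary
    order = np.lexsort((np.arange(total), -disp))
    return order[:n_genes]


def standardize(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene z-score across cells; constant genes are left at zero."""
    v = matrix.values
    mean = v.mean(axis=0)
    std = v.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return NormalizedMatrix(
        values=(v - mean) / std,
        selected_gene_ids=list(matrix.selected_gene_ids),
        cell_ids=list(matrix.cell_ids),
        pseudocount=matrix.pseudocount,
        standardized=True,
    )


def build_features(dataset: GeneExpressionDataset, n_hvg: int,
                   pseudocount: float = 1.0,
                   standardize_features: bool = True) -> NormalizedMatrix:
    """CLR over all genes -> subset to HVGs -> (optionally) z-score per gene."""
    clr = clr_normalize(dataset, pseudocount=pseudocount)
    idx = select_hvg(dataset, n_hvg)
    subset = NormalizedMatrix(
        values=clr.values[:, idx],
        selected_gene_ids=[dataset.gene_ids[i] for i in idx],
        cell_ids=list(dataset.cell_ids),
        pseudocount=pseudocount,
    )
    return standardize(subset) if standardize_features else subset
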