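"""Reading and writing count matrices, labels, graphs and metric reports.

On disk, count matrices are genes x cells (the community convention for
Matrix Market exports); downstream analysis code transposes to cells x
features exactly once, in :mod:`copulagcn.preprocess`. MTX coordinates are
1-based on disk and converted to 0-based at this boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Malformed or incomplete on-disk input (missing sidecar, bad header)."""


class ValidationError(ValueError):
    """Input parsed but violates a dataset invariant."""


@dataclasses.dataclass
class GeneExpressionDataset:
    """Raw counts (genes x cells) with identifiers and optional labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"counts has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell ids must be unique")
        _validate_counts(self.counts)
        self.counts = self.counts.astype(np.int64, copy=False)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n_cells,):
                raise ValidationError(
                    f"labels has shape {self.labels.shape}, expected ({n_cells},)"
                )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def label_categories(self) -> list[str]:
        """Distinct labels in stable sorted order (the one-vs-rest column order)."""
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        return sorted(set(str(x) for x in self.labels))


def _validate_counts(counts: np.ndarray) -> None:
    if counts.size == 0:
        raise ValidationError("empty count matrix")
    neg = np.argwhere(counts < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(f"negative count at gene {i}, cell {j}")
    if not np.issubdtype(counts.dtype, np.integer):
        frac = np.argwhere(counts != np.floor(counts))
        if frac.size:
            i, j = frac[0]
            raise ValidationError(f"non-integer count at gene {i}, cell {j}")


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str | Path, format: str = "mtx") -> GeneExpressionDataset:
    """Read a genes x cells count matrix.

    ``mtx`` expects ``genes.tsv`` and ``cells.tsv`` sidecars (one id per
    line) next to the matrix file; ``csv`` expects gene ids in the first
    column and cell ids in the header row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "cells.tsv"
        for side in (genes_path, cells_path):
            if not side.exists():
                raise FormatError(f"missing sidecar file {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        counts = np.asarray(mat)
        _validate_counts(counts)
        return GeneExpressionDataset(
            counts=counts.astype(np.int64),
            gene_ids=_read_id_file(genes_path),
            cell_ids=_read_id_file(cells_path),
        )
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy()
        _validate_counts(counts)
        return GeneExpressionDataset(
            counts=counts.astype(np.int64),
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
        )
    raise FormatError(f"unknown count format {format!r}")


def write_counts(dataset: GeneExpressionDataset, path: str | Path,
                 format: str = "mtx") -> None:
    """Write counts in a form :func:`read_counts` inverts exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(dataset.counts), field="integer")
        (path.parent / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in dataset.gene_ids))
        (path.parent / "cells.tsv").write_text(
            "".join(f"{c}\n" for c in dataset.cell_ids))
    elif format == "csv":
        pd.DataFrame(
            dataset.counts, index=dataset.gene_ids, columns=dataset.cell_ids
        ).to_csv(path)
    else:
        raise FormatError(f"unknown count format {format!r}")


def read_labels(path: str | Path, cell_ids: list[str]) -> np.ndarray:
    """Read a two-column ``cell_id<TAB>label`` TSV aligned to ``cell_ids``.

    Rows may appear in any order; alignment is by id. Unknown, duplicate or
    missing cells are errors.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            cid, label = parts
            if cid in mapping:
                raise ValidationError(f"duplicate cell id {cid!r} in {path}")
            mapping[cid] = label
    known = set(cell_ids)
    extra = [c for c in mapping if c not in known]
    if extra:
        raise ValidationError(f"label file references unknown cell ids: {extra[:5]}")
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValidationError(f"label file missing cells: {missing[:5]}")
    return np.array([mapping[c] for c in cell_ids], dtype=object)


def write_labels(labels: np.ndarray, cell_ids: list[str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in zip(cell_ids, labels)))


@dataclasses.dataclass
class MetricsReport:
    """Per-fold, per-label classification metrics with macro averages.

    ``per_fold`` is a list (one entry per fold) of ``{label: {metric:
    value}}`` dicts; a metric may be None when the test fold lacks both
    classes for that label (excluded from macro averages).
    """

    per_fold: list[dict[str, dict[str, float | None]]]
    macro: dict[str, float]
    metadata: dict

    def __post_init__(self) -> None:
        for fold in self.per_fold:
            for label, metrics in fold.items():
                for name, v in metrics.items():
                    if v is not None and not (0.0 <= v <= 1.0):
                        raise ValidationError(
                            f"metric {name} for label {label} outside [0,1]: {v}")

    @staticmethod
    def from_folds(per_fold, metadata) -> "MetricsReport":
        """Build a report, recomputing macro averages from the fold entries."""
        macro: dict[str, float] = {}
        names = sorted({m for fold in per_fold for d in fold.values() for m in d})
        for name in names:
            vals = [d[name] for fold in per_fold for d in fold.values()
                    if d.get(name) is not None]
            if vals:
                macro[f"macro_{name}"] = float(np.mean(vals))
        return MetricsReport(per_fold=per_fold, macro=macro, metadata=metadata)


def write_metrics(report: MetricsReport, path: str | Path) -> None:
    payload = {
        "per_fold": report.per_fold,
        "macro": report.macro,
        "metadata": report.metadata,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_metrics(path: str | Path) -> MetricsReport:
    with open(path) as fh:
        payload = json.load(fh)
    return MetricsReport(per_fold=payload["per_fold"], macro=payload["macro"],
                         metadata=payload["metadata"])
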