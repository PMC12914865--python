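"""K-nearest-neighbor cell-cell graph with weighted adjacency and degree.

Each cell is a node; edges link transcriptionally similar cells. The
directed k-NN relation (self excluded, Euclidean distance on the feature
matrix) is symmetrized by union, so every node ends up incident to at
least k edges and, in binary mode, at most 2k.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import scipy.sparse
import scipy.spatial.distance

from .data_io import ValidationError


@dataclasses.dataclass
class CellGraph:
    """Undirected weighted graph over cells.

    ``edges`` is an (E, 2) int array with i < j per row, no self-loops;
    ``weights`` the matching positive weight per edge.
    """

    n: int
    edges: np.ndarray
    weights: np.ndarray
    neighbor_k: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if len(self.weights) != len(self.edges):
            raise ValidationError("edge/weight length mismatch")
        if self.edges.size:
            if np.any(self.edges[:, 0] >= self.edges[:, 1]):
                raise ValidationError("edges must satisfy i < j (no self-loops)")
            if self.edges.max() >= self.n or self.edges.min() < 0:
                raise ValidationError("edge endpoint out of range")
            if np.any(self.weights <= 0):
                raise ValidationError("edge weights must be positive")
            pairs = {tuple(e) for e in self.edges.tolist()}
            if len(pairs) != len(self.edges):
                raise ValidationError("duplicate edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, weights: np.ndarray | None = None) -> scipy.sparse.csr_matrix:
        """Symmetric sparse adjacency; optionally with substituted edge weights."""
        w = self.weights if weights is None else np.asarray(weights, float)
        i, j = (self.edges[:, 0], self.edges[:, 1]) if self.edges.size else ([], [])
        a = scipy.sparse.coo_matrix(
            (np.concatenate([w, w]) if len(w) else np.empty(0),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n))
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def pairwise_distances(features: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Dense symmetric distance matrix between cells (rows of ``features``)."""
    x = np.asarray(getattr(features, "values", features), dtype=np.float64)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 cells")
    if not np.all(np.isfinite(x)):
        raise ValidationError("features contain NaN/Inf")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x, metric="euclidean"))
    return d


def knn_graph(distances: np.ndarray, k: int,
              weight_mode: str = "binary") -> CellGraph:
    """Union-symmetrized k-nearest-neighbor graph from a distance matrix.

    Ties at the k-th distance break toward the lower cell index. ``binary``
    weights are 1; ``heat_kernel`` weights are exp(-d^2 / sigma^2) with
    sigma the median distance over included edges.
    """
    d = np.asarray(distances, dtype=np.float64)
    n = d.shape[0]
    if k <= 0:
        raise ValidationError("k must be positive")
    if k >= n:
        raise ValidationError(f"k={k} must be < number of cells ({n})")
    if weight_mode not in ("binary", "heat_kernel"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    # deterministic neighbor ranking: by (distance, index), self excluded
    idx = np.arange(n)
    masked = d.copy()
    np.fill_diagonal(masked, np.inf)
    order = np.lexsort((np.broadcast_to(idx, (n, n)), masked), axis=1)
    neighbors = order[:, :k]

    pairs = set()
    for i in range(n):
        for j in neighbors[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)

    if weight_mode == "binary":
        weights = np.ones(len(edges))
    else:
        ed = d[edges[:, 0], edges[:, 1]]
        sigma = float(np.median(ed))
        weights = np.exp(-(ed ** 2) / sigma ** 2) if sigma > 0 else np.ones(len(edges))
        weights = np.maximum(weights, 1e-300)
    return CellGraph(n=n, edges=edges, weights=weights, neighbor_k=k)


def gcn_normalized_adjacency(graph: CellGraph) -> scipy.sparse.csr_matrix:
    """Symmetric GCN propagation operator S = D~^(-1/2) (A + I) D~^(-1/2).

    D~ is the degree matrix of A + I. S is symmetric with spectral radius
    <= 1; for an empty graph S = I.
    """
    a = graph.adjacency() + scipy.sparse.identity(graph.n, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    d = scipy.sparse.diags(inv_sqrt)
    return (d @ a @ d).tocsr()


def write_graph(graph: CellGraph, path: str | Path) -> None:
    """Edge-list TSV ``i<TAB>j<TAB>weight`` with i < j, 0-based, plus header."""
    with open(path, "w") as fh:
        fh.write(f"# n={graph.n} k={graph.neighbor_k}\n")
        for (i, j), w in zip(graph.edges, graph.weights):
            fh.write(f"{i}\t{j}\t{float(w)!r}\n")


def read_graph(path: str | Path) -> CellGraph:
    edges, weights = [], []
    n = k = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = dict(tok.split("=") for tok in line[1:].split())
                n, k = int(header["n"]), int(header["k"])
                continue
            i, j, w = line.split("\t")
            edges.append((int(i), int(j)))
            weights.append(float(w))
    if n is None:
        raise ValidationError("graph file missing header line")
    return CellGraph(n=n, edges=np.array(edges).reshape(-1, 2),
                     weights=np.array(weights), neighbor_k=k)
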