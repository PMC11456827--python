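"""KNN cell graph construction and symmetric normalization.

The graph autoencoder and the fusion step both consume the identity-augmented
symmetrically normalized adjacency Ā = D̃^{-1/2}(A + I)D̃^{-1/2}, where A is
the union-symmetrized KNN graph of cells in the processed expression space
and D̃ is by default the degree matrix of A + I (the renormalization trick;
degrees of A alone can vanish for isolated cells).  Eigenvalues of Ā lie in
[-1, 1], which keeps repeated propagation Ā·Z non-expansive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ParameterError, ValidationError
from .io import CountMatrix

__all__ = ["CellGraph", "build_knn_graph", "normalize_adjacency", "build_graph"]


@dataclass
class CellGraph:
    """Binary symmetric adjacency A plus its normalized form Ā."""

    adjacency: np.ndarray
    k_neighbors: int
    norm_adjacency: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency must have zero diagonal")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValidationError("adjacency entries must be 0/1")
        self.adjacency = a

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> np.ndarray:
        """Upper-triangle edges as a two-column array of 0-based indices."""
        i, j = np.nonzero(np.triu(self.adjacency))
        return np.column_stack([i, j])


def _pairwise_distances(x: np.ndarray, metric: str) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    if metric not in ("euclidean", "cosine"):
        raise ParameterError(f"unsupported metric {metric!r}")
    return squareform(pdist(x, metric=metric))


def build_knn_graph(
    x: CountMatrix | np.ndarray, k: int = 15, metric: str = "euclidean"
) -> CellGraph:
    """Union-symmetrized exact KNN graph on the processed expression matrix.

    a_ij = 1 iff i is among the k nearest neighbors of j or vice versa
    (self excluded).  Distance ties are broken by ascending cell index, so
    the graph is deterministic.
    """
    vals = x.values if isinstance(x, CountMatrix) else np.asarray(x, dtype=float)
    n = vals.shape[0]
    if not (1 <= k < n):
        raise ParameterError(f"k must satisfy 1 <= k < n_cells, got k={k}, n={n}")
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite values in expression matrix")
    dist = _pairwise_distances(vals, metric)
    np.fill_diagonal(dist, np.inf)
    # stable argsort => ties resolved by ascending cell index
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
    a = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    a[rows, nn.ravel()] = 1.0
    a = np.maximum(a, a.T)  # union symmetrization
    np.fill_diagonal(a, 0.0)
    return CellGraph(adjacency=a, k_neighbors=k)


def normalize_adjacency(g: CellGraph, renormalize: bool = True) -> CellGraph:
    """Attach Ā = D̃^{-1/2}(A + I)D̃^{-1/2} to the graph.

    With ``renormalize`` (default) D̃ is the degree matrix of A + I, so every
    node has degree >= 1.  The literal variant uses degrees of A alone and
    raises if any cell is isolated.
    """
    a = g.adjacency
    a_tilde = a + np.eye(g.n_cells)
    deg = a_tilde.sum(axis=1) if renormalize else a.sum(axis=1)
    if np.any(deg == 0):
        raise ValidationError("isolated cells have zero degree; use renormalize=True")
    inv_sqrt = 1.0 / np.sqrt(deg)
    a_norm = a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    a_norm = 0.5 * (a_norm + a_norm.T)  # kill last-bit asymmetry
    g.norm_adjacency = a_norm
    return g


def build_graph(
    x: CountMatrix | np.ndarray, k: int = 15, metric: str = "euclidean"
) -> CellGraph:
    """Convenience: KNN graph with Ā already attached."""
    return normalize_adjacency(build_knn_graph(x, k=k, metric=metric))
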