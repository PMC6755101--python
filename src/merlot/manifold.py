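"""Low-dimensional embeddings and the local-averaging reduction.

A diffusion map is the default manifold for tree reconstruction: it is a
spectral embedding of a density-normalized Gaussian affinity kernel whose
leading non-trivial eigenvectors capture differentiation geometry.  Any
user-supplied coordinates can be used instead.

For large datasets the scaffold search (all-pairs shortest paths) is made
tractable by *local averaging*: the manifold coordinates are clustered into
``4·sqrt(N)`` centroids, the tree is built on the centroids, and the fitted
tree is then *inflated* back onto the full set of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

__all__ = [
    "ManifoldCoords",
    "CentroidReduction",
    "DiffusionMap",
    "CentroidReducer",
    "compute_diffusion_map",
    "reduce_by_centroids",
    "default_n_centroids",
    "inflate_tree",
]


@dataclass
class ManifoldCoords:
    """N × D embedding coordinates with cell identifiers.

    D is typically between 2 and 20; as a rule of thumb a topology with
    B branches needs about B + 1 informative dimensions.
    """

    coords: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    dim_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be an N × D matrix")
        n, d = self.coords.shape
        if n < 3:
            raise ValueError("need at least 3 cells")
        if d < 2:
            raise ValueError("need at least 2 dimensions")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.dim_names:
            self.dim_names = [f"DC{j + 1}" for j in range(d)]
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class CentroidReduction:
    """Partition of N cells into C centroids (local-averaging mode)."""

    centroids: np.ndarray
    membership: np.ndarray
    C: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.membership = np.asarray(self.membership, dtype=int)
        counts = np.bincount(self.membership, minlength=self.C)
        if np.any(counts == 0):
            raise ValueError("every centroid must have at least one member")


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, ExpressionMatrix):
        return data.values
    if isinstance(data, ManifoldCoords):
        return data.coords
    return np.asarray(data, dtype=float)


class DiffusionMap(TransformerMixin, BaseEstimator):
    """Diffusion-map embedding of expression profiles.

    The affinity kernel is Gaussian with per-cell local scaling
    ``K_ij = exp(-d_ij^2 / (sigma_i * sigma_j))`` where ``sigma_i`` is the
    distance of cell *i* to its ``n_neighbors``-th nearest neighbor
    (``kernel_scale='auto'``), or a single global bandwidth when
    ``kernel_scale`` is a number.  The kernel is density-normalized
    (alpha = 1) before the Markov normalization, removing the influence of
    sampling density.

    Eigenvectors are ordered by eigenvalue magnitude, and each is given a
    fixed sign (its largest-magnitude entry made positive) so that the
    embedding is deterministic.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_cells, n_components)
        Non-trivial diffusion components, scaled by their eigenvalues.
    eigenvalues_ : ndarray of shape (n_components,)
    """

    def __init__(self, n_components: int = 10, kernel_scale: float | str = "auto",
                 n_neighbors: int = 15):
        self.n_components = n_components
        self.kernel_scale = kernel_scale
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None) -> "DiffusionMap":
        X = _as_matrix(X)
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 cells")
        if self.n_components >= n:
            raise ValueError("n_components must be smaller than the number of cells")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite expression values")

        d2 = squareform(pdist(X, metric="sqeuclidean"))
        if self.kernel_scale == "auto":
            d = np.sqrt(d2)
            kth = min(self.n_neighbors, n - 1)
            sigma = np.sort(d, axis=1)[:, kth]
            sigma[sigma <= 0] = 1.0  # duplicated points: fall back to unit scale
            scale = np.outer(sigma, sigma)
        else:
            s = float(self.kernel_scale)
            if s <= 0:
                raise ValueError("kernel_scale must be positive")
            scale = s * s
        K = np.exp(-d2 / scale)

        # density normalization (alpha = 1), then symmetric Markov form
        q = K.sum(axis=1)
        K = K / np.outer(q, q)
        dgr = K.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(dgr)
        A = K * np.outer(inv_sqrt, inv_sqrt)

        evals, evecs = np.linalg.eigh(A)
        order = np.argsort(-np.abs(evals))
        evals, evecs = evals[order], evecs[:, order]
        # right eigenvectors of the Markov matrix; drop the trivial first one
        psi = evecs * inv_sqrt[:, None]
        psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
        lam = evals[1 : self.n_components + 1]
        comps = psi[:, 1 : self.n_components + 1] * lam[None, :]
        # fixed sign convention: largest-magnitude entry positive
        flip = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(comps.shape[1])])
        flip[flip == 0] = 1.0
        comps = comps * flip[None, :]

        self.eigenvalues_ = lam
        self.embedding_ = comps
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_

    def transform(self, X) -> np.ndarray:
        # spectral embeddings are transductive: only the fitted data has
        # coordinates
        raise NotImplementedError(
            "DiffusionMap is transductive; use fit_transform on the full dataset"
        )


class CentroidReducer(ClusterMixin, BaseEstimator):
    """Cluster manifold coordinates into centroids for local averaging.

    ``n_centroids='auto'`` uses ``round(4 * sqrt(N))`` centroids.  k-means
    with a fixed ``random_state`` is used so memberships are reproducible.
    """

    def __init__(self, n_centroids: int | str = "auto", random_state: int = 0):
        self.n_centroids = n_centroids
        self.random_state = random_state

    def fit(self, X, y=None) -> "CentroidReducer":
        X = _as_matrix(X)
        n = X.shape[0]
        c = default_n_centroids(n) if self.n_centroids == "auto" else int(self.n_centroids)
        if c > n:
            raise ValueError("n_centroids cannot exceed the number of cells")
        if c < 1:
            raise ValueError("n_centroids must be positive")
        if c == n:
            self.cluster_centers_ = X.copy()
            self.labels_ = np.arange(n)
        else:
            km = KMeans(n_clusters=c, n_init=10, random_state=self.random_state)
            self.labels_ = km.fit_predict(X)
            self.cluster_centers_ = km.cluster_centers_
        self.n_centroids_ = c
        return self

    def reduction_(self) -> CentroidReduction:
        return CentroidReduction(self.cluster_centers_, self.labels_, self.n_centroids_)


def default_n_centroids(n_cells: int) -> int:
    """Default centroid count for local averaging: round(4·sqrt(N))."""
    return int(round(4.0 * np.sqrt(n_cells)))


def compute_diffusion_map(
    expr: ExpressionMatrix | np.ndarray,
    n_components: int = 10,
    kernel_scale: float | str = "auto",
) -> ManifoldCoords:
    """Functional wrapper over :class:`DiffusionMap`."""
    dm = DiffusionMap(n_components=n_components, kernel_scale=kernel_scale)
    comps = dm.fit_transform(expr)
    ids = expr.cell_ids if isinstance(expr, ExpressionMatrix) else []
    return ManifoldCoords(comps, list(ids), [f"DC{j + 1}" for j in range(comps.shape[1])])


def reduce_by_centroids(
    coords: ManifoldCoords | np.ndarray,
    n_centroids: int | str = "auto",
    seed: int = 0,
) -> CentroidReduction:
    """Functional wrapper over :class:`CentroidReducer`."""
    red = CentroidReducer(n_centroids=n_centroids, random_state=seed).fit(coords)
    return red.reduction_()


def inflate_tree(reduced_tree, coords: ManifoldCoords | np.ndarray):
    """Re-assign all original cells to a tree fitted on centroids.

    Topology and node positions are unchanged; only the cell-to-node
    assignment is recomputed against the N original cells.
    """
    X = _as_matrix(coords)
    if X.shape[1] != reduced_tree.node_coords_.shape[1]:
        raise ValueError("coordinate dimensionality does not match tree nodes")
    return reduced_tree.inflate(X)
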