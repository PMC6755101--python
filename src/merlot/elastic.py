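"""Elastic principal trees (EPT).

An EPT approximates a point cloud with a tree of k support nodes by
minimizing the elastic energy

    U = (1/N) sum_i ||x_i - v_c(i)||^2          (data approximation)
      + lam * sum_(a,b) in edges ||v_a - v_b||^2   (stretching)
      + mu  * sum_stars ||v_c - mean(neighbors)||^2 (bending at stars)

with alternating minimization: cells are assigned to their nearest node,
then node positions are the exact solution of the resulting quadratic
system.  The tree is initialized from a scaffold (endpoints, branchpoints
and their connectivity) and grown by bisecting the longest edge at its
midpoint until the requested number of nodes is reached; the scaffold
topology (endpoint/branchpoint counts and branch connectivity) is never
changed by the optimization.

Default elasticity constants were calibrated for k = 100 support nodes as
mu0 = 0.0025 and lam0 = 0.8e-9, rescaled for other k as
mu = (k-1)*mu0 and lam = (k-2)^3*lam0.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .manifold import ManifoldCoords

__all__ = [
    "MU0",
    "LAM0",
    "DEFAULT_K",
    "elasticity_params",
    "ElasticPrincipalTree",
    "fit_elastic_tree",
    "bisect_tree",
]

MU0 = 0.0025
LAM0 = 0.8e-9
DEFAULT_K = 100


def elasticity_params(k: int, mu0: float = MU0, lam0: float = LAM0) -> tuple[float, float]:
    """Star (mu) and edge (lam) elasticity for a tree of k support nodes."""
    if k < 3:
        raise ValueError("need at least 3 support nodes")
    return (k - 1) * mu0, (k - 2) ** 3 * lam0


def _adjacency(k: int, edges) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(k)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _assign(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Nearest support node per cell; ties go to the lower node index."""
    return np.argmin(cdist(X, V, metric="sqeuclidean"), axis=1)


def _solve_positions(
    X: np.ndarray, labels: np.ndarray, edges, k: int, mu: float, lam: float
) -> np.ndarray:
    """Exact minimizer of the elastic energy for fixed cell assignment."""
    n = X.shape[0]
    counts = np.bincount(labels, minlength=k).astype(float)
    A = np.zeros((k, k))
    A[np.diag_indices(k)] += counts / n
    B = np.zeros((k, X.shape[1]))
    np.add.at(B, labels, X / n)
    for a, b in edges:
        A[a, a] += lam
        A[b, b] += lam
        A[a, b] -= lam
        A[b, a] -= lam
    adj = _adjacency(k, edges)
    for c in range(k):
        nbrs = adj[c]
        m = len(nbrs)
        if m < 2:  # stars only at nodes of degree >= 2
            continue
        w = np.zeros(k)
        w[c] = 1.0
        for u in nbrs:
            w[u] -= 1.0 / m
        A += mu * np.outer(w, w)
    return np.linalg.solve(A, B)


def _energy(
    X: np.ndarray, V: np.ndarray, labels: np.ndarray, edges, mu: float, lam: float
) -> float:
    approx = float(np.mean(np.sum((X - V[labels]) ** 2, axis=1)))
    stretch = float(sum(np.sum((V[a] - V[b]) ** 2) for a, b in edges))
    adj = _adjacency(V.shape[0], edges)
    bend = 0.0
    for c, nbrs in enumerate(adj):
        if len(nbrs) < 2:
            continue
        bend += float(np.sum((V[c] - V[nbrs].mean(axis=0)) ** 2))
    return approx + lam * stretch + mu * bend


def _roles_from_degree(k: int, edges) -> list[str]:
    deg = np.zeros(k, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return [
        "endpoint" if d == 1 else ("branchpoint" if d >= 3 else "internal")
        for d in deg
    ]


class ElasticPrincipalTree(BaseEstimator):
    """Elastic principal tree fitted to manifold coordinates.

    Parameters
    ----------
    n_nodes : int
        Number k of support nodes (default 100).
    mu, lam : float or None
        Elasticity constants; None uses ``elasticity_params(n_nodes)``.
    max_iter : int
        Maximum alternating iterations in the final optimization.
    tol : float
        Relative energy-change convergence threshold.

    The scaffold is passed to :meth:`fit`; when omitted, a scaffold is
    fitted internally in auto mode.

    Attributes
    ----------
    node_coords_ : (k, D) support-node positions.
    edges_ : list of node-index pairs.
    node_roles_ : 'endpoint' / 'branchpoint' / 'internal' per node.
    cell2node_ : nearest support node per cell (alias ``labels_``).
    energy_history_ : energies of the final optimization, non-increasing.
    endpoint_nodes_ : node indices of endpoints in scaffold detection order.
    """

    def __init__(self, n_nodes: int = DEFAULT_K, mu: float | None = None,
                 lam: float | None = None, max_iter: int = 100, tol: float = 1e-6):
        self.n_nodes = n_nodes
        self.mu = mu
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_parts(cls, node_coords, edges, node_roles, mu, lam, cell2node):
        tree = cls(n_nodes=len(node_coords), mu=mu, lam=lam)
        tree.node_coords_ = np.asarray(node_coords, float)
        tree.edges_ = [tuple(e) for e in edges]
        tree.node_roles_ = list(node_roles)
        tree.mu_ = float(mu)
        tree.lam_ = float(lam)
        tree.cell2node_ = np.asarray(cell2node, int)
        tree.endpoint_nodes_ = [
            i for i, r in enumerate(tree.node_roles_) if r == "endpoint"
        ]
        return tree

    @property
    def labels_(self) -> np.ndarray:
        return self.cell2node_

    @property
    def k_(self) -> int:
        return self.node_coords_.shape[0]

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y=None, scaffold=None) -> "ElasticPrincipalTree":
        coords = X.coords if isinstance(X, ManifoldCoords) else np.asarray(X, float)
        if scaffold is None:
            from .scaffold import ScaffoldTree

            scaffold = ScaffoldTree().fit(coords)
        k0 = len(scaffold.nodes_)
        if self.n_nodes < k0:
            raise ValueError(
                f"n_nodes ({self.n_nodes}) must be >= scaffold node count ({k0})"
            )
        if self.mu is None or self.lam is None:
            mu_d, lam_d = elasticity_params(max(self.n_nodes, 3))
            mu = mu_d if self.mu is None else self.mu
            lam = lam_d if self.lam is None else self.lam
        else:
            mu, lam = self.mu, self.lam

        V = coords[np.asarray(scaffold.nodes_)].copy()
        edges = [tuple(e) for e in scaffold.edges_nodeidx_]
        endpoint_nodes = [
            i for i, r in enumerate(scaffold.node_roles_) if r == "endpoint"
        ]

        # growth: optimize briefly, then split the longest edge at its midpoint
        labels = _assign(coords, V)
        while V.shape[0] < self.n_nodes:
            labels = _assign(coords, V)
            V = _solve_positions(coords, labels, edges, V.shape[0], mu, lam)
            V, edges = _split_longest_edge(V, edges)

        # final optimization at fixed topology
        history: list[float] = []
        prev = np.inf
        for _ in range(self.max_iter):
            labels = _assign(coords, V)
            V = _solve_positions(coords, labels, edges, V.shape[0], mu, lam)
            e = _energy(coords, V, labels, edges, mu, lam)
            history.append(e)
            if np.isfinite(prev) and prev - e <= self.tol * max(abs(prev), 1e-300):
                prev = e
                break
            prev = e
        else:
            if len(history) >= 2 and history[-2] - history[-1] > self.tol * abs(history[-2]):
                warnings.warn("elastic tree optimization did not converge; "
                              "returning best-so-far tree")
        labels = _assign(coords, V)

        self.node_coords_ = V
        self.edges_ = edges
        self.node_roles_ = _roles_from_degree(V.shape[0], edges)
        self.cell2node_ = labels
        self.mu_ = float(mu)
        self.lam_ = float(lam)
        self.energy_history_ = np.asarray(history)
        self.endpoint_nodes_ = endpoint_nodes
        self.scaffold_ = scaffold
        self._check_topology(scaffold)
        return self

    def _check_topology(self, scaffold) -> None:
        n_end = sum(r == "endpoint" for r in self.node_roles_)
        n_branch = sum(r == "branchpoint" for r in self.node_roles_)
        s_end = sum(r == "endpoint" for r in scaffold.node_roles_)
        s_branch = sum(r == "branchpoint" for r in scaffold.node_roles_)
        if (n_end, n_branch) != (s_end, s_branch):
            raise RuntimeError(
                "elastic optimization changed the scaffold topology: "
                f"({n_end}, {n_branch}) vs ({s_end}, {s_branch})"
            )

    # -- post-fit operations --------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Nearest support node for each row of X."""
        coords = X.coords if isinstance(X, ManifoldCoords) else np.asarray(X, float)
        return _assign(coords, self.node_coords_)

    def inflate(self, X) -> "ElasticPrincipalTree":
        """Copy of the tree with cells of ``X`` re-assigned to its nodes."""
        new = copy.deepcopy(self)
        new.cell2node_ = self.predict(X)
        return new

    def bisect(self, X=None) -> "ElasticPrincipalTree":
        """Split every edge at its midpoint, giving 2k - 1 support nodes.

        Elasticity constants are rescaled via :func:`elasticity_params`;
        when coordinates are given, cells are re-assigned to the new nodes.
        """
        V = self.node_coords_
        k = V.shape[0]
        newV = [V]
        new_edges: list[tuple[int, int]] = []
        nxt = k
        for a, b in self.edges_:
            mid = 0.5 * (V[a] + V[b])
            newV.append(mid[None, :])
            new_edges.append((a, nxt))
            new_edges.append((nxt, b))
            nxt += 1
        V2 = np.vstack(newV)
        mu, lam = elasticity_params(V2.shape[0])
        cell2node = self.cell2node_
        new = self._from_parts(
            V2, new_edges, _roles_from_degree(V2.shape[0], new_edges), mu, lam, cell2node
        )
        if X is not None:
            new.cell2node_ = new.predict(X)
        return new

    def energy(self, X) -> float:
        coords = X.coords if isinstance(X, ManifoldCoords) else np.asarray(X, float)
        labels = _assign(coords, self.node_coords_)
        return _energy(coords, self.node_coords_, labels, self.edges_, self.mu_, self.lam_)


def _split_longest_edge(V: np.ndarray, edges: list[tuple[int, int]]):
    lengths = np.array([np.sum((V[a] - V[b]) ** 2) for a, b in edges])
    idx = int(np.argmax(lengths))  # ties: smallest edge index
    a, b = edges[idx]
    mid = 0.5 * (V[a] + V[b])
    k = V.shape[0]
    V = np.vstack([V, mid[None, :]])
    edges = edges[:idx] + edges[idx + 1 :] + [(a, k), (k, b)]
    return V, edges


def fit_elastic_tree(
    coords,
    scaffold,
    k: int = DEFAULT_K,
    mu: float | None = None,
    lam: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ElasticPrincipalTree:
    """Functional wrapper over :class:`ElasticPrincipalTree`."""
    return ElasticPrincipalTree(
        n_nodes=k, mu=mu, lam=lam, max_iter=max_iter, tol=tol
    ).fit(coords, scaffold=scaffold)


def bisect_tree(tree: ElasticPrincipalTree, coords=None) -> ElasticPrincipalTree:
    """Functional wrapper over :meth:`ElasticPrincipalTree.bisect`."""
    return tree.bisect(coords)
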