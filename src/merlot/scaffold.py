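"""Scaffold-tree reconstruction in the manifold.

The scaffold tree locates the endpoints and branchpoints of a lineage tree
among the cells themselves.  All-pairs shortest paths are computed on the
complete graph over cells with squared Euclidean edge weights — squaring is
essential: with plain distances the direct edge (i, j) is always shortest,
while squared weights make paths through intermediate cells cheaper, so the
shortest path follows the data density.

``S[i, j]`` counts the cells on the shortest path between i and j
(inclusive).  Endpoints are grown greedily by the gain criterion

    s_E(n) = 0.5 * min{ S_kn + S_nl - S_kl : k, l in E },

the number of cells a candidate endpoint adds to the tree.  In auto mode
candidates are accepted while the maximal gain exceeds sqrt(N); the first
candidate below that threshold gets one last chance: the tree is
provisionally connected and the candidate is kept only if its new branch
attracts more than ``MinBranchCells = sqrt(N)`` cells.  Endpoints are then
connected through branchpoint cells with the neighbor-joining criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator

from .manifold import ManifoldCoords

__all__ = [
    "PathStats",
    "ScaffoldTree",
    "shortest_path_cell_counts",
    "endpoint_gain",
    "find_endpoints",
    "connect_endpoints",
    "assign_branches",
]


@dataclass
class PathStats:
    """All-pairs shortest-path summary over the complete cell graph.

    S : symmetric integer matrix, S[i, j] = cells on the shortest path
        (both ends included); S[i, i] = 1.
    D2 : total squared-Euclidean length of each shortest path.
    predecessors : predecessor matrix for path reconstruction.
    """

    S: np.ndarray
    D2: np.ndarray
    predecessors: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]

    def path(self, i: int, j: int) -> np.ndarray:
        """Cell-index sequence of the shortest path from i to j."""
        if i == j:
            return np.array([i])
        seq = [j]
        k = j
        while k != i:
            k = int(self.predecessors[i, k])
            if k < 0:
                raise ValueError(f"no path between {i} and {j}")
            seq.append(k)
        return np.array(seq[::-1])


def shortest_path_cell_counts(coords: ManifoldCoords | np.ndarray) -> PathStats:
    """All-pairs shortest paths with squared Euclidean edge weights."""
    X = coords.coords if isinstance(coords, ManifoldCoords) else np.asarray(coords, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    W = squareform(pdist(X, metric="sqeuclidean"))
    # dense csgraph treats zeros as missing edges; keep duplicate-point edges
    tiny = np.finfo(float).tiny
    off = ~np.eye(n, dtype=bool)
    W[off & (W == 0)] = tiny

    D2, pred = shortest_path(W, method="auto", directed=False, return_predecessors=True)

    # count cells along each path by dynamic programming over the
    # predecessor structure, processing targets in order of distance
    S = np.ones((n, n), dtype=np.int64)
    for i in range(n):
        order = np.argsort(D2[i], kind="stable")
        row_pred = pred[i]
        row_S = S[i]
        for j in order:
            if j == i:
                continue
            p = row_pred[j]
            row_S[j] = row_S[p] + 1
    # symmetrize from the lower-index source (tie paths may differ by direction)
    iu = np.triu_indices(n, 1)
    S[(iu[1], iu[0])] = S[iu]
    D2[(iu[1], iu[0])] = D2[iu]
    return PathStats(S=S, D2=D2, predecessors=pred)


def endpoint_gain(stats: PathStats, endpoints, n: int) -> float:
    """Cells a candidate endpoint n would add to the current tree."""
    E = list(endpoints)
    if len(E) < 2:
        raise ValueError("need at least 2 endpoints")
    if n in E:
        raise ValueError("candidate is already an endpoint")
    S = stats.S
    E = np.asarray(E)
    # min over unordered pairs k != l (S symmetric, so ordered == unordered)
    sk = S[E, n]
    best = np.inf
    for a in range(len(E)):
        for b in range(a + 1, len(E)):
            v = sk[a] + sk[b] - S[E[a], E[b]]
            if v < best:
                best = v
    return 0.5 * float(best)


def _gain_all(stats: PathStats, E: list[int]) -> np.ndarray:
    """Vectorized endpoint gain for every cell (members of E set to -inf)."""
    S = stats.S.astype(float)
    Ea = np.asarray(E)
    sk = S[Ea, :]  # |E| × N
    n = S.shape[0]
    best = np.full(n, np.inf)
    for a in range(len(Ea)):
        for b in range(a + 1, len(Ea)):
            np.minimum(best, sk[a] + sk[b] - S[Ea[a], Ea[b]], out=best)
    gains = 0.5 * best
    gains[Ea] = -np.inf
    return gains


def _seed_pair(stats: PathStats) -> tuple[int, int]:
    """Pair maximizing the cell count S_kl; ties broken by the longest total
    path length, then by smallest indices."""
    S, D2 = stats.S, stats.D2
    n = S.shape[0]
    iu = np.triu_indices(n, 1)
    counts = S[iu]
    best = counts.max()
    cand = np.flatnonzero(counts == best)
    lengths = D2[iu][cand]
    cand = cand[lengths == lengths.max()]
    k = int(iu[0][cand[0]])
    l = int(iu[1][cand[0]])
    return k, l


@dataclass
class _NJTree:
    nodes: list[int]  # cell indices, endpoints first
    roles: list[str]  # "endpoint" | "branchpoint"
    edges: list[tuple[int, int]]  # indices into nodes
    branch_paths: list[np.ndarray]  # cell-index path per edge


def connect_endpoints(stats: PathStats, endpoints) -> _NJTree:
    """Join endpoints through branchpoint cells by neighbor joining.

    While more than two nodes remain unprocessed, the pair (k, l) with
    minimal NJ distance ``S_kl - (sum_m S_mk + S_ml) / (|V| - 2)`` is
    replaced by the branchpoint cell m minimizing
    ``S_km + S_lm + sum_{n in V\\{k,l}} S_nm / (|V| - 2)``.  The same cell
    may be picked as branchpoint more than once; repeats are merged into a
    single tree node.
    """
    E = [int(e) for e in endpoints]
    if len(E) < 2:
        raise ValueError("need at least 2 endpoints")
    S = stats.S.astype(float)
    n = S.shape[0]

    cells: list[int] = list(E)  # tree nodes as cell indices (unique)
    roles: list[str] = ["endpoint"] * len(E)
    edges: set[tuple[int, int]] = set()  # pairs of cell indices

    def add_edge(a: int, b: int) -> None:
        if a == b:
            return
        edges.add((min(a, b), max(a, b)))

    def ensure_node(c: int, role: str) -> None:
        if c not in cells:
            cells.append(c)
            roles.append(role)

    V = list(E)
    while len(V) > 2:
        m_v = len(V)
        # Eq.-style NJ pair selection; ties by smallest (k, l)
        best = (np.inf, None)
        Va = np.asarray(V)
        colsum = S[Va][:, Va].sum(axis=0)  # sum_m S_m,v over V
        for a in range(m_v):
            for b in range(a + 1, m_v):
                d = S[Va[a], Va[b]] - (colsum[a] + colsum[b]) / (m_v - 2)
                key = (d, (min(Va[a], Va[b]), max(Va[a], Va[b])))
                if key < (best[0], best[1] if best[1] else (n, n)):
                    best = (d, key[1], (a, b))
        _, (k, l), (ai, bi) = best

        # branchpoint cell: minimal distance to k, l and on average to the rest
        rest = [v for v in V if v != k and v != l]
        crit = S[k] + S[l]
        if rest:
            crit = crit + S[np.asarray(rest)].sum(axis=0) / (m_v - 2)
        crit = crit.copy()
        crit[[k, l]] = np.inf  # no self-edges
        # endpoints keep degree 1: they are never branchpoint candidates
        # (already-chosen branchpoints may be re-selected and merged)
        masked = crit.copy()
        masked[list(E)] = np.inf
        if np.isfinite(masked).any():
            crit = masked  # tiny inputs where all cells are endpoints keep crit
        m = int(np.argmin(crit))  # ties: smallest cell index

        ensure_node(m, "branchpoint")
        add_edge(k, m)
        add_edge(l, m)
        V = [v for v in V if v != k and v != l]
        if m not in V:
            V.append(m)

    if len(V) == 2:
        add_edge(V[0], V[1])

    index = {c: i for i, c in enumerate(cells)}
    edge_list = sorted((index[a], index[b]) for a, b in edges)
    paths = [stats.path(cells[a], cells[b]) for a, b in edge_list]
    return _NJTree(nodes=cells, roles=roles, edges=edge_list, branch_paths=paths)


def assign_branches(branch_paths: list[np.ndarray], coords) -> np.ndarray:
    """Map every cell to the branch holding its nearest path cell.

    Ties are broken toward the lowest branch index.
    """
    X = coords.coords if isinstance(coords, ManifoldCoords) else np.asarray(coords, float)
    if not branch_paths:
        raise ValueError("tree has no branches")
    path_cells = np.concatenate(branch_paths)
    path_branch = np.concatenate(
        [np.full(len(p), b, dtype=int) for b, p in enumerate(branch_paths)]
    )
    d = cdist(X, X[path_cells], metric="sqeuclidean")
    # order path cells by branch index so argmin ties resolve to low branches
    order = np.argsort(path_branch, kind="stable")
    nearest = np.argmin(d[:, order], axis=1)
    return path_branch[order][nearest]


class ScaffoldTree(BaseEstimator):
    """Scaffold lineage tree over manifold coordinates.

    Parameters
    ----------
    mode : 'auto' or 'fixed'
        'auto' grows endpoints until the gain criterion and branch-size
        check fail; 'fixed' adds exactly ``n_endpoints`` regardless of
        branch size.
    n_endpoints : int, required in fixed mode.
    min_branch_cells : int or 'auto'
        Minimum cells a new branch must attract in auto mode
        (default round(sqrt(N))).

    Attributes
    ----------
    endpoints_ : endpoint cell indices in detection order.
    branchpoints_ : branchpoint cell indices (merged, unique).
    nodes_ : all tree-node cell indices (endpoints first).
    node_roles_ : 'endpoint' / 'branchpoint' per node.
    edges_nodeidx_ : edges as pairs of indices into ``nodes_``.
    branch_paths_ : cell-index sequence of each branch.
    labels_ : branch label per cell.
    path_stats_ : the :class:`PathStats` used.
    """

    def __init__(self, mode: str = "auto", n_endpoints: int | None = None,
                 min_branch_cells: int | str = "auto"):
        self.mode = mode
        self.n_endpoints = n_endpoints
        self.min_branch_cells = min_branch_cells

    def fit(self, X, y=None) -> "ScaffoldTree":
        coords = X.coords if isinstance(X, ManifoldCoords) else np.asarray(X, float)
        n = coords.shape[0]
        stats = shortest_path_cell_counts(coords)
        endpoints = find_endpoints(
            coords,
            mode=self.mode,
            n_endpoints=self.n_endpoints,
            min_branch_cells=self.min_branch_cells,
            stats=stats,
        )[0]
        nj = connect_endpoints(stats, endpoints)
        self.endpoints_ = list(endpoints)
        self.branchpoints_ = [c for c, r in zip(nj.nodes, nj.roles) if r == "branchpoint"]
        self.nodes_ = np.asarray(nj.nodes)
        self.node_roles_ = list(nj.roles)
        self.edges_nodeidx_ = list(nj.edges)
        self.branch_paths_ = nj.branch_paths
        self.labels_ = assign_branches(nj.branch_paths, coords)
        self.path_stats_ = stats
        self.n_cells_ = n
        self._check_tree()
        return self

    def _check_tree(self) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes_)))
        g.add_edges_from(self.edges_nodeidx_)
        if not nx.is_tree(g):
            raise RuntimeError("scaffold construction produced a non-tree graph")


def find_endpoints(
    coords,
    mode: str = "auto",
    n_endpoints: int | None = None,
    min_branch_cells: int | str = "auto",
    stats: PathStats | None = None,
) -> tuple[list[int], PathStats]:
    """Locate endpoint cells by the greedy gain criterion.

    Returns the endpoint list (in detection order) and the path statistics.
    """
    X = coords.coords if isinstance(coords, ManifoldCoords) else np.asarray(coords, float)
    n = X.shape[0]
    if stats is None:
        stats = shortest_path_cell_counts(X)
    if mode not in ("auto", "fixed"):
        raise ValueError("mode must be 'auto' or 'fixed'")
    if mode == "fixed":
        if n_endpoints is None or n_endpoints < 2:
            raise ValueError("fixed mode requires n_endpoints >= 2")
        if n_endpoints > n:
            raise ValueError("n_endpoints cannot exceed the number of cells")
    thresh = np.sqrt(n)
    if min_branch_cells == "auto":
        min_branch_cells = int(round(thresh))

    k, l = _seed_pair(stats)
    E = [k, l]

    if mode == "fixed":
        while len(E) < n_endpoints:
            gains = _gain_all(stats, E)
            E.append(int(np.argmax(gains)))
        return E, stats

    while len(E) < n:
        gains = _gain_all(stats, E)
        cand = int(np.argmax(gains))
        if gains[cand] > thresh:
            E.append(cand)
            continue
        # last chance: provisionally connect with the candidate and keep it
        # only if its branch attracts more than MinBranchCells cells
        if not np.isfinite(gains[cand]):
            break
        nj = connect_endpoints(stats, E + [cand])
        labels = assign_branches(nj.branch_paths, X)
        cand_node = nj.nodes.index(cand)
        new_branches = [
            b for b, (a, bb) in enumerate(nj.edges) if cand_node in (a, bb)
        ]
        branch_size = int(np.isin(labels, new_branches).sum())
        if branch_size > min_branch_cells:
            E.append(cand)
            continue
        break
    return E, stats
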