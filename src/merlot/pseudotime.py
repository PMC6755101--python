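"""Pseudotime along the tree.

Pseudotime is the number of tree edges separating a support node from the
chosen initial node t0; cells inherit the pseudotime of their nearest node,
or a continuous value by orthogonal projection onto the edge between their
nearest node and its nearest tree neighbor.  Both the manifold-space tree
and the expression-space embedding expose the attributes this module needs
(`node_coords_`, `edges_`, `cell2node_`, `endpoint_nodes_`), so pseudotime
can be computed in either space.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "PseudotimeAssignment",
    "assign_pseudotime",
    "longest_trajectory",
    "gene_profile",
]


@dataclass
class PseudotimeAssignment:
    t0_node: int
    node_times: np.ndarray  # edge counts from t0, length k
    cell_times: np.ndarray  # per cell, integer or continuous
    space: str = "manifold"


def _tree_graph(tree) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(tree.node_coords_.shape[0]))
    g.add_edges_from(tree.edges_)
    return g


def _resolve_t0(tree, t0, t0_cell, X) -> int:
    k = tree.node_coords_.shape[0]
    if t0_cell is not None:
        cell2node = np.asarray(tree.cell2node_)
        return int(cell2node[int(t0_cell)])
    if t0 == "auto":
        # one of the first two detected endpoints: take the first
        return int(tree.endpoint_nodes_[0])
    t0 = int(t0)
    if not 0 <= t0 < k:
        raise ValueError(f"t0 node {t0} not in tree (k = {k})")
    return t0


def assign_pseudotime(
    tree,
    t0: int | str = "auto",
    t0_cell: int | None = None,
    continuous: bool = False,
    X=None,
    space: str = "manifold",
) -> PseudotimeAssignment:
    """Assign pseudotime to support nodes and cells.

    Parameters
    ----------
    tree : fitted ElasticPrincipalTree or GeneSpaceEmbedding.
    t0 : node id or 'auto' (first detected endpoint).
    t0_cell : cell index; its nearest node becomes t0 (overrides ``t0``).
    continuous : bool
        Project each cell onto the edge between its nearest node and that
        node's nearest tree neighbor, interpolating linearly (clamped to
        the segment ends).  Requires the cell coordinates ``X`` in the
        tree's space.
    """
    g = _tree_graph(tree)
    root = _resolve_t0(tree, t0, t0_cell, X)
    dist = nx.single_source_shortest_path_length(g, root)
    k = tree.node_coords_.shape[0]
    node_times = np.full(k, -1, dtype=float)
    for n, d in dist.items():
        node_times[n] = d
    if np.any(node_times < 0):
        raise ValueError("tree is not connected")

    cell2node = np.asarray(tree.cell2node_)
    if not continuous:
        cell_times = node_times[cell2node]
    else:
        if X is None:
            raise ValueError("continuous pseudotime requires cell coordinates X")
        coords = X.coords if hasattr(X, "coords") else np.asarray(X, float)
        V = tree.node_coords_
        cell_times = np.empty(len(cell2node))
        neighbors = {n: list(g.neighbors(n)) for n in g.nodes}
        for i, j in enumerate(cell2node):
            nbrs = neighbors[int(j)]
            x = coords[i]
            # nearest neighbor of the nearest node
            h = min(nbrs, key=lambda m: (float(np.sum((x - V[m]) ** 2)), m))
            a, b = V[j], V[h]
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else float(np.clip((x - a) @ ab / denom, 0.0, 1.0))
            cell_times[i] = node_times[j] + t * (node_times[h] - node_times[j])
    return PseudotimeAssignment(
        t0_node=root,
        node_times=node_times,
        cell_times=np.asarray(cell_times, float),
        space=space,
    )


def longest_trajectory(tree, times: PseudotimeAssignment | None = None) -> list[int]:
    """Endpoint-to-endpoint node path with the most pseudotime steps.

    Ties are broken toward the smallest endpoint-index pair.
    """
    g = _tree_graph(tree)
    endpoints = sorted(n for n in g.nodes if g.degree[n] == 1)
    if len(endpoints) < 2:
        return list(g.nodes)
    best_len = -1
    best_path: list[int] = []
    for ia, a in enumerate(endpoints):
        lengths, paths = nx.single_source_shortest_path_length(g, a), nx.single_source_shortest_path(g, a)
        for b in endpoints[ia + 1 :]:
            if lengths[b] > best_len:
                best_len = lengths[b]
                best_path = paths[b]
    return best_path


def gene_profile(
    embedded,
    times: PseudotimeAssignment,
    gene,
    path: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudotime series of one gene's imputed expression along a path.

    ``gene`` may be a gene id (when the embedding carries ``gene_ids_``)
    or a column index.  Returns (node pseudotimes, expression values)
    ordered by time along the path.
    """
    profiles = embedded.pseudocell_profiles_
    if isinstance(gene, str):
        gene_ids = getattr(embedded, "gene_ids_", None)
        if gene_ids is None or gene not in gene_ids:
            raise KeyError(f"unknown gene {gene!r}")
        col = gene_ids.index(gene)
    else:
        col = int(gene)
        if not 0 <= col < profiles.shape[1]:
            raise KeyError(f"gene index {col} out of range")
    if path is None:
        path = longest_trajectory(embedded, times)
    path = list(path)
    t = times.node_times[path]
    y = profiles[path, col]
    order = np.argsort(t, kind="stable")
    return t[order], y[order]
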