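"""Embedding the elastic tree into gene-expression space.

Each support node of the manifold-space tree is mapped one-to-one to a
*pseudocell* in the G-dimensional expression space: the node profile is
initialized with the mean expression of the cells assigned to the node
(zero vector for empty nodes) and the elastic optimizer is re-run in
expression space with the topology fixed and no node growth.  The result
is a set of imputed, smoothed expression profiles along the tree, and a
re-assignment of cells to nodes in the full-dimensional space which can in
turn refine cell pseudotimes.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .elastic import ElasticPrincipalTree, _assign, _energy, _solve_positions
from .io import ExpressionMatrix

__all__ = ["GeneSpaceEmbedding", "init_pseudocells", "embed_in_expression_space"]


def _values(expr) -> np.ndarray:
    return expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)


def init_pseudocells(expr, tree) -> np.ndarray:
    """Initial pseudocell profiles: mean expression of the cells assigned
    to each support node; nodes with no cells get a null vector."""
    X = _values(expr)
    labels = np.asarray(tree.cell2node_)
    if X.shape[0] != labels.shape[0]:
        raise ValueError(
            f"expression rows ({X.shape[0]}) do not match tree cell "
            f"assignment length ({labels.shape[0]})"
        )
    k = tree.node_coords_.shape[0]
    profiles = np.zeros((k, X.shape[1]))
    np.add.at(profiles, labels, X)
    counts = np.bincount(labels, minlength=k).astype(float)
    nz = counts > 0
    profiles[nz] /= counts[nz, None]
    return profiles


class GeneSpaceEmbedding(BaseEstimator):
    """Elastic-tree embedding into gene-expression space.

    Parameters
    ----------
    mu, lam : float or None
        Elasticity constants; None reuses those of the source tree.
    max_iter, tol : optimization controls as in :class:`ElasticPrincipalTree`.

    Attributes
    ----------
    pseudocell_profiles_ : (k, G) imputed expression per support node.
    node_coords_ : alias of ``pseudocell_profiles_`` (the tree lives in
        expression space after embedding).
    edges_, node_roles_, endpoint_nodes_ : copied from the source tree.
    cell2node_ : assignment of cells to nodes in expression space.
    energy_history_ : non-increasing elastic energies per iteration.
    """

    def __init__(self, mu: float | None = None, lam: float | None = None,
                 max_iter: int = 100, tol: float = 1e-6):
        self.mu = mu
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, tree: ElasticPrincipalTree | None = None) -> "GeneSpaceEmbedding":
        if tree is None:
            raise ValueError("a fitted manifold-space tree is required")
        vals = _values(X)
        mu = tree.mu_ if self.mu is None else self.mu
        lam = tree.lam_ if self.lam is None else self.lam
        edges = [tuple(e) for e in tree.edges_]
        k = tree.node_coords_.shape[0]

        P = init_pseudocells(X, tree)
        if not np.any(vals):
            warnings.warn("all-zero expression matrix; pseudocell profiles are zero")
            labels = _assign(vals, P)
            history = [0.0]
        else:
            history = []
            prev = np.inf
            for _ in range(self.max_iter):
                labels = _assign(vals, P)
                P = _solve_positions(vals, labels, edges, k, mu, lam)
                e = _energy(vals, P, labels, edges, mu, lam)
                history.append(e)
                if np.isfinite(prev) and prev - e <= self.tol * max(abs(prev), 1e-300):
                    break
                prev = e
            labels = _assign(vals, P)

        self.pseudocell_profiles_ = P
        self.node_coords_ = P
        self.edges_ = edges
        self.node_roles_ = list(tree.node_roles_)
        self.endpoint_nodes_ = list(tree.endpoint_nodes_)
        self.cell2node_ = labels
        self.mu_ = float(mu)
        self.lam_ = float(lam)
        self.energy_history_ = np.asarray(history)
        if isinstance(X, ExpressionMatrix):
            self.gene_ids_ = list(X.gene_ids)
        return self

    @property
    def labels_(self) -> np.ndarray:
        return self.cell2node_


def embed_in_expression_space(
    expr,
    tree: ElasticPrincipalTree,
    mu: float | None = None,
    lam: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GeneSpaceEmbedding:
    """Functional wrapper over :class:`GeneSpaceEmbedding`."""
    return GeneSpaceEmbedding(mu=mu, lam=lam, max_iter=max_iter, tol=tol).fit(
        expr, tree=tree
    )
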