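"""Branch-level differential expression and gene-correlation networks.

Differential expression between two cell groups (e.g. two branches, or one
branch against the rest of the tree) uses the Kruskal-Wallis rank sum test
per gene, with tie-corrected H statistic and the chi-square approximation
for the p-value.  Bonferroni-style e-values are p * G for G genes tested;
genes with e < 1e-3 are called differentially expressed by default.

The gene-correlation network keeps gene pairs whose Pearson correlation
passes a threshold (|r| by default, so strongly anti-correlated programs
are representable; the sign is stored as the edge weight) and clusters the
network with the walktrap random-walk community algorithm, dissolving
modules below a minimum size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

__all__ = [
    "DE_EVALUE_THRESHOLD",
    "CorrelationNetwork",
    "de_kruskal_wallis",
    "kruskal_wallis_h",
    "build_correlation_network",
    "cluster_network",
]

DE_EVALUE_THRESHOLD = 1e-3


def kruskal_wallis_h(values_a: np.ndarray, values_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group Kruskal-Wallis over gene columns.

    Returns (H, p) arrays; constant genes give H = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(values_a, float))
    b = np.atleast_2d(np.asarray(values_b, float))
    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    pooled = np.vstack([a, b])
    ranks = sps.rankdata(pooled, axis=0)
    ra = ranks[:na].mean(axis=0)
    rb = ranks[na:].mean(axis=0)
    mid = (n + 1) / 2.0
    H = 12.0 / (n * (n + 1)) * (na * (ra - mid) ** 2 + nb * (rb - mid) ** 2)
    # tie correction per gene: 1 - sum(t^3 - t) / (n^3 - n)
    corr = np.empty(pooled.shape[1])
    for g in range(pooled.shape[1]):
        _, counts = np.unique(pooled[:, g], return_counts=True)
        corr[g] = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    H = np.where(corr > 0, H / np.where(corr > 0, corr, 1.0), 0.0)
    p = np.where(corr > 0, sps.chi2.sf(H, df=1), 1.0)
    return H, p


def de_kruskal_wallis(
    expr: ExpressionMatrix | np.ndarray,
    group_a,
    group_b=None,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Kruskal-Wallis test between two cell groups.

    ``group_a``/``group_b`` are cell-index arrays or boolean masks; when
    ``group_b`` is omitted the comparison is against all remaining cells.
    Returns the full gene table sorted by ascending p-value with columns
    gene, H, p_value, e_value (= p * G), mean_diff (mean_a - mean_b) and
    the boolean DE call at e < 1e-3.
    """
    if isinstance(expr, ExpressionMatrix):
        values = expr.values
        gene_ids = gene_ids or expr.gene_ids
    else:
        values = np.asarray(expr, float)
        gene_ids = gene_ids or [f"gene_{j}" for j in range(values.shape[1])]
    n = values.shape[0]
    ia = _as_index(group_a, n)
    if group_b is None:
        mask = np.ones(n, bool)
        mask[ia] = False
        ib = np.flatnonzero(mask)
    else:
        ib = _as_index(group_b, n)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")

    H, p = kruskal_wallis_h(values[ia], values[ib])
    G = values.shape[1]
    table = pd.DataFrame(
        {
            "gene": gene_ids,
            "H": H,
            "p_value": p,
            "e_value": p * G,
            "mean_diff": values[ia].mean(axis=0) - values[ib].mean(axis=0),
        }
    )
    table["significant"] = table["e_value"] < DE_EVALUE_THRESHOLD
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def _as_index(group, n: int) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if group.size != n:
            raise ValueError("boolean group mask has wrong length")
        return np.flatnonzero(group)
    return group.astype(int)


@dataclass
class CorrelationNetwork:
    """Thresholded Pearson-correlation graph over genes."""

    genes: list[str]
    edges: list[tuple[int, int, float]]  # (gene idx, gene idx, signed r)
    threshold: float
    excluded: list[str] = field(default_factory=list)  # zero-variance genes
    modules: list[list[int]] = field(default_factory=list)
    unclustered: list[int] = field(default_factory=list)

    def to_igraph(self, absolute: bool = True):
        import igraph as ig

        g = ig.Graph()
        g.add_vertices(len(self.genes))
        g.vs["name"] = list(self.genes)
        g.add_edges([(a, b) for a, b, _ in self.edges])
        g.es["weight"] = [abs(w) if absolute else w for _, _, w in self.edges]
        g.es["r"] = [w for _, _, w in self.edges]
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.genes[a], self.genes[b], w) for a, b, w in self.edges],
            columns=["gene_a", "gene_b", "r"],
        )


def build_correlation_network(
    profiles,
    threshold: float = 0.9,
    gene_ids: list[str] | None = None,
    signed: bool = False,
) -> CorrelationNetwork:
    """Pairwise Pearson correlations between genes, thresholded into a graph.

    ``profiles`` is a profiles × genes matrix — imputed pseudocell profiles
    give far cleaner networks than raw cells.  Edges keep pairs with
    |r| >= threshold (or r >= threshold when ``signed``); the signed r is
    stored as the weight.  Zero-variance genes are excluded with a warning.
    """
    if isinstance(profiles, ExpressionMatrix):
        gene_ids = gene_ids or profiles.gene_ids
        profiles = profiles.values
    P = np.asarray(profiles, float)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 profiles to correlate genes")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    gene_ids = gene_ids or [f"gene_{j}" for j in range(P.shape[1])]

    var = P.var(axis=0)
    keep = var > 0
    excluded = [g for g, k in zip(gene_ids, keep) if not k]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance genes from the network")
    kept_idx = np.flatnonzero(keep)
    R = np.corrcoef(P[:, kept_idx].T) if kept_idx.size >= 2 else np.zeros((kept_idx.size,) * 2)

    edges: list[tuple[int, int, float]] = []
    m = kept_idx.size
    for a in range(m):
        row = R[a]
        sel = row[a + 1 :]
        hits = np.flatnonzero((sel >= threshold) if signed else (np.abs(sel) >= threshold))
        for h in hits:
            b = a + 1 + h
            edges.append((int(kept_idx[a]), int(kept_idx[b]), float(R[a, b])))
    return CorrelationNetwork(genes=list(gene_ids), edges=edges, threshold=threshold,
                              excluded=excluded)


def cluster_network(net: CorrelationNetwork, min_size: int = 3) -> CorrelationNetwork:
    """Walktrap community detection on absolute edge weights.

    Modules smaller than ``min_size`` are dissolved; their genes are
    reported as unclustered.  Genes with no retained edges are unclustered
    as well.  Returns the network with ``modules`` and ``unclustered``
    filled in.
    """
    if not net.edges:
        net.modules = []
        net.unclustered = sorted({i for i in range(len(net.genes))})
        return net
    g = net.to_igraph(absolute=True)
    communities = g.community_walktrap(weights="weight").as_clustering()
    connected = {a for a, _, _ in net.edges} | {b for _, b, _ in net.edges}
    modules: list[list[int]] = []
    unclustered: list[int] = [i for i in range(len(net.genes)) if i not in connected]
    for member_ids in communities:
        members = [i for i in member_ids if i in connected]
        if not members:
            continue
        if len(members) >= min_size:
            modules.append(sorted(members))
        else:
            unclustered.extend(members)
    net.modules = modules
    net.unclustered = sorted(unclustered)
    return net
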