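"""Simulation of branched scRNA-seq datasets with ground truth.

Datasets are generated in four steps: (i) a random binary-tree topology is
grown by repeatedly attaching a bifurcation to a random endpoint branch;
(ii) average expression levels mu_g(t, b) are simulated per pseudotime
step and branch; (iii) cells are sampled uniformly along each branch;
(iv) UMI counts are drawn from a negative binomial around mu_g(t, b).

The expression-level model is a latent-program random walk: a small number
of expression programs perform independent Gaussian random walks along
pseudotime, each child branch continuing from its parent's final state so
means are continuous across branchpoints and sibling branches diverge the
further they get from the branchpoint.  Gene means are a softplus of a
random linear mixture of the programs, globally scaled to a target mean
library size.  The negative binomial uses the mean/dispersion
parameterization, variance = mu + mu^2 / dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Branch",
    "SimTopology",
    "SimulatedDataset",
    "random_topology",
    "simulate_means",
    "sample_cells",
    "draw_counts",
    "simulate_dataset",
]

# study-condition defaults
DEFAULT_BRANCH_LENGTH = 40  # pseudotime steps per branch
DEFAULT_GENES = 500
DEFAULT_PROGRAMS = 10
DEFAULT_DIFFUSION_SD = 0.7  # per-step sd of the program random walks
DEFAULT_DISPERSION = 3.0  # NB dispersion r (variance = mu + mu^2/r)
DEFAULT_LIB_SIZE = 5000.0  # target mean total counts per cell


@dataclass
class Branch:
    id: int
    parent: int | None
    length: int  # pseudotime steps
    start: int  # absolute pseudotime of the branch's first step


@dataclass
class SimTopology:
    """Branched lineage-tree layout with per-branch pseudotime ranges."""

    branches: list[Branch]
    n_bifurcations: int
    seed: int | None = None

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def leaves(self) -> list[int]:
        parents = {b.parent for b in self.branches if b.parent is not None}
        return [b.id for b in self.branches if b.id not in parents]

    @property
    def n_endpoints(self) -> int:
        # every leaf tip plus the root's starting point
        return len(self.leaves) + 1

    @property
    def n_branchpoints(self) -> int:
        return self.n_bifurcations

    def children(self, branch_id: int) -> list[int]:
        return [b.id for b in self.branches if b.parent == branch_id]

    def newick(self) -> str:
        def subtree(bid: int) -> str:
            b = self.branches[bid]
            kids = self.children(bid)
            label = f"B{bid}:{b.length}"
            if not kids:
                return label
            return "(" + ",".join(subtree(c) for c in kids) + ")" + label

        return subtree(0) + ";"

    def longest_path_branches(self) -> list[int]:
        """Branches on the endpoint-to-endpoint path with most pseudotime
        steps (the longest trajectory of the true tree)."""
        import networkx as nx

        g = nx.Graph()
        # junction nodes: -1 is the root start; branch id b ends at node b
        for b in self.branches:
            top = -1 if b.parent is None else b.parent
            g.add_edge(top, b.id, weight=b.length, branch=b.id)
        tips = [-1] + self.leaves
        best = (-1, None)
        for i, a in enumerate(tips):
            lengths = nx.single_source_dijkstra_path_length(g, a, weight="weight")
            for c in tips[i + 1 :]:
                if lengths[c] > best[0]:
                    best = (lengths[c], (a, c))
        a, c = best[1]
        node_path = nx.shortest_path(g, a, c)
        return [g.edges[u, v]["branch"] for u, v in zip(node_path, node_path[1:])]


def random_topology(
    n_bifurcations: int,
    branch_length: int = DEFAULT_BRANCH_LENGTH,
    seed: int | None = None,
) -> SimTopology:
    """Grow a binary lineage tree by adding bifurcations to random endpoints."""
    if n_bifurcations < 0:
        raise ValueError("n_bifurcations must be >= 0")
    rng = np.random.default_rng(seed)
    branches = [Branch(id=0, parent=None, length=branch_length, start=0)]
    leaves = [0]
    for _ in range(n_bifurcations):
        pick = int(rng.integers(len(leaves)))
        parent = leaves.pop(pick)
        p = branches[parent]
        for _ in range(2):
            nid = len(branches)
            branches.append(
                Branch(id=nid, parent=parent, length=branch_length,
                       start=p.start + p.length)
            )
            leaves.append(nid)
    return SimTopology(branches=branches, n_bifurcations=n_bifurcations, seed=seed)


def simulate_means(
    top: SimTopology,
    n_genes: int = DEFAULT_GENES,
    n_programs: int = DEFAULT_PROGRAMS,
    diffusion_sd: float = DEFAULT_DIFFUSION_SD,
    lib_size: float = DEFAULT_LIB_SIZE,
    seed: int | None = None,
) -> dict[int, np.ndarray]:
    """Average expression mu_g(t, b) for every branch.

    Returns a dict mapping branch id to an array of shape
    (branch length, n_genes); row r is the mean vector at the branch's
    pseudotime step ``start + r``.  Means are strictly positive, continuous
    across branchpoints, and constant when ``diffusion_sd`` is 0.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    # gene loadings on programs and baseline log-level
    W = rng.normal(0.0, 1.0 / np.sqrt(n_programs), size=(n_programs, n_genes))
    base = rng.normal(1.0, 0.5, size=n_genes)

    # program random walks, children seeded with the parent's final state
    prog_end: dict[int, np.ndarray] = {}
    walks: dict[int, np.ndarray] = {}
    for b in top.branches:  # parents precede children by construction
        w0 = np.zeros(n_programs) if b.parent is None else prog_end[b.parent]
        steps = rng.normal(0.0, diffusion_sd, size=(b.length, n_programs))
        steps[0] = 0.0  # first step continues exactly from the parent
        walk = w0[None, :] + np.cumsum(steps, axis=0)
        walks[b.id] = walk
        prog_end[b.id] = walk[-1]

    means = {b.id: _softplus(base[None, :] + walks[b.id] @ W) for b in top.branches}
    # single global scale to the target mean library size
    mean_total = float(np.mean([m.sum(axis=1).mean() for m in means.values()]))
    scale = lib_size / mean_total
    return {bid: m * scale for bid, m in means.items()}


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(x, 0.0)


def sample_cells(
    top: SimTopology,
    cells_per_branch: int = 50,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (t, b) labels: exactly ``cells_per_branch`` cells per branch,
    pseudotime steps uniform over each branch's range.

    Returns (within-branch step index, branch id) arrays; the absolute
    pseudotime is ``top.branches[b].start + t``.
    """
    if cells_per_branch < 1:
        raise ValueError("cells_per_branch must be >= 1")
    rng = np.random.default_rng(seed)
    ts, bs = [], []
    for b in top.branches:
        ts.append(rng.integers(0, b.length, size=cells_per_branch))
        bs.append(np.full(cells_per_branch, b.id))
    return np.concatenate(ts), np.concatenate(bs)


def draw_counts(
    means: dict[int, np.ndarray],
    t: np.ndarray,
    b: np.ndarray,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int | None = None,
) -> np.ndarray:
    """Draw UMI counts ~ NB(mean = mu_g(t, b), dispersion r).

    variance = mu + mu^2 / r; reproducible under a fixed seed.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    mu = np.vstack([means[int(bb)][int(tt)] for tt, bb in zip(t, b)])
    if np.any(mu <= 0):
        raise ValueError("negative-binomial means must be positive")
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


@dataclass
class SimulatedDataset:
    """Counts plus ground-truth branch labels, pseudotimes and topology."""

    counts: np.ndarray
    true_branch: np.ndarray
    true_time: np.ndarray  # absolute pseudotime (branch start + step)
    topology: SimTopology
    seed: int | None = None
    means: dict[int, np.ndarray] | None = None
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.counts.shape[0]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(self.counts.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def true_mean(self, cell: int) -> np.ndarray:
        """mu_g(t, b) used for a given cell (requires stored means)."""
        if self.means is None:
            raise ValueError("means were not stored for this dataset")
        b = int(self.true_branch[cell])
        step = int(self.true_time[cell] - self.topology.branches[b].start)
        return self.means[b][step]


def simulate_dataset(
    n_bifurcations: int,
    cells_per_branch: int = 50,
    n_genes: int = DEFAULT_GENES,
    branch_length: int = DEFAULT_BRANCH_LENGTH,
    n_programs: int = DEFAULT_PROGRAMS,
    diffusion_sd: float = DEFAULT_DIFFUSION_SD,
    dispersion: float = DEFAULT_DISPERSION,
    lib_size: float = DEFAULT_LIB_SIZE,
    seed: int | None = None,
    keep_means: bool = True,
) -> SimulatedDataset:
    """One-stop simulation of a branched dataset with ground truth."""
    rng = np.random.default_rng(seed)
    s_top, s_mean, s_cells, s_counts = rng.integers(2**31, size=4)
    top = random_topology(n_bifurcations, branch_length, seed=int(s_top))
    means = simulate_means(
        top, n_genes, n_programs, diffusion_sd, lib_size, seed=int(s_mean)
    )
    t, b = sample_cells(top, cells_per_branch, seed=int(s_cells))
    counts = draw_counts(means, t, b, dispersion, seed=int(s_counts))
    starts = np.array([top.branches[int(bb)].start for bb in b])
    return SimulatedDataset(
        counts=counts,
        true_branch=b,
        true_time=starts + t,
        topology=top,
        seed=seed,
        means=means if keep_means else None,
    )
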