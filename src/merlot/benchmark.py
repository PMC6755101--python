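"""End-to-end reconstruction of simulated datasets and scoring.

This is the harness behind the synthetic benchmark: simulate a branched
dataset, embed it with a diffusion map, reconstruct the scaffold and
elastic tree, assign pseudotime, and score branch assignment (NMI) and
pseudotime ordering (Goodman-Kruskal gamma on the longest trajectory)
against the ground truth.

The number of diffusion components follows the rule of thumb that a
topology with B branches needs about B + 1 informative dimensions; a
b-bifurcation binary tree has 2b + 1 branches, so 2b + 2 components are
used.  The evaluation root t0 is placed at the support node nearest to the
cell with minimal true pseudotime (the start cell is treated as known, as
is standard when benchmarking trajectory methods).
"""

from __future__ import annotations

import numpy as np

from .elastic import DEFAULT_K, ElasticPrincipalTree
from .io import ExpressionMatrix
from .manifold import compute_diffusion_map
from .pseudotime import assign_pseudotime
from .scaffold import ScaffoldTree
from .score import BenchmarkResult, evaluate_reconstruction
from .simulate import SimulatedDataset, simulate_dataset

__all__ = ["reconstruct", "reconstruct_and_score", "benchmark_sweep", "components_for"]


def components_for(n_bifurcations: int) -> int:
    """Diffusion components used for a b-bifurcation tree (b + 2).

    One component per cell fate: enough to separate the b + 2 endpoint
    states while avoiding the noise that extra dimensions add.
    """
    return n_bifurcations + 2


def reconstruct(
    sim: SimulatedDataset,
    n_components: int | None = None,
    n_nodes: int = DEFAULT_K,
    mode: str = "auto",
    n_endpoints: int | None = None,
):
    """Diffusion map + scaffold + elastic tree + pseudotime for a simulation.

    Returns (scaffold, elastic tree, pseudotime assignment, coords).
    """
    if n_components is None:
        n_components = components_for(sim.topology.n_bifurcations)
    expr = ExpressionMatrix(sim.counts.astype(float), list(sim.cell_ids), list(sim.gene_ids))
    coords = compute_diffusion_map(expr.normalized_log(), n_components=n_components)
    scaffold = ScaffoldTree(mode=mode, n_endpoints=n_endpoints).fit(coords)
    k = max(n_nodes, len(scaffold.nodes_))
    tree = ElasticPrincipalTree(n_nodes=k).fit(coords, scaffold=scaffold)
    root_cell = int(np.argmin(sim.true_time))
    times = assign_pseudotime(tree, t0_cell=root_cell)
    return scaffold, tree, times, coords


def reconstruct_and_score(
    sim: SimulatedDataset,
    n_components: int | None = None,
    n_nodes: int = DEFAULT_K,
    dataset: str = "",
) -> BenchmarkResult:
    """Reconstruct a simulated dataset in auto mode and score it."""
    scaffold, tree, times, _ = reconstruct(sim, n_components, n_nodes)
    # branch label of each cell: its support node's branch via scaffold labels
    predicted_branch = _tree_branch_labels(tree)
    return evaluate_reconstruction(
        sim,
        predicted_branch,
        times.cell_times,
        n_endpoints_predicted=len(scaffold.endpoints_),
        dataset=dataset,
    )


def _tree_branch_labels(tree: ElasticPrincipalTree) -> np.ndarray:
    """Branch label per cell from the elastic tree: cut the tree at
    branchpoints and label each node by its segment."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(tree.node_coords_.shape[0]))
    g.add_edges_from(tree.edges_)
    branchpoints = {n for n in g.nodes if g.degree[n] >= 3}
    h = g.copy()
    h.remove_nodes_from(branchpoints)
    node_branch = np.full(tree.node_coords_.shape[0], -1, dtype=int)
    for label, comp in enumerate(sorted(nx.connected_components(h), key=min)):
        for n in comp:
            node_branch[n] = label
    # branchpoint nodes inherit a neighboring segment's label
    for bp in sorted(branchpoints):
        for nb in sorted(g.neighbors(bp)):
            if node_branch[nb] >= 0:
                node_branch[bp] = node_branch[nb]
                break
    return node_branch[np.asarray(tree.cell2node_)]


def benchmark_sweep(
    bifurcations,
    n_seeds: int = 20,
    cells_per_branch: int = 100,
    n_genes: int = 500,
    base_seed: int = 0,
) -> list[BenchmarkResult]:
    """Run the scaled benchmark: ``n_seeds`` simulations per bifurcation
    count, reconstructed in auto mode and scored."""
    results = []
    for b in bifurcations:
        for s in range(n_seeds):
            seed = (base_seed + 104729 * b + s) % (2**31)
            sim = simulate_dataset(
                b, cells_per_branch=cells_per_branch, n_genes=n_genes, seed=seed
            )
            res = reconstruct_and_score(sim, dataset=f"b{b}_s{s}")
            results.append(res)
    return results
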