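"""End-to-end pipeline: embedding -> scaffold -> elastic tree -> imputation
-> pseudotime (-> optional DE / correlation network), with all artifacts
written to an output directory and a machine-readable run log."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import build_correlation_network, cluster_network, de_kruskal_wallis
from .elastic import DEFAULT_K, LAM0, MU0, ElasticPrincipalTree
from .embed import GeneSpaceEmbedding
from .io import (
    ExpressionMatrix,
    read_coords,
    read_expression,
    scaffold_to_json,
    scaffold_to_newick,
    tree_to_json,
    write_coords,
)
from .manifold import CentroidReducer, ManifoldCoords, compute_diffusion_map
from .pseudotime import assign_pseudotime
from .scaffold import ScaffoldTree

log = logging.getLogger("merlot")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; serializable round-trip identical."""

    expression: str = ""
    coords: str | None = None  # user-supplied manifold (skips embedding)
    out_dir: str = "merlot_out"
    transpose: bool = False
    normalize: bool = True  # library-size normalize + log1p before embedding
    n_components: int = 10
    mode: str = "auto"
    n_endpoints: int | None = None
    min_branch_cells: int | str = "auto"
    n_nodes: int = DEFAULT_K
    mu0: float = MU0
    lam0: float = LAM0
    local_averaging: bool = False
    n_centroids: int | str = "auto"
    t0: int | str = "auto"
    continuous_pseudotime: bool = False
    diffexp_branch: int | None = None
    gcn_threshold: float | None = None
    gcn_min_module: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Any stage failure raises with the stage name; artifacts written before
    the failure are preserved.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    stage = "read-input"
    try:
        expr = read_expression(config.expression, transpose=config.transpose)
        log.info("expression: %d cells x %d genes", expr.n_cells, expr.n_genes)

        stage = "embedding"
        if config.coords:
            coords = read_coords(config.coords)
            log.info("using user-supplied coordinates (%d dims)", coords.n_dims)
        else:
            source = expr.normalized_log() if config.normalize else expr
            coords = compute_diffusion_map(source, n_components=config.n_components)
        write_coords(coords, out / "coords.tsv")

        stage = "scaffold"
        if config.local_averaging:
            reducer = CentroidReducer(
                n_centroids=config.n_centroids, random_state=config.seed
            ).fit(coords)
            work = ManifoldCoords(
                reducer.cluster_centers_,
                [f"centroid_{i}" for i in range(reducer.n_centroids_)],
            )
        else:
            reducer = None
            work = coords
        scaffold = ScaffoldTree(
            mode=config.mode,
            n_endpoints=config.n_endpoints,
            min_branch_cells=config.min_branch_cells,
        ).fit(work)
        (out / "scaffold.json").write_text(scaffold_to_json(scaffold, work.cell_ids))
        (out / "scaffold.nwk").write_text(scaffold_to_newick(scaffold, work.cell_ids) + "\n")

        stage = "elastic-tree"
        k = max(config.n_nodes, len(scaffold.nodes_))
        mu = (k - 1) * config.mu0
        lam = (k - 2) ** 3 * config.lam0
        tree = ElasticPrincipalTree(n_nodes=k, mu=mu, lam=lam).fit(work, scaffold=scaffold)
        if reducer is not None:
            tree = tree.inflate(coords.coords)
        (out / "tree.json").write_text(tree_to_json(tree))

        stage = "imputation"
        embedded = GeneSpaceEmbedding().fit(expr, tree=tree)
        pd.DataFrame(
            embedded.pseudocell_profiles_,
            index=[f"node_{i}" for i in range(tree.k_)],
            columns=expr.gene_ids,
        ).to_csv(out / "pseudocells.tsv", sep="\t", float_format="%.6g")

        stage = "pseudotime"
        times = assign_pseudotime(
            tree,
            t0=config.t0 if isinstance(config.t0, (int, str)) else "auto",
            continuous=config.continuous_pseudotime,
            X=coords.coords,
        )
        branch_labels = _branch_table(tree, scaffold, reducer)
        pd.DataFrame(
            {
                "cell": coords.cell_ids,
                "pseudotime": times.cell_times,
                "node": tree.cell2node_,
                "branch": branch_labels,
            }
        ).to_csv(out / "pseudotime.tsv", sep="\t", index=False, float_format="%.6g")

        if config.diffexp_branch is not None:
            stage = "diffexp"
            mask = branch_labels == config.diffexp_branch
            table = de_kruskal_wallis(expr, np.flatnonzero(mask))
            table.to_csv(out / f"diffexp_branch{config.diffexp_branch}.tsv",
                         sep="\t", index=False, float_format="%.6g")

        if config.gcn_threshold is not None:
            stage = "gcn"
            net = build_correlation_network(
                embedded.pseudocell_profiles_,
                threshold=config.gcn_threshold,
                gene_ids=expr.gene_ids,
            )
            net = cluster_network(net, min_size=config.gcn_min_module)
            net.edge_frame().to_csv(out / "gcn_edges.tsv", sep="\t", index=False,
                                    float_format="%.6g")
            modules = pd.DataFrame(
                [
                    (net.genes[g], m)
                    for m, members in enumerate(net.modules)
                    for g in members
                ]
                + [(net.genes[g], -1) for g in net.unclustered],
                columns=["gene", "module"],
            )
            modules.to_csv(out / "gcn_modules.tsv", sep="\t", index=False)

        stage = "run-log"
        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "python": platform.python_version(),
                    "config": asdict(config),
                    "n_cells": expr.n_cells,
                    "n_genes": expr.n_genes,
                    "n_endpoints": len(scaffold.endpoints_),
                    "n_branchpoints": len(scaffold.branchpoints_),
                    "n_nodes": int(tree.k_),
                },
                indent=1,
            )
        )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _branch_table(tree, scaffold, reducer) -> np.ndarray:
    from .benchmark import _tree_branch_labels

    return _tree_branch_labels(tree)
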