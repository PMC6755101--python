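"""Readers, writers and the core expression-matrix container.

The canonical orientation everywhere in the package is cells in rows and
genes in columns.  TSV/CSV files carry a header row of gene names and the
cell identifiers in the first column.  MatrixMarket input is a triplet
``.mtx`` file with two sidecar files, ``<path>.rownames`` and
``<path>.colnames``, holding one identifier per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_coords",
    "write_coords",
    "scaffold_to_json",
    "scaffold_to_newick",
    "tree_to_json",
    "tree_from_json",
]

#: significant digits used for TSV output
TSV_PRECISION = 6


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Cells × genes matrix of non-negative expression values.

    Attributes
    ----------
    values : ndarray of shape (n_cells, n_genes)
        UMI counts or normalized expression; must be finite and >= 0.
    cell_ids, gene_ids : list of str
        Unique identifiers for rows and columns.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if n < 1 or g < 1:
            raise ValueError("expression matrix must have >= 1 cell and gene")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at cell {bad[0]}, gene {bad[1]}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at cell {bad[0]}, gene {bad[1]}"
            )
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(g)]
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lists do not match matrix shape")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def normalized_log(self, target_sum: float | None = None) -> "ExpressionMatrix":
        """Library-size normalize to ``target_sum`` (default: median total)
        and log1p-transform.  The standard preprocessing before a diffusion
        map of raw counts."""
        totals = self.values.sum(axis=1)
        totals = np.where(totals > 0, totals, 1.0)
        if target_sum is None:
            target_sum = float(np.median(totals))
        vals = np.log1p(self.values / totals[:, None] * target_sum)
        return ExpressionMatrix(vals, list(self.cell_ids), list(self.gene_ids))


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    transpose: bool = False,
    counts: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket.

    Parameters
    ----------
    transpose : bool
        Set when the file stores genes in rows (the matrix is transposed
        to the canonical cells × genes orientation after reading).
    counts : bool
        Enforce integer-valued, non-negative entries (UMI count mode).
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = Path(str(path) + ".rownames")
        cols = Path(str(path) + ".colnames")
        cell_ids = rows.read_text().split() if rows.exists() else []
        gene_ids = cols.read_text().split() if cols.exists() else []
        values = np.asarray(mat, dtype=float)
    elif fmt in ("tsv", "csv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        values = values.T
        cell_ids, gene_ids = gene_ids, cell_ids
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: non-finite values in expression matrix")
    if counts and np.any(values != np.round(values)):
        raise ValueError(f"{path}: non-integer values in count mode")
    return ExpressionMatrix(values, cell_ids, gene_ids)


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(expr.values))
        Path(str(path) + ".rownames").write_text("\n".join(expr.cell_ids) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(expr.gene_ids) + "\n")
        return
    sep = "," if fmt == "csv" else "\t"
    expr.to_frame().to_csv(path, sep=sep, float_format=f"%.{TSV_PRECISION}g")


def read_coords(path: str | Path):
    """Read manifold coordinates (TSV, cell ids in the first column)."""
    from .manifold import ManifoldCoords

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ManifoldCoords(
        coords=df.to_numpy(dtype=float),
        cell_ids=[str(i) for i in df.index],
        dim_names=[str(c) for c in df.columns],
    )


def write_coords(coords, path: str | Path) -> None:
    pd.DataFrame(coords.coords, index=coords.cell_ids, columns=coords.dim_names).to_csv(
        path, sep="\t", float_format=f"%.{TSV_PRECISION}g"
    )


# ---------------------------------------------------------------------------
# tree serialization


def scaffold_to_json(scaffold, cell_ids: list[str] | None = None) -> str:
    """Serialize a fitted ScaffoldTree as JSON (nodes with roles, edges,
    branch paths as cell ids)."""
    name = (lambda i: cell_ids[i]) if cell_ids is not None else (lambda i: int(i))
    payload = {
        "mode": scaffold.mode,
        "nodes": [
            {"cell": name(int(c)), "role": role}
            for c, role in zip(scaffold.nodes_, scaffold.node_roles_)
        ],
        "edges": [[int(a), int(b)] for a, b in scaffold.edges_nodeidx_],
        "branch_paths": [[name(int(c)) for c in p] for p in scaffold.branch_paths_],
    }
    return json.dumps(payload, indent=1)


def scaffold_to_newick(scaffold, cell_ids: list[str] | None = None) -> str:
    """Topology alone in Newick form, leaves labelled by endpoint cells."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(scaffold.nodes_)))
    g.add_edges_from(scaffold.edges_nodeidx_)
    name = (lambda i: str(cell_ids[scaffold.nodes_[i]])) if cell_ids is not None else (
        lambda i: f"c{scaffold.nodes_[i]}"
    )

    def subtree(node: int, parent: int | None) -> str:
        children = [n for n in g.neighbors(node) if n != parent]
        if not children:
            return name(node)
        inner = ",".join(subtree(c, node) for c in children)
        return f"({inner}){name(node)}"

    root = 0  # first endpoint
    return subtree(root, None) + ";"


def tree_to_json(tree) -> str:
    """Serialize a fitted ElasticPrincipalTree (or gene-space embedding)."""
    payload = {
        "mu": float(tree.mu_),
        "lam": float(tree.lam_),
        "nodes": [
            {"id": i, "coords": [float(x) for x in c], "role": r}
            for i, (c, r) in enumerate(zip(tree.node_coords_, tree.node_roles_))
        ],
        "edges": [[int(a), int(b)] for a, b in tree.edges_],
        "cell2node": [int(j) for j in tree.cell2node_],
    }
    return json.dumps(payload)


def tree_from_json(text: str):
    """Inverse of :func:`tree_to_json`; returns a fitted ElasticPrincipalTree."""
    from .elastic import ElasticPrincipalTree

    payload = json.loads(text)
    return ElasticPrincipalTree._from_parts(
        node_coords=np.array([n["coords"] for n in payload["nodes"]], dtype=float),
        edges=[tuple(e) for e in payload["edges"]],
        node_roles=[n["role"] for n in payload["nodes"]],
        mu=payload["mu"],
        lam=payload["lam"],
        cell2node=np.array(payload["cell2node"], dtype=int),
    )
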