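"""Interoperable exports: TSV tables, edge lists, Newick dendrograms.

All numeric table exports are fixed to 10 significant digits so files
round-trip deterministically; readers are provided next to writers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from coexnet.modules import Dendrogram
from coexnet.netcore import CorrelationMatrix
from coexnet.types import Eigengenes, ExpressionMatrix, ModulePartition

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def write_expression(em: ExpressionMatrix, path) -> None:
    write_table(em.values, path, index_label="gene_id")


def read_expression(path, meta: pd.DataFrame, size_factors: pd.Series | None = None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    sf = size_factors if size_factors is not None else pd.Series(1.0, index=values.columns)
    return ExpressionMatrix(values=values, sample_meta=meta, size_factors=sf)


def write_partition(part: ModulePartition, path) -> None:
    write_table(part.to_frame(), path)


def read_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t", index_col=0)
    provenance = df["provenance"].iloc[0] if len(df) else "unmerged"
    return ModulePartition(assignment=df["module"], provenance=provenance)


def write_eigengenes(eg: Eigengenes, path) -> None:
    write_table(eg.values, path, index_label="module")


def export_edge_list(
    r: CorrelationMatrix,
    part: ModulePartition,
    module: str,
    threshold: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge and node tables of one module's correlation subnetwork.

    Undirected edges (source < target lexicographically) connect
    same-module gene pairs with |r| strictly above ``threshold``,
    weighted by the raw correlation — the format graph tools such as
    Cytoscape import directly. The node table carries each gene's
    intramodular correlation connectivity (sum of |r| to same-module
    partners).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if module not in set(part.assignment):
        raise ValueError(f"unknown module {module!r}")
    members = sorted(part.members(module))
    sub = r.r.loc[members, members]
    arr = sub.to_numpy()
    edges = []
    for i, a in enumerate(members):
        for j in range(i + 1, len(members)):
            if abs(arr[i, j]) > threshold:
                edges.append({"source": a, "target": members[j], "weight": arr[i, j]})
    edge_df = pd.DataFrame(edges, columns=["source", "target", "weight"])
    k_in = np.abs(arr).sum(axis=1) - 1.0  # exclude self-correlation
    node_df = pd.DataFrame(
        {"gene_id": members, "module": module, "k_intramodular_cor": k_in}
    )
    return edge_df, node_df


def to_newick(dend: Dendrogram) -> str:
    """Newick serialization of the UPGMA tree with branch lengths.

    Branch lengths follow the ultrametric convention: each child's
    length is half the parent's join height minus half its own.
    """
    Z = dend.linkage
    n = dend.n_leaves

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2]

    def render(node: int, parent_h: float) -> str:
        length = parent_h / 2.0 - height(node) / 2.0
        if node < n:
            return f"{dend.leaf_ids[node]}:{length:.10g}"
        row = node - n
        left = render(int(Z[row, 0]), Z[row, 2])
        right = render(int(Z[row, 1]), Z[row, 2])
        return f"({left},{right}):{length:.10g}"

    root = 2 * n - 2
    row = root - n
    left = render(int(Z[row, 0]), Z[row, 2])
    right = render(int(Z[row, 1]), Z[row, 2])
    return f"({left},{right});"
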