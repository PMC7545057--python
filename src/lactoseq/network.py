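"""Pearson co-expression network over DEGs and hub ("node gene") ranking.

Correlations are computed on log2(RPKM + pseudocount) across all samples
jointly, in gene blocks so peak memory stays O(block x n) even for DEG
sets of ~10^4 genes.  An edge joins two genes when |r| meets the threshold
(0.92 by default); node genes are ranked by the number of correlated
partners (degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "CorrelationDiagnostics",
    "log_expression",
    "pairwise_pearson",
    "build_network",
    "rank_node_genes",
]

DEFAULT_CORR_THRESHOLD = 0.92


@dataclass
class CorrelationDiagnostics:
    zero_variance_genes: list = field(default_factory=list)
    n_genes: int = 0
    n_pairs_evaluated: int = 0


def log_expression(
    matrix: ExpressionMatrix,
    genes=None,
    pseudocount: float = 0.125,
) -> pd.DataFrame:
    """log2(value + pseudocount) for the requested gene subset."""
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]
    return np.log2(values + pseudocount)


def pairwise_pearson(
    matrix: ExpressionMatrix,
    genes=None,
    pseudocount: float = 0.125,
    block_size: int = 512,
    min_abs_r: float = 0.0,
    diagnostics: "CorrelationDiagnostics | None" = None,
) -> Iterator[pd.DataFrame]:
    """Stream Pearson correlations for all unordered gene pairs.

    Yields DataFrames with columns (gene_a, gene_b, r) covering each block
    of rows against all later genes; only pairs with |r| >= ``min_abs_r``
    are materialized.  Genes with zero variance across samples produce no
    pairs and are listed in ``diagnostics``.
    """
    logx = log_expression(matrix, genes, pseudocount)
    if logx.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation analysis")
    x = logx.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    keep = norms > 0
    if diagnostics is not None:
        diagnostics.zero_variance_genes = logx.index[~keep].tolist()
        diagnostics.n_genes = int(keep.sum())
    ids = logx.index[keep].to_numpy()
    xn = x[keep] / norms[keep, None]
    n = len(ids)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r_block = xn[start:stop] @ xn[start:].T  # block vs itself and later genes
        rows, cols = np.nonzero(np.abs(r_block) >= min_abs_r)
        mask = cols + start > rows + start  # strictly upper triangle
        rows, cols = rows[mask], cols[mask]
        if diagnostics is not None:
            diagnostics.n_pairs_evaluated += (stop - start) * (n - start) - sum(
                range(1, stop - start + 1)
            )
        yield pd.DataFrame({
            "gene_a": ids[rows + start],
            "gene_b": ids[cols + start],
            "r": np.clip(r_block[rows, cols], -1.0, 1.0),
        })


def build_network(
    matrix: ExpressionMatrix,
    genes=None,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    use_abs: bool = True,
    pseudocount: float = 0.125,
    block_size: int = 512,
    diagnostics: "CorrelationDiagnostics | None" = None,
) -> pd.DataFrame:
    """Edge table of the co-expression network.

    An edge is retained when |r| >= threshold (inclusive); with
    ``use_abs=False`` only positive correlations r >= threshold count.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    min_abs = threshold if use_abs else 0.0
    chunks = []
    for chunk in pairwise_pearson(
        matrix, genes, pseudocount, block_size, min_abs_r=min_abs, diagnostics=diagnostics
    ):
        if not use_abs:
            chunk = chunk[chunk["r"] >= threshold]
        chunks.append(chunk)
    if not chunks:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    edges = pd.concat(chunks, ignore_index=True)
    return edges.sort_values(["gene_a", "gene_b"], ignore_index=True)


def rank_node_genes(
    edges: pd.DataFrame,
    gene_universe=None,
    top_k: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degree-rank genes; hubs ("node genes") have the most partners.

    Returns ``(full_table, top_table)``.  The full table covers every gene
    in ``gene_universe`` (or every gene touched by an edge), sorted by
    descending degree with ties broken by gene id; ``rank`` is the 1-based
    position in that order.  The top table keeps the first ``top_k`` rows
    plus any gene tied with the degree at the boundary, so hubs are never
    truncated arbitrarily.
    """
    g = nx.Graph()
    if gene_universe is not None:
        g.add_nodes_from(gene_universe)
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    table = pd.DataFrame(
        {"gene_id": list(g.nodes), "degree": [g.degree(v) for v in g.nodes]}
    ).sort_values(["degree", "gene_id"], ascending=[False, True], ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k >= len(table):
        return table, table.copy()
    boundary_degree = table["degree"].iloc[top_k - 1]
    top = table[(table["rank"] <= top_k) | (table["degree"] == boundary_degree)]
    return table, top.reset_index(drop=True)
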