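"""Markov clustering (MCL) of weighted TF interaction graphs.

The classic flow simulation on graphs: build a column-stochastic
transition matrix with self-loops, then alternate expansion (matrix
squaring) with inflation (elementwise power followed by column
renormalization) until the matrix stops changing.  Flow concentrates
within natural clusters; the clusters are read off as the connected
components of the non-zero structure of the converged matrix.  The
procedure is deterministic for a fixed input, and expansion can never
create flow between disconnected components, so clusters never span
components of the input graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["ClusterPartition", "mcl_cluster"]


@dataclass
class ClusterPartition:
    """Node -> cluster assignment from one MCL run."""

    assignments: dict
    n_clusters: int
    convergence_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["node", "cluster"]
        )


def _as_edge_tuples(edges) -> list[tuple[str, str, float]]:
    if isinstance(edges, pd.DataFrame):
        return [
            (str(a), str(b), float(w))
            for a, b, w in edges[["node_a", "node_b", "weight"]].itertuples(index=False)
        ]
    out = []
    for e in edges:
        if len(e) == 2:
            a, b = e
            w = 1.0
        else:
            a, b, w = e
        out.append((str(a), str(b), float(w)))
    return out


def mcl_cluster(
    edges,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    nodes: list | None = None,
    self_loop_weight: float = 1.0,
    prune: float = 1e-10,
) -> ClusterPartition:
    """Cluster a weighted undirected graph with the MCL process.

    ``edges`` is an iterable of (node_a, node_b[, weight]) or a
    DataFrame with those columns; ``nodes`` optionally adds isolated
    nodes (each becomes a singleton cluster).  Self-loops of
    ``self_loop_weight`` are added to every node before normalization.
    Entries below ``prune`` are zeroed each iteration for stability.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    edge_list = _as_edge_tuples(edges)
    node_set = sorted({n for a, b, _ in edge_list for n in (a, b)} | set(map(str, nodes or [])))
    n = len(node_set)
    if n == 0:
        return ClusterPartition(assignments={}, n_clusters=0, convergence_iterations=0)
    index = {v: i for i, v in enumerate(node_set)}

    M = np.zeros((n, n))
    for a, b, w in edge_list:
        if w <= 0:
            raise ValueError(f"edge weight must be positive: ({a}, {b}, {w})")
        i, j = index[a], index[b]
        if i == j:
            continue
        M[i, j] = max(M[i, j], w)  # simple graph: keep the strongest duplicate
        M[j, i] = M[i, j]
    np.fill_diagonal(M, self_loop_weight)
    M /= M.sum(axis=0, keepdims=True)

    iterations = 0
    for iterations in range(1, max_iter + 1):
        expanded = M @ M
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsums = inflated.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        inflated /= colsums
        if np.max(np.abs(inflated - M)) < tol:
            M = inflated
            break
        M = inflated

    # clusters = connected components of the converged non-zero structure
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > prune)
    g.add_edges_from((int(i), int(j)) for i, j in zip(rows, cols) if i != j)
    assignments = {}
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    for cid, comp in enumerate(components):
        for i in comp:
            assignments[node_set[i]] = cid
    return ClusterPartition(
        assignments=assignments,
        n_clusters=len(components),
        convergence_iterations=iterations,
    )
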