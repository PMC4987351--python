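"""Cost-thresholded binary graphs on a minimum-spanning-tree backbone.

A subject's absolute correlation matrix is turned into an unweighted,
undirected, *connected* graph at a fixed cost (fraction of realized edges
among all N(N-1)/2 node pairs).  Connectivity is guaranteed by first
extracting the maximum-|r| spanning tree (equivalently the minimum spanning
tree under weight 1 - |r|, Prim's algorithm) and then adding the strongest
remaining pairs until the target edge count M = round(cost * N(N-1)/2) is
reached.  Fixing cost instead of a correlation cutoff equalizes edge counts
across subjects, which keeps graph metrics comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .regions import RegionDefinition, hemisphere_indices
from .wavelet import CorrelationMatrix


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with cost and threshold provenance."""

    adjacency: np.ndarray
    node_ids: list[int]
    cost: float
    threshold_r: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


def subset_hemisphere(corr: CorrelationMatrix, side: str) -> CorrelationMatrix:
    """Principal submatrix over one hemisphere's regions (midline dropped)."""
    idx = hemisphere_indices(corr.regions, side)
    sub = corr.values[np.ix_(idx, idx)]
    return CorrelationMatrix(
        sub,
        [corr.regions[i] for i in idx],
        corr.spec,
        corr.subject_id,
        corr.session_id,
        hemisphere_scope=side,
    )


def _pair_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def mst_backbone(corr: CorrelationMatrix | np.ndarray) -> list[tuple[int, int]]:
    """Maximum-|r| spanning tree via Prim with lexicographic tie-breaking.

    Returns N-1 edges as (i, j) index pairs with i < j.  Ties in |r| are
    broken on (min index, max index), making the tree deterministic.
    """
    values = corr.values if isinstance(corr, CorrelationMatrix) else corr
    a = np.abs(np.asarray(values, dtype=float))
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes for a spanning tree")
    in_tree = [0]
    out = set(range(1, n))
    edges: list[tuple[int, int]] = []
    while out:
        best = None
        for u in in_tree:
            for v in out:
                key = (-a[u, v], *_pair_key(u, v))
                if best is None or key < best[0]:
                    best = (key, _pair_key(u, v), v)
        _, edge, v = best
        edges.append(edge)
        in_tree.append(v)
        out.remove(v)
    return sorted(edges)


def minimum_feasible_cost(n: int) -> float:
    """Cost of the spanning tree alone: (N-1) / (N(N-1)/2)."""
    return (n - 1) / (n * (n - 1) / 2)


def threshold_to_cost(
    corr: CorrelationMatrix,
    cost: float,
    provenance: Optional[dict] = None,
) -> BinaryGraph:
    """Binary graph with M = round(cost * N(N-1)/2) edges, MST included.

    Edge count rounding is round-half-to-even.  Non-tree pairs are admitted
    by descending |r| with lexicographic tie-breaking, so for costs
    c1 < c2 the edge set at c1 is a subset of the edge set at c2.
    """
    n = corr.n_regions
    total = n * (n - 1) // 2
    if cost > 1:
        raise ValueError("cost cannot exceed 1")
    m = int(np.round(cost * total))
    if m < n - 1:
        raise ValueError(
            f"cost {cost:.4f} below the spanning-tree floor; minimum "
            f"feasible cost is {minimum_feasible_cost(n):.4f}"
        )
    a = np.abs(corr.values)
    tree = set(mst_backbone(corr))
    non_tree = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in tree
    ]
    non_tree.sort(key=lambda e: (-a[e[0], e[1]], e[0], e[1]))
    extra = non_tree[: m - (n - 1)]
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in list(tree) + extra:
        adj[i, j] = adj[j, i] = 1
    threshold_r = float(a[extra[-1][0], extra[-1][1]]) if extra else float("nan")
    prov = dict(provenance or {})
    prov.setdefault("subject_id", corr.subject_id)
    prov.setdefault("session_id", corr.session_id)
    prov.setdefault("hemisphere", corr.hemisphere_scope)
    if corr.spec is not None:
        prov.setdefault("scale", corr.spec.scale)
    return BinaryGraph(adj, corr.region_ids, cost, threshold_r, prov)


# ---------------------------------------------------------------------------
# Text IO

def write_adjacency_tsv(graph: BinaryGraph, path) -> None:
    df = pd.DataFrame(graph.adjacency, columns=graph.node_ids)
    df.insert(0, "region_id", graph.node_ids)
    df.to_csv(path, sep="\t", index=False)


def write_edgelist(graph: BinaryGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# i\tj (0-based node indices)\n")
        for i, j in graph.edges():
            fh.write(f"{i}\t{j}\n")
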