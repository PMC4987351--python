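"""Nodal graph metrics: degree, efficiencies, betweenness, clustering.

Five nodal metrics characterize each region's role in the binary graph:

* ``D_i``   — degree, the number of edges at node i;
* ``Eg_i``  — nodal global efficiency, ``(1/(N-1)) sum_j 1/L_ij`` with
  shortest-path length ``L_ij`` in hops (``1/inf = 0``);
* ``B_i``   — betweenness centrality, the fraction-weighted count of
  shortest paths through i over unordered pairs, unnormalized;
* ``El_i``  — local efficiency, the global efficiency of the subgraph
  induced by i's neighbours (0 when degree < 2);
* ``C_i``   — clustering coefficient ``2 t_i / (D_i (D_i - 1))`` with
  ``t_i`` the number of triangles at i (0 when degree < 2).

Computation is delegated to networkx; the test-suite checks every metric
against independent brute-force implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import BinaryGraph

METRIC_NAMES = ("D", "Eg", "B", "El", "C")


@dataclass
class NodalMetricProfile:
    """Per-node values of the five metrics for one subject/hemisphere/cost."""

    node_ids: list[int]
    D: np.ndarray
    Eg: np.ndarray
    B: np.ndarray
    El: np.ndarray
    C: np.ndarray
    provenance: dict = field(default_factory=dict)

    def get(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise KeyError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
        return getattr(self, metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "D": self.D,
                "Eg": self.Eg,
                "B": self.B,
                "El": self.El,
                "C": self.C,
            }
        )


def degree(g: BinaryGraph) -> np.ndarray:
    return g.adjacency.sum(axis=1).astype(float)


def nodal_global_efficiency(g: BinaryGraph) -> np.ndarray:
    nxg = g.to_networkx()
    n = g.n_nodes
    out = np.zeros(n)
    for i in range(n):
        lengths = nx.single_source_shortest_path_length(nxg, i)
        out[i] = sum(1.0 / d for node, d in lengths.items() if node != i)
    if n > 1:
        out /= n - 1
    return out


def betweenness(g: BinaryGraph) -> np.ndarray:
    nxg = g.to_networkx()
    bc = nx.betweenness_centrality(nxg, normalized=False)
    return np.array([bc[i] for i in range(g.n_nodes)], dtype=float)


def local_efficiency(g: BinaryGraph) -> np.ndarray:
    nxg = g.to_networkx()
    out = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = list(nxg.neighbors(i))
        if len(nbrs) < 2:
            continue
        out[i] = nx.global_efficiency(nxg.subgraph(nbrs))
    return out


def clustering(g: BinaryGraph) -> np.ndarray:
    cc = nx.clustering(g.to_networkx())
    return np.array([cc[i] for i in range(g.n_nodes)], dtype=float)


METRIC_FUNCS = {
    "D": degree,
    "Eg": nodal_global_efficiency,
    "B": betweenness,
    "El": local_efficiency,
    "C": clustering,
}


def compute_metric(g: BinaryGraph, metric: str) -> np.ndarray:
    """One nodal metric vector by name ("D", "Eg", "B", "El" or "C")."""
    try:
        return METRIC_FUNCS[metric](g)
    except KeyError:
        raise KeyError(
            f"unknown metric {metric!r}; choose from {METRIC_NAMES}"
        ) from None


def metric_profile(g: BinaryGraph) -> NodalMetricProfile:
    """All five nodal metric vectors for one graph."""
    return NodalMetricProfile(
        node_ids=list(g.node_ids),
        D=degree(g),
        Eg=nodal_global_efficiency(g),
        B=betweenness(g),
        El=local_efficiency(g),
        C=clustering(g),
        provenance=dict(g.provenance, cost=g.cost),
    )


def global_summary(p: NodalMetricProfile) -> dict[str, float]:
    """Node-averaged (global) value of each metric."""
    return {m: float(np.mean(p.get(m))) for m in METRIC_NAMES}


def write_profile_tsv(p: NodalMetricProfile, path) -> None:
    with open(path, "w") as fh:
        for k, v in p.provenance.items():
            fh.write(f"# {k}: {v}\n")
        p.to_frame().to_csv(fh, sep="\t", index=False)
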