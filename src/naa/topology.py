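"""Node topology indicators and edge betweenness.

Five node indicators feed the entropy-weight/TOPSIS ranking: degree
centrality, betweenness centrality, closeness centrality, local
clustering coefficient, and the topological coefficient (the Cytoscape
NetworkAnalyzer neighbor-sharing statistic).  Edge betweenness supplies
the edge weights of the weighted association coefficients.

All shortest paths are unweighted (hop counts).  Closeness uses the
Wasserman–Faust component-size correction so it stays meaningful, and
positively oriented, on the frequently disconnected associated networks.
"""

from __future__ import annotations

from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_COLUMNS",
    "as_networkx",
    "node_indicators",
    "topological_coefficient",
    "edge_betweenness",
    "EDGE_BETWEENNESS_FLOOR",
]

INDICATOR_COLUMNS = (
    "degree",
    "betweenness",
    "closeness",
    "clustering",
    "topological_coefficient",
)

#: Added to every edge-betweenness value so weighted edge sums can never
#: be identically zero (bridgeless leaves of shortest-path trees may
#: otherwise receive exactly 0 on some graphs).
EDGE_BETWEENNESS_FLOOR = 1e-9


def as_networkx(g: Any) -> nx.Graph:
    """Coerce a PathwayNetwork/AssociatedNetwork/nx.Graph to an nx.Graph."""
    if isinstance(g, nx.Graph):
        return g
    if hasattr(g, "to_networkx"):
        return g.to_networkx()
    raise TypeError(f"cannot interpret {type(g).__name__} as a graph")


def topological_coefficient(g: nx.Graph) -> dict[Any, float]:
    """Neighbor-sharing topological coefficient, NetworkAnalyzer convention.

    For node v with degree > 1, let M(v) be the nodes m != v sharing at
    least one neighbor with v, and J(v, m) = |N(v) ∩ N(m)|, plus 1 if m is
    itself adjacent to v.  Then T(v) = mean_m J(v, m) / deg(v).  Nodes with
    degree <= 1, or with no neighbor-sharing partner, score 0.
    """
    tc: dict[Any, float] = {}
    neigh = {v: set(g[v]) for v in g}
    for v in g:
        nv = neigh[v]
        if len(nv) <= 1:
            tc[v] = 0.0
            continue
        partners = {m for u in nv for m in neigh[u] if m != v}
        if not partners:
            tc[v] = 0.0
            continue
        j_sum = 0.0
        for m in partners:
            shared = len(nv & neigh[m])
            j_sum += shared + (1 if m in nv else 0)
        tc[v] = j_sum / (len(partners) * len(nv))
    return tc


def node_indicators(g: Any) -> pd.DataFrame:
    """The five per-node indicators as a DataFrame, rows sorted by node id.

    Degree centrality is deg(v)/(n-1); betweenness is normalized
    shortest-path betweenness; closeness is Wasserman–Faust corrected;
    clustering is the local triangle density (0 for degree < 2).  A
    single-node graph yields an all-zero row.
    """
    G = as_networkx(g)
    if G.number_of_nodes() == 0:
        raise ValueError("cannot compute indicators of an empty graph")
    nodes = sorted(G.nodes())
    if len(nodes) == 1:
        return pd.DataFrame(
            0.0, index=pd.Index(nodes, name="node"), columns=list(INDICATOR_COLUMNS)
        )
    data = {
        "degree": nx.degree_centrality(G),
        "betweenness": nx.betweenness_centrality(G, normalized=True),
        "closeness": nx.closeness_centrality(G, wf_improved=True),
        "clustering": nx.clustering(G),
        "topological_coefficient": topological_coefficient(G),
    }
    df = pd.DataFrame({c: [data[c][n] for n in nodes] for c in INDICATOR_COLUMNS},
                      index=pd.Index(nodes, name="node")).astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite indicator value")
    return df


def edge_betweenness(g: Any, floor: float = EDGE_BETWEENNESS_FLOOR) -> dict[tuple, float]:
    """Normalized shortest-path edge betweenness on canonical edge pairs.

    Every value is raised by ``floor`` so downstream weighted sums are
    strictly positive.  An edgeless graph yields an empty table.
    """
    G = as_networkx(g)
    if G.number_of_edges() == 0:
        return {}
    eb = nx.edge_betweenness_centrality(G, normalized=True)
    out: dict[tuple, float] = {}
    for (u, v), val in eb.items():
        key = (u, v) if u <= v else (v, u)
        out[key] = val + floor
    return out
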