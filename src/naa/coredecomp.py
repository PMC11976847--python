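"""Protected k-core decomposition and maximum-coreness target extraction.

The classical k-core of a graph is the maximal subgraph in which every
node has degree >= k.  The variant here exempts a set of *protected*
nodes — key proteins from the TOPSIS ranking and differentially
expressed proteins — from the degree requirement: during the recursive
removal only non-protected nodes with current degree < k are deleted
(with their incident edges), so protected nodes survive every round and
keep their edges to surviving neighbors.  Protection shields the node
itself, and a protected node's edges still count toward its neighbors'
degrees.

The maximum coreness Ks is the largest k at which the protected k-core
still retains at least one non-protected node; defining Ks by
non-protected survival keeps it bounded (a fully protected residue would
otherwise survive any k).  The Ks-core is the *target network*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

import networkx as nx

from .topology import as_networkx

__all__ = ["KCoreResult", "protected_kcore", "max_ks_core"]


@dataclass(frozen=True)
class KCoreResult:
    """Maximum coreness, the Ks-core subgraph, and retained protected nodes."""

    ks: int
    core_nodes: frozenset
    core_edges: frozenset[tuple]
    protected_retained: frozenset

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.core_nodes))
        g.add_edges_from(sorted(self.core_edges))
        return g


def _check_protected(g: nx.Graph, protected: Iterable) -> frozenset:
    protected = frozenset(protected)
    missing = sorted(n for n in protected if n not in g)
    if missing:
        raise ValueError(f"protected nodes absent from the graph: {missing}")
    return protected


def protected_kcore(g: Any, protected: Iterable = (), k: int = 0) -> nx.Graph:
    """The k-core obtained while never removing protected nodes.

    Repeatedly removes any non-protected node whose current degree is
    below k, together with its incident edges, until no such node remains.
    The result is an induced subgraph of the input and is independent of
    removal order (the removable set only grows as degrees drop).
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    G = as_networkx(g)
    protected = _check_protected(G, protected)
    core = G.copy()
    queue = [n for n in core if n not in protected and core.degree(n) < k]
    while queue:
        node = queue.pop()
        if node not in core:
            continue
        neighbors = list(core[node])
        core.remove_node(node)
        for nb in neighbors:
            if nb in core and nb not in protected and core.degree(nb) < k:
                queue.append(nb)
    return core


def max_ks_core(g: Any, protected: Iterable = ()) -> KCoreResult:
    """Extract the maximum-coreness (Ks) protected core.

    Ks is the largest k for which the protected k-core keeps at least one
    non-protected node; Ks = 0 when no non-protected node exists at all
    (the result then carries the whole graph).  Deterministic for a given
    input.
    """
    G = as_networkx(g)
    protected = _check_protected(G, protected)

    def has_free_node(core: nx.Graph) -> bool:
        return any(n not in protected for n in core)

    best_k = 0
    best_core = protected_kcore(G, protected, 0)
    if has_free_node(best_core):
        max_deg = max((d for _, d in G.degree()), default=0)
        for k in range(1, max_deg + 2):
            core = protected_kcore(G, protected, k)
            if has_free_node(core):
                best_k, best_core = k, core
            else:
                break
    return KCoreResult(
        ks=best_k,
        core_nodes=frozenset(best_core.nodes()),
        core_edges=frozenset(
            (u, v) if u <= v else (v, u) for u, v in best_core.edges()
        ),
        protected_retained=frozenset(n for n in best_core if n in protected),
    )
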