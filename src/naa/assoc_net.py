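"""The network association algorithm (NAA).

Two pathway networks a and b are merged into an *associated network*
a-b: the union of their nodes and edges, optionally augmented with
*derived* edges taken from a reference interactome (edges between union
nodes that appear in neither pathway's own edge set).  On that network:

    C_N = N_r / N_ab                     node association coefficient
    C_E = (E_r + E_d) / E_ab             edge association coefficient
    C   = sqrt((C_N^2 + C_E^2) / 2)      overall coefficient

where N_r counts overlapping nodes (present in both pathways), E_r
overlapping edges (present in both edge sets), and E_d derived edges.
When the associated network has no edges C_E is undefined and C reduces
to C_N.  Weighted counterparts replace counts with weight sums: node
weights come from TOPSIS scores, edge weights from edge betweenness.
All coefficients lie in [0, 1] and are symmetric in a and b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from . import mcda, topology
from .graph_io import Interactome, PathwayNetwork, canonical_edge

__all__ = [
    "AssociatedNetwork",
    "AssociationCounts",
    "AssociationScore",
    "PairwiseResult",
    "build_association",
    "count_components",
    "association_coefficient",
    "weighted_association",
    "default_weights",
    "pairwise_matrix",
    "combine_pathways",
    "NODE_WEIGHT_FLOOR",
]

#: TOPSIS scores used as node weights are floored here so the worst-ranked
#: node never zeroes out of the weighted sums.
NODE_WEIGHT_FLOOR = 1e-6

NODE_LABELS = ("a_only", "b_only", "shared")
EDGE_LABELS = ("a_only", "b_only", "overlapping", "derived")


@dataclass(frozen=True)
class AssociatedNetwork:
    """Union network with per-node and per-edge provenance labels.

    Node labels: ``a_only`` / ``b_only`` / ``shared``.  Edge labels:
    ``a_only`` / ``b_only`` / ``overlapping`` (in both input edge sets) /
    ``derived`` (in neither; contributed by the interactome).
    """

    name: str
    node_labels: Mapping[str, str]
    edge_labels: Mapping[tuple[str, str], str]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.node_labels)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edge_labels)

    @property
    def shared_nodes(self) -> frozenset[str]:
        return frozenset(n for n, l in self.node_labels.items() if l == "shared")

    def edges_with_label(self, label: str) -> frozenset[tuple[str, str]]:
        return frozenset(e for e, l in self.edge_labels.items() if l == label)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        for n in sorted(self.node_labels):
            g.add_node(n, label=self.node_labels[n])
        for (u, v) in sorted(self.edge_labels):
            g.add_edge(u, v, label=self.edge_labels[(u, v)])
        return g

    def to_pathway_network(self) -> PathwayNetwork:
        return PathwayNetwork(self.name, self.nodes, self.edges)


@dataclass(frozen=True)
class AssociationCounts:
    """Node/edge tallies of an associated network a-b."""

    n_a: int
    n_b: int
    n_ab: int
    e_ab: int
    n_r: int
    e_r: int
    e_d: int

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_ab, self.e_ab, self.n_r, self.e_r, self.e_d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_r > min(self.n_a, self.n_b):
            raise ValueError("overlapping nodes cannot exceed either network's size")
        if self.e_r + self.e_d > self.e_ab:
            raise ValueError("overlapping + derived edges cannot exceed total edges")
        if self.n_ab > self.n_a + self.n_b:
            raise ValueError("union node count cannot exceed the sum of sizes")


@dataclass(frozen=True)
class AssociationScore:
    """NAA coefficients; weighted fields are present only when computed.

    ``edgeless`` marks the E_ab = 0 special case, in which C_E is undefined
    and C equals C_N.
    """

    c_n: float
    c_e: float | None
    c: float
    edgeless: bool = False
    c_nw: float | None = None
    c_ew: float | None = None
    c_w: float | None = None

    def __post_init__(self) -> None:
        for name in ("c_n", "c_e", "c", "c_nw", "c_ew", "c_w"):
            val = getattr(self, name)
            if val is not None and not (-1e-12 <= val <= 1 + 1e-12):
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.edgeless and self.c_e is not None:
            raise ValueError("edgeless score cannot carry an edge coefficient")


def _rms_pair(a: float, b: float) -> float:
    return math.sqrt((a * a + b * b) / 2.0)


def build_association(
    net_a: PathwayNetwork,
    net_b: PathwayNetwork,
    interactome: Interactome | None = None,
    derived_mode: str = "any",
) -> AssociatedNetwork:
    """Merge two pathway networks into the labeled associated network a-b.

    Nodes are V_a ∪ V_b; edges are E_a ∪ E_b plus derived interactome
    edges between union nodes that belong to neither input edge set.  The
    interactome contributes edges only, never new nodes.  With
    ``derived_mode="cross-only"`` a derived edge must bridge the two
    pathways (at least one endpoint in V_a and one in V_b; edges between
    two a-only or two b-only nodes are dropped); the default ``"any"``
    keeps every qualifying interactome edge.
    """
    if derived_mode not in ("any", "cross-only"):
        raise ValueError(f"unknown derived_mode {derived_mode!r}")
    # sorted construction keeps downstream float summations order-stable
    node_labels: dict[str, str] = {}
    for n in sorted(net_a.nodes | net_b.nodes):
        in_a, in_b = n in net_a.nodes, n in net_b.nodes
        node_labels[n] = "shared" if (in_a and in_b) else ("a_only" if in_a else "b_only")

    edge_labels: dict[tuple[str, str], str] = {}
    for e in sorted(net_a.edges | net_b.edges):
        in_a, in_b = e in net_a.edges, e in net_b.edges
        edge_labels[e] = "overlapping" if (in_a and in_b) else ("a_only" if in_a else "b_only")

    if interactome is not None:
        union = set(node_labels)
        for e in sorted(interactome.edges_within(union)):
            if e in edge_labels:
                continue
            if derived_mode == "cross-only":
                u, v = e
                touches_a = u in net_a.nodes or v in net_a.nodes
                touches_b = u in net_b.nodes or v in net_b.nodes
                if not (touches_a and touches_b):
                    continue
            edge_labels[e] = "derived"

    name = f"{net_a.name}-{net_b.name}"
    return AssociatedNetwork(name=name, node_labels=dict(node_labels),
                             edge_labels=dict(edge_labels))


def count_components(assoc: AssociatedNetwork, n_a: int, n_b: int) -> AssociationCounts:
    """Read the NAA tallies off an associated network's labels."""
    return AssociationCounts(
        n_a=n_a,
        n_b=n_b,
        n_ab=len(assoc.node_labels),
        e_ab=len(assoc.edge_labels),
        n_r=sum(1 for l in assoc.node_labels.values() if l == "shared"),
        e_r=sum(1 for l in assoc.edge_labels.values() if l == "overlapping"),
        e_d=sum(1 for l in assoc.edge_labels.values() if l == "derived"),
    )


def association_coefficient(counts: AssociationCounts) -> AssociationScore:
    """Unweighted NAA coefficients C_N, C_E, C from the tallies."""
    if counts.n_ab == 0:
        raise ValueError("association undefined for an empty associated network")
    c_n = counts.n_r / counts.n_ab
    if counts.e_ab == 0:
        return AssociationScore(c_n=c_n, c_e=None, c=c_n, edgeless=True)
    c_e = (counts.e_r + counts.e_d) / counts.e_ab
    return AssociationScore(c_n=c_n, c_e=c_e, c=_rms_pair(c_n, c_e))


def weighted_association(
    assoc: AssociatedNetwork,
    node_w: Mapping[str, float],
    edge_w: Mapping[tuple[str, str], float],
) -> AssociationScore:
    """Weighted NAA coefficients; also carries the unweighted trio.

    C_Nw is the weight sum over shared nodes divided by the weight sum
    over all nodes; C_Ew the weight sum over overlapping and derived edges
    divided by the weight sum over all edges.  Uniform weights reduce the
    weighted coefficients to the unweighted ones.  Every node and edge of
    the associated network must carry a nonnegative weight, and the total
    node weight must be positive.
    """
    missing_nodes = sorted(n for n in assoc.node_labels if n not in node_w)
    missing_edges = sorted(e for e in assoc.edge_labels if e not in edge_w)
    if missing_nodes or missing_edges:
        raise ValueError(
            f"missing weights for nodes {missing_nodes[:5]} and edges {missing_edges[:5]}"
        )
    bad = [k for k in assoc.node_labels if node_w[k] < 0]
    bad += [k for k in assoc.edge_labels if edge_w[k] < 0]
    if bad:
        raise ValueError(f"negative weights for {bad[:5]}")

    nodes_sorted = sorted(assoc.node_labels)
    total_node_w = sum(node_w[n] for n in nodes_sorted)
    if total_node_w <= 0:
        raise ValueError("total node weight must be positive")
    shared_w = sum(
        node_w[n] for n in nodes_sorted if assoc.node_labels[n] == "shared"
    )
    c_nw = shared_w / total_node_w

    n_ab = len(assoc.node_labels)
    if n_ab == 0:
        raise ValueError("association undefined for an empty associated network")
    n_r = sum(1 for l in assoc.node_labels.values() if l == "shared")
    c_n = n_r / n_ab
    e_ab = len(assoc.edge_labels)

    if e_ab == 0:
        return AssociationScore(
            c_n=c_n, c_e=None, c=c_n, edgeless=True,
            c_nw=c_nw, c_ew=None, c_w=c_nw,
        )

    e_r = sum(1 for l in assoc.edge_labels.values() if l == "overlapping")
    e_d = sum(1 for l in assoc.edge_labels.values() if l == "derived")
    c_e = (e_r + e_d) / e_ab

    edges_sorted = sorted(assoc.edge_labels)
    total_edge_w = sum(edge_w[e] for e in edges_sorted)
    if total_edge_w <= 0:
        raise ValueError("total edge weight must be positive")
    assoc_edge_w = sum(
        edge_w[e] for e in edges_sorted
        if assoc.edge_labels[e] in ("overlapping", "derived")
    )
    c_ew = assoc_edge_w / total_edge_w
    return AssociationScore(
        c_n=c_n, c_e=c_e, c=_rms_pair(c_n, c_e),
        c_nw=c_nw, c_ew=c_ew, c_w=_rms_pair(c_nw, c_ew),
    )


def default_weights(
    assoc: AssociatedNetwork,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """NAA weights from the associated network's own topology.

    Node weights are TOPSIS final indices over the five topology
    indicators with entropy weighting, floored at ``NODE_WEIGHT_FLOOR``;
    edge weights are normalized edge betweenness (already floored).
    Requires at least two nodes (entropy over one object is undefined).
    """
    indicators = topology.node_indicators(assoc)
    ew = mcda.entropy_weights(indicators)
    scores = mcda.topsis(indicators, ew).scores
    node_w = {n: max(float(s), NODE_WEIGHT_FLOOR) for n, s in scores.items()}
    edge_w = topology.edge_betweenness(assoc)
    return node_w, edge_w


@dataclass(frozen=True)
class PairwiseResult:
    """All pairwise scores, the coefficient matrix, and the best pair."""

    scores: Mapping[tuple[str, str], AssociationScore]
    matrix: pd.DataFrame
    best_pair: tuple[str, str]

    @property
    def best_score(self) -> AssociationScore:
        return self.scores[self.best_pair]


def pairwise_matrix(
    signal_sets: Sequence[PathwayNetwork],
    process_sets: Sequence[PathwayNetwork],
    interactome: Interactome | None = None,
    weighted: bool = False,
    derived_mode: str = "any",
) -> PairwiseResult:
    """Score every (signal, process) pathway pair.

    When ``weighted`` is set, node and edge weights are computed afresh on
    each pair's own associated network (topology → entropy weights →
    TOPSIS → weighted coefficients); weights are never shared across
    pairs.  The matrix holds C_w when weighted, else C; the best pair is
    the argmax (ties broken lexicographically by pair names).
    """
    if not signal_sets or not process_sets:
        raise ValueError("need at least one network on each side")
    scores: dict[tuple[str, str], AssociationScore] = {}
    matrix = pd.DataFrame(
        index=pd.Index([s.name for s in signal_sets], name="signal"),
        columns=pd.Index([p.name for p in process_sets], name="process"),
        dtype=float,
    )
    for sig in signal_sets:
        for proc in process_sets:
            try:
                assoc = build_association(sig, proc, interactome, derived_mode)
                if weighted:
                    node_w, edge_w = default_weights(assoc)
                    score = weighted_association(assoc, node_w, edge_w)
                else:
                    counts = count_components(assoc, sig.n_nodes, proc.n_nodes)
                    score = association_coefficient(counts)
            except Exception as exc:
                raise RuntimeError(
                    f"association failed for pair ({sig.name}, {proc.name}): {exc}"
                ) from exc
            scores[(sig.name, proc.name)] = score
            matrix.loc[sig.name, proc.name] = (
                score.c_w if weighted and score.c_w is not None else score.c
            )
    best_pair = min(
        scores, key=lambda pair: (-float(matrix.loc[pair[0], pair[1]]), pair)
    )
    return PairwiseResult(scores=scores, matrix=matrix, best_pair=best_pair)


def combine_pathways(nets: Sequence[PathwayNetwork], name: str) -> PathwayNetwork:
    """Union of node and edge sets under a new name (idempotent)."""
    if not nets:
        raise ValueError("need at least one network to combine")
    nodes: frozenset[str] = frozenset()
    edges: frozenset[tuple[str, str]] = frozenset()
    for net in nets:
        nodes |= net.nodes
        edges |= net.edges
    return PathwayNetwork(name=name, nodes=nodes, edges=edges)
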