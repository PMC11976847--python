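"""Readers, writers, the DEP filter, and seeded synthetic fixtures.

Pathway networks are simple undirected graphs over uppercase gene symbols.
On disk they are SIF files (``node1 <relation> node2``) or two-column TSV
edge lists; gene sets are standard GMT; protein quantification tables are
TSV with columns ``protein_id``, ``log2fc``, ``p_value``.

All modules share one canonical edge form: the lexicographically sorted
node pair produced by :func:`canonical_edge`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "PathwayNetwork",
    "Interactome",
    "canonical_edge",
    "normalize_symbol",
    "read_edge_list",
    "write_edge_list",
    "read_node_table",
    "write_node_table",
    "read_gmt",
    "read_quant_table",
    "filter_deps",
    "read_node_weights",
    "read_edge_weights",
    "synth_pathway_pair",
    "synth_quant_table",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input rows; the message names the file and line."""


def normalize_symbol(sym: str) -> str:
    """Uppercase and whitespace-trim a gene symbol.

    Overlap counting between networks must not depend on the capitalization
    conventions of the source files, so every reader funnels through here.
    """
    return str(sym).strip().upper()


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PathwayNetwork:
    """A named simple undirected graph over gene-symbol nodes.

    Invariants enforced at construction: no self-loops, edges stored in
    canonical sorted-pair form, every edge endpoint present in ``nodes``.
    Isolated nodes are allowed.
    """

    name: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r} in network {self.name!r}")
            if (u, v) != canonical_edge(u, v):
                raise ValueError(f"edge {(u, v)!r} not in canonical form")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"edge {(u, v)!r} has endpoint outside node set of {self.name!r}"
                )

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        normalize: bool = True,
    ) -> "PathwayNetwork":
        """Build from an edge iterable, dropping self-loops (logged) and duplicates."""
        norm = normalize_symbol if normalize else (lambda s: s)
        edge_set: set[tuple[str, str]] = set()
        node_set: set[str] = {norm(n) for n in extra_nodes}
        for u, v in edges:
            u, v = norm(u), norm(v)
            if u == v:
                log.warning("dropping self-loop %s-%s in %s", u, v, name)
                node_set.add(u)
                continue
            edge_set.add(canonical_edge(u, v))
            node_set.update((u, v))
        return cls(name=name, nodes=frozenset(node_set), edges=frozenset(edge_set))

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "") -> "PathwayNetwork":
        return cls.from_edges(name, g.edges(), extra_nodes=g.nodes(), normalize=False)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Interactome:
    """A reference protein–protein interaction edge set with symmetric lookup."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], normalize: bool = True
    ) -> "Interactome":
        norm = normalize_symbol if normalize else (lambda s: s)
        out: set[tuple[str, str]] = set()
        for u, v in edges:
            u, v = norm(u), norm(v)
            if u == v:
                continue
            out.add(canonical_edge(u, v))
        return cls(edges=frozenset(out))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        u, v = pair
        return canonical_edge(u, v) in self.edges

    def edges_within(self, nodes: Iterable[str]) -> frozenset[tuple[str, str]]:
        """All interactome edges whose both endpoints lie in ``nodes``."""
        node_set = set(nodes)
        return frozenset(
            e for e in self.edges if e[0] in node_set and e[1] in node_set
        )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    dialect: str | None = None,
    name: str | None = None,
) -> PathwayNetwork:
    """Read a SIF or two-column TSV edge list into a :class:`PathwayNetwork`.

    ``dialect`` is ``"sif"`` or ``"tsv"``; when *None* it is inferred from
    the file suffix (``.sif`` -> SIF, everything else TSV).  Gene symbols
    are uppercased, duplicate edges collapsed, self-loops dropped with a
    warning.  An empty file yields an empty network.  A malformed row
    raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    if dialect is None:
        dialect = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if dialect == "tsv" else line.split()
            if dialect == "tsv":
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ParseError(
                        f"{path}:{lineno}: expected two tab-separated node columns, "
                        f"got {line!r}"
                    )
                edges.append((fields[0], fields[1]))
            else:  # sif: node1 relation node2 [node3 ...]
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 'node relation node', got {line!r}"
                    )
                src, _relation, *targets = fields
                edges.extend((src, t) for t in targets)
    return PathwayNetwork.from_edges(name if name is not None else path.stem, edges)


def write_edge_list(
    net: PathwayNetwork, path: str | Path, dialect: str = "tsv", relation: str = "pp"
) -> None:
    """Write the network's edges; see :func:`write_node_table` for isolated nodes."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            if dialect == "tsv":
                fh.write(f"{u}\t{v}\n")
            elif dialect == "sif":
                fh.write(f"{u} {relation} {v}\n")
            else:
                raise ValueError(f"unknown edge-list dialect {dialect!r}")


def read_node_table(path: str | Path) -> frozenset[str]:
    """Read a one-column node list (companion to an edge list; keeps isolates)."""
    with open(path) as fh:
        return frozenset(
            normalize_symbol(line) for line in fh if line.strip()
        )


def write_node_table(net: PathwayNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in sorted(net.nodes):
            fh.write(f"{n}\n")


def read_gmt(path: str | Path) -> list[tuple[str, frozenset[str]]]:
    """Read a GMT gene-set file: name, description, then genes, tab-separated.

    Genes are uppercased and deduplicated; records are returned in file
    order.  A line with fewer than three columns raises :class:`ParseError`.
    """
    path = Path(path)
    records: list[tuple[str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, _desc, *genes = fields
            gene_set = frozenset(
                normalize_symbol(g) for g in genes if g.strip()
            )
            records.append((name.strip(), gene_set))
    return records


QUANT_COLUMNS = ("protein_id", "log2fc", "p_value")


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read a protein quantification TSV (protein_id, log2fc, p_value).

    Validates uniqueness of protein ids, finiteness of log2fc, and that
    p-values lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing quantification columns {missing}")
    df = df.loc[:, list(QUANT_COLUMNS)].copy()
    df["protein_id"] = df["protein_id"].map(normalize_symbol)
    if df["protein_id"].duplicated().any():
        dups = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise ParseError(f"{path}: duplicate protein ids {sorted(set(dups))[:5]}")
    if not np.isfinite(df["log2fc"]).all():
        raise ParseError(f"{path}: non-finite log2fc values")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ParseError(f"{path}: p_value outside [0, 1]")
    return df


def filter_deps(
    table: pd.DataFrame, p_max: float = 0.05, min_abs_lfc: float = 0.0
) -> frozenset[str]:
    """Select differentially expressed proteins.

    A protein qualifies when ``p_value < p_max`` and ``|log2fc| > min_abs_lfc``,
    both inequalities strict, so boundary rows (p equal to the cutoff, or a
    fold change of exactly zero at the default) are excluded.
    """
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if min_abs_lfc < 0:
        raise ValueError(f"min_abs_lfc must be >= 0, got {min_abs_lfc}")
    if len(table) == 0:
        return frozenset()
    keep = (table["p_value"] < p_max) & (table["log2fc"].abs() > min_abs_lfc)
    return frozenset(table.loc[keep, "protein_id"])


def read_node_weights(path: str | Path) -> dict[str, float]:
    """Read a two-column ``node <TAB> weight`` table; weights must be >= 0."""
    weights: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'node<TAB>weight'")
            node = normalize_symbol(fields[0])
            try:
                w = float(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {fields[1]!r}") from exc
            if w < 0:
                raise ParseError(f"{path}:{lineno}: negative weight for {node}")
            if node in weights:
                raise ParseError(f"{path}:{lineno}: duplicate node {node}")
            weights[node] = w
    return weights


def read_edge_weights(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a ``node1 <TAB> node2 <TAB> weight`` table, canonicalizing pairs."""
    weights: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'u<TAB>v<TAB>weight'")
            edge = canonical_edge(normalize_symbol(fields[0]), normalize_symbol(fields[1]))
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
            if w < 0:
                raise ParseError(f"{path}:{lineno}: negative weight for {edge}")
            if edge in weights:
                raise ParseError(f"{path}:{lineno}: duplicate edge {edge}")
            weights[edge] = w
    return weights


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def synth_pathway_pair(
    n_a: int,
    n_b: int,
    n_shared: int,
    p_edge: float,
    n_derived: int,
    seed: int,
    name_a: str = "A",
    name_b: str = "B",
) -> tuple[PathwayNetwork, PathwayNetwork, Interactome]:
    """Generate two Erdős–Rényi pathway graphs with controlled overlap.

    The two graphs share exactly ``n_shared`` nodes.  The returned
    interactome contains every pathway edge plus exactly ``n_derived``
    extra edges between union nodes that appear in neither pathway edge
    set.  Fully reproducible for a fixed seed.
    """
    if n_shared > min(n_a, n_b):
        raise ValueError("n_shared cannot exceed min(n_a, n_b)")
    if n_derived < 0:
        raise ValueError("n_derived must be >= 0")
    if not (0.0 <= p_edge <= 1.0):
        raise ValueError("p_edge must be in [0, 1]")
    rng = np.random.default_rng(seed)

    shared = [f"S{i:03d}" for i in range(n_shared)]
    a_only = [f"{name_a}{i:03d}" for i in range(n_a - n_shared)]
    b_only = [f"{name_b}{i:03d}" for i in range(n_b - n_shared)]
    nodes_a = sorted(shared + a_only)
    nodes_b = sorted(shared + b_only)

    def er_edges(nodes: Sequence[str]) -> set[tuple[str, str]]:
        out = set()
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < p_edge:
                out.add(canonical_edge(u, v))
        return out

    edges_a = er_edges(nodes_a)
    edges_b = er_edges(nodes_b)
    net_a = PathwayNetwork(name_a, frozenset(nodes_a), frozenset(edges_a))
    net_b = PathwayNetwork(name_b, frozenset(nodes_b), frozenset(edges_b))

    union_nodes = sorted(set(nodes_a) | set(nodes_b))
    pathway_edges = edges_a | edges_b
    candidates = sorted(
        e
        for e in (canonical_edge(u, v) for u, v in itertools.combinations(union_nodes, 2))
        if e not in pathway_edges
    )
    if n_derived > len(candidates):
        raise ValueError(
            f"requested {n_derived} derived edges but only {len(candidates)} "
            "non-pathway node pairs exist"
        )
    idx = rng.choice(len(candidates), size=n_derived, replace=False) if n_derived else []
    derived = {candidates[i] for i in np.sort(np.asarray(idx, dtype=int))}
    interactome = Interactome(frozenset(pathway_edges | derived))
    return net_a, net_b, interactome


def synth_quant_table(
    protein_ids: Sequence[str],
    frac_dep: float,
    effect_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a protein quantification table with a known DEP fraction.

    A fraction ``frac_dep`` of proteins receives a nonzero log2 fold change
    drawn from N(0, effect_sd) (resampled away from zero) and a p-value
    below 0.05; the rest receive log2fc of either sign with p-values above
    0.05, so they fail the DEP filter on the p-value criterion alone.
    """
    if not (0.0 <= frac_dep <= 1.0):
        raise ValueError("frac_dep must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [normalize_symbol(p) for p in protein_ids]
    n = len(ids)
    n_dep = int(round(frac_dep * n))
    is_dep = np.zeros(n, dtype=bool)
    if n_dep:
        is_dep[rng.choice(n, size=n_dep, replace=False)] = True
    lfc = rng.normal(0.0, effect_sd, size=n)
    lfc[lfc == 0.0] = effect_sd  # N(0,1) draws of exactly 0 are measure-zero anyway
    pvals = np.where(
        is_dep,
        rng.uniform(1e-6, 0.049, size=n),
        rng.uniform(0.051, 1.0, size=n),
    )
    return pd.DataFrame(
        {"protein_id": ids, "log2fc": lfc, "p_value": pvals}
    )
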