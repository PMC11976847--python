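"""Shared fixtures: small hand-built networks and a synthetic study layout."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from naa import Interactome, PathwayNetwork, canonical_edge, synth_quant_table
from naa.graph_io import write_edge_list


@pytest.fixture
def triangle_a() -> PathwayNetwork:
    return PathwayNetwork.from_edges("a", [("A", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def triangle_b() -> PathwayNetwork:
    return PathwayNetwork.from_edges("b", [("B", "C"), ("B", "D"), ("C", "D")])


def random_network(name: str, nodes: list[str], p: float, rng: np.random.Generator) -> PathwayNetwork:
    edges = [
        canonical_edge(u, v)
        for u, v in itertools.combinations(sorted(nodes), 2)
        if rng.random() < p
    ]
    return PathwayNetwork(name, frozenset(nodes), frozenset(edges))


@pytest.fixture
def study_dir(tmp_path):
    """A small on-disk study: networks dir, interactome, quant table, config.

    Engineered so that the (SIG1, PROC1) pair shares most of its nodes and
    edges while every other pair is node-disjoint, making the expected
    argmax of the pairwise matrix unambiguous.
    """
    rng = np.random.default_rng(2024)
    base_nodes = [f"G{i:02d}" for i in range(10)]
    sig1 = random_network("SIG1", base_nodes, 0.5, rng)
    # PROC1 keeps 8 of SIG1's nodes and most induced edges
    kept = sorted(base_nodes[:8])
    kept_edges = {e for e in sig1.edges if e[0] in kept and e[1] in kept}
    proc1 = PathwayNetwork(
        "PROC1", frozenset(kept + ["H00", "H01"]),
        frozenset(kept_edges | {canonical_edge("H00", "H01")}),
    )
    sig2 = random_network("SIG2", [f"X{i:02d}" for i in range(8)], 0.4, rng)
    proc2 = random_network("PROC2", [f"Y{i:02d}" for i in range(8)], 0.4, rng)

    nets_dir = tmp_path / "networks"
    nets_dir.mkdir()
    for net in (sig1, proc1, sig2, proc2):
        write_edge_list(net, nets_dir / f"{net.name}.tsv")

    all_nodes = sorted(sig1.nodes | proc1.nodes | sig2.nodes | proc2.nodes)
    inter_edges = set(sig1.edges | proc1.edges | sig2.edges | proc2.edges)
    inter_edges.add(canonical_edge("G00", "H00"))  # one derived edge
    interactome = PathwayNetwork("interactome", frozenset(all_nodes), frozenset(inter_edges))
    write_edge_list(interactome, tmp_path / "interactome.tsv")

    quant = synth_quant_table(all_nodes, frac_dep=0.3, seed=7)
    quant.to_csv(tmp_path / "quant.tsv", sep="\t", index=False)

    config = tmp_path / "config.yaml"
    config.write_text(
        "quant: quant.tsv\n"
        "networks_dir: networks\n"
        "interactome: interactome.tsv\n"
        "signal: [SIG1, SIG2]\n"
        "process: [PROC1, PROC2]\n"
        f"out_dir: {tmp_path / 'out'}\n"
        "weighted: true\n"
        "seed: 17\n"
    )
    return tmp_path
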