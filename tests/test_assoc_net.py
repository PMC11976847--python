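"""Associated-network construction and the association coefficients."""

import math

import numpy as np
import pytest

from naa import (
    Interactome,
    PathwayNetwork,
    association_coefficient,
    build_association,
    combine_pathways,
    count_components,
    pairwise_matrix,
    synth_pathway_pair,
    weighted_association,
)
from naa.assoc_net import AssociationCounts

from _oracles import assoc_coeff_oracle, assoc_counts_oracle


class TestBuildAssociation:
    def test_two_triangles(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        assert assoc.nodes == {"A", "B", "C", "D"}
        assert len(assoc.edges) == 5
        assert assoc.edges_with_label("overlapping") == {("B", "C")}
        assert assoc.edges_with_label("derived") == frozenset()
        assert assoc.shared_nodes == {"B", "C"}

    def test_interactome_adds_one_derived_edge(self, triangle_a, triangle_b):
        inter = Interactome.from_edges([("A", "D")])
        assoc = build_association(triangle_a, triangle_b, inter)
        assert len(assoc.edges) == 6
        assert assoc.edges_with_label("derived") == {("A", "D")}

    def test_identical_networks(self, triangle_a):
        assoc = build_association(triangle_a, triangle_a)
        assert set(assoc.node_labels.values()) == {"shared"}
        assert set(assoc.edge_labels.values()) == {"overlapping"}

    def test_interactome_never_adds_nodes(self, triangle_a, triangle_b):
        inter = Interactome.from_edges([("A", "Z"), ("Z", "Q")])
        assoc = build_association(triangle_a, triangle_b, inter)
        assert "Z" not in assoc.nodes and "Q" not in assoc.nodes

    def test_cross_only_mode_drops_same_side_edges(self):
        a = PathwayNetwork.from_edges("a", [("A1", "A2")], extra_nodes=["A3"])
        b = PathwayNetwork.from_edges("b", [("B1", "B2")])
        inter = Interactome.from_edges([("A1", "A3"), ("A1", "B1")])
        any_mode = build_association(a, b, inter, derived_mode="any")
        cross = build_association(a, b, inter, derived_mode="cross-only")
        assert any_mode.edges_with_label("derived") == {("A1", "A3"), ("A1", "B1")}
        assert cross.edges_with_label("derived") == {("A1", "B1")}


class TestCounts:
    def test_two_triangles(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        c = count_components(assoc, 3, 3)
        assert (c.n_a, c.n_b, c.n_ab, c.e_ab, c.n_r, c.e_r, c.e_d) == (3, 3, 4, 5, 2, 1, 0)

    def test_identical_networks(self, triangle_a):
        assoc = build_association(triangle_a, triangle_a)
        c = count_components(assoc, 3, 3)
        assert c.n_r == 3 and c.e_r == 3 and c.e_d == 0

    def test_edgeless_pair(self):
        a = PathwayNetwork("a", frozenset({"A", "B"}), frozenset())
        b = PathwayNetwork("b", frozenset({"B", "C"}), frozenset())
        c = count_components(build_association(a, b), 2, 2)
        assert c.e_ab == 0 and c.n_r == 1 and c.n_ab == 3

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            AssociationCounts(n_a=2, n_b=2, n_ab=3, e_ab=1, n_r=3, e_r=0, e_d=0)


class TestCoefficient:
    def test_hand_worked_example(self, triangle_a, triangle_b):
        c = count_components(build_association(triangle_a, triangle_b), 3, 3)
        score = association_coefficient(c)
        assert score.c_n == 0.5
        assert score.c_e == 0.2
        assert score.c == pytest.approx(math.sqrt(0.145), abs=1e-15)

    def test_identity_scores_one(self, triangle_a):
        c = count_components(build_association(triangle_a, triangle_a), 3, 3)
        score = association_coefficient(c)
        assert (score.c_n, score.c_e, score.c) == (1.0, 1.0, 1.0)

    def test_edgeless_reduces_to_node_coefficient(self):
        c = AssociationCounts(n_a=2, n_b=2, n_ab=3, e_ab=0, n_r=1, e_r=0, e_d=0)
        score = association_coefficient(c)
        assert score.edgeless and score.c_e is None
        assert score.c == score.c_n == pytest.approx(1 / 3)

    def test_empty_association_is_error(self):
        c = AssociationCounts(n_a=0, n_b=0, n_ab=0, e_ab=0, n_r=0, e_r=0, e_d=0)
        with pytest.raises(ValueError):
            association_coefficient(c)

    def test_derived_edge_never_decreases_c_e(self):
        base = AssociationCounts(n_a=4, n_b=4, n_ab=6, e_ab=8, n_r=2, e_r=2, e_d=0)
        more = AssociationCounts(n_a=4, n_b=4, n_ab=6, e_ab=9, n_r=2, e_r=2, e_d=1)
        assert association_coefficient(more).c_e >= association_coefficient(base).c_e


class TestWeighted:
    def test_hand_worked_example(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        node_w = {"A": 1.0, "B": 2.0, "C": 2.0, "D": 1.0}
        edge_w = {e: 1.0 for e in assoc.edges}
        score = weighted_association(assoc, node_w, edge_w)
        assert score.c_nw == pytest.approx(4 / 6, abs=1e-15)
        assert score.c_ew == pytest.approx(0.2, abs=1e-15)
        assert score.c_w == pytest.approx(math.sqrt(((4 / 6) ** 2 + 0.04) / 2), abs=1e-15)

    def test_uniform_weights_reduce_to_unweighted(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        node_w = {n: 1.0 for n in assoc.nodes}
        edge_w = {e: 1.0 for e in assoc.edges}
        score = weighted_association(assoc, node_w, edge_w)
        assert score.c_nw == pytest.approx(score.c_n, abs=1e-12)
        assert score.c_ew == pytest.approx(score.c_e, abs=1e-12)
        assert score.c_w == pytest.approx(score.c, abs=1e-12)

    def test_zero_shared_weight(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        node_w = {"A": 1.0, "B": 0.0, "C": 0.0, "D": 1.0}
        edge_w = {e: 1.0 for e in assoc.edges}
        assert weighted_association(assoc, node_w, edge_w).c_nw == 0.0

    def test_missing_weight_lists_offenders(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        with pytest.raises(ValueError, match="missing weights"):
            weighted_association(assoc, {"A": 1.0}, {})

    def test_all_zero_node_weights_rejected(self, triangle_a, triangle_b):
        assoc = build_association(triangle_a, triangle_b)
        node_w = {n: 0.0 for n in assoc.nodes}
        edge_w = {e: 1.0 for e in assoc.edges}
        with pytest.raises(ValueError, match="positive"):
            weighted_association(assoc, node_w, edge_w)


class TestRandomPairsAgainstOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_counts_and_coefficients_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a, b, inter = synth_pathway_pair(
            int(rng.integers(2, 15)), int(rng.integers(2, 15)),
            int(rng.integers(0, 3)), float(rng.uniform(0.1, 0.7)),
            int(rng.integers(0, 4)), seed=seed + 100,
        )
        assoc = build_association(a, b, inter)
        counts = count_components(assoc, a.n_nodes, b.n_nodes)
        expected = assoc_counts_oracle(a.nodes, a.edges, b.nodes, b.edges, inter.edges)
        assert counts.n_ab == expected["n_ab"]
        assert counts.e_ab == expected["e_ab"]
        assert counts.n_r == expected["n_r"]
        assert counts.e_r == expected["e_r"]
        assert counts.e_d == expected["e_d"]
        got = association_coefficient(counts)
        want = assoc_coeff_oracle(expected)
        assert got.c == pytest.approx(want["c"], abs=1e-12)
        assert 0.0 <= got.c <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry(self, seed):
        a, b, inter = synth_pathway_pair(8, 10, 3, 0.4, 2, seed=seed)
        c_ab = association_coefficient(
            count_components(build_association(a, b, inter), a.n_nodes, b.n_nodes)
        )
        c_ba = association_coefficient(
            count_components(build_association(b, a, inter), b.n_nodes, a.n_nodes)
        )
        assert c_ab.c == pytest.approx(c_ba.c, abs=1e-15)


class TestPairwiseMatrix:
    def test_identical_pair_cell_is_one(self, triangle_a):
        pw = pairwise_matrix([triangle_a], [triangle_a])
        assert float(pw.matrix.iloc[0, 0]) == 1.0

    def test_disjoint_column_is_zero(self, triangle_a):
        far = PathwayNetwork.from_edges("far", [("X", "Y"), ("Y", "Z")])
        sig2 = PathwayNetwork.from_edges("sig2", [("A", "B")])
        pw = pairwise_matrix([triangle_a, sig2], [far, triangle_a])
        assert (pw.matrix["far"] == 0.0).all()
        assert pw.best_pair == ("a", "a")

    def test_role_swap_leaves_score_unchanged(self, triangle_a, triangle_b):
        pw1 = pairwise_matrix([triangle_a], [triangle_b])
        pw2 = pairwise_matrix([triangle_b], [triangle_a])
        assert float(pw1.matrix.iloc[0, 0]) == pytest.approx(
            float(pw2.matrix.iloc[0, 0]), abs=1e-15
        )

    def test_weighted_mode_runs_per_pair(self, triangle_a, triangle_b):
        pw = pairwise_matrix([triangle_a], [triangle_b], weighted=True)
        score = pw.best_score
        assert score.c_w is not None and 0.0 <= score.c_w <= 1.0

    def test_pair_error_carries_labels(self):
        # a single-node associated network cannot be entropy-weighted
        lonely = PathwayNetwork("solo", frozenset({"Q"}), frozenset())
        with pytest.raises(RuntimeError, match=r"\(solo, solo\)"):
            pairwise_matrix([lonely], [lonely], weighted=True)


class TestCombine:
    def test_union(self):
        x = PathwayNetwork.from_edges("x", [("A", "B")])
        y = PathwayNetwork.from_edges("y", [("B", "C")])
        combined = combine_pathways([x, y], "x+y")
        assert combined.nodes == {"A", "B", "C"}
        assert combined.edges == {("A", "B"), ("B", "C")}

    def test_idempotent(self, triangle_a):
        once = combine_pathways([triangle_a], "t")
        twice = combine_pathways([triangle_a, triangle_a], "t")
        assert once.nodes == twice.nodes == triangle_a.nodes
        assert once.edges == twice.edges == triangle_a.edges
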