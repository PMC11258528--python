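"""Conditional-independence testing, IAMB, and network averaging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import bnscreen as b
from bnscreen.structure import DiscreteData, _find_sepset


def brute_force_g(df, x, y, z):
    """Independent G computation by explicit summation over the contingency table."""
    n = len(df)
    g = 0.0
    z = list(z)
    groups = [(None, df)] if not z else list(df.groupby(z, sort=True))
    for _, sub in groups:
        nk = len(sub)
        for xv, sx in sub.groupby(x, sort=True):
            for yv, sxy in sx.groupby(y, sort=True):
                nxy = len(sxy)
                nx = (sub[x] == xv).sum()
                ny = (sub[y] == yv).sum()
                g += 2.0 * nxy * math.log(nxy * nk / (nx * ny))
    dof = (df[x].nunique() - 1) * (df[y].nunique() - 1)
    for v in z:
        dof *= df[v].nunique()
    return g, dof


class TestCITest:
    def test_identical_balanced_binary_closed_form(self):
        df = pd.DataFrame({"x": [0, 1] * 50})
        df["y"] = df["x"]
        res = b.ci_test(df, "x", "y")
        assert res.g == pytest.approx(2 * 100 * math.log(2), abs=1e-9)
        assert res.dof == 1
        assert res.p_value < 1e-12

    def test_constant_column_null(self):
        df = pd.DataFrame({"x": [1] * 40, "y": [0, 1] * 20})
        res = b.ci_test(df, "x", "y")
        assert res.g == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("with_z", [False, True])
    def test_matches_brute_force_on_random_tables(self, with_z, rng):
        """200 random ≤4×4×4 instances agree with the explicit-table oracle."""
        for _ in range(100):
            rx, ry, rz = rng.integers(2, 5, size=3)
            n = int(rng.integers(30, 200))
            df = pd.DataFrame(
                {
                    "x": rng.integers(0, rx, n),
                    "y": rng.integers(0, ry, n),
                    "z": rng.integers(0, rz, n),
                }
            )
            z = ["z"] if with_z else []
            res = b.ci_test(df, "x", "y", z)
            g, dof = brute_force_g(df, "x", "y", z)
            assert res.g == pytest.approx(g, abs=1e-9)
            assert res.dof == dof

    def test_empty_data_is_error(self):
        with pytest.raises(ValueError):
            b.ci_test(pd.DataFrame({"x": [], "y": []}), "x", "y")


def sample_chain(n, seed):
    """A → T → B with strong links."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    t = np.where(rng.random(n) < 0.85, a, 1 - a)
    c = np.where(rng.random(n) < 0.85, t, 1 - t)
    return pd.DataFrame({"A": a, "T": t, "B": c})


def sample_collider(n, seed, p_edge=0.85):
    """A → Y ← B with independent A, B."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    c = rng.integers(0, 2, n)
    y = np.where(rng.random(n) < p_edge, a | c, rng.integers(0, 2, n))
    return pd.DataFrame({"A": a, "B": c, "Y": y})


class TestIAMB:
    def test_chain_blanket(self):
        df = sample_chain(5000, 3)
        assert b.iamb_markov_blanket("T", df) == {"A", "B"}
        assert b.iamb_markov_blanket("A", df) == {"T"}

    def test_independent_target_empty(self, rng):
        df = pd.DataFrame(rng.integers(0, 2, size=(3000, 4)), columns=list("wxyz"))
        assert b.iamb_markov_blanket("w", df, alpha=0.01) == set()

    def test_spouse_found_through_child(self):
        df = sample_collider(8000, 11)
        assert b.iamb_markov_blanket("A", df) == {"Y", "B"}

    def test_column_order_insensitive(self):
        df = sample_chain(4000, 5)
        mb1 = b.iamb_markov_blanket("T", df)
        mb2 = b.iamb_markov_blanket("T", df[["B", "T", "A"]])
        assert mb1 == mb2

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            b.iamb_markov_blanket("x", pd.DataFrame({"x": [0, 1]}))


class TestLearnStructure:
    def test_collider_orientation(self):
        g = b.learn_structure(sample_collider(8000, 2))
        assert ("A", "Y") in g.directed and ("B", "Y") in g.directed

    def test_independent_columns_edgeless(self, rng):
        df = pd.DataFrame(rng.integers(0, 3, size=(2000, 4)), columns=list("abcd"))
        g = b.learn_structure(df, alpha=0.01)
        assert not g.skeleton_edges()

    def test_deterministic(self):
        df = sample_chain(3000, 7)
        g1, g2 = b.learn_structure(df), b.learn_structure(df)
        assert g1.directed == g2.directed and g1.undirected == g2.undirected

    def test_chain_skeleton_without_spurious_edge(self):
        g = b.learn_structure(sample_chain(6000, 9))
        assert g.skeleton_edges() == {frozenset(("A", "T")), frozenset(("T", "B"))}


class TestBootstrapAndAveraging:
    def test_single_replicate_strengths_are_binary(self):
        df = sample_chain(1500, 1)
        conf = b.bootstrap_confidence(df, B=1, seed=4)
        for e in conf.pairs():
            a, c = tuple(e)
            assert conf.strength(a, c) in (0.0, 1.0)

    def test_directions_sum_to_one(self):
        df = sample_collider(2000, 3)
        conf = b.bootstrap_confidence(df, B=20, seed=4)
        for e in conf.pairs():
            a, c = tuple(e)
            if conf.strength(a, c) > 0:
                assert conf.direction(a, c) + conf.direction(c, a) == pytest.approx(1.0)

    def test_strength_threshold_boundary(self):
        conf = b.EdgeConfidence(nodes=["a", "c"], n_boot=10000)
        conf.presence[frozenset(("a", "c"))] = 5000
        conf.orientation[("a", "c")] = 4000.0
        g, _ = b.average_network(conf)
        assert g.skeleton_edges() == {frozenset(("a", "c"))}
        conf.presence[frozenset(("a", "c"))] = 4999
        g, _ = b.average_network(conf)
        assert not g.skeleton_edges()

    def test_majority_direction_and_tie_rule(self):
        conf = b.EdgeConfidence(nodes=["a", "c", "e"], n_boot=10)
        conf.presence[frozenset(("a", "c"))] = 10
        conf.orientation[("a", "c")] = 4.0  # minority: orient c→a
        conf.presence[frozenset(("c", "e"))] = 10
        conf.orientation[("c", "e")] = 5.0  # exact tie: lexicographic c→e
        g, notes = b.average_network(conf)
        assert ("c", "a") in g.directed
        assert ("c", "e") in g.directed
        assert any("tie" in n for n in notes)

    def test_cycle_broken_at_weakest_edge(self):
        conf = b.EdgeConfidence(nodes=["a", "c", "e"], n_boot=10)
        for pair, strength, fwd in [(("a", "c"), 9, 9.0), (("c", "e"), 8, 8.0), (("e", "a"), 6, 6.0)]:
            conf.presence[frozenset(pair)] = strength
            conf.orientation[pair] = fwd
        g, notes = b.average_network(conf)
        assert ("e", "a") not in g.directed
        assert ("a", "c") in g.directed and ("c", "e") in g.directed
        assert any("cycle" in n for n in notes)

    def test_empty_confidence_empty_graph(self):
        g, _ = b.average_network(b.EdgeConfidence(nodes=["a", "c"], n_boot=5))
        assert not g.skeleton_edges()


class TestPruning:
    def test_dependent_edge_retained_independent_removed(self, rng):
        n = 4000
        x = rng.integers(0, 2, n)
        df = pd.DataFrame({"x": x, "y": x, "z": rng.integers(0, 2, n)})
        g = b.BNGraph(["x", "y", "z"], {("x", "y"), ("z", "y")}, set())
        pruned = b.prune_by_independence(g, df)
        assert ("x", "y") in pruned.directed
        assert ("z", "y") not in pruned.directed

    def test_null_edge_removal_rate(self):
        """Type-I behaviour: an edge between independent columns is pruned ~95% of the time."""
        removed = 0
        reps = 40
        g = b.BNGraph(["x", "y"], {("x", "y")}, set())
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            df = pd.DataFrame({"x": rng.integers(0, 2, 2000), "y": rng.integers(0, 2, 2000)})
            removed += ("x", "y") not in b.prune_by_independence(g, df).directed
        assert removed / reps >= 0.85

    def test_edgeless_unchanged(self, rng):
        df = pd.DataFrame({"x": rng.integers(0, 2, 100), "y": rng.integers(0, 2, 100)})
        g = b.BNGraph(["x", "y"], set(), set())
        assert not b.prune_by_independence(g, df).skeleton_edges()


class TestBlanketReadoff:
    def test_parents_children_spouses(self):
        g = b.BNGraph(list("AYCDE"), {("A", "Y"), ("Y", "C"), ("D", "C"), ("Y", "E")}, set())
        mb = b.markov_blanket_of(g, "Y")
        assert (mb.parents, mb.children, mb.spouses) == ({"A"}, {"C", "E"}, {"D"})

    def test_isolated_node_empty(self):
        g = b.BNGraph(["Y", "Z"], set(), set())
        mb = b.markov_blanket_of(g, "Y")
        assert mb.all() == set()

    def test_linked_coparent_is_not_spouse(self):
        """A co-parent already linked to the node counts as parent, not spouse."""
        g = b.BNGraph(list("DYC"), {("D", "C"), ("D", "Y"), ("Y", "C")}, set())
        mb = b.markov_blanket_of(g, "Y")
        assert mb.parents == {"D"} and mb.spouses == set()

    def test_undirected_incident_is_error(self):
        g = b.BNGraph(["Y", "A"], set(), {("Y", "A")})
        with pytest.raises(ValueError, match="orient"):
            b.markov_blanket_of(g, "Y")

    def test_spouse_definition_matches_enumeration(self):
        """Exhaustive check of the read-off on all DAGs over 4 nodes with ≤4 edges."""
        nodes = list("YABC")
        pairs = list(itertools.permutations(nodes, 2))
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(0, 5)
            edges = set(map(tuple, rng.choice(pairs, size=k, replace=False))) if k else set()
            try:
                g = b.BNGraph(nodes, edges, set())
            except ValueError:  # cyclic or duplicate draw
                continue
            mb = b.markov_blanket_of(g, "Y")
            parents = {a for a, c in edges if c == "Y"}
            children = {c for a, c in edges if a == "Y"}
            spouses = {
                a
                for c in children
                for a, cc in edges
                if cc == c and a != "Y" and a not in parents and a not in children
            }
            assert mb.parents == parents
            assert mb.children == children
            assert mb.spouses == spouses


class TestAllPathFeatures:
    def test_chain_with_isolated_node(self):
        g = b.BNGraph(list("ABYC"), {("A", "B"), ("B", "Y")}, set())
        assert b.all_path_features(g, "Y") == {"A", "B"}

    def test_blanket_subset_of_path_features(self):
        g = b.learn_structure(sample_collider(5000, 21))
        if not g.has_undirected_incident("Y"):
            mb = b.markov_blanket_of(g, "Y")
            assert mb.all() <= b.all_path_features(g, "Y")

    def test_complete_skeleton(self):
        g = b.BNGraph(list("abc"), set(), {("a", "b"), ("b", "c"), ("a", "c")})
        assert b.all_path_features(g, "a") == {"b", "c"}


def test_sepset_search_separates_chain_ends():
    df = sample_chain(5000, 13)
    dd = DiscreteData(df)
    mbs = {v: b.iamb_markov_blanket(v, dd) for v in df.columns}
    sep = _find_sepset(dd, "A", "B", mbs, 0.05)
    assert sep == {"T"}
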