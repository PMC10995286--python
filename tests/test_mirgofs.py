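"""GO-annotation miRNA similarity: IC, LCA/HCD, term weights, profiles."""

import math
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from mirsea.core import AssociationTable, OntologyDAG
from mirsea.mirgofs import (
    AnnotatedGOGraph,
    build_mirsn_goa,
    build_term_weighting,
    go_term_similarity,
    information_content,
    lca_hcd,
    mirgofs_similarity,
    term_weight,
    TermWeighting,
)
from mirsea.synthetic import gen_go_annotations, gen_ontology


def make_graph(edges, annotations):
    terms = {t for e in edges for t in e} | {t for _, t in annotations}
    dag = OntologyDAG(terms, edges)
    return AnnotatedGOGraph(dag, AssociationTable(annotations))


@pytest.fixture
def diamond_graph():
    """root <- p1, p2; c <- p1, p2. Genes g1..g4 spread over the terms."""
    edges = [("p1", "root"), ("p2", "root"), ("c", "p1"), ("c", "p2")]
    annotations = [
        ("g1", "c"), ("g2", "p1"), ("g3", "p2"), ("g4", "root"),
    ]
    return make_graph(edges, annotations)


class TestAnnotatedGOGraph:
    def test_true_path_closure(self, diamond_graph):
        assert diamond_graph.gene_sets["c"] == {"g1"}
        assert diamond_graph.gene_sets["p1"] == {"g1", "g2"}
        assert diamond_graph.gene_sets["root"] == {"g1", "g2", "g3", "g4"}

    def test_child_subset_of_parent_on_random_fixtures(self):
        dag = gen_ontology(15, seed=9, prefix="go")
        genes = [f"g{i}" for i in range(10)]
        ann = gen_go_annotations(dag, genes, seed=9)
        graph = AnnotatedGOGraph(dag, ann)
        for child, parent in dag.edges:
            if child in graph.gene_sets and parent in graph.gene_sets:
                assert graph.gene_sets[child] <= graph.gene_sets[parent]

    def test_ic_monotone_child_at_least_parent(self):
        dag = gen_ontology(15, seed=10, prefix="go")
        genes = [f"g{i}" for i in range(12)]
        graph = AnnotatedGOGraph(dag, gen_go_annotations(dag, genes, seed=10))
        for child, parent in dag.edges:
            if child in graph.ic and parent in graph.ic:
                assert graph.ic[child] >= graph.ic[parent] - 1e-12

    def test_unannotated_terms_pruned(self):
        graph = make_graph([("a", "root"), ("b", "root")], [("g1", "a")])
        assert "b" not in graph.terms
        with pytest.raises(KeyError, match="pruned"):
            information_content(graph, "b")


class TestInformationContent:
    def test_root_is_zero(self, diamond_graph):
        assert information_content(diamond_graph, "root") == 0.0

    @pytest.mark.parametrize(
        "n_term, n_root, expected", [(50, 100, 0.6931), (1, 100, 4.6052)]
    )
    def test_log_fraction(self, n_term, n_root, expected):
        annotations = [(f"g{i}", "x") for i in range(n_term)]
        annotations += [(f"g{i}", "root") for i in range(n_root)]
        graph = make_graph([("x", "root")], annotations)
        assert information_content(graph, "x") == pytest.approx(expected, abs=1e-4)


class TestLcaHcd:
    def test_same_term(self, diamond_graph):
        assert lca_hcd(diamond_graph, "p1", "p1") == ({"p1"}, {"p1"})

    def test_siblings_without_shared_child(self):
        graph = make_graph(
            [("a", "root"), ("b", "root")], [("g1", "a"), ("g2", "b")]
        )
        lca, hcd = lca_hcd(graph, "a", "b")
        assert lca == {"root"}
        assert hcd == set()

    def test_diamond_parents_share_root_and_child(self, diamond_graph):
        lca, hcd = lca_hcd(diamond_graph, "p1", "p2")
        assert lca == {"root"}
        assert hcd == {"c"}

    def test_matches_exhaustive_intersection(self):
        dag = gen_ontology(12, seed=4, prefix="go")
        genes = [f"g{i}" for i in range(8)]
        graph = AnnotatedGOGraph(dag, gen_go_annotations(dag, genes, seed=4))
        terms = sorted(graph.terms)
        for x, y in combinations(terms[:6], 2):
            lca, hcd = lca_hcd(graph, x, y)
            ca = dag.ancestor_closure(x) & dag.ancestor_closure(y)
            cd = dag.descendant_closure(x) & dag.descendant_closure(y)
            expected_lca = {
                t for t in ca if not any(
                    t in dag.ancestor_closure(o) - {o} for o in ca
                )
            }
            expected_hcd = {
                t for t in cd if not any(
                    t in dag.descendant_closure(o) - {o} for o in cd
                )
            }
            assert lca == expected_lca
            assert hcd == expected_hcd


class TestGoTermSimilarity:
    def test_self_similarity_is_one(self, diamond_graph):
        assert go_term_similarity(diamond_graph, "c", "c") == 1.0

    def test_root_only_common_ancestor_gives_zero(self):
        graph = make_graph(
            [("a", "root"), ("b", "root")], [("g1", "a"), ("g2", "b")]
        )
        assert go_term_similarity(graph, "a", "b") == 0.0

    def test_hand_case_quarter(self):
        # IC(x)=IC(y)=ln 4 = 2*ln 2, LCA term with IC=ln 2, no common descendant
        annotations = (
            [("g1", "x")] + [("g2", "y")]
            + [(g, "mid") for g in ("g1", "g2")]
            + [(f"g{i}", "root") for i in range(1, 5)]
        )
        graph = make_graph([("x", "mid"), ("y", "mid"), ("mid", "root")], annotations)
        assert information_content(graph, "x") == pytest.approx(math.log(4))
        assert go_term_similarity(graph, "x", "y") == pytest.approx(0.25)

    def test_symmetric_and_bounded(self):
        dag = gen_ontology(14, seed=6, prefix="go")
        genes = [f"g{i}" for i in range(10)]
        graph = AnnotatedGOGraph(dag, gen_go_annotations(dag, genes, seed=6))
        terms = sorted(graph.terms)[:8]
        for x, y in combinations(terms, 2):
            s = go_term_similarity(graph, x, y)
            assert 0.0 <= s <= 1.0
            assert s == go_term_similarity(graph, y, x)


def exhaustive_upper_tail(N, M, n, k) -> Fraction:
    """P(X >= k) by direct summation with exact rational arithmetic."""
    return sum(
        (
            Fraction(comb(M, i) * comb(N - M, n - i), comb(N, n))
            for i in range(k, min(n, M) + 1)
        ),
        Fraction(0),
    )


class TestTermWeight:
    def test_zero_overlap_gives_zero_weight(self):
        assert term_weight(10, 5, 4, 0) == 0.0

    def test_hand_case_full_overlap(self):
        assert term_weight(10, 5, 4, 4) == pytest.approx(-math.log(5 / 210), abs=1e-4)

    def test_hand_case_single_overlap(self):
        assert term_weight(10, 5, 4, 1) == pytest.approx(0.02410, abs=1e-5)

    def test_impossible_counts_error(self):
        with pytest.raises(ValueError, match="impossible"):
            term_weight(10, 5, 4, 5)

    @pytest.mark.parametrize("N", range(2, 9))
    def test_matches_exact_enumeration(self, N):
        for M in range(1, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(n, M) + 1):
                    tail = exhaustive_upper_tail(N, M, n, k)
                    w = term_weight(N, M, n, k)
                    if k == 0:
                        assert w == 0.0
                    elif tail > 0:
                        assert w == pytest.approx(-math.log(float(tail)), abs=1e-9)


class TestMirgofsSimilarity:
    def test_identical_profiles_give_one(self, diamond_graph):
        w = build_term_weighting(diamond_graph, "m1", {"g1", "g2"})
        assert mirgofs_similarity(diamond_graph, w, w) == pytest.approx(1.0)

    def test_zero_cross_similarity_gives_zero(self):
        graph = make_graph(
            [("a", "root"), ("b", "root")], [("g1", "a"), ("g2", "b")]
        )
        wa = TermWeighting("m1", {"a": 1.0}, 2, 1)
        wb = TermWeighting("m2", {"b": 1.0}, 2, 1)
        assert mirgofs_similarity(graph, wa, wb) == 0.0

    def test_hand_case_single_terms(self, monkeypatch):
        graph = make_graph([("x", "root"), ("y", "root")], [("g1", "x"), ("g2", "y")])
        monkeypatch.setattr(
            "mirsea.mirgofs.go_term_similarity", lambda g, a, b: 0.5
        )
        wq = TermWeighting("q", {"x": 2.0}, 2, 1)
        wt = TermWeighting("t", {"y": 1.0}, 2, 1)
        assert mirgofs_similarity(graph, wq, wt) == pytest.approx(0.5)

    def test_all_zero_weights_is_an_error(self, diamond_graph):
        w = build_term_weighting(diamond_graph, "m1", {"g1"})
        empty = TermWeighting("m2", {}, 4, 1)
        with pytest.raises(ValueError, match="m2"):
            mirgofs_similarity(diamond_graph, w, empty)

    def test_invariant_to_duplicate_annotation_rows(self):
        dag = gen_ontology(10, seed=8, prefix="go")
        genes = [f"g{i}" for i in range(8)]
        ann = gen_go_annotations(dag, genes, seed=8)
        doubled = AssociationTable(list(ann.pairs) + list(ann.pairs))
        g1 = AnnotatedGOGraph(dag, ann)
        g2 = AnnotatedGOGraph(dag, doubled)
        w1 = build_term_weighting(g1, "m", set(genes[:3]))
        w2 = build_term_weighting(g2, "m", set(genes[:3]))
        assert dict(w1.weights) == dict(w2.weights)


class TestBuildMirsnGoa:
    @pytest.fixture
    def fixture_inputs(self):
        dag = gen_ontology(12, seed=12, prefix="go")
        genes = [f"g{i}" for i in range(10)]
        ann = gen_go_annotations(dag, genes, seed=12)
        targets = AssociationTable(
            [("m1", "g0"), ("m1", "g1"), ("m2", "g0"), ("m2", "g1"),
             ("m3", "g5"), ("m4", "g7"), ("m4", "g8")]
        )
        return targets, dag, ann

    def test_identical_target_sets_give_one(self, fixture_inputs):
        targets, dag, ann = fixture_inputs
        m = build_mirsn_goa(targets, dag, ann)
        assert m.loc("m1", "m2") == pytest.approx(1.0)

    def test_matrix_equals_pairwise_similarity(self, fixture_inputs):
        targets, dag, ann = fixture_inputs
        m = build_mirsn_goa(targets, dag, ann)
        graph = AnnotatedGOGraph(dag, ann)
        weightings = {
            mid: build_term_weighting(graph, mid, targets.annotations_of(mid))
            for mid in m.ids
        }
        for a in m.ids:
            for b in m.ids:
                if a != b:
                    expected = mirgofs_similarity(graph, weightings[a], weightings[b])
                    assert m.loc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mirna_without_annotated_targets_excluded(self, fixture_inputs):
        targets, dag, ann = fixture_inputs
        with_orphan = AssociationTable(
            list(targets.pairs) + [("m5", "not-a-gene")]
        )
        m = build_mirsn_goa(with_orphan, dag, ann)
        assert "m5" not in m.ids
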