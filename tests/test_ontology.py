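"""Controlled-vocabulary loading, closures, IC and Resnik similarity."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppitype import ontology as onto


def bfs_ancestors(ontology, term_id):
    """Naive per-query BFS oracle for the ancestor closure."""
    out, frontier = set(), [term_id]
    while frontier:
        nxt = []
        for t in frontier:
            for p in ontology.terms[t].parents:
                if p not in out:
                    out.add(p)
                    nxt.append(p)
        frontier = nxt
    return out


class TestLoadObo:
    def test_chain_has_single_root(self, chain):
        assert chain.roots == {"A"}
        assert set(chain.terms) == {"A", "B", "C"}
        assert chain.terms["C"].name == "leaf term"

    def test_multiple_is_a_lines_make_a_dag(self, diamond):
        assert diamond.terms["D"].parents == {"B", "C"}

    def test_obsolete_terms_are_skipped(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: A\nname: live\n\n"
            "[Term]\nid: B\nname: dead\nis_obsolete: true\n"
        )
        ont = onto.load_obo(io.StringIO(text))
        assert set(ont.terms) == {"A"}

    def test_cycle_is_a_hard_error(self):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: A\nname: a\nis_a: B\n\n"
            "[Term]\nid: B\nname: b\nis_a: A\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            onto.load_obo(io.StringIO(text))

    def test_dangling_is_a_target_is_a_hard_error(self):
        text = "format-version: 1.2\n\n[Term]\nid: A\nname: a\nis_a: GHOST\n"
        with pytest.raises(ValueError, match="GHOST"):
            onto.load_obo(io.StringIO(text))

    def test_parent_child_tsv_reader(self):
        edges = io.StringIO("# child\tparent\nB\tA\nC\tB\nA\t\n")
        names = io.StringIO("A\talpha\n")
        ont = onto.load_parent_child_tsv(edges, names)
        assert ont.roots == {"A"}
        assert ont.terms["A"].name == "alpha"
        assert ont.ancestors("C") == {"A", "B"}


class TestClosure:
    def test_chain_ancestors(self, chain):
        assert chain.ancestors("C") == {"A", "B"}
        assert chain.ancestors("A") == set()

    def test_diamond_ancestors(self, diamond):
        assert diamond.ancestors("D") == bfs_ancestors(diamond, "D") == {
            "A", "B", "C",
        }

    def test_unknown_term_errors(self, chain):
        with pytest.raises(KeyError, match="nope"):
            chain.ancestors("nope")

    def test_closure_includes_self_and_is_idempotent(self, chain):
        c = chain.closure({"C"})
        assert c == {"A", "B", "C"}
        assert chain.closure(c) == c
        assert chain.closure(set()) == set()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_memoized_ancestors_match_bfs_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        terms = []
        for i in range(n):
            # parents only among earlier terms: acyclic by construction
            k = int(rng.integers(0, min(i, 3) + 1))
            parents = frozenset(
                f"T{j}" for j in rng.choice(i, size=k, replace=False)
            ) if i else frozenset()
            terms.append(onto.Term(f"T{i}", parents=parents))
        ont = onto.Ontology(terms)
        for t in ont.terms:
            assert ont.ancestors(t) == bfs_ancestors(ont, t)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_closure_is_monotone(self, data):
        ont = onto.Ontology([
            onto.Term("A"),
            onto.Term("B", parents=frozenset("A")),
            onto.Term("C", parents=frozenset("A")),
            onto.Term("D", parents=frozenset("BC")),
        ])
        universe = sorted(ont.terms)
        s = set(data.draw(st.sets(st.sampled_from(universe))))
        t = s | set(data.draw(st.sets(st.sampled_from(universe))))
        assert ont.closure(s) <= ont.closure(t)


class TestInformationContent:
    def test_root_annotation_gives_zero_ic(self, chain):
        table = onto.information_content(chain, {"e1": {"A"}})
        assert table.ic["A"] == 0.0

    def test_two_entity_closure_frequencies(self, chain):
        # e1 -> {B} closes to {A,B}; e2 -> {A}: A seen 2/2, B seen 1/2
        table = onto.information_content(chain, {"e1": {"B"}, "e2": {"A"}})
        assert table.ic["A"] == 0.0
        assert table.ic["B"] == pytest.approx(-math.log(0.5))
        assert "C" not in table.ic  # never reached

    def test_empty_corpus_errors(self, chain):
        with pytest.raises(ValueError, match="empty"):
            onto.information_content(chain, {})

    def test_ic_antitone_along_is_a(self, diamond):
        table = onto.information_content(
            diamond, {"e1": {"D"}, "e2": {"B"}, "e3": {"C"}, "e4": {"A"}}
        )
        for tid, term in diamond.terms.items():
            for p in term.parents:
                if tid in table.ic and p in table.ic:
                    assert table.ic[p] <= table.ic[tid] + 1e-12


class TestResnik:
    @pytest.fixture
    def diamond_ic(self, diamond):
        # two of four entities reach B => IC(B) = -ln(1/2) ~ 0.693
        return onto.information_content(
            diamond, {"e1": {"D"}, "e2": {"B"}, "e3": {"A"}, "e4": {"A"}}
        )

    def test_self_similarity_is_own_ic(self, diamond, diamond_ic):
        assert onto.resnik_similarity(diamond_ic, diamond, "D", "D") == (
            pytest.approx(diamond_ic.ic["D"])
        )

    def test_root_only_common_ancestor_scores_zero(self, diamond, diamond_ic):
        assert onto.resnik_similarity(diamond_ic, diamond, "B", "C") == 0.0

    def test_max_ic_common_ancestor(self, diamond, diamond_ic):
        # common ancestors of B and D are {A, B}; max IC is IC(B) ~ 0.693
        got = onto.resnik_similarity(diamond_ic, diamond, "B", "D")
        assert got == pytest.approx(math.log(2))

    def test_symmetry_and_mica_definition(self, diamond, diamond_ic):
        terms = sorted(diamond.terms)
        for t1 in terms:
            for t2 in terms:
                a = onto.resnik_similarity(diamond_ic, diamond, t1, t2)
                b = onto.resnik_similarity(diamond_ic, diamond, t2, t1)
                assert a == b
                common = (diamond.ancestors(t1) | {t1}) & (
                    diamond.ancestors(t2) | {t2}
                )
                brute = max((diamond_ic.get(t) for t in common), default=0.0)
                assert a == pytest.approx(brute)


class TestProteinPairSimilarity:
    def test_identical_singletons(self, diamond):
        ic = onto.information_content(diamond, {"e1": {"D"}, "e2": {"A"}})
        got = onto.protein_pair_similarity(ic, diamond, {"D"}, {"D"})
        assert got == pytest.approx(ic.ic["D"])

    def test_root_disjoint_sets_score_zero(self, diamond):
        ic = onto.information_content(
            diamond, {"e1": {"B"}, "e2": {"C"}, "e3": {"A"}}
        )
        assert onto.protein_pair_similarity(ic, diamond, {"B"}, {"C"}) == 0.0

    def test_best_match_average_matches_hand_computation(self, diamond):
        ic = onto.information_content(
            diamond, {"e1": {"B"}, "e2": {"C"}, "e3": {"D"}, "e4": {"A"}}
        )
        # brute force over all term pairs
        def r(a, b):
            return onto.resnik_similarity(ic, diamond, a, b)

        s1, s2 = ["B"], ["B", "C"]
        fwd = max(r("B", "B"), r("B", "C"))       # best match of B in s2
        rev = (r("B", "B") + r("C", "B")) / 2     # best matches of s2 in s1
        expected = 0.5 * (fwd + rev)
        got = onto.protein_pair_similarity(ic, diamond, s1, s2)
        assert got == pytest.approx(expected)

    def test_empty_set_is_an_error(self, diamond):
        ic = onto.information_content(diamond, {"e1": {"A"}})
        with pytest.raises(ValueError):
            onto.protein_pair_similarity(ic, diamond, set(), {"A"})
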