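"""Hierarchical controlled vocabularies (psi-mi, GO-like).

A vocabulary is a rooted DAG of terms linked by ``is_a`` edges.  This module
loads OBO 1.2 files (or a simple child/parent TSV), computes ancestor
closures, term information content over an annotation corpus, and Resnik
semantic similarity between terms and between annotated proteins.

Only the ``is_a`` hierarchy is honoured; ``relationship:`` lines (part_of
etc.) and obsolete terms are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "Term",
    "Ontology",
    "InformationContentTable",
    "load_obo",
    "load_parent_child_tsv",
    "ancestors",
    "closure",
    "information_content",
    "resnik_similarity",
    "protein_pair_similarity",
]


@dataclass(frozen=True)
class Term:
    """A single controlled-vocabulary term."""

    term_id: str
    name: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)


class Ontology:
    """A rooted DAG of terms with memoized ancestor queries.

    Parameters
    ----------
    terms:
        Iterable of :class:`Term`.  Every parent id must itself be a term
        and the parent graph must be acyclic.
    """

    def __init__(self, terms: Iterable[Term]):
        self.terms: dict[str, Term] = {t.term_id: t for t in terms}
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise ValueError(
                        f"term {t.term_id!r} has dangling is_a target {p!r}"
                    )
        self._check_acyclic()
        self.roots: frozenset[str] = frozenset(
            tid for tid, t in self.terms.items() if not t.parents
        )
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                g.add_edge(t.term_id, p)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise ValueError(f"is_a cycle detected involving term {cyc[0][0]!r}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive is_a closure of ``term_id``, excluding the term itself."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term id {term_id!r}")
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.terms[term_id].parents:
            out.add(p)
            out |= self.ancestors(p)
        res = frozenset(out)
        self._anc_cache[term_id] = res
        return res

    def closure(self, term_set: Iterable[str]) -> frozenset[str]:
        """``term_set`` plus all is_a ancestors (self-inclusive, idempotent)."""
        out: set[str] = set()
        for t in term_set:
            out.add(t)
            out |= self.ancestors(t)
        return frozenset(out)

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms whose ancestor closure contains ``term_id`` (excl. self)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term id {term_id!r}")
        return frozenset(
            tid for tid in self.terms if term_id in self.ancestors(tid)
        )

    def subtree(self, term_id: str) -> frozenset[str]:
        """``term_id`` and all of its descendants."""
        return self.descendants(term_id) | {term_id}


@dataclass
class InformationContentTable:
    """Per-term information content, IC(t) = -ln(closure frequency of t).

    Terms never reached by any entity's annotation closure are absent.
    """

    ic: dict[str, float]
    corpus_size: int

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)


def load_obo(obo_stream: IO[str] | str) -> Ontology:
    """Read an OBO 1.2 file into an :class:`Ontology`.

    Honours ``id``, ``name``, ``is_a`` and ``is_obsolete``; obsolete terms
    are skipped, all other tags (including ``relationship:``) are ignored.
    """
    graph = obonet.read_obo(obo_stream, ignore_obsolete=True)
    terms = []
    for tid, data in graph.nodes(data=True):
        if not data:
            # node materialized only as an is_a target, never defined
            raise ValueError(f"dangling is_a target {tid!r}")
        parents = frozenset(
            tgt for _, tgt, key in graph.out_edges(tid, keys=True) if key == "is_a"
        )
        terms.append(Term(term_id=tid, name=data.get("name", ""), parents=parents))
    return Ontology(terms)


def load_parent_child_tsv(
    edges_stream: IO[str], names_stream: IO[str] | None = None
) -> Ontology:
    """Read a two-column ``child_id<TAB>parent_id`` file ('' parent = root).

    Optional ``names_stream`` holds ``term_id<TAB>name`` lines.  Lines
    starting with '#' are comments in both files.
    """
    parents: dict[str, set[str]] = {}
    for line in edges_stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        child = fields[0]
        parent = fields[1] if len(fields) > 1 else ""
        parents.setdefault(child, set())
        if parent:
            parents.setdefault(parent, set())
            parents[child].add(parent)
    names: dict[str, str] = {}
    if names_stream is not None:
        for line in names_stream:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, _, name = line.partition("\t")
            names[tid] = name
    return Ontology(
        Term(term_id=tid, name=names.get(tid, ""), parents=frozenset(ps))
        for tid, ps in parents.items()
    )


def ancestors(ontology: Ontology, term_id: str) -> frozenset[str]:
    return ontology.ancestors(term_id)


def closure(ontology: Ontology, term_set: Iterable[str]) -> frozenset[str]:
    return ontology.closure(term_set)


def information_content(
    ontology: Ontology, annotations: Mapping[str, Iterable[str]]
) -> InformationContentTable:
    """Closure-based IC over an annotation corpus.

    The frequency of a term is the fraction of entities whose annotation
    closure contains it; IC = -ln(frequency).  Natural log throughout.

    Parameters
    ----------
    annotations:
        Map entity id -> iterable of directly annotated term ids.  Every
        term must exist in the ontology.
    """
    if not annotations:
        raise ValueError("empty annotation corpus")
    n = len(annotations)
    counts: dict[str, int] = {}
    for terms in annotations.values():
        for t in ontology.closure(terms):
            counts[t] = counts.get(t, 0) + 1
    ic = {t: -math.log(c / n) for t, c in counts.items()}
    return InformationContentTable(ic=ic, corpus_size=n)


def resnik_similarity(
    ic_table: InformationContentTable, ontology: Ontology, t1: str, t2: str
) -> float:
    """IC of the most informative common ancestor of ``t1`` and ``t2``.

    Each term counts as its own ancestor, so resnik(t, t) = IC(t).  Terms
    missing from the IC table contribute IC 0, so two terms whose only
    common ancestor is a root score 0.
    """
    common = (ontology.ancestors(t1) | {t1}) & (ontology.ancestors(t2) | {t2})
    if not common:
        return 0.0
    return max(ic_table.get(t) for t in common)


def protein_pair_similarity(
    ic_table: InformationContentTable,
    ontology: Ontology,
    terms_p1: Iterable[str],
    terms_p2: Iterable[str],
) -> float:
    """Symmetric best-match-average Resnik similarity between two term sets.

    For each term in one set, take its best Resnik score against the other
    set; average those maxima within each direction; return the mean of the
    two directional averages.  Raises on an empty set — callers skip pairs
    with unannotated proteins.
    """
    s1, s2 = list(terms_p1), list(terms_p2)
    if not s1 or not s2:
        raise ValueError("protein_pair_similarity requires two non-empty term sets")
    sim = {
        (a, b): resnik_similarity(ic_table, ontology, a, b)
        for a in s1
        for b in s2
    }
    fwd = sum(max(sim[(a, b)] for b in s2) for a in s1) / len(s1)
    rev = sum(max(sim[(a, b)] for a in s1) for b in s2) / len(s2)
    return 0.5 * (fwd + rev)
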