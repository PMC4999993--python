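"""Gene Ontology handling: OBO parsing, is_a propagation, annotation counting
and information content.

The ontology is restricted to ``is_a`` edges: annotation with a term implies
annotation with every is_a ancestor, and that closure is the propagation rule
used throughout the package.  Other relationship types (``part_of``,
``regulates``, ...) are ignored.

Information content of a term *t* follows the Bayesian estimator of Clark and
Radivojac: ``IC(t) = -log2( N({t} ∪ P(t)) / N(P(t)) )`` where ``P(t)`` is the
set of is_a parents of *t* and ``N(S)`` counts proteins annotated with every
term in ``S``.  It measures how much a term narrows down function beyond what
its parents already state, in bits.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import (
    LookupError_,
    ParseError,
    StructuralError,
    UndefinedICError,
)

logger = logging.getLogger(__name__)

#: GO namespaces, one root per namespace.
DOMAINS = ("molecular_function", "biological_process", "cellular_component")


@dataclass(frozen=True)
class Ontology:
    """An is_a DAG over GO terms.

    Parameters
    ----------
    parents
        Mapping term -> frozenset of direct is_a parents (non-obsolete terms
        only; roots map to the empty set).
    namespace
        Mapping term -> GO domain name.
    roots
        Terms with no parents, one per domain.
    obsolete
        Identifiers of retired terms, excluded from the DAG.
    alt_ids
        Mapping of alternate identifiers to their canonical term.
    """

    parents: Mapping[str, frozenset[str]]
    namespace: Mapping[str, str]
    roots: frozenset[str]
    obsolete: frozenset[str] = frozenset()
    alt_ids: Mapping[str, str] = field(default_factory=dict)
    names: Mapping[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def canonical(self, term: str) -> str:
        """Map an alt_id to its canonical identifier (identity otherwise)."""
        if term in self.alt_ids:
            mapped = self.alt_ids[term]
            logger.debug("alt_id %s mapped to %s", term, mapped)
            return mapped
        return term

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.alt_ids

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of *term* (roots included, *term* excluded)."""
        term = self.canonical(term)
        if term not in self.parents:
            raise LookupError_(f"unknown GO term: {term}")
        return self._ancestors_cached(term)

    # separate method so the cache key is the canonical id only
    def _ancestors_cached(self, term: str) -> frozenset[str]:
        cache = self.__dict__.setdefault("_anc_cache", {})
        if term in cache:
            return cache[term]
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents[p])
        result = frozenset(out)
        cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """All terms having *term* as an is_a ancestor."""
        term = self.canonical(term)
        if term not in self.parents:
            raise LookupError_(f"unknown GO term: {term}")
        children: dict[str, list[str]] = self.__dict__.get("_children", None)
        if children is None:
            children = {t: [] for t in self.parents}
            for child, ps in self.parents.items():
                for p in ps:
                    children[p].append(child)
            self.__dict__["_children"] = children
        out: set[str] = set()
        stack = list(children[term])
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(children[c])
        return frozenset(out)

    def domain(self, term: str) -> str:
        term = self.canonical(term)
        try:
            return self.namespace[term]
        except KeyError:
            raise LookupError_(f"unknown GO term: {term}") from None


def parse_obo(obo_text: str) -> Ontology:
    """Parse an OBO 1.2 document into an :class:`Ontology`.

    Obsolete terms are flagged and excluded from the DAG; ``alt_id`` entries
    are mapped to their canonical identifiers.  A cyclic is_a graph raises
    :class:`StructuralError`; an is_a line referencing an undeclared term
    raises :class:`ParseError` naming the offending stanza.
    """
    graph = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=False)

    obsolete = {
        n for n, d in graph.nodes(data=True) if d.get("is_obsolete") == "true"
    }
    declared = {n for n, d in graph.nodes(data=True) if "name" in d or n in obsolete}

    parents: dict[str, frozenset[str]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if node in obsolete:
            continue
        if node not in declared:
            # referenced by an is_a line but never declared
            continue
        ps = []
        for p in data.get("is_a", []):
            if p not in declared:
                raise ParseError(
                    f"term {node}: is_a references undeclared id {p}"
                )
            if p in obsolete:
                raise ParseError(
                    f"term {node}: is_a references obsolete id {p}"
                )
            ps.append(p)
        parents[node] = frozenset(ps)
        namespace[node] = data.get("namespace", "")
        names[node] = data.get("name", "")

    undeclared = set(graph.nodes) - declared
    if undeclared:
        # an undeclared node only appears as the target of someone's is_a
        for node, data in graph.nodes(data=True):
            for p in data.get("is_a", []):
                if p in undeclared:
                    raise ParseError(
                        f"term {node}: is_a references undeclared id {p}"
                    )

    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise StructuralError(f"cyclic is_a graph: {cycle}")

    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    roots = frozenset(t for t, ps in parents.items() if not ps)
    return Ontology(
        parents=parents,
        namespace=namespace,
        roots=roots,
        obsolete=frozenset(obsolete),
        alt_ids=alt_ids,
        names=names,
    )


def propagate(terms: Iterable[str], onto: Ontology) -> frozenset[str]:
    """Close a term set under is_a ancestry, excluding the domain roots.

    Returns the input set unioned with every is_a ancestor of its members,
    minus the three domain roots.  Idempotent and monotone.
    """
    out: set[str] = set()
    for t in terms:
        t = onto.canonical(t)
        if t not in onto.parents:
            raise LookupError_(f"unknown GO term: {t}")
        out.add(t)
        out |= onto.ancestors(t)
    return frozenset(out - onto.roots)


# ---------------------------------------------------------------------------
# Annotations


@dataclass
class AnnotationTable:
    """Protein -> GO annotations with evidence codes.

    ``records`` holds raw (protein, term, evidence) triples; ``by_protein``
    the per-protein term sets actually used for counting.  ``propagate``
    closes the sets under is_a ancestry *including* the domain roots, so that
    the counting function N(.) sees every protein annotated in a domain as
    carrying that domain's root.
    """

    records: list[tuple[str, str, str]]
    propagated: bool = False
    by_protein: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_protein:
            for prot, term, _ev in self.records:
                self.by_protein.setdefault(prot, set()).add(term)

    @property
    def proteins(self) -> set[str]:
        return set(self.by_protein)

    def filter_evidence(self, codes: Iterable[str]) -> "AnnotationTable":
        codes = set(codes)
        kept = [r for r in self.records if r[2] in codes]
        return AnnotationTable(records=kept)

    def exclude_terms(self, terms: Iterable[str]) -> "AnnotationTable":
        terms = set(terms)
        kept = [r for r in self.records if r[1] not in terms]
        return AnnotationTable(records=kept)

    def propagate(self, onto: Ontology, include_roots: bool = True
                  ) -> "AnnotationTable":
        """Return a propagated copy (idempotent)."""
        new_sets: dict[str, set[str]] = {}
        for prot, terms in self.by_protein.items():
            closed: set[str] = set()
            for t in terms:
                t = onto.canonical(t)
                if t not in onto.parents:
                    raise LookupError_(f"unknown GO term: {t}")
                closed.add(t)
                closed |= onto.ancestors(t)
            if not include_roots:
                closed -= set(onto.roots)
            new_sets[prot] = closed
        return AnnotationTable(
            records=list(self.records), propagated=True, by_protein=new_sets
        )


def read_gaf(text: str) -> AnnotationTable:
    """Read GAF-style annotations: tab-separated ``protein  GO-id  evidence``
    lines, comments starting with '!'."""
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"GAF line {lineno}: expected 3 columns")
        records.append((parts[0], parts[1], parts[2]))
    return AnnotationTable(records=records)


def write_gaf(table: AnnotationTable) -> str:
    lines = ["!gaf-version: 2.0-lite"]
    for prot, term, ev in table.records:
        lines.append(f"{prot}\t{term}\t{ev}")
    return "\n".join(lines) + "\n"


def count_annotations(table: AnnotationTable, term_set: Iterable[str]) -> int:
    """N(S): number of proteins whose (propagated) term set contains every
    term in S.  N(empty set) is the total protein count."""
    term_set = set(term_set)
    if not term_set:
        return len(table.by_protein)
    return sum(1 for terms in table.by_protein.values()
               if term_set <= terms)


def information_content(
    t: str, table: AnnotationTable, onto: Ontology, base: float = 2.0
) -> float:
    """Information content of term *t* in bits (for the default base 2).

    ``-log_base( N({t} ∪ P(t)) / N(P(t)) )`` with P(t) the is_a parents of t.
    Zero when every protein carrying the parents also carries t.
    """
    t = onto.canonical(t)
    if t not in onto.parents:
        raise LookupError_(f"unknown GO term: {t}")
    parents = set(onto.parents[t])
    n_parents = count_annotations(table, parents)
    if n_parents == 0:
        raise UndefinedICError(f"IC undefined for {t}: N(P(t)) = 0")
    n_joint = count_annotations(table, parents | {t})
    if n_joint == 0:
        raise UndefinedICError(f"IC undefined for {t}: term never annotated")
    return -math.log(n_joint / n_parents, base)


def ic_table(
    terms: Iterable[str], table: AnnotationTable, onto: Ontology,
    base: float = 2.0
) -> dict[str, float]:
    """Information content for every term in *terms* that has a defined IC."""
    out = {}
    for t in terms:
        try:
            out[t] = information_content(t, table, onto, base=base)
        except UndefinedICError:
            continue
    return out
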