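"""Baseline GO term predictors: annotation-frequency (Naive) and
identity-based transfer from sequence-search hits (BLAST).

The Naive model ranks GO terms by prevalence: raw annotations are filtered by
evidence code, the uninformative term "protein binding" (GO:0005515) is
dropped, counts are propagated along is_a edges, and each domain's counts are
scaled by its root count and rounded to three decimals.  Every query protein
receives the full table.

The transfer baseline keeps sequence-search hits inside an E-value window and
copies each subject's annotations to the query with confidence = percent
identity / 100, keeping the maximum score per (query, term).  The default
window keeps hits with E-value *above* 1e-03, deliberately restricting
transfers to remote homologs; flip the window bounds for the conventional
strong-hit behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError
from .ontology import AnnotationTable, Ontology, propagate
from .predictions import PredictionSet, round3

logger = logging.getLogger(__name__)

PROTEIN_BINDING = "GO:0005515"

#: evidence codes used by the baselines (includes IPI)
BASELINE_EVIDENCE = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "IC", "TAS"}
)
#: evidence codes used to build evaluation benchmarks (no IPI)
BENCHMARK_EVIDENCE = frozenset(
    {"EXP", "IDA", "IMP", "IGI", "IEP", "TAS", "IC"}
)

DEFAULT_EVALUE_MIN = 1e-03


@dataclass(frozen=True)
class SearchHit:
    """One tabular sequence-search hit (blast outfmt-6 subset)."""

    query: str
    subject: str
    pident: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValidationError(f"percent identity {self.pident} not in [0, 100]")
        if self.evalue < 0:
            raise ValidationError(f"negative E-value {self.evalue}")


def read_hits(text: str) -> list[SearchHit]:
    """Parse tabular hits: 12-column blast outfmt-6 ordering or a minimal
    4-column ``query subject pident evalue`` layout."""
    hits = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 12:
            q, s, pid, ev = parts[0], parts[1], parts[2], parts[10]
        elif len(parts) >= 4:
            q, s, pid, ev = parts[0], parts[1], parts[2], parts[3]
        else:
            raise ParseError(f"hits line {lineno}: expected >= 4 columns")
        hits.append(SearchHit(q, s, float(pid), float(ev)))
    return hits


@dataclass
class NaiveModel:
    """Per-domain term -> score table assigned wholesale to every query."""

    table: dict[str, float] = field(default_factory=dict)
    domain_of: dict[str, str] = field(default_factory=dict)

    def predict(self, proteins: Iterable[str]) -> PredictionSet:
        ps = PredictionSet()
        for prot in proteins:
            for term, score in self.table.items():
                ps.add(prot, term, score)
        return ps


def build_naive(
    table: AnnotationTable,
    onto: Ontology,
    evidence_filter: Iterable[str] = BASELINE_EVIDENCE,
) -> NaiveModel:
    """Build the frequency baseline from raw (unpropagated) annotations."""
    filtered = table.filter_evidence(evidence_filter).exclude_terms(
        {PROTEIN_BINDING}
    )
    propagated = filtered.propagate(onto, include_roots=True)

    counts: dict[str, int] = {}
    for terms in propagated.by_protein.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1

    model = NaiveModel()
    for root in onto.roots:
        domain = onto.namespace[root]
        root_count = counts.get(root, 0)
        if root_count == 0:
            logger.warning("domain %s has zero root count; omitted", domain)
            continue
        domain_terms = [t for t in counts if onto.namespace.get(t) == domain]
        for t in domain_terms:
            model.table[t] = round3(counts[t] / root_count)
            model.domain_of[t] = domain
    return model


def blast_transfer(
    hits: Sequence[SearchHit],
    table: AnnotationTable,
    onto: Ontology,
    evalue_min: float = DEFAULT_EVALUE_MIN,
    evalue_max: float = float("inf"),
    evidence_filter: Iterable[str] = BASELINE_EVIDENCE,
) -> PredictionSet:
    """Transfer subjects' annotations to queries with score = identity/100.

    Hits are kept when ``evalue_min < evalue <= evalue_max``; the default
    window keeps only weak hits (remote-homology regime).  Per (query, term)
    the maximum score is retained; hit order never matters.
    """
    annotated = table.filter_evidence(evidence_filter).exclude_terms(
        {PROTEIN_BINDING}
    )
    subject_terms: dict[str, frozenset[str]] = {}
    ps = PredictionSet()
    for hit in hits:
        if not (evalue_min < hit.evalue <= evalue_max):
            continue
        if hit.subject not in subject_terms:
            raw = annotated.by_protein.get(hit.subject, set())
            subject_terms[hit.subject] = (
                propagate(raw, onto) if raw else frozenset()
            )
        terms = subject_terms[hit.subject]
        if not terms:
            logger.debug("hit %s -> %s: subject unannotated, skipped",
                         hit.query, hit.subject)
            continue
        score = hit.pident / 100.0
        for t in terms:
            ps.add(hit.query, t, score, keep_max=True)
    return ps
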