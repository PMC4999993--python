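"""Synthetic datasets with planted feature -> function structure.

Everything the rest of the package consumes — ontologies, proteomes with GO
annotations, sequence-search hits, splice-isoform catalogues — can be
generated here, deterministically under a single seed.  The generators plant
known structure (a GO term whose positives are sequences satisfying a
biophysical predicate, isoforms that deliberately violate retention
filters), and return a manifest recording every decision, so tests can
compare pipeline output against ground truth.

The planted predicates are realised through residue-pool biasing: e.g. a
"disorder" rule samples positive sequences mostly from disorder-promoting
residues (P, E, S, Q, K) and negatives from order-promoting ones, then
verifies the predicate through the real feature extractor, resampling on the
rare miss.  Labels are then flipped at the rule's noise rate, emulating
annotation noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .features import default_registry, extract_features
from .ontology import DOMAINS
from .splicing import IsoformRecord

DISORDER_POOL = "PESQK"
ORDER_POOL = "WFIYVLCM"
MIXED_POOL = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_POOL = "AILVF"

#: evidence codes sampled into generated GAFs; includes IEA so that both the
#: experimental-only and the baseline evidence filters have work to do
GAF_EVIDENCE_CODES = ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
                      "IEA")

DEFAULT_LENGTH_RANGE = (50, 600)


@dataclass(frozen=True)
class PlantedRule:
    """A feature -> function rule the generator embeds in the proteome.

    Proteins whose feature group summary satisfies ``value <op> threshold``
    are labelled with *term* (subject to label flips at *noise*); when
    *complement_term* is set, the remaining proteins are annotated with it,
    which keeps every protein annotated in the term's GO domain.
    """

    term: str
    group: str = "disorder"
    scalar: int = 0
    threshold: float = 0.4
    op: str = ">"
    noise: float = 0.1
    complement_term: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise < 0.5:
            raise ValidationError("noise rate must be in [0, 0.5)")
        if self.op not in (">", "<"):
            raise ValidationError("predicate op must be '>' or '<'")

    def holds(self, value: float) -> bool:
        return value > self.threshold if self.op == ">" else value < self.threshold


# ---------------------------------------------------------------------------
# Toy ontology


def make_toy_ontology(
    n_terms: int,
    branching: int = 2,
    seed: int = 0,
    n_obsolete: int = 0,
) -> tuple[str, dict]:
    """Generate an OBO 1.2 document with one root per GO domain.

    Non-root terms are spread across the three domains round-robin; each
    attaches to 1..*branching* uniformly chosen parents within its domain,
    giving a DAG for branching >= 2 and a forest of chains/trees otherwise.
    Returns (obo_text, manifest); the manifest records terms, edges, roots
    and domain membership.
    """
    if n_terms < 4:
        raise ValidationError("need at least 4 terms (3 roots + 1 child)")
    rng = np.random.default_rng(seed)

    ids = [f"GO:{i + 1:07d}" for i in range(n_terms + n_obsolete)]
    roots = ids[:3]
    domain_of = {r: d for r, d in zip(roots, DOMAINS)}
    by_domain: dict[str, list[str]] = {d: [r] for r, d in zip(roots, DOMAINS)}
    edges: list[tuple[str, str]] = []

    for i, term in enumerate(ids[3:n_terms]):
        domain = DOMAINS[i % 3]
        pool = by_domain[domain]
        n_parents = min(1 + int(rng.integers(0, max(branching, 1))), len(pool))
        picked = rng.choice(len(pool), size=n_parents, replace=False)
        for j in sorted(picked):
            edges.append((term, pool[j]))
        by_domain[domain].append(term)
        domain_of[term] = domain

    obsolete = ids[n_terms:]

    stanzas = ["format-version: 1.2", "ontology: synthetic-go", ""]
    parent_lookup: dict[str, list[str]] = {}
    for c, p in edges:
        parent_lookup.setdefault(c, []).append(p)
    for term in ids[:n_terms]:
        stanzas.append("[Term]")
        stanzas.append(f"id: {term}")
        stanzas.append(f"name: synthetic term {term[3:]}")
        stanzas.append(f"namespace: {domain_of[term]}")
        for p in parent_lookup.get(term, []):
            stanzas.append(f"is_a: {p} ! synthetic term {p[3:]}")
        stanzas.append("")
    for term in obsolete:
        stanzas.append("[Term]")
        stanzas.append(f"id: {term}")
        stanzas.append(f"name: retired synthetic term {term[3:]}")
        stanzas.append("is_obsolete: true")
        stanzas.append("")

    manifest = {
        "n_terms": n_terms,
        "terms": ids[:n_terms],
        "roots": dict(zip(DOMAINS, roots)),
        "edges": edges,
        "domain_of": domain_of,
        "obsolete": obsolete,
        "seed": seed,
    }
    return "\n".join(stanzas), manifest


def pick_disjoint_terms(manifest: dict, onto, domain: str
                        ) -> tuple[str, str]:
    """Pick two non-root terms of *domain* that are is_a-disjoint (neither
    is an ancestor of the other), preferring the deepest available term.

    A planted rule needs such a pair: annotating predicate-negatives with an
    ancestor of the planted term would leave the term with no negatives
    after propagation.
    """
    root = manifest["roots"][domain]
    terms = [t for t in manifest["terms"]
             if manifest["domain_of"][t] == domain and t != root]
    for term in reversed(terms):
        anc = onto.ancestors(term)
        for comp in terms:
            if comp == term or comp in anc or term in onto.ancestors(comp):
                continue
            return term, comp
    raise ValidationError(
        f"no is_a-disjoint term pair exists in domain {domain}"
    )


# ---------------------------------------------------------------------------
# Proteome with planted rules


def _sample_sequence(rng: np.random.Generator, length: int,
                     rule: PlantedRule, positive: bool) -> str:
    """Draw a sequence biased to satisfy (or violate) the rule's predicate."""
    if rule.group == "disorder":
        frac = rng.uniform(0.55, 0.85) if positive else rng.uniform(0.05, 0.35)
        n_dis = int(round(frac * length))
        residues = [DISORDER_POOL[i] for i in
                    rng.integers(0, len(DISORDER_POOL), n_dis)]
        residues += [ORDER_POOL[i] for i in
                     rng.integers(0, len(ORDER_POOL), length - n_dis)]
        rng.shuffle(residues)  # type: ignore[arg-type]
        return "".join(residues)
    if rule.group == "transmembrane":
        base = [MIXED_POOL[i] for i in rng.integers(0, len(MIXED_POOL), length)]
        if positive:
            span = int(rng.integers(21, 30))
            start = int(rng.integers(0, max(1, length - span)))
            for j in range(start, min(length, start + span)):
                base[j] = HYDROPHOBIC_POOL[int(rng.integers(0, len(HYDROPHOBIC_POOL)))]
        return "".join(base)
    raise ValidationError(
        f"no sequence sampler for feature group {rule.group!r}"
    )


def make_proteome(
    n_proteins: int,
    rules: Sequence[PlantedRule],
    seed: int = 0,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    evidence_codes: Sequence[str] = GAF_EVIDENCE_CODES,
    max_resample: int = 25,
) -> tuple[str, str, dict]:
    """Generate a FASTA proteome, a GAF and a truth manifest.

    Proteins are assigned to rules round-robin; for its rule each protein is
    a predicate-positive with probability 1/2, its sequence is drawn to
    satisfy or violate the predicate (verified through the feature
    extractor), and the final label flips at the rule's noise rate.  GAF
    records carry evidence codes drawn from *evidence_codes*.
    """
    if not rules:
        raise ValidationError("at least one planted rule is required")
    rng = np.random.default_rng(seed)
    registry = default_registry()

    fasta_lines: list[str] = []
    gaf_lines = ["!gaf-version: 2.0-lite"]
    manifest: dict = {"seed": seed, "proteins": {}, "rules": [
        {"term": r.term, "group": r.group, "scalar": r.scalar,
         "threshold": r.threshold, "op": r.op, "noise": r.noise,
         "complement_term": r.complement_term}
        for r in rules
    ]}

    lo, hi = length_range
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        rule = rules[i % len(rules)]
        want_positive = bool(rng.random() < 0.5)
        length = int(rng.integers(lo, hi + 1))
        seq = None
        for _attempt in range(max_resample):
            cand = _sample_sequence(rng, length, rule, want_positive)
            vec = extract_features(cand, registry, sequence_id=pid)
            value = float(vec.values[rule.group][rule.scalar])
            if rule.holds(value) == want_positive:
                seq = cand
                break
        if seq is None:
            raise ValidationError(
                f"could not satisfy predicate for {pid} "
                f"(rule {rule.term}, positive={want_positive})"
            )
        label = want_positive
        flipped = bool(rng.random() < rule.noise)
        if flipped:
            label = not label

        fasta_lines.append(f">{pid}")
        for j in range(0, len(seq), 60):
            fasta_lines.append(seq[j:j + 60])

        code = evidence_codes[int(rng.integers(0, len(evidence_codes)))]
        if label:
            gaf_lines.append(f"{pid}\t{rule.term}\t{code}")
        elif rule.complement_term is not None:
            gaf_lines.append(f"{pid}\t{rule.complement_term}\t{code}")

        manifest["proteins"][pid] = {
            "rule_term": rule.term,
            "predicate_value": value,
            "predicate_positive": want_positive,
            "label": label,
            "flipped": flipped,
            "length": len(seq),
            "evidence": code,
        }

    manifest["n_label_positive"] = sum(
        1 for p in manifest["proteins"].values() if p["label"]
    )
    return ("\n".join(fasta_lines) + "\n",
            "\n".join(gaf_lines) + "\n",
            manifest)


# ---------------------------------------------------------------------------
# Sequence-search hits


def make_hits(
    queries: Sequence[str],
    subjects: Sequence[str],
    seed: int = 0,
    hits_per_query: int = 3,
) -> tuple[str, dict]:
    """Random tabular hits (query, subject, %identity, E-value) linking
    queries to annotated subjects; identities U(20, 60), E-values
    log-uniform in [1e-6, 10]."""
    rng = np.random.default_rng(seed)
    lines = []
    manifest: dict = {"hits": []}
    for q in queries:
        k = min(hits_per_query, len(subjects))
        picked = rng.choice(len(subjects), size=k, replace=False)
        for j in picked:
            s = subjects[j]
            pid = float(np.round(rng.uniform(20.0, 60.0), 1))
            ev = float(10 ** rng.uniform(-6, 1))
            lines.append(f"{q}\t{s}\t{pid}\t{ev:.3g}")
            manifest["hits"].append((q, s, pid, ev))
    return "\n".join(lines) + "\n", manifest


# ---------------------------------------------------------------------------
# Isoform catalogue


def make_isoform_catalogue(
    n_genes: int,
    iso_per_gene: tuple[int, int] = (1, 4),
    seed: int = 0,
    deletion_frac: tuple[float, float] = (0.1, 0.4),
    violation_rate: float = 0.1,
    main_violation_rate: float = 0.05,
    length_range: tuple[int, int] = (60, 300),
) -> tuple[list[IsoformRecord], dict[str, str], dict]:
    """Generate a splice-isoform catalogue with planted filter violations.

    Each gene gets one main isoform and 0..k alternatives produced by
    deleting an internal segment of the main sequence.  With probability
    *violation_rate* an alternative is planted to violate one of the
    retention filters (too short, too long, nonstandard residue, separate
    database entry); with probability *main_violation_rate* the *main*
    isoform violates a filter, exercising the cascade rule.  The manifest
    records the expected post-filter dataset.
    """
    rng = np.random.default_rng(seed)
    records: list[IsoformRecord] = []
    sequences: dict[str, str] = {}
    manifest: dict = {"seed": seed, "genes": {}, "expected_entries": {}}

    lo, hi = iso_per_gene
    for gi in range(n_genes):
        gene = f"G{gi:04d}"
        main_id = f"{gene}-1"
        length = int(rng.integers(*length_range))
        main_seq = "".join(
            MIXED_POOL[i] for i in rng.integers(0, len(MIXED_POOL), length)
        )
        main_bad = bool(rng.random() < main_violation_rate)
        external_main = False
        if main_bad:
            main_seq = main_seq + main_seq * (1500 // len(main_seq) + 1)  # rule c
        records.append(IsoformRecord(gene, main_id, main=True,
                                     external=external_main))
        sequences[main_id] = main_seq

        n_alts = int(rng.integers(lo, hi + 1)) - 1
        alt_ids, alt_ok = [], []
        for ai in range(n_alts):
            alt_id = f"{gene}-{ai + 2}"
            dfrac = rng.uniform(*deletion_frac)
            cut = int(round(dfrac * len(main_seq)))
            start = int(rng.integers(0, max(1, len(main_seq) - cut)))
            alt_seq = main_seq[:start] + main_seq[start + cut:]
            external = False
            violated = None
            if rng.random() < violation_rate:
                kind = rng.choice(["short", "nonstandard", "external"])
                if kind == "short":
                    alt_seq = alt_seq[:int(rng.integers(3, 14))]
                elif kind == "nonstandard":
                    pos = int(rng.integers(0, len(alt_seq)))
                    alt_seq = alt_seq[:pos] + "X" + alt_seq[pos + 1:]
                else:
                    external = True
                violated = str(kind)
            records.append(IsoformRecord(gene, alt_id, main=False,
                                         external=external))
            sequences[alt_id] = alt_seq
            alt_ids.append(alt_id)
            ok = (violated is None and MIN_OK <= len(alt_seq) <= MAX_OK)
            alt_ok.append(ok)

        manifest["genes"][gene] = {
            "main": main_id,
            "main_ok": not main_bad,
            "alternatives": alt_ids,
            "alternatives_ok": alt_ok,
        }
        if not main_bad:
            manifest["expected_entries"][gene] = {
                "main": main_id,
                "alternatives": sorted(
                    a for a, ok in zip(alt_ids, alt_ok) if ok
                ),
            }
    manifest["expected_gene_count"] = len(manifest["expected_entries"])
    return records, sequences, manifest


MIN_OK = 15
MAX_OK = 1500


# ---------------------------------------------------------------------------
# Catalogue serialisation (tab-separated: entry, isoform, main flag, external)


def catalogue_to_tsv(records: Sequence[IsoformRecord]) -> str:
    lines = ["#entry\tisoform\tmain\texternal"]
    for r in records:
        lines.append(f"{r.entry}\t{r.isoform}\t{int(r.main)}\t{int(r.external)}")
    return "\n".join(lines) + "\n"


def catalogue_from_tsv(text: str) -> list[IsoformRecord]:
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        entry, iso, main, external = line.split("\t")
        out.append(IsoformRecord(entry, iso, main=bool(int(main)),
                                 external=bool(int(external))))
    return out
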