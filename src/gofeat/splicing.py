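"""Functional conservation and divergence across splice isoforms.

Starting from per-isoform GO term predictions, this module quantifies, for
each functional class G:

* **conservation** — among database entries where G is predicted for at
  least one isoform, the fraction where it is predicted for *all* isoforms;
* **primarity** (delta_G) — the enrichment of G among main (canonical)
  isoforms relative to alternative variants,
  ``delta_G = m_G / n - a_G / (m - n)`` with m_G and a_G the numbers of main
  and alternative isoforms carrying G, n the number of entries and m the
  total number of isoforms.  Positive values mean G tracks the canonical
  product; negative values mean it is preferentially found on alternatives;
* **feature enrichment** (E_{g,f}) — whether a feature f takes higher or
  lower values on the isoforms annotated with g than it did in the
  classifier's positive training set, via a percentile mapping of the median:
  ``E = (p_hat - 50) / 50`` where p_hat is the lowest percentile of the
  isoform median within the training distribution;
* **feature-score correlation** — Pearson correlation between a feature's
  values on annotated isoforms and the classifier's posterior scores.

Isoforms enter the dataset only after passing the standard filters: known
sequence, 15-1500 residues, standard residues only, and not recorded in a
separate database entry.  Losing a main isoform removes its alternatives
as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import GofeatError, NotReported, ValidationError
from .ontology import AnnotationTable, Ontology, propagate
from .predictions import PredictionSet

logger = logging.getLogger(__name__)

MIN_LEN = 15
MAX_LEN = 1500
DEFAULT_CALL_THRESHOLD = 0.5
DEFAULT_MIN_ENTRIES = 20
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class IsoformRecord:
    """One catalogue row: entry (gene), isoform id, main flag, and whether
    the isoform is recorded in a separate database entry."""

    entry: str
    isoform: str
    main: bool
    external: bool = False


@dataclass
class IsoformDataset:
    """Filtered isoform catalogue with sequences and consolidated calls."""

    entries: dict[str, tuple[str, tuple[str, ...]]]  # entry -> (main, alts)
    sequences: dict[str, str]
    calls: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        """Number of entries (genes)."""
        return len(self.entries)

    @property
    def m_total(self) -> int:
        """Total number of isoforms."""
        return sum(1 + len(alts) for _main, alts in self.entries.values())

    def isoforms(self) -> list[str]:
        out = []
        for main, alts in self.entries.values():
            out.append(main)
            out.extend(alts)
        return out

    def entry_of(self, isoform: str) -> str:
        for entry, (main, alts) in self.entries.items():
            if isoform == main or isoform in alts:
                return entry
        raise GofeatError(f"isoform {isoform} has no parent entry")


def _passes_filters(seq: str | None, external: bool) -> bool:
    if external:                                   # rule e
        return False
    if seq is None or seq == "":                   # rule a
        return False
    if len(seq) < MIN_LEN:                         # rule b
        return False
    if len(seq) > MAX_LEN:                         # rule c
        return False
    if any(aa not in STANDARD_AA for aa in seq.upper()):   # rule d
        return False
    return True


def filter_isoforms(
    records: Sequence[IsoformRecord],
    sequences: Mapping[str, str | None],
) -> IsoformDataset:
    """Apply the isoform retention filters and the main-variant cascade.

    Each retained entry keeps exactly one main isoform; excluding a main
    isoform excludes all its alternatives.  Entries left without isoforms
    are dropped.
    """
    by_entry: dict[str, dict] = {}
    for rec in records:
        slot = by_entry.setdefault(rec.entry, {"main": None, "alts": []})
        if rec.main:
            if slot["main"] is not None:
                raise ValidationError(
                    f"entry {rec.entry} declares two main isoforms"
                )
            slot["main"] = rec
        else:
            slot["alts"].append(rec)

    entries: dict[str, tuple[str, tuple[str, ...]]] = {}
    seqs: dict[str, str] = {}
    for entry, slot in by_entry.items():
        main = slot["main"]
        if main is None:
            logger.debug("entry %s has no main isoform; dropped", entry)
            continue
        main_seq = sequences.get(main.isoform)
        if not _passes_filters(main_seq, main.external):
            logger.debug("entry %s: main isoform filtered; cascade drop",
                         entry)
            continue
        kept_alts = []
        for alt in slot["alts"]:
            alt_seq = sequences.get(alt.isoform)
            if _passes_filters(alt_seq, alt.external):
                kept_alts.append(alt.isoform)
                seqs[alt.isoform] = alt_seq.upper()
        entries[entry] = (main.isoform, tuple(sorted(kept_alts)))
        seqs[main.isoform] = main_seq.upper()
    return IsoformDataset(entries=entries, sequences=seqs)


def consolidate_predictions(
    ds: IsoformDataset,
    preds: PredictionSet,
    curated: AnnotationTable,
    onto: Ontology,
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
) -> IsoformDataset:
    """Turn posterior scores into term calls screened against curation.

    An isoform carries term g iff its score >= *call_threshold* and g lies
    in the is_a closure of the curated (entry-level) annotation set of its
    parent entry.  The consolidated calls are stored on the dataset.
    """
    closures: dict[str, frozenset[str]] = {}
    for entry in ds.entries:
        raw = curated.by_protein.get(entry, set())
        closures[entry] = propagate(raw, onto) if raw else frozenset()

    iso_entry = {
        iso: entry
        for entry, (main, alts) in ds.entries.items()
        for iso in (main, *alts)
    }
    calls: dict[str, frozenset[str]] = {}
    for iso in ds.isoforms():
        entry = iso_entry.get(iso)
        if entry is None:
            raise GofeatError(f"isoform {iso} has no parent entry")
        allowed = closures[entry]
        scored = preds.for_protein(iso)
        kept = {
            onto.canonical(t)
            for t, s in scored.items()
            if s >= call_threshold and onto.canonical(t) in allowed
        }
        calls[iso] = frozenset(kept)
    ds.calls = calls
    return ds


@dataclass
class TermSplicingStats:
    """Per-term survey outcome."""

    term: str
    conservation: float | None
    primarity: float
    m_g: int
    a_g: int
    entries_covered: int


def conservation(
    g: str, ds: IsoformDataset, min_entries: int = DEFAULT_MIN_ENTRIES
) -> float:
    """Fraction of covered entries where every isoform carries *g*.

    Coverage means the term is called on at least one isoform of the entry.
    Raises :class:`NotReported` below *min_entries* covered entries.
    """
    covered = 0
    conserved = 0
    for entry, (main, alts) in ds.entries.items():
        isoforms = (main, *alts)
        carrying = [iso for iso in isoforms if g in ds.calls.get(iso, ())]
        if carrying:
            covered += 1
            if len(carrying) == len(isoforms):
                conserved += 1
    if covered < min_entries:
        raise NotReported(
            f"{g}: predicted in {covered} entries < {min_entries}"
        )
    return conserved / covered


def primarity(g: str, ds: IsoformDataset) -> float:
    """delta_G = m_G/n - a_G/(m - n): +1 when g sits on every main isoform
    and no alternative, -1 in the opposite extreme, 0 when equally
    prevalent in the two sets."""
    n = ds.n
    m = ds.m_total
    if n < 1:
        raise ValidationError("empty isoform dataset")
    if m <= n:
        raise NotReported("dataset has no alternative isoforms")
    m_g = a_g = 0
    for entry, (main, alts) in ds.entries.items():
        if g in ds.calls.get(main, ()):
            m_g += 1
        for alt in alts:
            if g in ds.calls.get(alt, ()):
                a_g += 1
    return m_g / n - a_g / (m - n)


def term_counts(g: str, ds: IsoformDataset) -> tuple[int, int, int]:
    """(m_G, a_G, entries covered) for term g."""
    m_g = a_g = covered = 0
    for entry, (main, alts) in ds.entries.items():
        any_iso = False
        if g in ds.calls.get(main, ()):
            m_g += 1
            any_iso = True
        for alt in alts:
            if g in ds.calls.get(alt, ()):
                a_g += 1
                any_iso = True
        covered += any_iso
    return m_g, a_g, covered


def survey(
    ds: IsoformDataset, min_entries: int = DEFAULT_MIN_ENTRIES
) -> list[TermSplicingStats]:
    """Conservation and primarity for every called term with sufficient
    coverage."""
    terms: set[str] = set()
    for calls in ds.calls.values():
        terms |= calls
    out = []
    for g in sorted(terms):
        m_g, a_g, covered = term_counts(g, ds)
        if covered < min_entries:
            continue
        out.append(TermSplicingStats(
            term=g,
            conservation=conservation(g, ds, min_entries=min_entries),
            primarity=primarity(g, ds),
            m_g=m_g,
            a_g=a_g,
            entries_covered=covered,
        ))
    return out


@dataclass
class FeatureEnrichment:
    """Signed percentile enrichment of a feature among annotated isoforms
    relative to the classifier's positive training distribution."""

    term: str
    feature: str
    median_training: float
    median_variants: float
    percentile: float
    e: float


def feature_enrichment(
    g: str,
    f: str,
    T_values: Sequence[float],
    V_values: Sequence[float],
) -> FeatureEnrichment:
    """E_{g,f} = (p_hat - 50) / 50 in [-1, 1].

    p_hat is the lowest percentile of the isoform-set median within the
    empirical training distribution: the fraction of training values
    strictly below the median, times 100.  E is exactly 0 when the two
    medians coincide, positive when the feature runs higher on the
    annotated isoforms, negative when lower.
    """
    T = np.asarray(T_values, dtype=float)
    V = np.asarray(V_values, dtype=float)
    if T.size == 0 or V.size == 0:
        raise ValidationError("empty value set for enrichment")
    m_T = float(np.median(T))
    m_V = float(np.median(V))
    if m_V == m_T:
        e, p_hat = 0.0, 50.0
    elif np.all(T == T[0]):
        # degenerate constant training distribution
        logger.debug("%s/%s: constant training values", g, f)
        e = 1.0 if m_V > m_T else -1.0
        p_hat = 50.0 * (1 + e)
    else:
        p_hat = 100.0 * float(np.mean(T < m_V))
        e = float(np.clip((p_hat - 50.0) / 50.0, -1.0, 1.0))
    return FeatureEnrichment(
        term=g, feature=f,
        median_training=m_T, median_variants=m_V,
        percentile=p_hat, e=e,
    )


def feature_score_correlation(
    f_values: Sequence[float], scores: Sequence[float]
) -> float | None:
    """Pearson correlation between feature values and classifier posteriors.

    Returns None (the "grey cell") with fewer than 3 paired observations or
    zero variance in either series.
    """
    x = np.asarray(f_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size:
        raise ValidationError("feature values and scores differ in length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    r, _p = stats.pearsonr(x, y)
    return float(r)


def group_correlation_summary(
    correlations: Mapping[str, float | None]
) -> float | None:
    """Median correlation across a feature group's scalars, ignoring
    missing cells; None when every cell is missing."""
    vals = [v for v in correlations.values() if v is not None]
    if not vals:
        return None
    return float(np.median(vals))
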