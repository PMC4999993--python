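"""Protein-centric evaluation of GO term predictions.

For each benchmark protein x and decision threshold v the predicted set
P_{x,v} collects every term scoring >= v together with its is_a ancestors
(roots excluded); the reference set R_x is the propagated annotation set.
With tp = |P ∩ R|, fp = |P \\ R| and fn = |R \\ P|:

    precision(v) = (1/n) Σ tp / (tp + fp)      over the n proteins with
                                               at least one prediction >= v
    recall(v)    = (1/m) Σ tp / (tp + fn)      over all m benchmark proteins
    F(v)         = harmonic mean of the two

Fmax is the maximum of F(v) over the threshold grid.  A complementary view
trims each protein's ranked predictions to a fixed length l (or to the
protein's annotation count), resolving score ties by uniform sampling
without replacement over many replicates, and reports mean precision,
recall, F and the summed information content of true positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .baselines import BENCHMARK_EVIDENCE, PROTEIN_BINDING
from .errors import GofeatError, LookupError_, ValidationError
from .ontology import AnnotationTable, Ontology, propagate
from .predictions import PredictionSet

logger = logging.getLogger(__name__)

DEFAULT_REPLICATES = 1000
MIN_TARGETS = 25


@dataclass
class Benchmark:
    """Per-domain reference term sets, propagated and root-free."""

    domains: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def proteins(self, domain: str) -> dict[str, frozenset[str]]:
        if domain not in self.domains:
            raise GofeatError(f"benchmark has no domain {domain!r}")
        return self.domains[domain]

    def m(self, domain: str) -> int:
        return len(self.proteins(domain))


def build_benchmark(
    raw: AnnotationTable,
    onto: Ontology,
    codes: Iterable[str] = BENCHMARK_EVIDENCE,
) -> Benchmark:
    """Filter raw annotations by evidence code, drop GO:0005515, propagate,
    strip roots and split by GO domain.  Proteins left with an empty set are
    excluded."""
    filtered = raw.filter_evidence(codes).exclude_terms({PROTEIN_BINDING})
    propagated = filtered.propagate(onto, include_roots=False)
    bench = Benchmark()
    for prot, terms in propagated.by_protein.items():
        if not terms:
            logger.debug("protein %s has no reference terms; excluded", prot)
            continue
        by_domain: dict[str, set[str]] = {}
        for t in terms:
            by_domain.setdefault(onto.namespace[t], set()).add(t)
        for domain, ts in by_domain.items():
            bench.domains.setdefault(domain, {})[prot] = frozenset(ts)
    return bench


def protein_pr(
    P_xv: Iterable[str], R_x: Iterable[str]
) -> tuple[int, int, int, float | None, float]:
    """Per-protein counts and rates: (tp, fp, fn, precision, recall).

    Precision is None when the predicted set is empty (the protein is then
    excluded from the precision average); recall is 0 in that case.
    """
    P, R = set(P_xv), set(R_x)
    tp = len(P & R)
    fp = len(P - R)
    fn = len(R - P)
    precision = tp / (tp + fp) if P else None
    recall = tp / (tp + fn) if R else 0.0
    return tp, fp, fn, precision, recall


@dataclass
class ThresholdMetrics:
    """Averaged metrics at one decision threshold, with summed counts."""

    v: float
    tp: int
    fp: int
    fn: int
    n: int          # proteins with >= 1 prediction scoring >= v
    m: int          # benchmark proteins in the domain
    precision: float
    recall: float
    f: float


def _f_measure(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def pr_curve(
    preds: PredictionSet,
    bench: Benchmark,
    onto: Ontology,
    domain: str,
    thresholds: Sequence[float] | None = None,
) -> tuple[list[ThresholdMetrics], float, float]:
    """Precision-recall sweep for one GO domain.

    Returns (per-threshold metrics, Fmax, threshold attaining Fmax).  The
    default grid is the union of all distinct prediction scores with the
    0.01-spaced lattice on [0, 1].
    """
    refs = bench.proteins(domain)
    if not refs:
        raise GofeatError(f"empty benchmark domain {domain!r}")
    m = len(refs)

    # keep only predictions for terms of this domain
    per_protein: dict[str, list[tuple[str, float]]] = {}
    distinct: set[float] = set()
    for prot in refs:
        items = [
            (t, s) for t, s in preds.for_protein(prot).items()
            if onto.canonical(t) in onto.parents
            and onto.namespace[onto.canonical(t)] == domain
        ]
        per_protein[prot] = items
        distinct.update(s for _t, s in items)

    if thresholds is None:
        grid = sorted(distinct | {round(0.01 * k, 2) for k in range(101)})
    else:
        grid = sorted(set(thresholds))

    out: list[ThresholdMetrics] = []
    fmax, best_v = 0.0, grid[0] if grid else 0.0
    for v in grid:
        tps = fps = fns = 0
        precisions: list[float] = []
        recalls: list[float] = []
        n = 0
        for prot, R in refs.items():
            scored = [t for t, s in per_protein[prot] if s >= v]
            if scored:
                n += 1
                P = propagate(scored, onto)
            else:
                P = frozenset()
            tp, fp, fn, prec, rec = protein_pr(P, R)
            tps, fps, fns = tps + tp, fps + fp, fns + fn
            if prec is not None:
                precisions.append(prec)
            recalls.append(rec)
        avg_p = float(np.mean(precisions)) if precisions else 0.0
        avg_r = float(np.sum(recalls)) / m
        f = _f_measure(avg_p, avg_r)
        out.append(ThresholdMetrics(
            v=v, tp=tps, fp=fps, fn=fns, n=n, m=m,
            precision=avg_p, recall=avg_r, f=f,
        ))
        if f > fmax:
            fmax, best_v = f, v
    return out, fmax, best_v


def fmax(
    preds: PredictionSet,
    bench: Benchmark,
    onto: Ontology,
    domain: str,
    thresholds: Sequence[float] | None = None,
) -> float:
    """Maximum F-measure over the threshold grid."""
    _curve, fm, _v = pr_curve(preds, bench, onto, domain, thresholds)
    return fm


def tp_information(
    P: Iterable[str], R: Iterable[str], ic: Mapping[str, float]
) -> float:
    """Summed information content of the true-positive terms."""
    total = 0.0
    for t in set(P) & set(R):
        if t not in ic:
            raise LookupError_(f"no information content for term {t}")
        total += ic[t]
    return total


@dataclass
class TopLReport:
    """Averages over tie-resolving replicates of length-l trimmed lists."""

    l: int | str                 # int, or "n" for the per-protein truth count
    replicates: int
    n_targets: int
    precision: float
    recall: float
    f: float
    tp_ic: float


def _sample_top_l(
    ranked: Sequence[tuple[str, float]], l: int, rng: np.random.Generator
) -> list[str]:
    """Top-l under random tie resolution: everything strictly above the
    cutoff score enters; the remaining slots are drawn uniformly without
    replacement from the terms tied at the cutoff."""
    if l >= len(ranked):
        return [t for t, _s in ranked]
    cutoff = ranked[l - 1][1]
    above = [t for t, s in ranked if s > cutoff]
    tied = [t for t, s in ranked if s == cutoff]
    need = l - len(above)
    picked = rng.choice(len(tied), size=need, replace=False)
    return above + [tied[i] for i in picked]


def top_l_eval(
    preds: PredictionSet,
    bench: Benchmark,
    onto: Ontology,
    domain: str,
    l_values: Sequence[int | str] = (1, 2, 3, 4, 5, "n"),
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    ic: Mapping[str, float] | None = None,
    min_targets: int = MIN_TARGETS,
) -> list[TopLReport]:
    """Evaluate length-trimmed prediction lists for one GO domain.

    ``l_values`` may mix integers with the sentinel ``"n"``, meaning each
    protein's own reference annotation count.  A report is emitted only when
    at least *min_targets* proteins have >= l predictions and >= l reference
    annotations.  Tie resolution is seeded; proteins without ties are
    evaluated deterministically in a single pass.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    refs = bench.proteins(domain)
    ranked_by_prot: dict[str, list[tuple[str, float]]] = {}
    for prot in refs:
        items = [
            (t, s) for t, s in preds.for_protein(prot).items()
            if onto.canonical(t) in onto.parents
            and onto.namespace[onto.canonical(t)] == domain
        ]
        items.sort(key=lambda ts: (-ts[1], ts[0]))
        ranked_by_prot[prot] = items

    reports: list[TopLReport] = []
    for l_spec in l_values:
        rng = np.random.default_rng(seed)
        rows: list[tuple[float, float, float, float]] = []
        for prot, R in refs.items():
            ranked = ranked_by_prot[prot]
            l = len(R) if l_spec == "n" else int(l_spec)
            if l_spec != "n" and (len(ranked) < l or len(R) < l):
                continue
            if not ranked:
                continue
            if l > len(ranked):
                logger.debug("%s: l=%d exceeds %d predictions; list as-is",
                             prot, l, len(ranked))
                l = len(ranked)
            # ties matter only when the cutoff score recurs around rank l
            deterministic = (
                l >= len(ranked)
                or ranked[l - 1][1] != ranked[l][1]
            )
            reps = 1 if deterministic else replicates
            acc = np.zeros(4)
            for _ in range(reps):
                chosen = _sample_top_l(ranked, l, rng)
                P = propagate(chosen, onto)
                tp, fp, fn, prec, rec = protein_pr(P, R)
                prec = prec if prec is not None else 0.0
                f = _f_measure(prec, rec)
                ic_sum = tp_information(P, R, ic) if ic is not None else 0.0
                acc += (prec, rec, f, ic_sum)
            rows.append(tuple(acc / reps))
        if len(rows) < min_targets:
            logger.info("l=%s: only %d qualifying targets (< %d); skipped",
                        l_spec, len(rows), min_targets)
            continue
        arr = np.array(rows)
        reports.append(TopLReport(
            l=l_spec,
            replicates=replicates,
            n_targets=len(rows),
            precision=float(arr[:, 0].mean()),
            recall=float(arr[:, 1].mean()),
            f=float(arr[:, 2].mean()),
            tp_ic=float(arr[:, 3].mean()),
        ))
    return reports


def metrics_table(curve: Sequence[ThresholdMetrics]) -> str:
    """Render a threshold sweep as a TSV (Threshold, TP, FP, FN, NP,
    Precision, Recall, F1)."""
    lines = ["Threshold\tTP\tFP\tFN\tNP\tPrecision\tRecall\tF1"]
    for tm in curve:
        lines.append(
            f"{tm.v:.3f}\t{tm.tp}\t{tm.fp}\t{tm.fn}\t{tm.n}\t"
            f"{tm.precision:.3f}\t{tm.recall:.3f}\t{tm.f:.3f}"
        )
    return "\n".join(lines) + "\n"
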