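"""Protein-centric precision-recall machinery, Fmax, top-l trimming and IC
weighting."""

import math

import numpy as np
import pytest

from gofeat.errors import LookupError_
from gofeat.evaluation import (
    build_benchmark,
    pr_curve,
    protein_pr,
    top_l_eval,
    tp_information,
)
from gofeat.ontology import (
    AnnotationTable,
    information_content,
    parse_obo,
    propagate,
    read_gaf,
)
from gofeat.predictions import PredictionSet

from conftest import CHAIN_OBO

#: one MF root with three independent children (a, b, c) and a grandchild
FLAT_OBO = """\
format-version: 1.2
ontology: synthetic-go

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: a
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: b
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000004
name: c
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000005
name: a-child
namespace: molecular_function
is_a: GO:0000002
"""

MF = "molecular_function"


@pytest.fixture(scope="module")
def flat_onto():
    return parse_obo(FLAT_OBO)


class TestBuildBenchmark:
    def test_iea_excluded(self, flat_onto):
        bench = build_benchmark(
            read_gaf("P1\tGO:0000002\tIEA\nP2\tGO:0000003\tIDA\n"), flat_onto
        )
        assert set(bench.proteins(MF)) == {"P2"}

    def test_protein_binding_only_protein_absent(self, flat_onto):
        obo = FLAT_OBO + (
            "\n[Term]\nid: GO:0005515\nname: protein binding\n"
            "namespace: molecular_function\nis_a: GO:0000001\n"
        )
        onto = parse_obo(obo)
        bench = build_benchmark(
            read_gaf("P1\tGO:0005515\tIDA\nP2\tGO:0000002\tIDA\n"), onto
        )
        assert set(bench.proteins(MF)) == {"P2"}

    def test_mixed_codes_hand_count(self, flat_onto):
        gaf = "\n".join([
            "P1\tGO:0000002\tIDA",      # kept
            "P1\tGO:0000003\tIEA",      # dropped (code)
            "P2\tGO:0000005\tEXP",      # kept, propagates to a
            "P3\tGO:0000004\tIPI",      # dropped (IPI not benchmark code)
            "P4\tGO:0000003\tTAS",      # kept
            "P5\tGO:0000002\tND",       # dropped
        ]) + "\n"
        bench = build_benchmark(read_gaf(gaf), flat_onto)
        assert set(bench.proteins(MF)) == {"P1", "P2", "P4"}
        assert bench.proteins(MF)["P2"] == {"GO:0000005", "GO:0000002"}

    def test_reference_sets_are_root_free(self, flat_onto):
        bench = build_benchmark(read_gaf("P1\tGO:0000005\tIDA\n"), flat_onto)
        assert "GO:0000001" not in bench.proteins(MF)["P1"]


class TestProteinPr:
    def test_identity(self):
        assert protein_pr({"a", "b"}, {"a", "b"}) == (2, 0, 0, 1.0, 1.0)

    def test_partial_overlap(self):
        tp, fp, fn, p, r = protein_pr({"a", "b", "c"}, {"a", "d"})
        assert (tp, fp, fn) == (1, 2, 1)
        assert p == pytest.approx(1 / 3)
        assert r == pytest.approx(1 / 2)

    def test_empty_prediction_excluded_from_precision(self):
        tp, fp, fn, p, r = protein_pr(set(), {"a"})
        assert p is None
        assert r == 0.0


class TestPrCurve:
    def test_perfect_predictor(self, flat_onto):
        bench = build_benchmark(
            read_gaf("P1\tGO:0000002\tIDA\nP2\tGO:0000003\tIDA\n"), flat_onto
        )
        preds = PredictionSet.from_triples([
            ("P1", "GO:0000002", 1.0), ("P2", "GO:0000003", 1.0),
        ])
        curve, fmax, v = pr_curve(preds, bench, flat_onto, MF)
        assert fmax == pytest.approx(1.0)
        at_one = [tm for tm in curve if tm.v == 1.0][0]
        assert at_one.precision == at_one.recall == at_one.f == 1.0

    def test_matches_brute_force_reimplementation(self, flat_onto):
        """Metrics at 11 thresholds equal an independent naive computation."""
        rng = np.random.default_rng(42)
        terms = ["GO:0000002", "GO:0000003", "GO:0000004", "GO:0000005"]
        gaf_lines, triples = [], []
        for i in range(5):
            prot = f"P{i}"
            for t in rng.choice(terms, size=2, replace=False):
                gaf_lines.append(f"{prot}\t{t}\tIDA")
            for t in terms:
                if rng.random() < 0.7:
                    triples.append((prot, t, float(rng.integers(0, 11)) / 10))
        bench = build_benchmark(read_gaf("\n".join(gaf_lines) + "\n"),
                                flat_onto)
        preds = PredictionSet.from_triples(triples)
        grid = [k / 10 for k in range(11)]
        curve, _f, _v = pr_curve(preds, bench, flat_onto, MF,
                                 thresholds=grid)

        for tm in curve:
            # independent oracle: direct set arithmetic per protein
            precisions, recalls = [], []
            for prot, R in bench.proteins(MF).items():
                scored = {
                    t for t, s in preds.for_protein(prot).items()
                    if s >= tm.v
                }
                P = set(propagate(scored, flat_onto)) if scored else set()
                if P:
                    precisions.append(len(P & R) / len(P))
                recalls.append(len(P & R) / len(R))
            exp_p = sum(precisions) / len(precisions) if precisions else 0.0
            exp_r = sum(recalls) / len(bench.proteins(MF))
            assert tm.precision == pytest.approx(exp_p)
            assert tm.recall == pytest.approx(exp_r)
            exp_f = (2 * exp_p * exp_r / (exp_p + exp_r)
                     if exp_p + exp_r else 0.0)
            assert tm.f == pytest.approx(exp_f)

    def test_counts_monotone_in_threshold(self, flat_onto):
        rng = np.random.default_rng(7)
        gaf = "P0\tGO:0000002\tIDA\nP1\tGO:0000005\tIDA\n"
        triples = [
            (f"P{i}", t, round(float(rng.random()), 3))
            for i in range(2)
            for t in ("GO:0000002", "GO:0000003", "GO:0000005")
        ]
        bench = build_benchmark(read_gaf(gaf), flat_onto)
        preds = PredictionSet.from_triples(triples)
        curve, _f, _v = pr_curve(preds, bench, flat_onto, MF)
        for a, b in zip(curve, curve[1:]):
            assert b.tp <= a.tp and b.fp <= a.fp and b.fn >= a.fn
            assert b.n <= a.n

    def test_fmax_attained_on_grid(self, flat_onto):
        bench = build_benchmark(read_gaf("P1\tGO:0000002\tIDA\n"), flat_onto)
        preds = PredictionSet.from_triples([
            ("P1", "GO:0000002", 0.8), ("P1", "GO:0000003", 0.4),
        ])
        curve, fmax, v = pr_curve(preds, bench, flat_onto, MF)
        assert fmax == max(tm.f for tm in curve)
        assert [tm.f for tm in curve if tm.v == v][0] == fmax


class TestTopL:
    def test_no_ties_deterministic(self, flat_onto):
        bench = build_benchmark(read_gaf("P1\tGO:0000002\tIDA\n"), flat_onto)
        preds = PredictionSet.from_triples([
            ("P1", "GO:0000002", 0.9), ("P1", "GO:0000003", 0.3),
        ])
        a = top_l_eval(preds, bench, flat_onto, MF, l_values=[1],
                       replicates=50, seed=0, min_targets=1)[0]
        b = top_l_eval(preds, bench, flat_onto, MF, l_values=[1],
                       replicates=50, seed=99, min_targets=1)[0]
        assert a.precision == b.precision == 1.0
        assert a.f == b.f

    def test_all_tied_mean_precision_converges(self, flat_onto):
        """3 predictions tied at 0.5 with one correct: mean top-1 precision
        approaches 1/3 within the binomial sampling bound."""
        bench = build_benchmark(read_gaf("P1\tGO:0000002\tIDA\n"), flat_onto)
        preds = PredictionSet.from_triples([
            ("P1", "GO:0000002", 0.5),
            ("P1", "GO:0000003", 0.5),
            ("P1", "GO:0000004", 0.5),
        ])
        rep = top_l_eval(preds, bench, flat_onto, MF, l_values=[1],
                         replicates=1000, seed=3, min_targets=1)[0]
        sigma = math.sqrt((1 / 3) * (2 / 3) / 1000)
        assert abs(rep.precision - 1 / 3) <= 2 * sigma

    def test_full_length_perfect_ranking(self, flat_onto):
        bench = build_benchmark(
            read_gaf("P1\tGO:0000002\tIDA\nP1\tGO:0000003\tIDA\n"), flat_onto
        )
        preds = PredictionSet.from_triples([
            ("P1", "GO:0000002", 0.9),
            ("P1", "GO:0000003", 0.8),
            ("P1", "GO:0000004", 0.1),
        ])
        rep = top_l_eval(preds, bench, flat_onto, MF, l_values=["n"],
                         replicates=10, seed=0, min_targets=1)[0]
        assert rep.f == pytest.approx(1.0)

    def test_min_targets_floor_suppresses_report(self, flat_onto):
        bench = build_benchmark(read_gaf("P1\tGO:0000002\tIDA\n"), flat_onto)
        preds = PredictionSet.from_triples([("P1", "GO:0000002", 0.9)])
        reports = top_l_eval(preds, bench, flat_onto, MF, l_values=[1],
                             replicates=10, seed=0, min_targets=25)
        assert reports == []


class TestTpInformation:
    def test_empty_intersection_is_zero(self):
        assert tp_information({"a"}, {"b"}, {"a": 1.0, "b": 2.0}) == 0.0

    def test_single_term(self):
        assert tp_information({"t"}, {"t"}, {"t": 2.0}) == 2.0

    def test_missing_ic_named(self):
        with pytest.raises(LookupError_, match="t"):
            tp_information({"t"}, {"t"}, {})

    def test_chain_telescoping_identity(self, chain_onto):
        """Summed IC over a predicted=reference chain path equals -log2 of
        the leaf annotation frequency."""
        records = [(f"L{i}", "GO:0000003", "IDA") for i in range(2)]
        records += [(f"M{i}", "GO:0000002", "IDA") for i in range(3)]
        records += [(f"R{i}", "GO:0000001", "IDA") for i in range(5)]
        table = AnnotationTable(records).propagate(chain_onto)
        ic = {
            t: information_content(t, table, chain_onto)
            for t in ("GO:0000002", "GO:0000003")
        }
        path = {"GO:0000002", "GO:0000003"}
        assert tp_information(path, path, ic) == pytest.approx(
            -math.log2(2 / 10)
        )
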