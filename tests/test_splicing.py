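"""Isoform filtering, prediction consolidation, conservation, primarity and
feature enrichment."""

import itertools

import numpy as np
import pytest

from gofeat.errors import NotReported, ValidationError
from gofeat.ontology import AnnotationTable, parse_obo
from gofeat.predictions import PredictionSet
from gofeat.splicing import (
    IsoformDataset,
    IsoformRecord,
    consolidate_predictions,
    conservation,
    feature_enrichment,
    feature_score_correlation,
    filter_isoforms,
    group_correlation_summary,
    primarity,
    survey,
)

from conftest import CHAIN_OBO

GOOD = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"


def _records(*specs):
    return [IsoformRecord(*s) for s in specs]


class TestFilterIsoforms:
    def test_short_alternative_removed_siblings_kept(self):
        recs = _records(("G1", "G1-1", True), ("G1", "G1-2", False),
                        ("G1", "G1-3", False))
        seqs = {"G1-1": GOOD, "G1-2": "MKTAYIAKQR", "G1-3": GOOD + "A"}
        ds = filter_isoforms(recs, seqs)
        assert ds.entries["G1"] == ("G1-1", ("G1-3",))

    def test_long_main_cascades_whole_entry(self):
        recs = _records(("G1", "G1-1", True), ("G1", "G1-2", False))
        seqs = {"G1-1": "A" * 2000, "G1-2": GOOD}
        assert filter_isoforms(recs, seqs).entries == {}

    def test_nonstandard_residue_removed(self):
        recs = _records(("G1", "G1-1", True), ("G1", "G1-2", False))
        seqs = {"G1-1": GOOD, "G1-2": GOOD[:10] + "X" + GOOD[10:]}
        ds = filter_isoforms(recs, seqs)
        assert ds.entries["G1"] == ("G1-1", ())

    def test_unknown_sequence_removed(self):
        recs = _records(("G1", "G1-1", True), ("G1", "G1-2", False))
        ds = filter_isoforms(recs, {"G1-1": GOOD})
        assert ds.entries["G1"] == ("G1-1", ())

    def test_separate_entry_flag_removed(self):
        recs = _records(("G1", "G1-1", True), ("G1", "G1-2", False, True))
        seqs = {"G1-1": GOOD, "G1-2": GOOD}
        ds = filter_isoforms(recs, seqs)
        assert ds.entries["G1"] == ("G1-1", ())

    def test_two_mains_rejected(self):
        recs = _records(("G1", "G1-1", True), ("G1", "G1-2", True))
        with pytest.raises(ValidationError):
            filter_isoforms(recs, {"G1-1": GOOD, "G1-2": GOOD})

    def test_filters_order_independent(self):
        """The retained dataset is the same whatever order records arrive."""
        recs = _records(
            ("G1", "G1-1", True), ("G1", "G1-2", False),
            ("G2", "G2-1", True), ("G2", "G2-2", False),
            ("G3", "G3-1", True),
        )
        seqs = {"G1-1": GOOD, "G1-2": "SHORT", "G2-1": "B" + GOOD,
                "G2-2": GOOD, "G3-1": GOOD}
        reference = None
        for perm in itertools.permutations(recs):
            ds = filter_isoforms(list(perm), seqs)
            if reference is None:
                reference = ds.entries
            assert ds.entries == reference
        # G2's main has a nonstandard residue: cascade removed the entry
        assert "G2" not in reference


class TestConsolidate:
    @pytest.fixture()
    def onto(self):
        return parse_obo(CHAIN_OBO)

    def _ds(self):
        return IsoformDataset(
            entries={"G1": ("G1-1", ("G1-2",))},
            sequences={"G1-1": GOOD, "G1-2": GOOD},
        )

    def test_uncurated_term_dropped(self, onto):
        preds = PredictionSet.from_triples([("G1-1", "GO:0000003", 0.9)])
        curated = AnnotationTable([("G1", "GO:0000002", "IDA")])
        ds = consolidate_predictions(self._ds(), preds, curated, onto)
        # the leaf is not in the closure of the curated mid term
        assert ds.calls["G1-1"] == frozenset()

    def test_curated_term_above_threshold_kept(self, onto):
        preds = PredictionSet.from_triples([("G1-1", "GO:0000002", 0.7)])
        curated = AnnotationTable([("G1", "GO:0000002", "IDA")])
        ds = consolidate_predictions(self._ds(), preds, curated, onto)
        assert ds.calls["G1-1"] == {"GO:0000002"}

    def test_predicted_ancestor_of_curated_term_kept(self, onto):
        preds = PredictionSet.from_triples([("G1-2", "GO:0000002", 0.8)])
        curated = AnnotationTable([("G1", "GO:0000003", "IDA")])
        ds = consolidate_predictions(self._ds(), preds, curated, onto)
        assert ds.calls["G1-2"] == {"GO:0000002"}

    def test_below_threshold_dropped(self, onto):
        preds = PredictionSet.from_triples([("G1-1", "GO:0000002", 0.4)])
        curated = AnnotationTable([("G1", "GO:0000002", "IDA")])
        ds = consolidate_predictions(self._ds(), preds, curated, onto)
        assert ds.calls["G1-1"] == frozenset()

    def test_calls_subset_of_raw_predictions(self, onto):
        preds = PredictionSet.from_triples([
            ("G1-1", "GO:0000002", 0.9), ("G1-1", "GO:0000003", 0.9),
        ])
        curated = AnnotationTable([("G1", "GO:0000002", "IDA")])
        ds = consolidate_predictions(self._ds(), preds, curated, onto)
        assert ds.calls["G1-1"] <= set(preds.for_protein("G1-1"))


def _extremal_ds(n=20, calls_main=True, calls_alt=True):
    entries = {f"G{i}": (f"G{i}-1", (f"G{i}-2",)) for i in range(n)}
    ds = IsoformDataset(entries=entries, sequences={})
    ds.calls = {}
    for i in range(n):
        ds.calls[f"G{i}-1"] = frozenset({"T"}) if calls_main else frozenset()
        ds.calls[f"G{i}-2"] = frozenset({"T"}) if calls_alt else frozenset()
    return ds


class TestConservation:
    def test_everywhere_gives_one(self):
        assert conservation("T", _extremal_ds()) == 1.0

    def test_main_only_gives_zero(self):
        assert conservation("T", _extremal_ds(calls_alt=False)) == 0.0

    def test_partial_coverage_ratio(self):
        ds = _extremal_ds()
        for i in range(13, 20):
            ds.calls[f"G{i}-2"] = frozenset()
        assert conservation("T", ds) == pytest.approx(0.65)

    def test_below_min_entries_not_reported(self):
        with pytest.raises(NotReported):
            conservation("T", _extremal_ds(n=5), min_entries=20)


class TestPrimarity:
    def test_all_main_no_alternative_is_plus_one(self):
        assert primarity("T", _extremal_ds(calls_alt=False)) == 1.0

    def test_everywhere_is_zero(self):
        assert primarity("T", _extremal_ds()) == 0.0

    def test_all_alternative_no_main_is_minus_one(self):
        assert primarity("T", _extremal_ds(calls_main=False)) == -1.0

    def test_invariant_under_entry_duplication(self):
        ds = _extremal_ds(n=10, calls_alt=False)
        for i in range(3, 10):
            ds.calls[f"G{i}-1"] = frozenset()
        base = primarity("T", ds)
        doubled = IsoformDataset(
            entries={**ds.entries,
                     **{f"H{i}": (f"H{i}-1", (f"H{i}-2",)) for i in range(10)}},
            sequences={},
        )
        doubled.calls = dict(ds.calls)
        for i in range(10):
            doubled.calls[f"H{i}-1"] = ds.calls[f"G{i}-1"]
            doubled.calls[f"H{i}-2"] = ds.calls[f"G{i}-2"]
        assert primarity("T", doubled) == pytest.approx(base)

    def test_no_alternatives_undefined(self):
        ds = IsoformDataset(entries={"G0": ("G0-1", ())}, sequences={})
        ds.calls = {"G0-1": frozenset({"T"})}
        with pytest.raises(NotReported):
            primarity("T", ds)


class TestSurvey:
    def test_counts_and_coverage(self):
        ds = _extremal_ds(n=20, calls_alt=False)
        stats = survey(ds, min_entries=20)
        assert len(stats) == 1
        st = stats[0]
        assert (st.m_g, st.a_g, st.entries_covered) == (20, 0, 20)
        assert st.primarity == 1.0
        assert st.conservation == 0.0


class TestFeatureEnrichment:
    T100 = list(range(100))

    def test_zero_at_equal_medians(self):
        fe = feature_enrichment("g", "f", self.T100, [49.5])
        assert fe.e == 0.0

    def test_plus_one_above_all_training_values(self):
        assert feature_enrichment("g", "f", self.T100, [1000]).e == 1.0

    def test_minus_one_below_all_training_values(self):
        assert feature_enrichment("g", "f", self.T100, [-5]).e == -1.0

    def test_quarter_percentile_maps_to_minus_half(self):
        assert feature_enrichment("g", "f", self.T100, [25]).e == pytest.approx(-0.5)

    def test_sign_tracks_median_difference(self):
        up = feature_enrichment("g", "f", self.T100, [80])
        down = feature_enrichment("g", "f", self.T100, [20])
        assert up.e > 0 > down.e

    def test_constant_training_distribution(self):
        assert feature_enrichment("g", "f", [1.0] * 5, [1.0]).e == 0.0
        assert feature_enrichment("g", "f", [1.0] * 5, [2.0]).e == 1.0
        assert feature_enrichment("g", "f", [1.0] * 5, [0.0]).e == -1.0

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            T = rng.normal(size=30)
            V = rng.normal(size=10)
            assert -1.0 <= feature_enrichment("g", "f", T, V).e <= 1.0


class TestFeatureScoreCorrelation:
    def test_affine_increasing_gives_one(self):
        f = [1.0, 2.0, 3.0, 4.0]
        scores = [0.1, 0.3, 0.5, 0.7]
        assert feature_score_correlation(f, scores) == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=1000)
        s = rng.uniform(size=1000)
        assert abs(feature_score_correlation(f, s)) < 0.1

    def test_constant_feature_is_missing(self):
        assert feature_score_correlation([1.0] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]) is None

    def test_too_few_observations_missing(self):
        assert feature_score_correlation([1.0, 2.0], [0.1, 0.2]) is None

    def test_group_summary_is_median_over_scalars(self):
        cells = {"f.0": 0.2, "f.1": None, "f.2": 0.8, "f.3": 0.4}
        assert group_correlation_summary(cells) == pytest.approx(0.4)
        assert group_correlation_summary({"f.0": None}) is None
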