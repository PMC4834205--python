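"""Micro P/R/F, NER scoring and filtering, ROC sweeps, overlap partitions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from crowdcid import (
    ConceptAnnotation,
    annotation_match,
    f_measure,
    max_recall,
    ner_error_filter,
    ner_prf,
    overlap_partition,
    relation_prf,
    roc_auc,
    roc_points,
    share_of_total,
)
from crowdcid.evaluation import prf_from_counts


class TestMicroPRF:
    def test_confusion_counts_from_full_workflow(self):
        # counts from the unfiltered crowd confusion matrix
        res = prf_from_counts(tp=576, fp=635, fn=490)
        assert res.precision == pytest.approx(0.4756, abs=5e-4)
        assert res.recall == pytest.approx(0.5403, abs=5e-4)
        assert res.f1 == pytest.approx(0.5059, abs=5e-4)

    def test_perfect_and_disjoint_predictions(self):
        gold = {("d1", "D1", "D2"), ("d2", "D1", "D3")}
        perfect = relation_prf(gold, gold)
        assert (perfect.precision, perfect.recall, perfect.f1) == (1.0, 1.0, 1.0)
        disjoint = relation_prf({("d9", "D8", "D9")}, gold)
        assert (disjoint.precision, disjoint.recall, disjoint.f1) == (0.0, 0.0, 0.0)

    def test_duplicates_collapse_to_sets(self):
        gold = [("d1", "D1", "D2")]
        pred = [("d1", "D1", "D2"), ("d1", "D1", "D2")]
        res = relation_prf(pred, gold)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pred=st.sets(st.integers(0, 30), max_size=15),
        gold=st.sets(st.integers(0, 30), max_size=15),
    )
    def test_agrees_with_elementwise_membership_count(self, pred, gold):
        to_triple = lambda i: (f"d{i % 5}", f"D1{i}", f"D2{i}")
        p = {to_triple(i) for i in pred}
        g = {to_triple(i) for i in gold}
        res = relation_prf(p, g)
        tp = sum(1 for t in p if t in g)
        assert res.tp == tp
        assert res.fp == len(p) - tp
        assert res.fn == sum(1 for t in g if t not in p)


class TestFMeasure:
    def test_development_set_operating_point(self):
        assert f_measure(0.528, 0.661) == pytest.approx(0.587, abs=5e-4)

    @pytest.mark.parametrize("p,r,f", [(1, 1, 1), (0, 0.7, 0), (0.7, 0, 0), (0, 0, 0)])
    def test_degenerate_values(self, p, r, f):
        assert f_measure(p, r) == f


def _ann(doc, start, end, surface, cls="chemical", ids=("D1",)):
    return ConceptAnnotation(doc, start, end, surface, cls, tuple(ids))


class TestAnnotationMatch:
    def test_exact_match_requires_span_and_ids(self):
        a = _ann("d1", 5, 9, "chem")
        assert annotation_match(a, _ann("d1", 5, 9, "chem"))
        assert not annotation_match(a, _ann("d1", 5, 9, "chem", ids=("D2",)))
        assert not annotation_match(a, _ann("d1", 6, 10, "hemx"))
        assert not annotation_match(a, _ann("d2", 5, 9, "chem"))


class TestNerPrf:
    def test_identical_sets_are_perfect(self):
        anns = [_ann("d1", 0, 4, "chem"), _ann("d1", 10, 14, "dise", "disease", ("D2",))]
        res = ner_prf(anns, list(anns))
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_extra_prediction_is_false_positive(self):
        gold = [_ann("d1", 0, 4, "chem")]
        pred = gold + [_ann("d1", 10, 14, "dise", "disease", ("D2",))]
        res = ner_prf(pred, gold)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_concept_doc_level_collapses_repeated_mentions(self):
        pred = [_ann("d1", 0, 4, "chem"), _ann("d1", 20, 24, "chem")]
        gold = [_ann("d1", 0, 4, "chem")]
        mention = ner_prf(pred, gold, level="mention")
        concept = ner_prf(pred, gold, level="concept_doc")
        assert (mention.tp, mention.fp) == (1, 1)
        assert (concept.tp, concept.fp) == (1, 0)


class TestNerErrorFilter:
    def _setting(self):
        gold_anns = [
            _ann("d1", 0, 4, "chem", "chemical", ("D1",)),
            _ann("d1", 10, 14, "dise", "disease", ("D2",)),
        ]
        pred_anns_bad_disease = [
            _ann("d1", 0, 4, "chem", "chemical", ("D1",)),
            _ann("d1", 10, 14, "dise", "disease", ("D9",)),  # wrong ID
        ]
        rel = {("d1", "D1", "D2")}
        return rel, gold_anns, pred_anns_bad_disease

    def test_relation_with_mismatched_disease_dropped_from_both_sides(self):
        rel, gold_anns, pred_anns = self._setting()
        pred_f, gold_f = ner_error_filter(rel, rel, pred_anns, gold_anns)
        assert pred_f == set() and gold_f == set()

    def test_all_matching_annotations_filter_is_identity(self):
        rel, gold_anns, _ = self._setting()
        pred_f, gold_f = ner_error_filter(rel, rel, gold_anns, gold_anns)
        assert pred_f == rel and gold_f == rel

    def test_subset_and_idempotence(self, small_corpus):
        docs, anns, gold, truth = small_corpus
        pred = {g.triple for g in gold[::2]} | {("9_fake", "D910000", "D920000")}
        gold_t = {g.triple for g in gold}
        pred_f, gold_f = ner_error_filter(pred, gold_t, anns, truth.gold_annotations)
        assert pred_f <= pred and gold_f <= gold_t
        again = ner_error_filter(pred_f, gold_f, anns, truth.gold_annotations)
        assert again == (pred_f, gold_f)


class TestMaxRecall:
    def test_three_of_four_gold_pairs_indexable(self):
        gold = [(f"d{i}", "D1", "D2") for i in range(4)]
        cands = {f"d{i}": {("D1", "D2")} for i in range(3)}
        cands["d3"] = {("D1", "D9")}  # gold pair missing here
        assert max_recall(cands, gold) == 0.75

    def test_candidates_from_gold_give_full_recall(self):
        gold = [("d1", "D1", "D2"), ("d2", "D3", "D4")]
        cands = {"d1": {("D1", "D2")}, "d2": {("D3", "D4")}}
        assert max_recall(cands, gold) == 1.0


def _votes_to_args(votes_pos, votes_neg):
    """Build roc_points inputs from per-class vote lists."""
    tallies = {}
    gold = []
    cands = []
    for i, v in enumerate(votes_pos):
        t = (f"p{i}", "D1", "D2")
        tallies[t] = v
        gold.append(t)
        cands.append(t)
    for i, v in enumerate(votes_neg):
        t = (f"n{i}", "D1", "D2")
        tallies[t] = v
        cands.append(t)
    return tallies, cands, gold


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        tallies, cands, gold = _votes_to_args([5, 5, 5], [0, 0, 0])
        assert roc_auc(roc_points(tallies, cands, gold)) == 1.0

    def test_uninformative_votes_give_auc_half(self):
        # identical vote multisets in both classes: AUC exactly 1/2
        votes = [0, 1, 2, 3, 4, 5]
        tallies, cands, gold = _votes_to_args(votes, votes)
        assert roc_auc(roc_points(tallies, cands, gold)) == pytest.approx(0.5)

    def test_threshold_endpoints(self):
        tallies, cands, gold = _votes_to_args([5, 2], [1, 0])
        points = {p.threshold: p for p in roc_points(tallies, cands, gold)}
        assert (points[0].fpr, points[0].tpr) == (1.0, 1.0)
        assert (points[6].fpr, points[6].tpr) == (0.0, 0.0)

    def test_points_monotone_and_auc_bounded(self):
        rng = np.random.default_rng(0)
        votes_pos = list(rng.integers(0, 6, size=25))
        votes_neg = list(rng.integers(0, 6, size=40))
        tallies, cands, gold = _votes_to_args(votes_pos, votes_neg)
        pts = roc_points(tallies, cands, gold)
        for a, b in zip(pts, pts[1:]):  # thresholds decrease
            assert b.tpr >= a.tpr and b.fpr >= a.fpr
        assert 0.0 <= roc_auc(pts) <= 1.0

    def test_reversed_scores_mirror_auc(self):
        rng = np.random.default_rng(1)
        votes_pos = list(rng.integers(0, 6, size=30))
        votes_neg = list(rng.integers(0, 6, size=30))
        tallies, cands, gold = _votes_to_args(votes_pos, votes_neg)
        auc = roc_auc(roc_points(tallies, cands, gold))
        rev = {t: 5 - v for t, v in tallies.items()}
        auc_rev = roc_auc(roc_points(rev, cands, gold))
        assert auc + auc_rev == pytest.approx(1.0)

    def test_matches_sklearn_on_vote_scores(self):
        rng = np.random.default_rng(2)
        votes_pos = list(rng.integers(2, 6, size=30))
        votes_neg = list(rng.integers(0, 4, size=45))
        tallies, cands, gold = _votes_to_args(votes_pos, votes_neg)
        auc = roc_auc(roc_points(tallies, cands, gold))
        y = [1] * len(votes_pos) + [0] * len(votes_neg)
        scores = votes_pos + votes_neg
        assert auc == pytest.approx(roc_auc_score(y, scores))

    def test_unindexable_gold_enters_with_zero_votes(self):
        tallies, cands, gold = _votes_to_args([5], [0])
        gold = gold + [("missing_doc", "D1", "D2")]  # never a candidate
        pts = {p.threshold: p for p in roc_points(tallies, cands, gold)}
        assert pts[5].tpr == pytest.approx(0.5)  # one of two gold found
        assert pts[0].tpr == 1.0

    def test_missing_tally_for_candidate_raises(self):
        with pytest.raises(ValueError, match="lack a vote tally"):
            roc_points({}, [("d1", "D1", "D2")], [])


class TestOverlap:
    def test_identical_systems_all_in_core(self):
        gold = {(f"d{i}", "D1", "D2") for i in range(7)}
        counts = overlap_partition({"a": gold, "b": gold, "c": gold}, gold)
        assert counts == {("a", "b", "c"): 7}

    def test_disjoint_systems_have_empty_pairwise_regions(self):
        gold = {(f"d{i}", "D1", "D2") for i in range(4)}
        systems = {
            "a": {("d0", "D1", "D2")},
            "b": {("d1", "D1", "D2")},
        }
        counts = overlap_partition(systems, gold)
        assert counts[("a",)] == 1 and counts[("b",)] == 1
        assert counts[()] == 2
        assert ("a", "b") not in counts

    def test_counts_equal_brute_force_membership(self):
        rng = np.random.default_rng(3)
        universe = [(f"d{i}", "D1", "D2") for i in range(40)]
        gold = {t for t in universe if rng.random() < 0.5}
        systems = {
            name: {t for t in universe if rng.random() < 0.4}
            for name in ("x", "y", "z")
        }
        counts = overlap_partition(systems, gold)
        for r in range(4):
            for combo in itertools.combinations(sorted(systems), r):
                expected = sum(
                    1
                    for t in gold
                    if all(t in systems[n] for n in combo)
                    and all(t not in systems[n] for n in systems if n not in combo)
                )
                assert counts.get(combo, 0) == expected
        assert sum(counts.values()) == len(gold)


class TestShareOfTotal:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(485, 1066, 45.50), (277, 1066, 25.98), (356, 1066, 33.40),
         (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_percentages(self, count, total, expected):
        assert share_of_total(count, total) == pytest.approx(expected, abs=0.01)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            share_of_total(0, 0)
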