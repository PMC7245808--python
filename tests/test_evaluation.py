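"""Metrics, kappa, overlap, PT frequency and differential term mining."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from eippcs.corpus_model import AnnotationSet, CorpusError, MethodResult
from eippcs.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    cohens_kappa,
    combine_term_diffs,
    confusion,
    evaluate_method,
    fp_only_terms,
    ngram_counts,
    overlap_analysis,
    percent_round,
    percent_trunc,
    precision_paper,
    precision_testset,
    pt_frequency,
    recall,
)
from eippcs.meddra import PTFilterSpec
from conftest import make_record


def _result(name, ids, universe):
    trace = {
        rid: (("r", "include"),) if rid in ids else (("r", "exclude"),)
        for rid in universe
    }
    return MethodResult(name, frozenset(ids), trace)


class TestConfusion:
    def test_perfect_retrieval(self):
        ann = AnnotationSet({"A": "EIPPCS", "B": "non_EIPPCS"})
        c = confusion(_result("m", {"A"}, {"A", "B"}), ann, {"A", "B"})
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_empty_retrieval(self):
        ann = AnnotationSet({"A": "EIPPCS", "B": "EIPPCS", "C": "non_EIPPCS"})
        c = confusion(_result("m", set(), ann.ids), ann, ann.ids)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 2, 1)

    def test_six_record_fixture_by_enumeration(self):
        ann = AnnotationSet({
            "A": "EIPPCS", "B": "EIPPCS", "C": "EIPPCS",
            "D": "non_EIPPCS", "E": "non_EIPPCS", "F": "non_EIPPCS",
        })
        retrieved = {"A", "B", "D"}
        c = confusion(_result("m", retrieved, ann.ids), ann, ann.ids)
        # brute-force set arithmetic
        positives = {"A", "B", "C"}
        assert c.tp == len(retrieved & positives) == 2
        assert c.fp == len(retrieved - positives) == 1
        assert c.fn == len(positives - retrieved) == 1
        assert c.tn == 2
        assert c.total == 6

    def test_unannotated_universe_id_rejected(self):
        ann = AnnotationSet({"A": "EIPPCS"})
        with pytest.raises(CorpusError, match="unannotated"):
            confusion(_result("m", set(), {"A", "Z"}), ann, {"A", "Z"})


class TestHeadlineMetrics:
    """The published worked examples: counts in, one-decimal figures out."""

    @pytest.mark.parametrize(
        "tp, fn, expected",
        [(38, 4, 38 / 42), (37, 5, 37 / 42), (0, 5, 0.0)],
    )
    def test_recall(self, tp, fn, expected):
        assert recall(ConfusionCounts(tp, 0, fn, 0)) == pytest.approx(expected)

    def test_recall_undefined_without_positives(self):
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 3, 0, 7))

    @pytest.mark.parametrize(
        "tp, total, expected",
        [(37, 1104, 37 / 1104), (38, 2042, 38 / 2042), (5, 5, 1.0)],
    )
    def test_precision_paper(self, tp, total, expected):
        assert precision_paper(tp, total) == pytest.approx(expected)

    def test_precision_paper_undefined_for_zero_retrieved(self):
        with pytest.raises(UndefinedMetricError):
            precision_paper(0, 0)

    def test_percent_renderings(self):
        assert percent_trunc(38 / 42) == 90.4   # truncated figure
        assert percent_round(37 / 42) == 88.1   # half-up figure
        assert percent_trunc(33 / 42) == 78.5
        assert percent_round(37 / 1104) == 3.4
        assert percent_round(38 / 2042) == 1.9
        assert percent_round(33 / 2019) == 1.6
        assert percent_round(42 / 2533) == 1.7

    def test_precision_testset_is_ppv(self):
        assert precision_testset(ConfusionCounts(2, 6, 1, 1)) == 0.25


class TestKappa:
    def test_identical_labelings_give_one(self):
        a = AnnotationSet({"A": "EIPPCS", "B": "non_EIPPCS", "C": "non_EIPPCS"})
        assert cohens_kappa(a, a) == pytest.approx(1.0)

    def test_chance_level_agreement_gives_zero(self):
        # po = 0.5 and both marginals are 50/50, so pe = 0.5
        a = AnnotationSet({"1": "EIPPCS", "2": "EIPPCS",
                           "3": "non_EIPPCS", "4": "non_EIPPCS"})
        b = AnnotationSet({"1": "EIPPCS", "2": "non_EIPPCS",
                           "3": "EIPPCS", "4": "non_EIPPCS"})
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_asymmetric_table_closed_form(self):
        # 2x2 table a=40, b=2, c=2, d=56 (n=100):
        # po = 0.96; pe = 0.42*0.42 + 0.58*0.58 = 0.5128
        # kappa = (0.96 - 0.5128) / (1 - 0.5128) = 0.9178981937...
        labels_a, labels_b = {}, {}
        counter = itertools.count()
        for count, (la, lb) in [(40, ("EIPPCS", "EIPPCS")),
                                (2, ("EIPPCS", "non_EIPPCS")),
                                (2, ("non_EIPPCS", "EIPPCS")),
                                (56, ("non_EIPPCS", "non_EIPPCS"))]:
            for _ in range(count):
                rid = str(next(counter))
                labels_a[rid], labels_b[rid] = la, lb
        kappa = cohens_kappa(AnnotationSet(labels_a), AnnotationSet(labels_b))
        assert kappa == pytest.approx((0.96 - 0.5128) / (1 - 0.5128))
        assert kappa == pytest.approx(0.9178981937, abs=1e-9)

    def test_degenerate_constant_labelings(self):
        a = AnnotationSet({"A": "EIPPCS", "B": "EIPPCS"})
        assert cohens_kappa(a, a) == 1.0

    def test_id_mismatch_rejected(self):
        a = AnnotationSet({"A": "EIPPCS"})
        b = AnnotationSet({"B": "EIPPCS"})
        with pytest.raises(CorpusError):
            cohens_kappa(a, b)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=40))
    def test_matches_sklearn_oracle(self, pairs):
        from sklearn.metrics import cohen_kappa_score

        to = lambda flag: "EIPPCS" if flag else "non_EIPPCS"
        a = AnnotationSet({str(i): to(x) for i, (x, _) in enumerate(pairs)})
        b = AnnotationSet({str(i): to(y) for i, (_, y) in enumerate(pairs)})
        ka = [a.labels[str(i)] for i in range(len(pairs))]
        kb = [b.labels[str(i)] for i in range(len(pairs))]
        expected = cohen_kappa_score(ka, kb)
        got = cohens_kappa(a, b)
        if expected != expected:  # sklearn returns NaN when pe == 1
            assert got in (0.0, 1.0)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


class TestOverlap:
    def test_positive_captured_by_all_three(self):
        universe = {"P"}
        results = [_result(m, {"P"}, universe) for m in ("a", "b", "c")]
        counts = overlap_analysis(results, {"P"})
        assert counts[("a", "b", "c")] == 1
        assert sum(counts.values()) == 1

    def test_none_bucket(self):
        universe = {"P", "Q"}
        results = [_result(m, {"P"}, universe) for m in ("a", "b")]
        counts = overlap_analysis(results, {"P", "Q"})
        assert counts[()] == 1
        assert counts[("a", "b")] == 1

    def test_random_fixture_matches_brute_force(self):
        import numpy as np

        rng = np.random.Generator(np.random.PCG64(3))
        ids = [f"R{i}" for i in range(20)]
        sets = {m: {i for i in ids if rng.random() < 0.5} for m in ("a", "b", "c")}
        results = [_result(m, sets[m], set(ids)) for m in ("a", "b", "c")]
        counts = overlap_analysis(results, ids)
        for pid in ids:
            key = tuple(sorted(m for m in sets if pid in sets[m]))
            # brute-force recount of the region this positive falls in
            assert counts[key] == sum(
                1 for q in ids
                if tuple(sorted(m for m in sets if q in sets[m])) == key
            )
        assert sum(counts.values()) == len(ids)

    def test_requires_two_results(self):
        with pytest.raises(CorpusError):
            overlap_analysis([_result("a", set(), set())], set())


class TestPTFrequency:
    SPEC = PTFilterSpec(frozenset({
        "Device malfunction", "Device failure",
        "Wrong technique in product usage process",
    }))

    def test_single_pt_histogram_and_composite(self, hierarchy):
        records = [
            make_record("A", "x", pt_codes={"10000002"}),  # Device malfunction
            make_record("B", "x", pt_codes={"10000002"}),
            make_record("C", "x", pt_codes={"10000002", "10000001"}),  # both
            make_record("D", "x", pt_codes={"10000021"}),  # off-spec
        ]
        table = pt_frequency({"A", "B", "C", "D"}, records, self.SPEC, hierarchy,
                             group_threshold=1)
        assert table["Device malfunction"] == 2
        assert table["Composite PTs"] == 1
        assert "Headache" not in table
        assert sum(table.values()) == 3

    def test_small_counts_grouped(self, hierarchy):
        records = (
            [make_record(f"M{i}", "x", pt_codes={"10000002"}) for i in range(10)]
            + [make_record("F", "x", pt_codes={"10000001"})]
        )
        ids = {r.id for r in records}
        table = pt_frequency(ids, records, self.SPEC, hierarchy, group_threshold=10)
        assert table == {"Device malfunction": 10, "PTs < 10": 1}

    def test_thirty_record_fixture_matches_hand_enumeration(self, hierarchy):
        records = []
        for i in range(18):
            records.append(make_record(f"A{i}", "x", pt_codes={"10000017"}))
        for i in range(7):
            records.append(make_record(f"B{i}", "x", pt_codes={"10000002"}))
        for i in range(3):
            records.append(make_record(f"C{i}", "x",
                                       pt_codes={"10000002", "10000017"}))
        for i in range(2):
            records.append(make_record(f"D{i}", "x", pt_codes={"10000021"}))
        ids = {r.id for r in records}
        table = pt_frequency(ids, records, self.SPEC, hierarchy, group_threshold=10)
        assert table == {
            "Wrong technique in product usage process": 18,
            "Composite PTs": 3,
            "PTs < 10": 7,
        }


class TestTermMining:
    def test_identical_pools_give_empty_list(self):
        texts = ["insulin used daily"]
        assert fp_only_terms(texts, texts) == []

    def test_prefilled_fixture_brute_force(self):
        fp = ["prefilled insulin syringes used daily"]
        tp = ["insulin used daily"]
        got = dict(fp_only_terms(fp, tp))
        # brute-force n-gram enumeration: every n-gram touching tokens
        # absent from the TP pool is FP-only
        for term in ("prefilled", "prefilled insulin",
                     "prefilled insulin syringes", "syringes"):
            assert got[term] == 1
        assert "insulin" not in got
        assert "used daily" not in got

    def test_every_returned_term_has_zero_tp_count(self):
        fp = ["the woman was introduced to the pen", "elevated blood glucose"]
        tp = ["the man used the pen"]
        tp_counts = ngram_counts(tp)
        for term, count in fp_only_terms(fp, tp):
            assert count >= 1
            assert tp_counts[term] == 0

    def test_top_k_and_tie_break(self):
        fp = ["zz zz aa"]
        tp = ["bb"]
        [first] = fp_only_terms(fp, tp, max_n=1, top_k=1)
        assert first == ("zz", 2)

    def test_ngrams_do_not_cross_sentences(self):
        counts = ngram_counts(["One two. Three four"], max_n=2)
        assert "two three" not in counts

    def test_combined_table_marks_absent_with_none(self):
        rows = combine_term_diffs({
            "i2e": [("prefilled", 5), ("woman", 3)],
            "cpr": [("woman", 4)],
        })
        by_term = {r.term: r.counts for r in rows}
        assert by_term["prefilled"] == {"i2e": 5, "cpr": None}
        assert by_term["woman"] == {"i2e": 3, "cpr": 4}
        assert rows[0].term == "prefilled"


class TestEvaluateMethod:
    def test_full_report(self):
        ann = AnnotationSet({
            "A": "EIPPCS", "B": "EIPPCS", "C": "non_EIPPCS", "D": "non_EIPPCS",
        })
        result = _result("m", {"A", "C"}, ann.ids)
        report = evaluate_method(result, ann, ann.ids, retrieved_total=100)
        assert report.recall == pytest.approx(0.5)
        assert report.precision_testset == pytest.approx(0.5)
        assert report.precision_paper == pytest.approx(1 / 100)
        assert report.retrieved_total == 100
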