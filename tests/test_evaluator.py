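"""Confusion counts, metrics with CIs, IAA symmetry, report rendering."""

import json
import math

import pytest

from ehreval import (
    AnnotationSet,
    ConfusionCounts,
    GoldStandard,
    SliceRequest,
    ValidationError,
    check_expected_compliance,
    confusion,
    harmonic_f1,
    iaa,
    metrics,
    render_report,
)
from ehreval.evaluator import round_half_up_2dp


def make_gold(doc_ids, variable, present_docs):
    cells = {(d, variable): d in set(present_docs) for d in doc_ids}
    return GoldStandard(
        labels=cells, provenance={c: "consensus" for c in cells}
    )


def make_predictions(doc_ids, variable, present_docs, annotator="system"):
    return AnnotationSet(
        annotator_id=annotator,
        labels={(d, variable): d in set(present_docs) for d in doc_ids},
    )


DOCS = [f"D{i}" for i in range(10)]


class TestConfusion:
    def test_perfect_predictions(self):
        gold = make_gold(DOCS, "asthma", DOCS[:4])
        pred = make_predictions(DOCS, "asthma", DOCS[:4])
        counts = confusion(gold, pred, "asthma")
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (4, 0, 0, 6)

    def test_complement_predictions(self):
        gold = make_gold(DOCS, "asthma", DOCS[:4])
        pred = make_predictions(DOCS, "asthma", DOCS[4:])
        counts = confusion(gold, pred, "asthma")
        assert counts.tp == 0 and counts.tn == 0
        assert (counts.fp, counts.fn) == (6, 4)

    def test_matches_cell_by_cell_recount(self, rng):
        docs = [f"D{i}" for i in range(200)]
        gold_pos = [d for d in docs if rng.random() < 0.5]
        pred_pos = [d for d in docs if rng.random() < 0.5]
        gold = make_gold(docs, "v", gold_pos)
        pred = make_predictions(docs, "v", pred_pos)
        counts = confusion(gold, pred, "v")
        gp, pp = set(gold_pos), set(pred_pos)
        assert counts.tp == len(gp & pp)
        assert counts.fp == len(pp - gp)
        assert counts.fn == len(gp - pp)
        assert counts.tn == len(docs) - len(gp | pp)
        assert counts.total == len(docs)

    def test_grid_mismatch_rejected(self):
        gold = make_gold(DOCS, "asthma", DOCS[:2])
        pred = make_predictions(DOCS[:-1], "asthma", [])
        with pytest.raises(ValidationError, match="missing"):
            confusion(gold, pred, "asthma")


class TestMetrics:
    def test_point_estimates_and_harmonic_identity(self):
        m = metrics(ConfusionCounts(tp=80, fp=10, fn=20, tn=90), variable="v")
        assert m.precision == pytest.approx(80 / 90)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12
        )

    @pytest.mark.parametrize(
        "p,r,expected",
        [
            (0.94, 0.96, 0.95),  # primary condition row
            (1.00, 0.75, 0.86),
            (0.99, 0.90, 0.94),
            (0.95, 0.90, 0.92),
        ],
    )
    def test_published_f1_rows_reproduced_from_p_and_r(self, p, r, expected):
        assert round_half_up_2dp(harmonic_f1(p, r)) == pytest.approx(expected)

    def test_zero_denominator_conventions(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5), variable="v")
        assert m.precision == 0.0 and not m.precision_defined
        assert m.recall == 0.0 and m.recall_defined
        assert m.f1 == 0.0

    def test_perfect_system_cis_contain_one(self):
        m = metrics(ConfusionCounts(tp=50, fp=0, fn=0, tn=50), variable="v")
        assert m.precision == m.recall == m.f1 == 1.0
        assert m.precision_ci.upper == 1.0
        assert m.recall_ci.upper == 1.0
        assert m.f1_ci.upper == 1.0

    def test_ci_construction_uses_clopper_pearson_counts(self):
        from ehreval import BinomialSample, clopper_pearson

        counts = ConfusionCounts(tp=171, fp=9, fn=19, tn=300)
        m = metrics(counts, alpha=0.05, variable="prick_test")
        p_ci = clopper_pearson(BinomialSample(171, 180), 0.05)
        r_ci = clopper_pearson(BinomialSample(171, 190), 0.05)
        assert m.precision_ci == p_ci
        assert m.recall_ci == r_ci
        assert m.f1_ci.lower == pytest.approx(
            harmonic_f1(p_ci.lower, r_ci.lower)
        )
        assert m.f1_ci.upper == pytest.approx(
            harmonic_f1(p_ci.upper, r_ci.upper)
        )

    def test_f1_between_harmonic_bounds(self, rng):
        for _ in range(50):
            tp = int(rng.integers(1, 100))
            fp = int(rng.integers(0, 100))
            fn = int(rng.integers(0, 100))
            m = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0), variable="v")
            p, r = m.precision, m.recall
            assert m.f1 <= math.sqrt(p * r) + 1e-12
            lo, hi = min(p, r), max(p, r)
            assert m.f1 <= lo * 2 / (1 + lo / hi) + 1e-12
            assert lo - 1e-12 <= m.f1 <= hi + 1e-12


class TestIaa:
    def test_identical_sets_have_perfect_agreement(self, grid_factory):
        a = grid_factory("a", DOCS, ["v"], [("D0", "v"), ("D3", "v")])
        b = grid_factory("b", DOCS, ["v"], [("D0", "v"), ("D3", "v")])
        assert iaa(a, b, "v").f1 == 1.0

    def test_disjoint_present_sets_have_zero_agreement(self, grid_factory):
        a = grid_factory("a", DOCS, ["v"], [("D0", "v")])
        b = grid_factory("b", DOCS, ["v"], [("D1", "v")])
        assert iaa(a, b, "v").f1 == 0.0

    def test_hand_counted_example(self, grid_factory):
        a = grid_factory("a", DOCS, ["v"], [("D1", "v"), ("D2", "v"), ("D3", "v")])
        b = grid_factory("b", DOCS, ["v"], [("D2", "v"), ("D3", "v"), ("D4", "v")])
        result = iaa(a, b, "v")
        assert (result.counts.tp, result.counts.fp, result.counts.fn) == (2, 1, 1)
        assert result.f1 == pytest.approx(2 / 3)

    def test_symmetric_under_annotator_swap(self, grid_factory, rng):
        for _ in range(50):
            pa = [("D%d" % i, "v") for i in range(10) if rng.random() < 0.4]
            pb = [("D%d" % i, "v") for i in range(10) if rng.random() < 0.4]
            a = grid_factory("a", DOCS, ["v"], pa)
            b = grid_factory("b", DOCS, ["v"], pb)
            assert iaa(a, b, "v").f1 == pytest.approx(iaa(b, a, "v").f1, abs=1e-12)


class TestCompliance:
    def test_width_compliance_like_the_primary_variable(self):
        # 0.94 precision over 289 retrieved, 0.96 recall over 281 positives
        counts = ConfusionCounts(tp=271, fp=18, fn=10, tn=220)
        m = metrics(counts, variable="asthma")
        request = SliceRequest(
            expected_precision=0.85, expected_recall=0.80, frequency=0.485
        )
        report = check_expected_compliance(m, request)
        assert report.precision_width_ok and report.recall_width_ok
        assert report.precision_meets_expected and report.recall_meets_expected

    def test_underperforming_recall_flagged(self):
        counts = ConfusionCounts(tp=100, fp=5, fn=100, tn=100)
        m = metrics(counts, variable="v")
        request = SliceRequest(
            expected_precision=0.85, expected_recall=0.80, frequency=0.485
        )
        report = check_expected_compliance(m, request)
        assert not report.recall_meets_expected


class TestRenderReport:
    def make_result(self):
        return metrics(ConfusionCounts(tp=271, fp=18, fn=10, tn=220),
                       variable="asthma")

    def test_markdown_row_style(self):
        out = render_report([self.make_result()], format="markdown")
        assert "| asthma |" in out
        # estimate (lower-upper), 2 decimals, half-up
        assert "0.94 (0.90-0.96)" in out

    def test_csv_parses(self):
        out = render_report([self.make_result()], format="csv")
        lines = out.strip().splitlines()
        assert lines[0] == "variable,precision,recall,f1"
        assert lines[1].startswith("asthma,")

    def test_json_round_trips_losslessly(self):
        from ehreval.evaluator import report_records

        results = [self.make_result()]
        rendered = render_report(results, format="json")
        assert json.loads(rendered) == report_records(results)

    def test_unknown_format_rejected(self):
        with pytest.raises(ValidationError, match="format"):
            render_report([self.make_result()], format="xml")

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            render_report([], format="json")

    def test_empty_variable_name_rejected(self):
        bad = metrics(ConfusionCounts(1, 1, 1, 1), variable="")
        with pytest.raises(ValidationError, match="variable"):
            render_report([bad], format="json")

    def test_rounding_is_half_up(self):
        assert round_half_up_2dp(0.945) == 0.95
        assert round_half_up_2dp(0.9449) == 0.94
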