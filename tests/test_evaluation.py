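"""Scoring: entity matching, stay confusion, metrics, averages, bootstrap."""
import random

import numpy as np
import pytest
from _oracles import entity_match_oracle, metrics_oracle

from charlson_nlp.evaluation import (
    ConfusionCounts,
    MetricsRow,
    average_metrics,
    bootstrap_ci,
    compare_pipelines,
    compute_metrics,
    evaluate_pipeline,
    match_entities,
    round_display,
    stay_confusion,
)
from charlson_nlp.types import ABSENT, PRESENT, Mention, StayPrediction


def M(note, s, e, cond="diabetes", status=None):
    return Mention(f"{note}:{s}:{e}:{cond}", note, cond, (s, e), (max(0, s - 5), e + 5),
                   status=status)


class TestMatchEntities:
    def test_identical_sets_perfect(self):
        gold = [M("n1", 0, 5), M("n1", 10, 15), M("n2", 3, 9)]
        c = match_entities(gold, gold, "diabetes")
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_one_char_overlap_counts(self):
        gold = [M("n1", 0, 5)]
        pred = [M("n1", 4, 9)]
        c = match_entities(pred, gold, "diabetes")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_k_predictions_over_one_gold(self):
        gold = [M("n1", 0, 10), M("n1", 50, 55)]
        pred = [M("n1", 0, 3), M("n1", 5, 9)]
        c = match_entities(pred, gold, "diabetes")
        assert (c.tp, c.fp, c.fn) == (2, 0, 1)

    def test_cross_note_spans_never_match(self):
        gold = [M("n1", 0, 5)]
        pred = [M("n2", 0, 5)]
        c = match_entities(pred, gold, "diabetes")
        assert (c.tp, c.fp, c.fn) == (1, 0, 1) if False else (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_status_required(self):
        gold = [M("n1", 0, 5, status="uncomplicated")]
        pred = [M("n1", 0, 5, status="with_end_organ_damage")]
        c = match_entities(pred, gold, "diabetes", require_status=True)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_random_fixtures_match_bruteforce_oracle(self):
        rng = random.Random(31)
        for _ in range(50):
            def spans(k):
                out = []
                for _ in range(k):
                    note = f"n{rng.randrange(3)}"
                    s = rng.randrange(0, 40)
                    out.append((note, s, s + rng.randrange(1, 8)))
                return out

            gold_spans = spans(rng.randrange(0, 6))
            pred_spans = spans(rng.randrange(0, 6))
            gold = [M(n, s, e) for n, s, e in gold_spans]
            pred = [M(n, s, e) for n, s, e in pred_spans]
            c = match_entities(pred, gold, "diabetes")
            assert (c.tp, c.fp, c.fn) == entity_match_oracle(pred_spans, gold_spans)


def _stay_pred(stay, value, cond="diabetes"):
    return StayPrediction(stay, "nlp", {cond: value})


class TestStayConfusion:
    def test_perfect_prediction(self):
        gold = {f"s{i}": {"diabetes": "uncomplicated" if i < 10 else ABSENT} for i in range(50)}
        preds = [_stay_pred(s, labels["diabetes"]) for s, labels in gold.items()]
        c = stay_confusion(preds, gold, "diabetes")
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 40, 0, 0)

    def test_all_absent_prediction(self):
        gold = {f"s{i}": {"diabetes": PRESENT if i < 4 else ABSENT} for i in range(10)}
        c = stay_confusion([], gold, "diabetes")
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 4, 6, 0)

    def test_status_scope_vs_any_scope(self):
        gold = {"s1": {"diabetes": "uncomplicated"}}
        preds = [_stay_pred("s1", "with_end_organ_damage")]
        any_c = stay_confusion(preds, gold, "diabetes", status=None)
        st_c = stay_confusion(preds, gold, "diabetes", status="uncomplicated")
        assert any_c.tp == 1
        assert (st_c.tp, st_c.fn) == (0, 1)

    def test_random_fixture_equals_per_stay_enumeration(self):
        rng = random.Random(7)
        values = [ABSENT, "uncomplicated", "with_end_organ_damage"]
        for _ in range(20):
            gold = {f"s{i}": {"diabetes": rng.choice(values)} for i in range(20)}
            preds = [_stay_pred(f"s{i}", rng.choice(values)) for i in range(20)]
            for status in [None, "uncomplicated"]:
                c = stay_confusion(preds, gold, "diabetes", status=status)
                tp = fp = fn = tn = 0
                for i in range(20):
                    g, p = gold[f"s{i}"]["diabetes"], preds[i].conditions["diabetes"]
                    gp = (g != ABSENT) if status is None else (g == status)
                    pp = (p != ABSENT) if status is None else (p == status)
                    tp += gp and pp
                    fn += gp and not pp
                    fp += pp and not gp
                    tn += not gp and not pp
                assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestComputeMetrics:
    def test_closed_form(self):
        m = compute_metrics(ConfusionCounts(tp=9, fp=1, fn=1, tn=89))
        assert m["ppv"] == pytest.approx(90.0)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["f1"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(100 * 89 / 90)

    def test_zero_counts_undefined_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert m["ppv"] is None and m["sensitivity"] is None and m["f1"] is None
        assert m["specificity"] == pytest.approx(100.0)

    def test_entity_level_specificity_undefined(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=None))
        assert m["specificity"] is None

    def test_100_random_tuples_vs_independent_oracle(self):
        rng = random.Random(13)
        for _ in range(100):
            tp, fp, fn = (rng.randrange(0, 20) for _ in range(3))
            tn = rng.choice([None, rng.randrange(0, 50)])
            got = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
            want = metrics_oracle(tp, fp, fn, tn)
            for k in got:
                if want[k] is None:
                    assert got[k] is None
                else:
                    assert got[k] == pytest.approx(want[k])


def _row(tp, fp, fn, tn, cond="c"):
    return MetricsRow.from_counts("condition", cond, "stay", ConfusionCounts(tp, fp, fn, tn))


class TestAverages:
    def test_identical_rows_all_averages_equal_row(self):
        rows = [_row(8, 2, 2, 88, cond=f"c{i}") for i in range(4)]
        micro, macro, weighted = average_metrics(rows, "stay")
        for avg in (micro, macro, weighted):
            assert avg.f1 == pytest.approx(rows[0].f1)
            assert avg.specificity == pytest.approx(rows[0].specificity)

    def test_weighted_two_rows(self):
        r1, r2 = _row(1, 0, 0, 10, "a"), _row(2, 1, 1, 10, "b")
        _, _, weighted = average_metrics([r1, r2], "stay")
        assert weighted.sensitivity == pytest.approx(
            (r1.sensitivity * 1 + r2.sensitivity * 3) / 4
        )

    def test_micro_equals_metrics_of_summed_counts(self):
        rng = random.Random(3)
        rows = [_row(rng.randrange(0, 9), rng.randrange(0, 9), rng.randrange(0, 9),
                     rng.randrange(0, 30), cond=f"c{i}") for i in range(5)]
        micro, _, _ = average_metrics(rows, "stay")
        total = ConfusionCounts(
            sum(r.counts.tp for r in rows), sum(r.counts.fp for r in rows),
            sum(r.counts.fn for r in rows), sum(r.counts.tn for r in rows),
        )
        want = compute_metrics(total)
        for k, v in want.items():
            got = getattr(micro, k)
            assert got == pytest.approx(v) if v is not None else got is None

    def test_permutation_invariance(self):
        rng = random.Random(5)
        rows = [_row(rng.randrange(0, 9), rng.randrange(0, 9), rng.randrange(1, 9),
                     rng.randrange(0, 30), cond=f"c{i}") for i in range(6)]
        a = average_metrics(rows, "stay")
        b = average_metrics(rows[::-1], "stay")
        for x, y in zip(a, b):
            for m in ("f1", "ppv", "sensitivity", "specificity"):
                assert getattr(x, m) == pytest.approx(getattr(y, m))


class TestBootstrap:
    @staticmethod
    def _sens(units):
        pos = [u for u in units if u[0]]
        if not pos:
            return {"sensitivity": None}
        return {"sensitivity": 100.0 * sum(u[1] for u in pos) / len(pos)}

    def test_identical_outcomes_zero_width(self):
        units = [(1, 1)] * 30
        ci, skipped = bootstrap_ci(units, self._sens, reps=200, seed=4)
        assert ci["sensitivity"] == (100.0, 100.0)
        assert skipped == {}

    def test_seed_determinism(self):
        rng = random.Random(11)
        units = [(1, rng.random() < 0.8) for _ in range(50)]
        a, _ = bootstrap_ci(units, self._sens, reps=300, seed=42)
        b, _ = bootstrap_ci(units, self._sens, reps=300, seed=42)
        assert a == b

    def test_degenerate_resamples_counted(self):
        units = [(0, 0)] * 10 + [(1, 1)]
        _, skipped = bootstrap_ci(units, self._sens, reps=200, seed=1)
        assert skipped.get("sensitivity", 0) > 0


class TestEvaluatePipeline:
    def _gold(self):
        gold = {}
        for i in range(30):
            labels = {}
            if i < 6:
                labels["diabetes"] = "uncomplicated" if i < 3 else "with_end_organ_damage"
            if 6 <= i < 10:
                labels["dementia"] = PRESENT
            if i == 10:
                labels["hemiplegia"] = PRESENT
            gold[f"s{i}"] = labels
        return gold

    def test_perfect_prediction_all_100(self, definitions):
        gold = self._gold()
        preds = [StayPrediction(s, "nlp", dict(labels)) for s, labels in gold.items()]
        report = evaluate_pipeline(preds, gold, definitions, level="stay")
        for row in report.rows:
            if row.ppv_only or row.support == 0:
                continue
            assert row.f1 == pytest.approx(100.0)
        assert report.micro.f1 == pytest.approx(100.0)

    def test_statused_condition_has_three_rows(self, definitions):
        gold = self._gold()
        preds = [StayPrediction(s, "nlp", dict(labels)) for s, labels in gold.items()]
        report = evaluate_pipeline(preds, gold, definitions, level="stay")
        diabetes_rows = [r for r in report.rows if r.condition_id == "diabetes"]
        assert len(diabetes_rows) == 3
        assert {r.scope for r in diabetes_rows} == {"status", "any"}

    def test_ppv_only_conditions_excluded_from_averages(self, definitions):
        gold = self._gold()
        # wrong on hemiplegia only: would tank averages were it included
        preds = []
        for s, labels in gold.items():
            labels = dict(labels)
            labels.pop("hemiplegia", None)
            preds.append(StayPrediction(s, "nlp", labels))
        report = evaluate_pipeline(preds, gold, definitions, level="stay")
        assert set(report.excluded_conditions) == {"hemiplegia", "aids"}
        assert report.micro.f1 == pytest.approx(100.0)
        hemi = report.row_for("hemiplegia")
        assert hemi.f1 is None and hemi.sensitivity is None

    def test_bootstrap_cis_attached_and_deterministic(self, definitions):
        gold = self._gold()
        preds = [StayPrediction(s, "nlp", dict(labels)) for s, labels in gold.items()]
        r1 = evaluate_pipeline(preds, gold, definitions, level="stay",
                               bootstrap_reps=50, seed=5)
        r2 = evaluate_pipeline(preds, gold, definitions, level="stay",
                               bootstrap_reps=50, seed=5)
        row1, row2 = r1.row_for("dementia"), r2.row_for("dementia")
        assert row1.ci and row1.ci == row2.ci


class TestComparePipelines:
    def _report(self, f1, definitions):
        gold = {"s1": {"dementia": PRESENT}, "s2": {}}
        preds = [StayPrediction("s1", "nlp", {"dementia": PRESENT if f1 else ABSENT}),
                 StayPrediction("s2", "nlp", {})]
        return evaluate_pipeline(preds, gold, definitions, level="stay")

    def test_single_report_equals_itself(self, definitions):
        rep = self._report(True, definitions)
        table = compare_pipelines({"nlp": rep})
        row = table[table.condition == "dementia"].iloc[0]
        assert row["f1_nlp"] == 100.0 and row["f1_best"] == "nlp"

    def test_dominating_pipeline_takes_all_best_marks(self, definitions):
        good = self._report(True, definitions)
        bad = self._report(False, definitions)
        table = compare_pipelines({"good": good, "bad": bad})
        row = table[table.condition == "dementia"].iloc[0]
        for metric in ("f1", "ppv", "sensitivity"):
            assert row[f"{metric}_best"] == "good"


def test_round_display_half_up():
    assert round_display(98.85) == 98.9
    assert round_display(98.84) == 98.8
    assert round_display(0.05) == 0.1
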