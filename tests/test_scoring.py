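"""Clinical identification, false-detection and inappropriate-ASM rules."""

from __future__ import annotations

import itertools
from datetime import datetime

import pytest

from neoseize.consensus import ConsensusAnnotation, SeizureInterval
from neoseize.scoring import (
    HourRecord,
    NeonateRecord,
    classify_neonate_clinical,
    hour_detection_summary,
    hour_strata,
    inappropriate_asm_events,
    neonate_confusion,
    score_hours,
    stratify_hours,
)


def make_record(n_hours, marked=(), asm=(), nid="n", group="algorithm", start=None):
    hours = [
        HourRecord(hour_index=k, form_marked=k in marked, asm_given=k in asm)
        for k in range(n_hours)
    ]
    return NeonateRecord(
        neonate_id=nid, hospital="H1", group=group, recording_duration_h=float(n_hours),
        hours=hours, start_datetime=start,
    )


def make_consensus(nid, events, duration_h):
    return ConsensusAnnotation(
        nid, [SeizureInterval(s, e) for s, e in events], duration_h
    )


class TestNeonateClassification:
    def test_all_blank_is_negative(self):
        assert not classify_neonate_clinical(make_record(12))

    def test_single_asm_is_positive(self):
        assert classify_neonate_clinical(make_record(12, asm={7}))

    def test_non_therapeutic_asm_does_not_count(self):
        hours = [HourRecord(0, False, True, asm_therapeutic=False)]
        r = NeonateRecord("n", "H1", "algorithm", 1.0, hours)
        assert not classify_neonate_clinical(r)

    def test_exhaustive_four_hour_patterns_match_any_oracle(self):
        # all 2^(2*4) placements of form marks and ASM over a 4-hour record
        for marks in itertools.product([0, 1], repeat=4):
            for asms in itertools.product([0, 1], repeat=4):
                r = make_record(
                    4,
                    marked={k for k in range(4) if marks[k]},
                    asm={k for k in range(4) if asms[k]},
                )
                assert classify_neonate_clinical(r) == (any(marks) or any(asms))


class TestNeonateConfusion:
    def _cohort(self, n_tp, n_tn, n_fp, n_fn):
        cohort = []
        i = 0
        for _ in range(n_tp):
            i += 1
            cohort.append((make_record(2, marked={0}, nid=f"n{i}"),
                           make_consensus(f"n{i}", [(0, 60)], 2.0)))
        for _ in range(n_tn):
            i += 1
            cohort.append((make_record(2, nid=f"n{i}"), make_consensus(f"n{i}", [], 2.0)))
        for _ in range(n_fp):
            i += 1
            cohort.append((make_record(2, marked={1}, nid=f"n{i}"),
                           make_consensus(f"n{i}", [], 2.0)))
        for _ in range(n_fn):
            i += 1
            cohort.append((make_record(2, nid=f"n{i}"),
                           make_consensus(f"n{i}", [(0, 60)], 2.0)))
        return cohort

    def test_engineered_counts(self):
        # the algorithm-arm confusion pattern: 26/81/15/6
        cc = neonate_confusion(self._cohort(26, 81, 15, 6))
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (26, 81, 15, 6)
        assert cc.n == 128

    def test_perfect_clinician(self, rng):
        cohort = []
        for i in range(30):
            gold = bool(rng.integers(0, 2))
            cons = make_consensus(f"n{i}", [(0, 45)] if gold else [], 2.0)
            rec = make_record(2, marked={0} if gold else set(), nid=f"n{i}")
            cohort.append((rec, cons))
        cc = neonate_confusion(cohort)
        assert cc.fp == 0 and cc.fn == 0

    def test_random_cohort_matches_loop_oracle(self, rng):
        cohort = []
        for i in range(50):
            gold = bool(rng.integers(0, 2))
            marked = {int(k) for k in rng.integers(0, 4, size=rng.integers(0, 3))}
            asm = {int(k) for k in rng.integers(0, 4, size=rng.integers(0, 2))}
            cohort.append(
                (make_record(4, marked=marked, asm=asm, nid=f"n{i}"),
                 make_consensus(f"n{i}", [(0, 40)] if gold else [], 4.0))
            )
        cc = neonate_confusion(cohort)
        tp = tn = fp = fn = 0  # independent recount
        for rec, cons in cohort:
            g = bool(cons.confirmed_events)
            c = any(h.form_marked or h.asm_given for h in rec.hours)
            tp += g and c
            fn += g and not c
            fp += (not g) and c
            tn += (not g) and not c
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn)

    def test_duplicate_id_rejected(self):
        pair = (make_record(2, nid="dup"), make_consensus("dup", [], 2.0))
        with pytest.raises(ValueError, match="duplicate"):
            neonate_confusion([pair, pair])


def rule_table_oracle(n_hours, gold, marked, asm):
    """Independent restatement of the hour rules, hour by hour."""
    ident = {}
    false_det = set()
    for k in range(n_hours):
        if k in gold:
            now = k in marked or k in asm
            nxt = (k + 1) in marked or (k + 1) in asm if k + 1 < n_hours else False
            ident[k] = now or nxt
        if k in marked and k not in gold and (k - 1) not in gold:
            false_det.add(k)
    inappropriate = {
        k for k in asm if k not in gold and (k - 1) not in gold
    }
    return ident, false_det, inappropriate


class TestHourRules:
    def test_hour_after_mark_identifies(self):
        scores = score_hours(make_record(8, marked={6}), gold_hours={5})
        assert scores[5].identified is True

    def test_two_hours_late_does_not_identify(self):
        scores = score_hours(make_record(8, asm={7}), gold_hours={5})
        assert scores[5].identified is False

    def test_mark_after_gold_hour_is_not_false_detection(self):
        scores = score_hours(make_record(8, marked={3}), gold_hours={2})
        assert scores[3].false_detection is False

    def test_identified_none_outside_gold_hours(self):
        scores = score_hours(make_record(4, marked={1}), gold_hours={2})
        assert scores[1].identified is None

    def test_exhaustive_three_hour_enumeration(self):
        # every placement of gold hours, marks and ASM over a 3-hour record
        subsets = [set(c) for r in range(4) for c in itertools.combinations(range(3), r)]
        for gold in subsets:
            for marked in subsets:
                for asm in subsets:
                    r = make_record(3, marked=marked, asm=asm)
                    scores = score_hours(r, gold)
                    ident, false_det, inappropriate = rule_table_oracle(3, gold, marked, asm)
                    for s in scores:
                        if s.gold_seizure_hour:
                            assert s.identified == ident[s.hour_index]
                        else:
                            assert s.identified is None
                        assert s.false_detection == (s.hour_index in false_det)
                    asm_res = inappropriate_asm_events(r, gold)
                    assert set(asm_res.inappropriate_hours) == inappropriate
                    assert asm_res.any_inappropriate == bool(inappropriate)

    def test_mark_monotonicity(self, rng):
        # adding a form mark never decreases identification or marked counts
        for _ in range(50):
            n = 12
            gold = {int(k) for k in rng.integers(0, n, size=4)}
            marked = {int(k) for k in rng.integers(0, n, size=3)}
            extra = int(rng.integers(0, n))
            base = hour_detection_summary(score_hours(make_record(n, marked=marked), gold))
            more = hour_detection_summary(
                score_hours(make_record(n, marked=marked | {extra}), gold)
            )
            assert more.n_identified >= base.n_identified
            assert more.n_marked_hours >= base.n_marked_hours
            assert base.n_false_detections <= base.n_marked_hours
            assert base.n_identified <= base.n_gold_hours


class TestSummaryAndAsm:
    def test_no_marks_summary(self):
        s = hour_detection_summary(score_hours(make_record(6), gold_hours={1, 4}))
        assert s == (2, 0, 0, 0)

    def test_summary_matches_recount(self, rng):
        records = []
        scores = []
        for i in range(10):
            gold = {int(k) for k in rng.integers(0, 8, size=3)}
            marked = {int(k) for k in rng.integers(0, 8, size=3)}
            r = make_record(8, marked=marked, nid=f"n{i}")
            records.append((r, gold))
            scores.extend(score_hours(r, gold))
        summ = hour_detection_summary(scores)
        n_gold = sum(len(g) for _, g in records)
        assert summ.n_gold_hours == n_gold
        n_marked = sum(sum(h.form_marked for h in r.hours) for r, _ in records)
        assert summ.n_marked_hours == n_marked

    def test_asm_hour_before_window(self):
        r = make_record(8, asm={4})
        assert inappropriate_asm_events(r, {3}).n_inappropriate == 0
        r0 = make_record(8, asm={0})
        assert inappropriate_asm_events(r0, set()).n_inappropriate == 1


class TestStratification:
    def test_weekend_start_all_weekend(self):
        strata = hour_strata(datetime(2015, 2, 14, 0, 0), 48)  # a Saturday
        assert all(day == "weekend" for day, _ in strata)

    def test_friday_evening_transition(self):
        # Friday 19:00 start: hour 0 weekday/day, hour 1 weekday/night,
        # hours 5+ weekend (Saturday 00:00 onward)
        strata = hour_strata(datetime(2015, 2, 13, 19, 0), 8)
        assert strata[0] == ("weekday", "day")
        assert strata[1] == ("weekday", "night")
        assert all(strata[k][0] == "weekend" for k in range(5, 8))

    def test_strata_partition_gold_hours(self, rng):
        scored = []
        for i in range(8):
            start = datetime(2015, 3, 2 + int(rng.integers(0, 7)), int(rng.integers(0, 24)))
            gold = {int(k) for k in rng.integers(0, 24, size=5)}
            marked = {int(k) for k in rng.integers(0, 24, size=4)}
            r = make_record(24, marked=marked, nid=f"n{i}", start=start)
            scored.append((r, score_hours(r, gold)))
        res = stratify_hours(scored)
        assert res["weekday"].n_gold_hours + res["weekend"].n_gold_hours == res["overall"].n_gold_hours
        assert res["day_shift"].n_gold_hours + res["night_shift"].n_gold_hours == res["overall"].n_gold_hours
        assert res["weekday"].n_identified + res["weekend"].n_identified == res["overall"].n_identified

    def test_missing_start_time_rejected(self):
        r = make_record(4)
        with pytest.raises(ValueError, match="start_datetime"):
            stratify_hours([(r, score_hours(r, set()))])
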