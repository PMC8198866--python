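"""The five measurement methods, bout detection and daily summaries."""

from datetime import datetime

import numpy as np
import pytest

from popai import classification as cl
from popai.classification import (
    ClassifiedTimeline,
    Label,
    classify_actigraph,
    classify_actigraph_plus,
    classify_activpal,
    classify_activpal_plus,
    classify_popai,
    detect_bouts,
    minute_posture_labels,
    partition_event_inference,
    participant_mean,
    summarize_days,
)
from popai.errors import RegistryMismatchError
from popai.preprocessing import WearMask, build_wear_mask, exclude_bedtime
from popai.sensor_io import CountsSeries, EventTimeline, Posture, PostureEvent, counts_in_span
from tests.conftest import EPOCH, make_timeline

H = 3600.0


def _counts(axis1, epoch=1.0):
    a = np.asarray(axis1, dtype=np.int64)
    return CountsSeries(a, np.zeros_like(a), np.zeros_like(a), EPOCH, epoch)


def popai_brute_force_sweep(n_events: int, seed: int) -> tuple[int, int]:
    """Check the POPAI classifier against a per-second brute-force oracle
    on random sitting events with random counts.

    The oracle accumulates counts one second at a time over each
    classified span and applies the pro-rated cut-point directly.
    Returns (spans checked, mismatches).
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    checked = 0
    for _ in range(n_events):
        d = float(np.round(rng.uniform(5.0, 400.0), 1))
        n_sec = int(np.ceil(d)) + 120
        axis = rng.integers(0, 6, n_sec).astype(np.int64) * rng.integers(0, 2, n_sec)
        tl = make_timeline([(d, Posture.SIT)])
        series = _counts(axis)
        ct = classify_popai(tl, series)
        for ws in partition_event_inference(tl.events[0]):
            total = 0.0
            t = ws.cls_start
            while t < ws.cls_end - 1e-9:
                step = min(1.0, ws.cls_end - t)
                sec = int(t)
                frac_hi = min(t + step, sec + 1) - t
                total += axis[sec] * frac_hi
                if t + step > sec + 1:
                    total += axis[sec + 1] * (t + step - sec - 1)
                t += step
            want = (
                Label.SEDENTARY
                if total < 75.0 * (ws.cls_end - ws.cls_start) / 60.0
                else Label.ACTIVE_SITTING
            )
            got_sed = ct.duration(Label.SEDENTARY, ws.cls_start, ws.cls_end)
            got = (
                Label.SEDENTARY
                if got_sed > (ws.cls_end - ws.cls_start) / 2
                else Label.ACTIVE_SITTING
            )
            checked += 1
            if got is not want:
                mismatches += 1
    return checked, mismatches


class TestPartition:
    def test_five_and_a_half_minute_event(self):
        ev = PostureEvent(0.0, 330.0, Posture.SIT)
        ws = partition_event_inference(ev)
        assert len(ws) == 6
        for i in range(5):
            assert (ws[i].win_start, ws[i].win_end) == (60.0 * i, 60.0 * (i + 1))
            assert (ws[i].cls_start, ws[i].cls_end) == (60.0 * i, 60.0 * (i + 1))
        last = ws[-1]
        assert (last.win_start, last.win_end) == (270.0, 330.0)
        assert (last.cls_start, last.cls_end) == (300.0, 330.0)

    def test_sub_minute_event_centred(self):
        ev = PostureEvent(100.0, 30.0, Posture.SIT)
        (ws,) = partition_event_inference(ev)
        assert (ws.win_start, ws.win_end) == (85.0, 145.0)
        assert (ws.cls_start, ws.cls_end) == (100.0, 130.0)

    def test_exact_minutes_no_overlap(self):
        ev = PostureEvent(0.0, 120.0, Posture.SIT)
        ws = partition_event_inference(ev)
        assert len(ws) == 2
        assert ws[0].cls_end == ws[1].cls_start
        assert ws[-1].cls_end == 120.0

    def test_classified_spans_partition_event(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = float(rng.uniform(5.0, 900.0))
            ws = partition_event_inference(PostureEvent(10.0, d, Posture.SIT))
            assert ws[0].cls_start == pytest.approx(10.0)
            assert ws[-1].cls_end == pytest.approx(10.0 + d)
            for a, b in zip(ws, ws[1:]):
                assert a.cls_end == pytest.approx(b.cls_start)

    def test_non_sit_rejected(self):
        with pytest.raises(ValueError):
            partition_event_inference(PostureEvent(0.0, 120.0, Posture.STAND))


class TestPopai:
    def test_fractional_cutpoint_20s_event(self):
        """A 20-s sitting event is judged against 25 counts: 10 counts ->
        sedentary; 30 counts -> active sitting."""
        for total, label in [(10, Label.SEDENTARY), (30, Label.ACTIVE_SITTING)]:
            axis = np.zeros(100, dtype=np.int64)
            axis[45] = total  # inside the event [40, 60)
            tl = make_timeline([(40.0, Posture.STAND), (20.0, Posture.SIT), (40.0, Posture.STAND)])
            ct = classify_popai(tl, _counts(axis))
            assert ct.duration(label) == pytest.approx(20.0)

    def test_minute_split_inside_event(self):
        axis = np.zeros(180, dtype=np.int64)
        axis[60] = 80  # second minute carries 80 counts
        tl = make_timeline([(180.0, Posture.SIT)])
        ct = classify_popai(tl, _counts(axis))
        assert ct.minutes(Label.SEDENTARY) == pytest.approx(2.0)
        assert ct.minutes(Label.ACTIVE_SITTING) == pytest.approx(1.0)
        assert (60.0, 120.0, Label.ACTIVE_SITTING) in ct.intervals

    def test_zero_counts_day_all_sitting_sedentary(self, sim_day):
        zero = _counts(np.zeros(int(sim_day.counts.duration), dtype=np.int64))
        ct = classify_popai(sim_day.timeline, zero)
        sit = sum(e.duration for e in sim_day.timeline.events if e.posture is Posture.SIT)
        assert ct.duration(Label.SEDENTARY) == pytest.approx(sit, abs=1e-6)
        assert ct.duration(Label.ACTIVE_SITTING) == 0.0

    def test_matches_per_second_brute_force(self):
        """Oracle equivalence over random sitting events (the full
        1000-event sweep runs in the acceptance suite)."""
        checked, mismatches = popai_brute_force_sweep(200, seed=12)
        assert checked >= 200
        assert mismatches == 0


class TestActivpal:
    def test_sedentary_equals_sit_exactly(self, sim_day):
        ct = classify_activpal(sim_day.timeline)
        sit = sum(e.duration for e in sim_day.timeline.events if e.posture is Posture.SIT)
        assert ct.duration(Label.SEDENTARY) == pytest.approx(sit, abs=1e-9)

    def test_no_sitting_gives_zero(self):
        tl = make_timeline([(300.0, Posture.STAND), (300.0, Posture.STEP, 500)])
        assert classify_activpal(tl).duration(Label.SEDENTARY) == 0.0

    def test_overestimation_equals_active_sitting(self, sim_day):
        """activPAL minus POPAI sedentary time equals POPAI's active
        sitting exactly — the overestimation is active sitting."""
        ct_ap = classify_activpal(sim_day.timeline)
        ct_po = classify_popai(sim_day.timeline, sim_day.counts)
        diff = ct_ap.duration(Label.SEDENTARY) - ct_po.duration(Label.SEDENTARY)
        assert diff == pytest.approx(ct_po.duration(Label.ACTIVE_SITTING), abs=1e-6)


class _CountOracleModel:
    """Span-aware oracle reproducing the fractional cut-point labels."""

    registry_version = "1.0"

    def __init__(self, counts, cutpoint=75.0):
        self.counts = counts
        self.cutpoint = cutpoint

    def predict_span(self, w0, w1, c0, c1, window):
        c = counts_in_span(self.counts, c0, c1)
        return 0 if c < self.cutpoint * (c1 - c0) / 60.0 else 1


class TestActivpalPlus:
    def test_count_oracle_reproduces_popai(self, sim_day):
        oracle = _CountOracleModel(sim_day.counts)
        ct_plus = classify_activpal_plus(sim_day.timeline, sim_day.raw_thigh, oracle)
        ct_po = classify_popai(sim_day.timeline, sim_day.counts)
        assert ct_plus.duration(Label.SEDENTARY) == pytest.approx(
            ct_po.duration(Label.SEDENTARY), abs=1e-6
        )
        assert ct_plus.duration(Label.ACTIVE_SITTING) == pytest.approx(
            ct_po.duration(Label.ACTIVE_SITTING), abs=1e-6
        )

    def test_registry_mismatch_rejected(self, sim_day):
        class Stale:
            registry_version = "0.0"

            def predict_window(self, w):
                return 0

        with pytest.raises(RegistryMismatchError):
            classify_activpal_plus(sim_day.timeline, sim_day.raw_thigh, Stale())

    def test_no_sitting_gives_zero(self, sim_day):
        tl = make_timeline([(600.0, Posture.STAND)])
        oracle = _CountOracleModel(_counts(np.zeros(600, dtype=np.int64)))
        ct = classify_activpal_plus(tl, sim_day.raw_thigh, oracle)
        assert ct.duration(Label.SEDENTARY) == 0.0


class TestActigraph:
    def test_cutpoint_boundary(self):
        for total, label in [(99, Label.SEDENTARY), (100, Label.STANDING_OTHER)]:
            axis = np.zeros(60, dtype=np.int64)
            axis[0] = total
            ct = classify_actigraph(_counts(axis))
            assert ct.intervals[0][2] is label

    def test_all_active_minutes_zero_sedentary(self):
        axis = np.full(300, 10, dtype=np.int64)  # 600 cpm
        assert classify_actigraph(_counts(axis)).duration(Label.SEDENTARY) == 0.0

    def test_matches_per_minute_rule(self):
        rng = np.random.default_rng(5)
        axis = (rng.integers(0, 4, 1800) * rng.integers(0, 2, 1800)).astype(np.int64)
        ct = classify_actigraph(_counts(axis))
        for m in range(30):
            cpm = axis[m * 60 : (m + 1) * 60].sum()
            want = Label.SEDENTARY if cpm < 100 else Label.STANDING_OTHER
            assert ct.duration(want, m * 60.0, (m + 1) * 60.0) == pytest.approx(60.0)


class TestActigraphPlus:
    def test_oracle_posture_with_zero_counts(self):
        axis = np.zeros(300, dtype=np.int64)
        labels = ["sit", "sit", "stand", "step", "sit"]
        ct = classify_actigraph_plus(_counts(axis), posture_labels=labels)
        assert ct.minutes(Label.SEDENTARY) == pytest.approx(3.0)
        assert ct.minutes(Label.STANDING_OTHER) == pytest.approx(1.0)
        assert ct.minutes(Label.LOCOMOTION) == pytest.approx(1.0)

    def test_75_boundary_on_sitting_minutes(self):
        for total, label in [(74, Label.SEDENTARY), (76, Label.ACTIVE_SITTING)]:
            axis = np.zeros(60, dtype=np.int64)
            axis[0] = total
            ct = classify_actigraph_plus(_counts(axis), posture_labels=["sit"])
            assert ct.intervals[0][2] is label

    def test_stand_everywhere_zero_sedentary(self):
        axis = np.zeros(600, dtype=np.int64)
        ct = classify_actigraph_plus(_counts(axis), posture_labels=["stand"] * 10)
        assert ct.duration(Label.SEDENTARY) == 0.0

    def test_minute_posture_labels_majority(self):
        tl = make_timeline([(100.0, Posture.SIT), (140.0, Posture.STAND)])
        assert minute_posture_labels(tl, [0.0, 60.0, 120.0]) == ["sit", "sit", "stand"]


class TestBouts:
    def _timeline_with_runs(self, runs):
        """Sedentary runs (minutes) separated by 1-min standing."""
        spans = []
        t = 0.0
        for r in runs:
            spans.append((t, t + r * 60.0, Label.SEDENTARY))
            t += r * 60.0
            spans.append((t, t + 60.0, Label.STANDING_OTHER))
            t += 60.0
        return ClassifiedTimeline(tuple(spans), "test", EPOCH)

    def test_threshold_totals(self):
        ct = self._timeline_with_runs([12, 5, 35])
        _, total10 = detect_bouts(ct, 10)
        _, total30 = detect_bouts(ct, 30)
        assert total10 == pytest.approx(47.0)
        assert total30 == pytest.approx(35.0)

    def test_unbroken_day_single_bout(self):
        ct = ClassifiedTimeline(((0.0, 600 * 60.0, Label.SEDENTARY),), "t", EPOCH)
        bouts, total = detect_bouts(ct, 10)
        assert len(bouts) == 1 and total == pytest.approx(600.0)
        assert detect_bouts(ct, 30)[1] == pytest.approx(600.0)

    def test_adjacent_sedentary_intervals_merge(self):
        ct = ClassifiedTimeline(
            ((0.0, 300.0, Label.SEDENTARY), (300.0, 900.0, Label.SEDENTARY)), "t", EPOCH
        )
        bouts, total = detect_bouts(ct, 10)
        assert bouts == [(0.0, 900.0)] and total == pytest.approx(15.0)

    def test_matches_run_length_scan(self):
        """Random label sequences: totals equal an independent run-length
        scan over the minute labels."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            labs = rng.choice([Label.SEDENTARY, Label.STANDING_OTHER], 240, p=[0.7, 0.3])
            spans = tuple(
                (60.0 * i, 60.0 * (i + 1), lab) for i, lab in enumerate(labs)
            )
            ct = ClassifiedTimeline(spans, "t", EPOCH)
            for thr in (10, 30):
                runs, cur = [], 0
                for lab in labs:
                    if lab is Label.SEDENTARY:
                        cur += 1
                    else:
                        runs.append(cur)
                        cur = 0
                runs.append(cur)
                want = sum(r for r in runs if r >= thr)
                assert detect_bouts(ct, thr)[1] == pytest.approx(want)

    def test_monotone_in_threshold(self, sim_day):
        ct = classify_popai(sim_day.timeline, sim_day.counts)
        totals = [detect_bouts(ct, thr)[1] for thr in (0, 10, 30, 60)]
        assert totals == sorted(totals, reverse=True)


class TestSummaries:
    def _mask(self, spans):
        return WearMask(thigh=tuple(spans), waist=tuple(spans))

    def test_day_below_ten_hours_excluded_from_mean(self):
        day = 86400.0
        ct = ClassifiedTimeline(
            ((0.0, 9.9 * H, Label.SEDENTARY), (day, day + 11 * H, Label.SEDENTARY)),
            "t",
            EPOCH,
        )
        mask = self._mask([(0.0, 9.9 * H), (day, day + 11 * H)])
        days = summarize_days(ct, mask, "P1")
        mean = participant_mean(days, min_wear_hours=10.0)
        assert mean["n_days"] == 1.0
        assert mean["sedentary_minutes"] == pytest.approx(11 * 60.0)

    def test_participant_mean_of_two_days(self):
        day = 86400.0
        ct = ClassifiedTimeline(
            (
                (0.0, 400 * 60.0, Label.SEDENTARY),
                (400 * 60.0, 14 * H, Label.STANDING_OTHER),
                (day, day + 420 * 60.0, Label.SEDENTARY),
                (day + 420 * 60.0, day + 14 * H, Label.STANDING_OTHER),
            ),
            "t",
            EPOCH,
        )
        mask = self._mask([(0.0, 14 * H), (day, day + 14 * H)])
        mean = participant_mean(summarize_days(ct, mask, "P1"))
        assert mean["sedentary_minutes"] == pytest.approx(410.0)

    def test_percentage_identity(self, sim_day):
        ct = classify_popai(sim_day.timeline, sim_day.counts)
        bed = exclude_bedtime(sim_day.timeline)
        mask = build_wear_mask(sim_day.timeline, bed.intervals, [])
        days = summarize_days(ct, mask, "P1")
        for d in days:
            if d.wear_minutes:
                assert d.sedentary_pct_of_wear == pytest.approx(
                    100.0 * d.sedentary_minutes / d.wear_minutes
                )

    def test_no_qualifying_day_warns_and_none(self):
        ct = ClassifiedTimeline(((0.0, 2 * H, Label.SEDENTARY),), "t", EPOCH)
        days = summarize_days(ct, self._mask([(0.0, 2 * H)]), "P1")
        with pytest.warns(UserWarning):
            assert participant_mean(days) is None


class TestInvariants:
    def test_conservation_popai(self, sim_two_days):
        """SEDENTARY + ACTIVE_SITTING equals SIT duration exactly."""
        ct = classify_popai(sim_two_days.timeline, sim_two_days.counts)
        sit = sum(
            e.duration for e in sim_two_days.timeline.events if e.posture is Posture.SIT
        )
        got = ct.duration(Label.SEDENTARY) + ct.duration(Label.ACTIVE_SITTING)
        assert got == pytest.approx(sit, abs=1e-6)

    def test_popai_never_exceeds_activpal(self, profile):
        from popai.synthetic import simulate_participant

        for seed in (1, 2, 3):
            sim = simulate_participant(profile, 1, seed=seed, with_raw=False)
            po = classify_popai(sim.timeline, sim.counts).duration(Label.SEDENTARY)
            ap = classify_activpal(sim.timeline).duration(Label.SEDENTARY)
            assert po <= ap + 1e-9
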