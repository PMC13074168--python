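from __future__ import annotations

import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deprx import (
    Category,
    DailyDose,
    Encounter,
    MedicationRecord,
    PatientHistory,
    build_trajectory,
    detect_inferred_discontinuation,
    filter_eligible,
)

END = date(2023, 3, 13)
START = date(2014, 5, 15)


def rec(day, name, daily, unit="mg", freq=1, category=Category.METFORMIN, pid="p"):
    return MedicationRecord(
        patient_id=pid,
        date=day,
        raw_name=name,
        canonical_name=name,
        category=category,
        dose=DailyDose(name, daily / freq, unit, freq),
    )


def hist(records=(), encounters=(), age=50, pid="p"):
    return PatientHistory(
        patient_id=pid,
        age=age,
        records=list(records),
        encounters=[Encounter(pid, d) for d in encounters],
    )


class TestEligibility:
    def test_age_and_visit_criteria(self):
        visits = [START + timedelta(days=30 * i) for i in range(5)]
        histories = [
            hist(age=90, encounters=visits, pid="too_old"),
            hist(age=50, encounters=visits[:1], pid="one_visit"),
            hist(age=50, encounters=visits[:3], pid="ok"),
            hist(age=None, encounters=visits, pid="no_age"),
        ]
        eligible, report = filter_eligible(histories, (START, END))
        assert [h.patient_id for h in eligible] == ["ok"]
        assert report.reasons == {
            "too_old": "age",
            "one_visit": "visits",
            "no_age": "missing_age",
        }

    def test_visits_outside_window_do_not_count(self):
        visits = [START - timedelta(days=10), START + timedelta(days=5)]
        eligible, report = filter_eligible(
            [hist(age=40, encounters=visits)], (START, END)
        )
        assert not eligible and report.counts["visits"] == 1

    def test_age_criterion_skipped_without_demographics(self):
        visits = [START + timedelta(days=30 * i) for i in range(3)]
        h = hist(age=None, encounters=visits)
        eligible, _ = filter_eligible([h], (START, END), require_age=False)
        assert eligible == [h]


class TestBuildTrajectory:
    def test_single_record_appears_in_both_windows(self):
        h = hist([rec(END - timedelta(days=100), "metformin", 1000)])
        traj = build_trajectory(h, END)
        assert traj.baseline.names() == traj.final.names() == {"metformin"}

    def test_interim_changes_invisible_when_endpoints_agree(self):
        d0 = END - timedelta(days=800)
        h = hist(
            [
                rec(d0, "metformin", 1000),
                rec(d0 + timedelta(days=400), "metformin", 2000),
                rec(d0 + timedelta(days=760), "metformin", 1000),
            ]
        )
        traj = build_trajectory(h, END)
        assert traj.baseline.members["metformin"].dose.daily_total == 1000
        assert traj.final.members["metformin"].dose.daily_total == 1000

    def test_invariant_to_input_row_order(self):
        d0 = END - timedelta(days=1200)
        records = [
            rec(d0 + timedelta(days=30 * i), name, daily)
            for i, (name, daily) in enumerate(
                [("metformin", 1000), ("sitagliptin", 100)] * 6
            )
        ]
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        assert build_trajectory(hist(records), END) == build_trajectory(
            hist(shuffled), END
        )

    def test_time_shift_leaves_summary_unchanged_apart_from_dates(self):
        d0 = END - timedelta(days=900)
        records = [
            rec(d0, "metformin", 2000),
            rec(d0 + timedelta(days=500), "metformin", 1000),
            rec(END - timedelta(days=50), "metformin", 1000),
        ]
        base = build_trajectory(hist(records), END)
        shift = timedelta(days=37)
        shifted = [
            MedicationRecord(
                r.patient_id, r.date + shift, r.raw_name, r.canonical_name,
                r.category, r.dose,
            )
            for r in records
        ]
        moved = build_trajectory(hist(shifted), END + shift)
        assert {n: m.dose for n, m in base.baseline.members.items()} == {
            n: m.dose for n, m in moved.baseline.members.items()
        }
        assert {n: m.dose for n, m in base.final.members.items()} == {
            n: m.dose for n, m in moved.final.members.items()
        }
        assert base.n_interim_transitions == moved.n_interim_transitions
        assert base.inferred_discontinuation == moved.inferred_discontinuation

    def test_same_date_duplicate_keeps_higher_dose(self):
        d0 = END - timedelta(days=100)
        h = hist([rec(d0, "metformin", 1000), rec(d0, "metformin", 2000)])
        traj = build_trajectory(h, END)
        assert traj.final.members["metformin"].dose.daily_total == 2000

    def test_no_records_yields_empty_snapshots(self):
        traj = build_trajectory(hist(encounters=[START, END]), END)
        assert traj.baseline.is_empty and traj.final.is_empty

    def test_metformin_restart_detected_after_annual_gap(self):
        d0 = END - timedelta(days=1500)
        gap = [
            rec(d0, "metformin", 1000),
            rec(d0 + timedelta(days=500), "metformin", 1000),
        ]
        assert build_trajectory(hist(gap), END).metformin_restarted
        steady = [
            rec(d0, "metformin", 1000),
            rec(d0 + timedelta(days=300), "metformin", 1000),
        ]
        assert not build_trajectory(hist(steady), END).metformin_restarted


class TestInferredDiscontinuation:
    def test_old_last_rx_with_later_encounter_flags(self):
        h = hist(
            [rec(date(2021, 6, 1), "metformin", 1000)],
            encounters=[date(2022, 9, 1)],
        )
        assert detect_inferred_discontinuation(h, date(2023, 3, 13))

    def test_recent_last_rx_does_not_flag(self):
        h = hist(
            [rec(date(2022, 12, 1), "metformin", 1000)],
            encounters=[date(2023, 1, 5)],
        )
        assert not detect_inferred_discontinuation(h, date(2023, 3, 13))

    def test_no_encounter_after_last_rx_does_not_flag(self):
        h = hist(
            [rec(date(2021, 6, 1), "metformin", 1000)],
            encounters=[date(2021, 1, 1)],
        )
        assert not detect_inferred_discontinuation(h, date(2023, 3, 13))

    @given(
        rx_offset=st.integers(1, 2000),
        enc_offsets=st.lists(st.integers(0, 2000), max_size=4),
    )
    @settings(max_examples=300, deadline=None)
    def test_flag_matches_definition_exactly(self, rx_offset, enc_offsets):
        last_rx = END - timedelta(days=rx_offset)
        encounters = [END - timedelta(days=o) for o in enc_offsets]
        h = hist([rec(last_rx, "metformin", 1000)], encounters=encounters)
        expected = rx_offset > 365 and any(e > last_rx for e in encounters)
        assert detect_inferred_discontinuation(h, END) == expected

    @given(
        rx_offset=st.integers(366, 2000),
        later_offset=st.integers(0, 2000),
        enc_offsets=st.lists(st.integers(0, 2000), min_size=1, max_size=4),
    )
    @settings(max_examples=300, deadline=None)
    def test_adding_later_rx_never_raises_the_flag(
        self, rx_offset, later_offset, enc_offsets
    ):
        encounters = [END - timedelta(days=o) for o in enc_offsets]
        base = [rec(END - timedelta(days=rx_offset), "metformin", 1000)]
        extra = base + [
            rec(END - timedelta(days=min(rx_offset, later_offset)),
                "metformin", 1000)
        ]
        before = detect_inferred_discontinuation(
            hist(base, encounters=encounters), END
        )
        after = detect_inferred_discontinuation(
            hist(extra, encounters=encounters), END
        )
        assert after <= before  # can only clear the flag, never raise it
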