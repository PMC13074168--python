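"""Per-patient medication trajectories: eligibility, snapshots, discontinuation.

A patient's dated prescription records are condensed to two regimen
snapshots — what they were on during the first 12 months after their first
diabetes-medication record (baseline) and during the last 12 months of the
data period (final) — plus summary features of the in-between history. The
classification rules compare these endpoint windows: interim churn that
returns to the same regimen is deliberately ignored ("no change" even if
there were changes in between).

The practices behind the source data require at least an annual visit for
refills, which licenses the inferred-discontinuation rule: a patient whose
last prescription is more than a year old, but who still attends, has had
their medication discontinued rather than transferred elsewhere.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .dosing import DailyDose
from .lexicon import Category

#: Default window length for the baseline/final snapshots (12 months).
DEFAULT_WINDOW_DAYS = 365


@dataclass(frozen=True)
class MedicationRecord:
    """One dated prescription row after name normalization."""

    patient_id: str
    date: date
    raw_name: str
    canonical_name: str
    category: Category
    dose: DailyDose
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class Encounter:
    """One documented clinic visit."""

    patient_id: str
    date: date


@dataclass
class PatientHistory:
    """All records and encounters for one patient, date-sorted."""

    patient_id: str
    age: Optional[float] = None
    records: List[MedicationRecord] = field(default_factory=list)
    encounters: List[Encounter] = field(default_factory=list)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.date, r.canonical_name))
        self.encounters = sorted(self.encounters, key=lambda e: e.date)


@dataclass(frozen=True)
class RegimenMember:
    canonical_name: str
    category: Category
    dose: DailyDose


@dataclass(frozen=True)
class RegimenSnapshot:
    """The regimen attributed to a reference window.

    One member per canonical medication; the most recent prescription of that
    medication inside the window defines its dose (same-date duplicates keep
    the higher dose, a conservative tie-break against over-calling dose
    reductions).
    """

    window_start: Optional[date]
    window_end: Optional[date]
    members: Dict[str, RegimenMember] = field(default_factory=dict)

    def names(self, category: Optional[Category] = None) -> set:
        if category is None:
            return set(self.members)
        return {n for n, m in self.members.items() if m.category == category}

    def categories(self) -> set:
        return {m.category for m in self.members.values()}

    @property
    def is_empty(self) -> bool:
        return not self.members


@dataclass(frozen=True)
class TrajectorySummary:
    """Endpoint comparison plus history features for one patient."""

    patient_id: str
    baseline: RegimenSnapshot
    final: RegimenSnapshot
    n_interim_transitions: int = 0
    inferred_discontinuation: bool = False
    metformin_restarted: bool = False
    dose_comparable: Dict[Category, bool] = field(
        default_factory=lambda: {c: True for c in Category}
    )

    @classmethod
    def from_members(
        cls,
        patient_id: str,
        baseline: Iterable[RegimenMember],
        final: Iterable[RegimenMember],
        **kwargs,
    ) -> "TrajectorySummary":
        """Build a summary directly from two member sets (testing, docs)."""
        b = {m.canonical_name: m for m in baseline}
        f = {m.canonical_name: m for m in final}
        bs = RegimenSnapshot(None, None, b)
        fs = RegimenSnapshot(None, None, f)
        if "dose_comparable" not in kwargs:
            kwargs["dose_comparable"] = _comparability(bs, fs)
        return cls(patient_id, bs, fs, **kwargs)


class ExclusionReport:
    """Per-reason counts and per-patient reasons from eligibility filtering."""

    def __init__(self):
        self.counts: Counter = Counter()
        self.reasons: Dict[str, str] = {}

    def exclude(self, patient_id: str, reason: str):
        self.counts[reason] += 1
        self.reasons[patient_id] = reason

    def __len__(self):
        return len(self.reasons)


def filter_eligible(
    histories: Iterable[PatientHistory],
    window: Tuple[date, date],
    min_age: float = 18,
    max_age: float = 89,
    min_visits: int = 2,
    require_age: bool = True,
) -> Tuple[List[PatientHistory], ExclusionReport]:
    """Retain patients aged 18-89 with >=2 encounters inside the window.

    With ``require_age=False`` (no demographics table supplied) the age
    criterion is skipped entirely rather than excluding everyone.
    """
    start, end = window
    report = ExclusionReport()
    eligible = []
    for h in histories:
        if require_age and h.age is None:
            report.exclude(h.patient_id, "missing_age")
            continue
        if h.age is not None and not (min_age <= h.age <= max_age):
            report.exclude(h.patient_id, "age")
            continue
        n_visits = sum(1 for e in h.encounters if start <= e.date <= end)
        if n_visits < min_visits:
            report.exclude(h.patient_id, "visits")
            continue
        eligible.append(h)
    return eligible, report


def detect_inferred_discontinuation(
    history: PatientHistory,
    extraction_end: date,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> bool:
    """Annual-refill rule: medications count as discontinued iff the last
    prescription predates the extraction end by more than a year AND a later
    encounter shows the patient was still active."""
    if not history.records:
        return False
    last_rx = max(r.date for r in history.records)
    if last_rx >= extraction_end - timedelta(days=window_days):
        return False
    return any(e.date > last_rx for e in history.encounters)


def _snapshot(
    records: Sequence[MedicationRecord],
    start: date,
    end: date,
    closed_end: bool,
) -> RegimenSnapshot:
    members: Dict[str, RegimenMember] = {}
    best: Dict[str, Tuple[date, float]] = {}
    for r in records:
        inside = (r.date >= start) and (r.date <= end if closed_end else r.date < end)
        if not inside:
            continue
        key = (r.date, r.dose.daily_total)
        if r.canonical_name not in best or key > best[r.canonical_name]:
            best[r.canonical_name] = key
            members[r.canonical_name] = RegimenMember(
                r.canonical_name, r.category, r.dose
            )
    return RegimenSnapshot(start, end, members)


def _comparability(
    baseline: RegimenSnapshot, final: RegimenSnapshot
) -> Dict[Category, bool]:
    # Per category, dose-change rules need a single unit system across both
    # windows; mixing insulin units with mass units suppresses them.
    flags = {}
    for cat in Category:
        units = {
            m.dose.unit
            for snap in (baseline, final)
            for m in snap.members.values()
            if m.category == cat
        }
        flags[cat] = not ("units" in units and units != {"units"})
    return flags


def build_trajectory(
    history: PatientHistory,
    extraction_end: date,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> TrajectorySummary:
    """Summarize a history into baseline/final snapshots and features.

    Baseline covers ``[first_record, first_record + window_days)``; the final
    window is anchored at the extraction end, ``[end - window_days, end]``
    (closed, so a prescription on the extraction date counts). Deterministic
    and invariant to input row order.
    """
    recs = history.records
    window = timedelta(days=window_days)
    if not recs:
        empty = RegimenSnapshot(extraction_end - window, extraction_end, {})
        return TrajectorySummary(history.patient_id, empty, empty)

    first = recs[0].date
    baseline = _snapshot(recs, first, first + window, closed_end=False)
    final = _snapshot(recs, extraction_end - window, extraction_end, closed_end=True)

    base_end = first + window
    final_start = extraction_end - window
    n_transitions = 0
    if base_end < final_start:
        span: Dict[str, Tuple[date, date]] = {}
        for r in recs:
            lo, hi = span.get(r.canonical_name, (r.date, r.date))
            span[r.canonical_name] = (min(lo, r.date), max(hi, r.date))
        for lo, hi in span.values():
            if lo >= base_end:  # started after the baseline window
                n_transitions += 1
            if hi < final_start:  # stopped before the final window
                n_transitions += 1

    met_dates = sorted(
        r.date for r in recs if r.category == Category.METFORMIN
    )
    restarted = any(
        (b - a).days > window_days for a, b in zip(met_dates, met_dates[1:])
    )

    return TrajectorySummary(
        patient_id=history.patient_id,
        baseline=baseline,
        final=final,
        n_interim_transitions=n_transitions,
        inferred_discontinuation=detect_inferred_discontinuation(
            history, extraction_end, window_days
        ),
        metformin_restarted=restarted,
        dose_comparable=_comparability(baseline, final),
    )
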