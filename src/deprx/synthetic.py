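"""Synthetic EHR-export cohorts with planted ground-truth labels.

The study data behind the framework cannot be shared, so this module emits
cohorts in the exact records/encounters table dialects the pipeline consumes,
with one scenario per patient and the scenario's known classification planted
as ground truth. Scenarios cover every deprescribing subtype, the
not-deprescribing controls (lateral switch chain, dose and category
escalation, stable regimen), the annual-refill inference and its
loss-to-follow-up counterexample, a mixed-signal case whose truth is
UNCLEAR, and a planted-ineligible patient.

Dose menus are small fixed grids per category (insulin 10/20/40 units/day,
metformin 500-2000 mg/day, single-agent menus for the non-insulin tier) and
regimen change points are drawn uniformly with wide spacing, so every planted
event lands cleanly in the baseline window, the interim, or the final window.
Generation is reproducible: the same seed yields byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import classifier as C
from .config import ConfigError, DEFAULT_EXTRACTION_END, DEFAULT_WINDOW_START
from .io import parse_encounter_rows, parse_record_rows
from .lexicon import Lexicon, load_lexicon
from .trajectory import PatientHistory

DEFAULT_WINDOW = (DEFAULT_WINDOW_START, DEFAULT_EXTRACTION_END)

#: Truth top-level for the planted-ineligible scenario.
EXCLUDED = "EXCLUDED"

#: Scenarios whose truth is a review flag rather than a clean label.
AMBIGUOUS_SCENARIOS = frozenset({"mixed_signal", "lost_to_follow_up"})

_NOISE_MEDS = (
    "Lisinopril 10 MG tablet",
    "Atorvastatin 20 mg tab",
    "vitamin d",
    "Omeprazole 20 MG capsule",
)

_BRANDS = {
    "insulin glargine": "Lantus",
    "metformin": "Glucophage",
    "sitagliptin": "Januvia",
    "glipizide": "Glucotrol",
    "empagliflozin": "Jardiance",
}


@dataclass
class SyntheticCase:
    """One generated patient history with its planted truth."""

    patient_id: str
    scenario_name: str
    truth_label: Tuple[str, str]
    age: Optional[float]
    record_rows: List[dict]
    encounter_rows: List[dict]
    history: PatientHistory


# -- low-level helpers -------------------------------------------------------


def _rand_date(rng, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _display(rng, canonical: str, amount: float, unit: str) -> str:
    """Vary how the name is written, as a real export would."""
    r = rng.random()
    if r < 0.5:
        return canonical
    if r < 0.75:
        return f"{canonical.upper()} {amount:g} {unit.upper()} TAB"
    return _BRANDS.get(canonical, canonical).title()


def _refills(
    rows: list,
    rng,
    pid: str,
    canonical: str,
    amount: float,
    unit: str,
    freq: float,
    start: date,
    stop: date,
):
    """Periodic prescription rows from start through stop (inclusive)."""
    if stop < start:
        stop = start
    d = start
    while d <= stop:
        rows.append(
            {
                "patient_id": pid,
                "date": d.isoformat(),
                "medication_name": _display(rng, canonical, amount, unit),
                "strength_amount": f"{amount:g}",
                "strength_unit": unit,
                "frequency_per_day": f"{freq:g}",
            }
        )
        nxt = d + timedelta(days=int(rng.integers(140, 200)))
        if d < stop < nxt:
            nxt = stop  # guarantee a row at the stop date
        d = nxt


def _encounters(rng, pid: str, start: date, stop: date) -> List[dict]:
    if stop < start:
        stop = start
    out = []
    d = start
    while d <= stop:
        out.append({"patient_id": pid, "date": d.isoformat()})
        d += timedelta(days=int(rng.integers(90, 160)))
    while len(out) < 2:
        out.append({"patient_id": pid, "date": stop.isoformat()})
    return out


def _near_end(rng, we: date) -> date:
    return we - timedelta(days=int(rng.integers(20, 200)))


def _t0(rng, ws: date, we: date) -> date:
    return _rand_date(rng, ws, we - timedelta(days=1600))


def _chg(rng, t0: date, we: date, tail: int = 380) -> date:
    return _rand_date(rng, t0 + timedelta(days=380), we - timedelta(days=tail))


@dataclass
class _Built:
    record_rows: List[dict]
    encounter_rows: List[dict]
    age: Optional[float]
    truth: Tuple[str, str]


def _std(rng, rows, pid, window, truth, age=None) -> _Built:
    ws, we = window
    t0 = min(date.fromisoformat(r["date"]) for r in rows)
    encs = _encounters(rng, pid, t0, we - timedelta(days=int(rng.integers(10, 60))))
    if age is None:
        age = float(rng.integers(30, 86))
    return _Built(rows, encs, age, truth)


# -- scenario builders -------------------------------------------------------


def _b_insulin_dose_reduced(rng, pid, window):
    ws, we = window
    t0, chg = _t0(rng, ws, we), None
    chg = _chg(rng, t0, we)
    hi, lo = [(40, 20), (20, 10), (40, 10)][int(rng.integers(0, 3))]
    rows: list = []
    _refills(rows, rng, pid, "insulin glargine", hi, "units", 1,
             t0, chg - timedelta(days=30))
    _refills(rows, rng, pid, "insulin glargine", lo, "units", 1,
             chg, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.INSULIN_DOSE_REDUCED))


def _b_insulin_to_noninsulin(rng, pid, window):
    ws, we = window
    t0, chg = _t0(rng, ws, we), None
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "insulin glargine", 30, "units", 1,
             t0, chg - timedelta(days=30))
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, chg, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.INSULIN_TO_NONINSULIN))


def _b_insulin_discontinued(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, _near_end(rng, we))
    _refills(rows, rng, pid, "insulin glargine", 20, "units", 1, t0, chg)
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.INSULIN_DISCONTINUED))


def _b_noninsulin_stopped(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "glipizide", 10, "mg", 1, t0, _near_end(rng, we))
    _refills(rows, rng, pid, "sitagliptin", 100, "mg", 1, t0, chg)
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.NONINSULIN_STOPPED))


def _b_noninsulin_dose_reduced(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "sitagliptin", 100, "mg", 1,
             t0, chg - timedelta(days=30))
    _refills(rows, rng, pid, "sitagliptin", 50, "mg", 1, chg, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.NONINSULIN_DOSE_REDUCED))


def _b_noninsulin_to_metformin(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, _near_end(rng, we))
    _refills(rows, rng, pid, "sitagliptin", 100, "mg", 1, t0, chg)
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.NONINSULIN_TO_METFORMIN))


def _b_metformin_stopped(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "glipizide", 10, "mg", 1, t0, _near_end(rng, we))
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, chg)
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.METFORMIN_STOPPED))


def _b_metformin_dose_reduced(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 2,
             t0, chg - timedelta(days=30))
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, chg, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, C.METFORMIN_DOSE_REDUCED))


def _b_lateral_switch(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    c1 = _rand_date(rng, t0 + timedelta(days=380), we - timedelta(days=600))
    c2 = _rand_date(rng, c1 + timedelta(days=120), we - timedelta(days=380))
    rows: list = []
    _refills(rows, rng, pid, "glipizide", 10, "mg", 1,
             t0, c1 - timedelta(days=30))
    _refills(rows, rng, pid, "sitagliptin", 100, "mg", 1,
             c1, c2 - timedelta(days=30))
    _refills(rows, rng, pid, "empagliflozin", 10, "mg", 1,
             c2, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.NOT_DEPRESCRIBED.value, C.LATERAL_CHANGE))


def _b_dose_escalation(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1,
             t0, chg - timedelta(days=30))
    _refills(rows, rng, pid, "metformin", 1000, "mg", 2, chg, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.NOT_DEPRESCRIBED.value, C.MEDICATION_INCREASE))


def _b_category_escalation(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    chg = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, _near_end(rng, we))
    _refills(rows, rng, pid, "insulin glargine", 20, "units", 1,
             chg, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.NOT_DEPRESCRIBED.value, C.MEDICATION_INCREASE))


def _b_stable_regimen(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, _near_end(rng, we))
    if rng.random() < 0.5:
        # interim wobble; first/last windows still agree, so: no change
        c1 = _rand_date(rng, t0 + timedelta(days=380), we - timedelta(days=620))
        _refills(rows, rng, pid, "metformin", 1000, "mg", 2,
                 c1, c1 + timedelta(days=180))
    return _std(rng, rows, pid, window,
                (C.TopLevel.NOT_DEPRESCRIBED.value, C.NO_CHANGE))


def _b_inferred_discontinuation(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    stop = _rand_date(rng, t0 + timedelta(days=200), we - timedelta(days=450))
    med, amount, unit, subtype = [
        ("metformin", 1000, "mg", C.METFORMIN_STOPPED),
        ("insulin glargine", 20, "units", C.INSULIN_DISCONTINUED),
        ("sitagliptin", 100, "mg", C.NONINSULIN_STOPPED),
    ][int(rng.integers(0, 3))]
    rows: list = []
    _refills(rows, rng, pid, med, amount, unit, 1, t0, stop)
    return _std(rng, rows, pid, window,
                (C.TopLevel.DEPRESCRIBED.value, subtype))


def _b_lost_to_follow_up(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    stop = _rand_date(rng, t0 + timedelta(days=300), we - timedelta(days=450))
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, stop)
    # encounters never postdate the last prescription, so the annual-refill
    # inference must not fire
    encs = _encounters(rng, pid, t0, stop)
    return _Built(rows, encs, float(rng.integers(30, 86)),
                  (C.TopLevel.UNCLEAR.value, C.NEEDS_REVIEW))


def _b_mixed_signal(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    c1 = _chg(rng, t0, we)
    c2 = _chg(rng, t0, we)
    rows: list = []
    _refills(rows, rng, pid, "insulin glargine", 40, "units", 1,
             t0, c1 - timedelta(days=30))
    _refills(rows, rng, pid, "insulin glargine", 20, "units", 1,
             c1, _near_end(rng, we))
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1,
             t0, c2 - timedelta(days=30))
    _refills(rows, rng, pid, "metformin", 1000, "mg", 2,
             c2, _near_end(rng, we))
    return _std(rng, rows, pid, window,
                (C.TopLevel.UNCLEAR.value, C.NEEDS_REVIEW))


def _b_ineligible(rng, pid, window):
    ws, we = window
    t0 = _t0(rng, ws, we)
    rows: list = []
    _refills(rows, rng, pid, "metformin", 1000, "mg", 1, t0, _near_end(rng, we))
    variant = ["age_high", "age_low", "visits", "missing_age"][
        int(rng.integers(0, 4))
    ]
    if variant == "visits":
        encs = [{"patient_id": pid, "date": t0.isoformat()}]
        return _Built(rows, encs, float(rng.integers(30, 86)),
                      (EXCLUDED, "visits"))
    encs = _encounters(rng, pid, t0, we - timedelta(days=30))
    if variant == "age_high":
        return _Built(rows, encs, 93.0, (EXCLUDED, "age"))
    if variant == "age_low":
        return _Built(rows, encs, 16.0, (EXCLUDED, "age"))
    return _Built(rows, encs, None, (EXCLUDED, "missing_age"))


SCENARIOS = {
    "insulin_dose_reduced": _b_insulin_dose_reduced,
    "insulin_to_noninsulin": _b_insulin_to_noninsulin,
    "insulin_discontinued": _b_insulin_discontinued,
    "noninsulin_stopped": _b_noninsulin_stopped,
    "noninsulin_dose_reduced": _b_noninsulin_dose_reduced,
    "noninsulin_to_metformin": _b_noninsulin_to_metformin,
    "metformin_stopped": _b_metformin_stopped,
    "metformin_dose_reduced": _b_metformin_dose_reduced,
    "lateral_switch": _b_lateral_switch,
    "dose_escalation": _b_dose_escalation,
    "category_escalation": _b_category_escalation,
    "stable_regimen": _b_stable_regimen,
    "inferred_discontinuation": _b_inferred_discontinuation,
    "lost_to_follow_up": _b_lost_to_follow_up,
    "mixed_signal": _b_mixed_signal,
    "ineligible": _b_ineligible,
}


def _validate_mix(mix: Optional[Dict[str, float]]) -> Tuple[list, list]:
    names = list(SCENARIOS)
    if mix is None:
        probs = [1.0 / len(names)] * len(names)
        return names, probs
    unknown = set(mix) - set(names)
    if unknown:
        raise ConfigError(
            f"unknown scenario name(s): {', '.join(sorted(unknown))}"
        )
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"scenario proportions must sum to 1, got {total!r}")
    if any(p < 0 for p in mix.values()):
        raise ConfigError("scenario proportions must be non-negative")
    names = [n for n in names if mix.get(n, 0.0) > 0]
    probs = [mix[n] for n in names]
    return names, probs


def generate_cohort(
    n: int,
    mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
    window: Tuple[date, date] = DEFAULT_WINDOW,
    out_dir: Union[str, Path, None] = None,
    lexicon: Optional[Lexicon] = None,
    noise_rate: float = 0.4,
) -> List[SyntheticCase]:
    """Generate ``n`` synthetic patients across the scenario mix.

    ``mix`` maps scenario name to proportion (default: uniform over all
    scenarios); patients are assigned scenarios multinomially. Histories are
    built by running the generated rows through the same lexicon/parsing
    pipeline the classifier uses. With ``out_dir`` the cohort is also written
    as records.csv / encounters.csv / patients.csv / truth.csv.
    """
    if n <= 0:
        raise ConfigError(f"patient count must be positive, got {n}")
    names, probs = _validate_mix(mix)
    rng = np.random.default_rng(int(seed) % 2**31)
    lexicon = lexicon or load_lexicon()
    width = max(4, len(str(n)))
    cases: List[SyntheticCase] = []
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        scenario = names[int(rng.choice(len(names), p=probs))]
        built = SCENARIOS[scenario](rng, pid, window)
        if rng.random() < noise_rate:
            noise_date = _rand_date(rng, window[0], window[1])
            built.record_rows.append(
                {
                    "patient_id": pid,
                    "date": noise_date.isoformat(),
                    "medication_name": _NOISE_MEDS[int(rng.integers(0, 4))],
                    "strength_amount": "10",
                    "strength_unit": "mg",
                    "frequency_per_day": "1",
                }
            )
        records, _ = parse_record_rows(
            built.record_rows, lexicon, window, source=f"synthetic:{pid}"
        )
        encounters, _ = parse_encounter_rows(
            built.encounter_rows, window, source=f"synthetic:{pid}"
        )
        history = PatientHistory(
            patient_id=pid,
            age=built.age,
            records=records,
            encounters=encounters,
        )
        cases.append(
            SyntheticCase(
                patient_id=pid,
                scenario_name=scenario,
                truth_label=built.truth,
                age=built.age,
                record_rows=built.record_rows,
                encounter_rows=built.encounter_rows,
                history=history,
            )
        )
    if out_dir is not None:
        write_cohort(cases, out_dir)
    return cases


def write_cohort(
    cases: List[SyntheticCase], out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Write the cohort tables; same cases always give byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "encounters": out / "encounters.csv",
        "patients": out / "patients.csv",
        "truth": out / "truth.csv",
    }
    rec_rows = [dict(r) for c in cases for r in c.record_rows]
    rec_rows.sort(key=lambda r: (r["patient_id"], r["date"], r["medication_name"]))
    pd.DataFrame(
        rec_rows,
        columns=[
            "patient_id",
            "date",
            "medication_name",
            "strength_amount",
            "strength_unit",
            "frequency_per_day",
        ],
    ).to_csv(paths["records"], index=False)
    enc_rows = [dict(r) for c in cases for r in c.encounter_rows]
    enc_rows.sort(key=lambda r: (r["patient_id"], r["date"]))
    pd.DataFrame(enc_rows, columns=["patient_id", "date"]).to_csv(
        paths["encounters"], index=False
    )
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "age": "" if c.age is None else f"{c.age:g}",
            }
            for c in cases
        ],
        columns=["patient_id", "age"],
    ).to_csv(paths["patients"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "top_level": c.truth_label[0],
                "subtype": c.truth_label[1],
                "scenario": c.scenario_name,
            }
            for c in cases
        ],
        columns=["patient_id", "top_level", "subtype", "scenario"],
    ).to_csv(paths["truth"], index=False)
    return paths
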