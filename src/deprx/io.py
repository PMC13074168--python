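"""Reading the EHR-export table dialects and writing classification output.

Input tables are delimited with a header row, ISO-8601 dates:

  records:    patient_id,date,medication_name,strength_amount,strength_unit,frequency_per_day
  encounters: patient_id,date
  patients:   patient_id,age            (optional demographics table)

Schema problems raise :class:`SchemaError` with file, line and column so a
malformed export fails loudly instead of silently skewing counts.
Unrecognized medication names (non-diabetes drugs, typos outside the
lexicon) are counted and excluded from classification input, never an error.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .dosing import DailyDose
from .lexicon import (
    COMBINATION_UNSPLIT,
    Lexicon,
    UNRECOGNIZED,
    expand_combination,
    normalize_name,
)
from .trajectory import Encounter, MedicationRecord, PatientHistory

RECORD_COLUMNS = (
    "patient_id",
    "date",
    "medication_name",
    "strength_amount",
    "strength_unit",
    "frequency_per_day",
)
ENCOUNTER_COLUMNS = ("patient_id", "date")
PATIENT_COLUMNS = ("patient_id", "age")


class SchemaError(ValueError):
    """A table does not match its declared dialect."""


@dataclass
class LoadStats:
    """Bookkeeping from parsing a records table."""

    n_rows: int = 0
    n_out_of_window: int = 0
    n_combination_unsplit: int = 0
    unrecognized: Counter = field(default_factory=Counter)


def _read_table(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _parse_date(value: str, source: str, lineno: int, column: str) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except ValueError:
        raise SchemaError(
            f"{source}, line {lineno}, column {column!r}: "
            f"{value!r} is not an ISO-8601 date"
        ) from None


def _parse_number(
    value: str, source: str, lineno: int, column: str
) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{source}, line {lineno}, column {column!r}: "
            f"{value!r} is not a number"
        ) from None


def parse_record_rows(
    rows: Iterable[dict],
    lexicon: Lexicon,
    window: Tuple[date, date],
    source: str = "records",
) -> Tuple[List[MedicationRecord], LoadStats]:
    """Normalize raw record rows into :class:`MedicationRecord` objects.

    Rows dated outside the analysis window are excluded (counted), names the
    lexicon cannot resolve are excluded (counted per name), and combination
    products are split into their components.
    """
    start, end = window
    stats = LoadStats()
    out: List[MedicationRecord] = []
    for lineno, row in enumerate(rows, start=2):
        stats.n_rows += 1
        d = _parse_date(row["date"], source, lineno, "date")
        if not (start <= d <= end):
            stats.n_out_of_window += 1
            continue
        raw = str(row["medication_name"])
        resolved = normalize_name(raw, lexicon)
        if resolved == UNRECOGNIZED:
            stats.unrecognized[raw.strip().lower()] += 1
            continue
        canonical, category = resolved
        amount = _parse_number(
            row["strength_amount"], source, lineno, "strength_amount"
        )
        freq = _parse_number(
            row["frequency_per_day"], source, lineno, "frequency_per_day"
        )
        try:
            dose = DailyDose(canonical, amount, row["strength_unit"], freq)
        except ValueError as exc:
            raise SchemaError(f"{source}, line {lineno}: {exc}") from None
        rec = MedicationRecord(
            patient_id=str(row["patient_id"]),
            date=d,
            raw_name=raw,
            canonical_name=canonical,
            category=category,
            dose=dose,
        )
        for expanded in expand_combination(rec, lexicon):
            if COMBINATION_UNSPLIT in expanded.flags:
                stats.n_combination_unsplit += 1
            out.append(expanded)
    return out, stats


def parse_encounter_rows(
    rows: Iterable[dict],
    window: Tuple[date, date],
    source: str = "encounters",
) -> Tuple[List[Encounter], int]:
    """Parse encounter rows, dropping (and counting) out-of-window visits."""
    start, end = window
    out: List[Encounter] = []
    n_outside = 0
    for lineno, row in enumerate(rows, start=2):
        d = _parse_date(row["date"], source, lineno, "date")
        if not (start <= d <= end):
            n_outside += 1
            continue
        out.append(Encounter(patient_id=str(row["patient_id"]), date=d))
    return out, n_outside


def read_records(
    path: Union[str, Path],
    lexicon: Lexicon,
    window: Tuple[date, date],
) -> Tuple[List[MedicationRecord], LoadStats]:
    df = _read_table(path, RECORD_COLUMNS)
    return parse_record_rows(
        df.to_dict("records"), lexicon, window, source=str(path)
    )


def read_encounters(
    path: Union[str, Path], window: Tuple[date, date]
) -> Tuple[List[Encounter], int]:
    df = _read_table(path, ENCOUNTER_COLUMNS)
    return parse_encounter_rows(df.to_dict("records"), window, source=str(path))


def read_patients(path: Union[str, Path]) -> Dict[str, Optional[float]]:
    """Demographics table: patient_id -> age (None where age is blank)."""
    df = _read_table(path, PATIENT_COLUMNS)
    ages: Dict[str, Optional[float]] = {}
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        raw = str(row["age"]).strip()
        if raw == "" or raw.lower() == "nan":
            ages[str(row["patient_id"])] = None
        else:
            ages[str(row["patient_id"])] = _parse_number(
                raw, str(path), lineno, "age"
            )
    return ages


def build_histories(
    records: Iterable[MedicationRecord],
    encounters: Iterable[Encounter],
    ages: Optional[Dict[str, Optional[float]]] = None,
) -> List[PatientHistory]:
    """Group records and encounters into per-patient histories.

    Output is sorted by patient id; row order of the inputs is irrelevant.
    Patients appearing only in the encounters (or demographics) table still
    get a history, so encounter-only patients flow through the pipeline.
    """
    recs: Dict[str, list] = defaultdict(list)
    encs: Dict[str, list] = defaultdict(list)
    for r in records:
        recs[r.patient_id].append(r)
    for e in encounters:
        encs[e.patient_id].append(e)
    ids = set(recs) | set(encs) | set(ages or {})
    return [
        PatientHistory(
            patient_id=pid,
            age=(ages or {}).get(pid),
            records=recs.get(pid, []),
            encounters=encs.get(pid, []),
        )
        for pid in sorted(ids)
    ]


def classifications_frame(classifications) -> pd.DataFrame:
    """One row per patient: patient_id,top_level,subtype,matched_rules,evidence."""
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "top_level": c.top_level.value,
                "subtype": c.subtype,
                "matched_rules": "|".join(c.all_matched_rules),
                "evidence": "; ".join(c.evidence),
            }
            for c in classifications
        ],
        columns=[
            "patient_id",
            "top_level",
            "subtype",
            "matched_rules",
            "evidence",
        ],
    )
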