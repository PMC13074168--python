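"""Normalization of free-text diabetes medication names.

Primary-care EHR exports record medication names as written: brand names,
generics, abbreviations, with or without strength/form suffixes and in any
case. Downstream trajectory rules operate on canonical generic names grouped
into the three intensity tiers used throughout T2D deprescribing work:
insulin, metformin, and all other (non-insulin/non-metformin) agents.

The mapping lives in an editable delimited table, not in code, so sites can
extend it. A default lexicon compiled from public generic/brand name pairs is
bundled with the package.
"""
from __future__ import annotations

import csv
import dataclasses
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple, Union


class Category(str, Enum):
    """Intensity tier of a glucose-lowering medication."""

    INSULIN = "INSULIN"
    METFORMIN = "METFORMIN"
    NON_INSULIN_OTHER = "NON_INSULIN_OTHER"


#: Sentinel returned for names that do not resolve to any lexicon entry.
UNRECOGNIZED = "UNRECOGNIZED"

#: Flag attached to a combination-product record that could not be split.
COMBINATION_UNSPLIT = "combination_unsplit"


class LexiconError(ValueError):
    """Raised when a lexicon table fails validation."""


def _key(name: str) -> str:
    """Canonical lookup key: lowercase, collapsed whitespace, '/' == '-'."""
    s = name.strip().lower().replace("/", "-")
    return re.sub(r"\s+", " ", s)


@dataclass(frozen=True)
class LexiconEntry:
    """One canonical medication with its synonyms and tier.

    ``components`` is non-empty only for fixed-dose combination products; when
    ``component_strengths`` is also present it is parallel to ``components``
    and gives the mg per administration contributed by each component.
    """

    canonical_name: str
    category: Category
    synonyms: frozenset = field(default_factory=frozenset)
    components: Tuple[str, ...] = ()
    component_strengths: Tuple[float, ...] = ()

    @property
    def is_combination(self) -> bool:
        return bool(self.components)


class Lexicon:
    """Validated collection of :class:`LexiconEntry` with name lookup."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        self._index: dict[str, LexiconEntry] = {}
        owner: dict[str, str] = {}
        for entry in entries:
            if not isinstance(entry.category, Category):
                allowed = ", ".join(c.value for c in Category)
                raise LexiconError(
                    f"entry {entry.canonical_name!r}: category "
                    f"{entry.category!r} is not one of: {allowed}"
                )
            ckey = _key(entry.canonical_name)
            if ckey in owner:
                raise LexiconError(
                    f"name {entry.canonical_name!r} maps to two entries: "
                    f"{owner[ckey]!r} and {entry.canonical_name!r}"
                )
            self._entries[entry.canonical_name] = entry
            owner[ckey] = entry.canonical_name
            self._index[ckey] = entry
            for syn in sorted(entry.synonyms):
                skey = _key(syn)
                if skey in owner:
                    raise LexiconError(
                        f"synonym {syn!r} maps to two entries: "
                        f"{owner[skey]!r} and {entry.canonical_name!r}"
                    )
                owner[skey] = entry.canonical_name
                self._index[skey] = entry
        for entry in self._entries.values():
            if entry.components and entry.component_strengths and len(
                entry.components
            ) != len(entry.component_strengths):
                raise LexiconError(
                    f"entry {entry.canonical_name!r}: component_strengths "
                    "must be parallel to components"
                )
            for comp in entry.components:
                target = self._index.get(_key(comp))
                if target is None:
                    raise LexiconError(
                        f"entry {entry.canonical_name!r}: component "
                        f"{comp!r} does not resolve to any entry"
                    )
                if target.is_combination:
                    raise LexiconError(
                        f"entry {entry.canonical_name!r}: component "
                        f"{comp!r} resolves to another combination"
                    )

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    @property
    def entries(self) -> Tuple[LexiconEntry, ...]:
        return tuple(self._entries.values())

    def lookup(self, name: str) -> Optional[LexiconEntry]:
        """Exact (key-normalized) lookup of a canonical name or synonym."""
        return self._index.get(_key(name))

    def resolve(self, raw: str) -> Optional[LexiconEntry]:
        """Match ``raw`` against the lexicon, ignoring case, surrounding
        whitespace and a trailing strength/form suffix.

        Matching drops whitespace-delimited tokens from the right until the
        remaining prefix hits the index, so ``"METFORMIN 500 MG TAB"``
        resolves via the prefix ``"metformin"`` while the strength-specific
        combination ``"sitagliptin-metformin 50-500"`` is matched in full
        before its generic prefix.
        """
        tokens = _key(raw).split(" ")
        for cut in range(len(tokens), 0, -1):
            hit = self._index.get(" ".join(tokens[:cut]))
            if hit is not None:
                return hit
        return None


def _parse_row(row: dict, lineno: int) -> LexiconEntry:
    name = (row.get("canonical_name") or "").strip()
    cat_token = (row.get("category") or "").strip()
    if not name or not cat_token:
        raise LexiconError(
            f"line {lineno}: canonical_name and category are required"
        )
    try:
        category = Category(cat_token.upper())
    except ValueError:
        allowed = ", ".join(c.value for c in Category)
        raise LexiconError(
            f"line {lineno}: unknown category {cat_token!r}; "
            f"allowed: {allowed}"
        ) from None
    synonyms = frozenset(
        s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()
    )
    components = tuple(
        c.strip() for c in (row.get("components") or "").split("|") if c.strip()
    )
    raw_strengths = (row.get("component_strengths") or "").strip()
    strengths: Tuple[float, ...] = ()
    if raw_strengths:
        try:
            strengths = tuple(float(s) for s in raw_strengths.split("|"))
        except ValueError:
            raise LexiconError(
                f"line {lineno}: component_strengths must be numeric"
            ) from None
    return LexiconEntry(
        canonical_name=name,
        category=category,
        synonyms=synonyms,
        components=components,
        component_strengths=strengths,
    )


_REQUIRED_COLUMNS = ("canonical_name", "category")


def load_lexicon(path: Union[str, Path, None] = None) -> Lexicon:
    """Load and validate a lexicon table.

    With no ``path`` the default lexicon bundled with the package is used.
    The table is comma-delimited with header
    ``canonical_name,category,synonyms,components,component_strengths``;
    synonyms and components are pipe-separated within their cell.
    """
    if path is None:
        ref = resources.files("deprx").joinpath("data/default_lexicon.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        p = Path(path)
        if not p.exists():
            raise LexiconError(f"lexicon file not found: {p}")
        text = p.read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    header = reader.fieldnames or []
    for col in _REQUIRED_COLUMNS:
        if col not in header:
            raise LexiconError(f"lexicon table is missing column {col!r}")
    entries = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    return Lexicon(entries)


def normalize_name(raw: str, lexicon: Lexicon):
    """Resolve a free-text medication name to ``(canonical, category)``.

    Unmatched names return :data:`UNRECOGNIZED` (callers count these for
    reporting); an empty name is an input error.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("medication name is empty")
    entry = lexicon.resolve(str(raw))
    if entry is None:
        return UNRECOGNIZED
    return entry.canonical_name, entry.category


def expand_combination(record, lexicon: Lexicon) -> list:
    """Split a fixed-dose combination record into one record per component.

    Each component record carries the lexicon-encoded component strength (mg)
    at the original frequency, so a metformin-containing combination counts
    toward both the METFORMIN and NON_INSULIN_OTHER regimens. Non-combination
    records pass through unchanged as a singleton list. A combination whose
    split is not encoded in the lexicon is returned unchanged but flagged
    :data:`COMBINATION_UNSPLIT` so it is surfaced rather than silently kept.
    """
    from .dosing import DailyDose  # local import to avoid a cycle

    entry = lexicon.lookup(record.canonical_name)
    if entry is None or not entry.is_combination:
        return [record]
    if not entry.component_strengths:
        return [
            dataclasses.replace(
                record, flags=tuple(record.flags) + (COMBINATION_UNSPLIT,)
            )
        ]
    out = []
    for comp, strength in zip(entry.components, entry.component_strengths):
        comp_entry = lexicon.lookup(comp)
        dose = DailyDose(
            canonical_name=comp_entry.canonical_name,
            amount=strength,
            unit="mg",
            frequency_per_day=record.dose.frequency_per_day,
        )
        out.append(
            dataclasses.replace(
                record,
                canonical_name=comp_entry.canonical_name,
                category=comp_entry.category,
                dose=dose,
            )
        )
    return out
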