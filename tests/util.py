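"""Shared builders for classifier-level tests."""
from __future__ import annotations

from deprx import Category, DailyDose, RegimenMember, TrajectorySummary

_UNIT = {
    Category.INSULIN: "units",
    Category.METFORMIN: "mg",
    Category.NON_INSULIN_OTHER: "mg",
}


def member(name: str, category: Category, daily: float, unit: str | None = None):
    return RegimenMember(
        name, category, DailyDose(name, daily, unit or _UNIT[category], 1)
    )


def ins(daily, name="insulin glargine"):
    return member(name, Category.INSULIN, daily)


def met(daily):
    return member("metformin", Category.METFORMIN, daily)


def ni(name, daily):
    return member(name, Category.NON_INSULIN_OTHER, daily)


def summary(baseline, final, **kw):
    return TrajectorySummary.from_members("pt", baseline, final, **kw)
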