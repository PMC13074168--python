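"""Daily-dose standardization and per-category dose totals.

Every prescription is reduced to a daily dose — dose per administration times
administrations per day — so that regimens recorded with different frequencies
become comparable over time. Insulin is dosed in units, oral agents in mass
units (mg; mcg is accepted and converted). Doses are never compared across
different drugs except for insulin, where the clinically meaningful quantity
is the total daily units summed over products (basal plus bolus).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

from .lexicon import Category

if TYPE_CHECKING:  # pragma: no cover
    from .trajectory import RegimenSnapshot

_UNIT_ALIASES = {
    "mg": "mg",
    "milligram": "mg",
    "milligrams": "mg",
    "mcg": "mcg",
    "ug": "mcg",
    "microgram": "mcg",
    "micrograms": "mcg",
    "units": "units",
    "unit": "units",
    "u": "units",
    "iu": "units",
}

#: Factors to a category's reference mass unit (mg).
_TO_MG = {"mg": 1.0, "mcg": 0.001}


def normalize_unit(unit: str) -> str:
    """Map a recorded unit token to one of {mg, mcg, units}."""
    token = str(unit).strip().lower().rstrip(".")
    try:
        return _UNIT_ALIASES[token]
    except KeyError:
        raise ValueError(f"unsupported dose unit: {unit!r}") from None


def compute_daily_dose(amount: float, frequency_per_day: float) -> float:
    """Daily dose = dose per administration x administrations per day.

    Exact product, no rounding. ``amount`` must be non-negative and
    ``frequency_per_day`` strictly positive (weekly injectables are recorded
    as a fractional frequency, e.g. 1/7).
    """
    if amount < 0:
        raise ValueError(f"dose amount must be non-negative, got {amount}")
    if frequency_per_day <= 0:
        raise ValueError(
            f"frequency_per_day must be positive, got {frequency_per_day}"
        )
    return amount * frequency_per_day


@dataclass(frozen=True)
class DailyDose:
    """A medication's standardized daily dose."""

    canonical_name: str
    amount: float
    unit: str
    frequency_per_day: float

    def __post_init__(self):
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        compute_daily_dose(self.amount, self.frequency_per_day)  # validates

    @property
    def daily_total(self) -> float:
        return compute_daily_dose(self.amount, self.frequency_per_day)

    @property
    def daily_total_mg(self) -> Optional[float]:
        """Daily total expressed in mg, or None for insulin units."""
        factor = _TO_MG.get(self.unit)
        return None if factor is None else self.daily_total * factor


@dataclass(frozen=True)
class CategoryTotal:
    """Result of summing a category's daily doses within one snapshot.

    ``comparable`` is False when no single meaningful total exists: mixed
    mass/insulin units, or more than one distinct non-insulin/non-metformin
    agent (those are treated as laterally equivalent and are never summed
    across drugs — dose-change rules then fall back to per-drug comparison).
    """

    value: Optional[float]
    unit: Optional[str]
    comparable: bool
    reason: str = ""


def category_daily_total(snapshot: "RegimenSnapshot", category: Category) -> CategoryTotal:
    """Total daily dose over a snapshot's members of one category.

    Empty category totals to 0. Insulin sums units across products;
    metformin sums mg; the heterogeneous non-insulin tier only has a defined
    total when a single agent is present.
    """
    members = [m for m in snapshot.members.values() if m.category == category]
    if not members:
        return CategoryTotal(0.0, None, True)
    units = {m.dose.unit for m in members}
    if "units" in units and units != {"units"}:
        return CategoryTotal(None, None, False, "mixed mass and insulin units")
    if category == Category.NON_INSULIN_OTHER and len(
        {m.canonical_name for m in members}
    ) > 1:
        return CategoryTotal(
            None, None, False, "multiple distinct non-insulin agents"
        )
    if units == {"units"}:
        return CategoryTotal(
            sum(m.dose.daily_total for m in members), "units", True
        )
    return CategoryTotal(
        sum(m.dose.daily_total_mg for m in members), "mg", True
    )
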