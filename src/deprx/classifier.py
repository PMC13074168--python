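"""The deprescribing classification rules.

Medication changes between a patient's baseline and final regimen windows are
classified into one top-level label — deprescribed, not deprescribed, or
unclear — with a subtype. The eight deprescribing subtypes follow the
three-tier intensity ordering (insulin above the heterogeneous non-insulin
oral/injectable agents, metformin at the bottom):

  insulin:      dose reduced; switched to a non-insulin medication;
                discontinued
  non-insulin:  agent stopped; same agent's dose reduced; switched to
                metformin (incl. multiple agents + metformin -> metformin
                only)
  metformin:    stopped (and never restarted); dose reduced

Moves up the intensity ordering (any agent -> insulin; metformin -> any
higher tier) and in-category dose increases are medication escalation.
Switches among different non-insulin, non-metformin agents are lateral:
they are treated as equivalent in intensity and are not deprescribing.
Trajectories that show both de-escalation and escalation, or an empty final
window that the annual-refill rule cannot explain, are flagged for human
review rather than forced into a category.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .dosing import CategoryTotal, category_daily_total
from .lexicon import Category
from .trajectory import RegimenSnapshot, TrajectorySummary

# -- rule labels -------------------------------------------------------------

INSULIN_DOSE_REDUCED = "INSULIN_DOSE_REDUCED"
INSULIN_TO_NONINSULIN = "INSULIN_TO_NONINSULIN"
INSULIN_DISCONTINUED = "INSULIN_DISCONTINUED"
NONINSULIN_STOPPED = "NONINSULIN_STOPPED"
NONINSULIN_DOSE_REDUCED = "NONINSULIN_DOSE_REDUCED"
NONINSULIN_TO_METFORMIN = "NONINSULIN_TO_METFORMIN"
METFORMIN_STOPPED = "METFORMIN_STOPPED"
METFORMIN_DOSE_REDUCED = "METFORMIN_DOSE_REDUCED"

INSULIN_DOSE_INCREASED = "INSULIN_DOSE_INCREASED"
ORAL_DOSE_INCREASED = "ORAL_DOSE_INCREASED"
INTENSITY_ESCALATION = "INTENSITY_ESCALATION"

LATERAL_CHANGE = "LATERAL_CHANGE"
MEDICATION_INCREASE = "MEDICATION_INCREASE"
NO_CHANGE = "NO_CHANGE"
NEEDS_REVIEW = "NEEDS_REVIEW"

#: Subtype precedence when several deprescribing rules match. The
#: switch-to-metformin rule outranks the generic non-insulin stop/dose rules
#: it subsumes (a multi-agent regimen collapsing to metformin alone is
#: reported as the switch, not as the stops it implies), mirroring how an
#: insulin-to-oral switch is reported in place of the insulin discontinuation
#: it implies.
DEPRESCRIBING_PRECEDENCE: Tuple[str, ...] = (
    INSULIN_DOSE_REDUCED,
    INSULIN_TO_NONINSULIN,
    INSULIN_DISCONTINUED,
    NONINSULIN_TO_METFORMIN,
    NONINSULIN_STOPPED,
    NONINSULIN_DOSE_REDUCED,
    METFORMIN_STOPPED,
    METFORMIN_DOSE_REDUCED,
)

DEPRESCRIBING_RULES: Set[str] = set(DEPRESCRIBING_PRECEDENCE)
ESCALATION_RULES: Set[str] = {
    INSULIN_DOSE_INCREASED,
    ORAL_DOSE_INCREASED,
    INTENSITY_ESCALATION,
}


class TopLevel(str, Enum):
    DEPRESCRIBED = "DEPRESCRIBED"
    NOT_DEPRESCRIBED = "NOT_DEPRESCRIBED"
    UNCLEAR = "UNCLEAR"


@dataclass(frozen=True)
class Policy:
    """Tunable classification thresholds.

    ``max_transitions``: more interim add/stop events than this (without a
    net change between windows) routes the case to review as too complex to
    call mechanically.
    """

    max_transitions: int = 4


@dataclass(frozen=True)
class Classification:
    patient_id: str
    top_level: TopLevel
    subtype: str
    all_matched_rules: Tuple[str, ...] = ()
    evidence: Tuple[str, ...] = ()


# -- rule evaluation ---------------------------------------------------------


def _mass_total(dose) -> Optional[float]:
    return dose.daily_total_mg


def _same_daily_dose(a, b) -> bool:
    if a.unit == b.unit:
        return a.daily_total == b.daily_total
    am, bm = a.daily_total_mg, b.daily_total_mg
    return am is not None and bm is not None and am == bm


def _compare_same_drug(a, b) -> Optional[int]:
    """-1/0/+1 comparison of two doses of the same drug, None if units mix."""
    if a.unit == b.unit:
        x, y = a.daily_total, b.daily_total
    else:
        x, y = a.daily_total_mg, b.daily_total_mg
        if x is None or y is None:
            return None
    return (x > y) - (x < y)


def _evaluate(traj: TrajectorySummary) -> Tuple[Set[str], List[str]]:
    B, F = traj.baseline, traj.final
    bm, fm = B.members, F.members
    rules: Set[str] = set()
    ev: List[str] = []

    if F.is_empty and not B.is_empty and not traj.inferred_discontinuation:
        ev.append(
            "no prescriptions in the final window and no encounter after the "
            "last prescription: stop vs loss to follow-up cannot be "
            "distinguished"
        )
        return rules, ev

    ins_b, ins_f = B.names(Category.INSULIN), F.names(Category.INSULIN)
    met_b, met_f = B.names(Category.METFORMIN), F.names(Category.METFORMIN)
    ni_b, ni_f = (
        B.names(Category.NON_INSULIN_OTHER),
        F.names(Category.NON_INSULIN_OTHER),
    )
    stopped_ni, started_ni = ni_b - ni_f, ni_f - ni_b
    new_insulin = bool(ins_f - ins_b) and not ins_b
    net_ni_added = len(started_ni) > len(stopped_ni)

    # insulin tier: total daily units across products
    if ins_b and ins_f and traj.dose_comparable[Category.INSULIN]:
        tb = category_daily_total(B, Category.INSULIN)
        tf = category_daily_total(F, Category.INSULIN)
        if tb.comparable and tf.comparable:
            if tf.value < tb.value:
                rules.add(INSULIN_DOSE_REDUCED)
                ev.append(
                    f"total daily insulin decreased {tb.value:g} -> "
                    f"{tf.value:g} units"
                )
            elif tf.value > tb.value:
                rules.add(INSULIN_DOSE_INCREASED)
                ev.append(
                    f"total daily insulin increased {tb.value:g} -> "
                    f"{tf.value:g} units"
                )
    if ins_b and not ins_f:
        rules.add(INSULIN_DISCONTINUED)
        ev.append("all insulin discontinued between windows")
        if (met_f | ni_f) - (met_b | ni_b):
            rules.add(INSULIN_TO_NONINSULIN)
            started = ", ".join(sorted((met_f | ni_f) - (met_b | ni_b)))
            ev.append(f"insulin stopped and {started} started")

    # non-insulin tier: lateral vs stop vs per-drug dose change
    if stopped_ni and started_ni:
        rules.add(LATERAL_CHANGE)
        ev.append(
            "lateral transition among non-insulin agents: "
            f"{', '.join(sorted(stopped_ni))} -> {', '.join(sorted(started_ni))}"
        )
    if len(stopped_ni) > len(started_ni) and not new_insulin:
        rules.add(NONINSULIN_STOPPED)
        ev.append(
            f"non-insulin agent(s) stopped: {', '.join(sorted(stopped_ni))}"
        )
    for name in sorted(ni_b & ni_f):
        cmp = _compare_same_drug(bm[name].dose, fm[name].dose)
        if cmp is None:
            ev.append(f"{name}: dose recorded in incompatible units; "
                      "dose-change rules suppressed")
        elif cmp > 0:
            rules.add(NONINSULIN_DOSE_REDUCED)
            ev.append(
                f"{name} daily dose reduced "
                f"{bm[name].dose.daily_total:g} -> {fm[name].dose.daily_total:g}"
            )
        elif cmp < 0:
            rules.add(ORAL_DOSE_INCREASED)
            ev.append(
                f"{name} daily dose increased "
                f"{bm[name].dose.daily_total:g} -> {fm[name].dose.daily_total:g}"
            )
    if ni_b and not F.is_empty and not ins_f and not ni_f and met_f:
        rules.add(NONINSULIN_TO_METFORMIN)
        ev.append("regimen changed to metformin only")

    # metformin tier
    if (
        met_b
        and not met_f
        and not traj.metformin_restarted
        and not new_insulin
        and not net_ni_added
    ):
        rules.add(METFORMIN_STOPPED)
        ev.append("metformin stopped and not restarted at any point")
    if met_b and met_f and traj.dose_comparable[Category.METFORMIN]:
        tb = category_daily_total(B, Category.METFORMIN)
        tf = category_daily_total(F, Category.METFORMIN)
        if tb.comparable and tf.comparable:
            if tf.value < tb.value:
                rules.add(METFORMIN_DOSE_REDUCED)
                ev.append(
                    f"total daily metformin decreased {tb.value:g} -> "
                    f"{tf.value:g} mg"
                )
            elif tf.value > tb.value:
                rules.add(ORAL_DOSE_INCREASED)
                ev.append(
                    f"total daily metformin increased {tb.value:g} -> "
                    f"{tf.value:g} mg"
                )

    # intensity escalation: up the category ordering, or net regimen growth
    started_any = set(fm) - set(bm)
    stopped_any = set(bm) - set(fm)
    if new_insulin:
        rules.add(INTENSITY_ESCALATION)
        ev.append("insulin newly started")
    if net_ni_added:
        rules.add(INTENSITY_ESCALATION)
        ev.append(
            f"net addition of non-insulin agent(s): "
            f"{', '.join(sorted(started_ni))}"
        )
    if started_any and not stopped_any:
        rules.add(INTENSITY_ESCALATION)
        ev.append(
            f"medication(s) added with nothing stopped: "
            f"{', '.join(sorted(started_any))}"
        )
    return rules, ev


def evaluate_rules(traj: TrajectorySummary) -> Set[str]:
    """All deprescribing/escalation/lateral rules matched by a trajectory.

    Pure predicate on the endpoint snapshots plus the inferred-discontinuation
    and metformin-restart features; dose-change rules are suppressed for a
    category flagged not dose-comparable.
    """
    rules, _ = _evaluate(traj)
    return rules


# -- top-level resolution ----------------------------------------------------


def _regimens_equivalent(traj: TrajectorySummary) -> bool:
    """No change between windows: insulin and metformin compared at category
    level (total daily units / total mg, so equal-dose product switches are
    no change), the heterogeneous non-insulin tier drug-by-drug."""
    B, F = traj.baseline, traj.final
    if B.categories() != F.categories():
        return False
    for cat in (Category.INSULIN, Category.METFORMIN):
        if cat not in B.categories():
            continue
        if traj.dose_comparable[cat]:
            tb = category_daily_total(B, cat)
            tf = category_daily_total(F, cat)
            if tb.value != tf.value:
                return False
        else:
            if B.names(cat) != F.names(cat):
                return False
            for n in B.names(cat):
                if not _same_daily_dose(B.members[n].dose, F.members[n].dose):
                    return False
    cat = Category.NON_INSULIN_OTHER
    if B.names(cat) != F.names(cat):
        return False
    for n in B.names(cat):
        if not _same_daily_dose(B.members[n].dose, F.members[n].dose):
            return False
    return True


def _discontinued_subtype(baseline: RegimenSnapshot) -> str:
    cats = baseline.categories()
    if Category.INSULIN in cats:
        return INSULIN_DISCONTINUED
    if Category.NON_INSULIN_OTHER in cats:
        return NONINSULIN_STOPPED
    return METFORMIN_STOPPED


def classify_patient(
    traj: TrajectorySummary, policy: Optional[Policy] = None
) -> Classification:
    """Resolve a trajectory to exactly one (top level, subtype).

    Resolution order: inferred discontinuation of the whole regimen; clean
    deprescribing; escalation; mixed deprescribing + escalation signals
    (review); lateral change; no change; overly complex interim history
    (review); anything else unresolvable from the export alone (review).
    """
    policy = policy or Policy()
    rules, ev = _evaluate(traj)
    depr = rules & DEPRESCRIBING_RULES
    esc = rules & ESCALATION_RULES

    def done(top, subtype, extra=()):
        return Classification(
            patient_id=traj.patient_id,
            top_level=top,
            subtype=subtype,
            all_matched_rules=tuple(sorted(rules)),
            evidence=tuple(ev) + tuple(extra),
        )

    if (
        traj.inferred_discontinuation
        and traj.final.is_empty
        and not traj.baseline.is_empty
    ):
        subtype = _discontinued_subtype(traj.baseline)
        rules = rules | {subtype}
        return done(
            TopLevel.DEPRESCRIBED,
            subtype,
            (
                "no prescriptions in the final 12 months with a later "
                "encounter: medications considered discontinued under the "
                "annual-refill rule",
            ),
        )
    if depr and not esc:
        subtype = next(r for r in DEPRESCRIBING_PRECEDENCE if r in depr)
        return done(TopLevel.DEPRESCRIBED, subtype)
    if esc and not depr:
        return done(TopLevel.NOT_DEPRESCRIBED, MEDICATION_INCREASE)
    if depr and esc:
        return done(
            TopLevel.UNCLEAR,
            NEEDS_REVIEW,
            ("mixed de-escalation and escalation signals",),
        )
    if LATERAL_CHANGE in rules:
        return done(TopLevel.NOT_DEPRESCRIBED, LATERAL_CHANGE)
    if _regimens_equivalent(traj):
        return done(TopLevel.NOT_DEPRESCRIBED, NO_CHANGE)
    if (
        traj.n_interim_transitions > policy.max_transitions
        and traj.baseline.categories() == traj.final.categories()
    ):
        return done(
            TopLevel.UNCLEAR,
            NEEDS_REVIEW,
            (
                f"{traj.n_interim_transitions} interim medication transitions "
                "without a net category change",
            ),
        )
    return done(TopLevel.UNCLEAR, NEEDS_REVIEW)


def classify_cohort(
    trajectories: Iterable[TrajectorySummary],
    policy: Optional[Policy] = None,
) -> List[Classification]:
    return [classify_patient(t, policy) for t in trajectories]


def summarize(classifications: Iterable[Classification]) -> Dict[str, Dict[str, int]]:
    """Per-top-level and per-subtype counts for cohort reporting."""
    top: Dict[str, int] = {t.value: 0 for t in TopLevel}
    sub: Dict[str, int] = {}
    for c in classifications:
        top[c.top_level.value] += 1
        sub[c.subtype] = sub.get(c.subtype, 0) + 1
    return {"top_level": top, "subtype": sub}
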