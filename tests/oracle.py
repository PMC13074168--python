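"""Independent flat transcription of the classification framework.

Written directly against plain dictionaries, separately from the package's
rule engine, to serve as a brute-force oracle for exhaustive enumeration.
A regimen is ``{name: (tier, unit, daily_total)}`` with tier one of
'ins' / 'met' / 'ni'. Returns ``(top_level, subtype)`` strings matching the
package's output vocabulary.
"""

_PRECEDENCE = (
    ("r1", "INSULIN_DOSE_REDUCED"),
    ("r2", "INSULIN_TO_NONINSULIN"),
    ("r3", "INSULIN_DISCONTINUED"),
    ("r6", "NONINSULIN_TO_METFORMIN"),
    ("r4", "NONINSULIN_STOPPED"),
    ("r5", "NONINSULIN_DOSE_REDUCED"),
    ("r7", "METFORMIN_STOPPED"),
    ("r8", "METFORMIN_DOSE_REDUCED"),
)


def oracle_classify(
    base,
    fin,
    inferred=False,
    restarted=False,
    transitions=0,
    max_transitions=4,
):
    def tier(d, t):
        return {k: v for k, v in d.items() if v[0] == t}

    bi, bmet, bni = tier(base, "ins"), tier(base, "met"), tier(base, "ni")
    fi, fmet, fni = tier(fin, "ins"), tier(fin, "met"), tier(fin, "ni")

    # whole-regimen discontinuation under the annual-refill inference
    if base and not fin:
        if not inferred:
            return ("UNCLEAR", "NEEDS_REVIEW")
        if bi:
            return ("DEPRESCRIBED", "INSULIN_DISCONTINUED")
        if bni:
            return ("DEPRESCRIBED", "NONINSULIN_STOPPED")
        return ("DEPRESCRIBED", "METFORMIN_STOPPED")

    depr, esc = set(), set()
    lateral = False
    ni_started = set(fni) - set(bni)
    ni_gone = set(bni) - set(fni)
    new_insulin = bool(fi) and not bi
    net_ni_add = len(ni_started) > len(ni_gone)

    tot = lambda d: sum(v[2] for v in d.values())
    if bi and fi:
        if tot(fi) < tot(bi):
            depr.add("r1")
        elif tot(fi) > tot(bi):
            esc.add("insulin_up")
    if bi and not fi:
        depr.add("r3")
        if (set(fmet) | set(fni)) - (set(bmet) | set(bni)):
            depr.add("r2")

    if ni_gone and ni_started:
        lateral = True
    if len(ni_gone) > len(ni_started) and not new_insulin:
        depr.add("r4")
    for k in set(bni) & set(fni):
        if fni[k][2] < bni[k][2]:
            depr.add("r5")
        elif fni[k][2] > bni[k][2]:
            esc.add("oral_up")
    if bni and fin and not fi and not fni and fmet:
        depr.add("r6")

    if bmet and not fmet and not restarted and not new_insulin and not net_ni_add:
        depr.add("r7")
    if bmet and fmet:
        if tot(fmet) < tot(bmet):
            depr.add("r8")
        elif tot(fmet) > tot(bmet):
            esc.add("oral_up")

    if new_insulin:
        esc.add("escalation")
    if net_ni_add:
        esc.add("escalation")
    if (set(fin) - set(base)) and not (set(base) - set(fin)):
        esc.add("escalation")

    if depr and not esc:
        for key, subtype in _PRECEDENCE:
            if key in depr:
                return ("DEPRESCRIBED", subtype)
    if esc and not depr:
        return ("NOT_DEPRESCRIBED", "MEDICATION_INCREASE")
    if depr and esc:
        return ("UNCLEAR", "NEEDS_REVIEW")
    if lateral:
        return ("NOT_DEPRESCRIBED", "LATERAL_CHANGE")

    tiers_b = {v[0] for v in base.values()}
    tiers_f = {v[0] for v in fin.values()}
    same = tiers_b == tiers_f
    if same and bi and tot(bi) != tot(fi):
        same = False
    if same and bmet and tot(bmet) != tot(fmet):
        same = False
    if same and (
        set(bni) != set(fni) or any(bni[k][2] != fni[k][2] for k in bni)
    ):
        same = False
    if same:
        return ("NOT_DEPRESCRIBED", "NO_CHANGE")
    if transitions > max_transitions and tiers_b == tiers_f:
        return ("UNCLEAR", "NEEDS_REVIEW")
    return ("UNCLEAR", "NEEDS_REVIEW")


#: 3 dose levels per medication plus absence; one insulin product, metformin,
#: and two laterally-equivalent non-insulin agents.
GRID_MEDICATIONS = (
    ("insulin glargine", "ins", "units", (10, 20, 40)),
    ("metformin", "met", "mg", (500, 1000, 2000)),
    ("sitagliptin", "ni", "mg", (25, 50, 100)),
    ("glipizide", "ni", "mg", (5, 10, 20)),
)


def enumerate_regimens():
    """All 256 regimens over the grid (each med absent or at one of 3 doses)."""
    regimens = [{}]
    for name, tier_tag, unit, doses in GRID_MEDICATIONS:
        regimens = [
            {**r, **({name: (tier_tag, unit, float(d))} if d else {})}
            for r in regimens
            for d in (0,) + doses
        ]
    return regimens
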