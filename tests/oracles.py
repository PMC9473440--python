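"""Independent straight-line scoring oracle.

Hand-written re-implementation of the answer-coding rules, used only to
cross-check femi.scoring.  Deliberately naive and explicit; shares no code
with the package's scoring module.
"""

from femi.records import ALL_QUESTIONS


def oracle_ipv(rec, coverage=ALL_QUESTIONS):
    vals = []
    n_answered = 0
    n_no = 0
    for a in rec.beating_justified:
        if a == "no":
            n_answered += 1
            n_no += 1
        elif a == "yes":
            n_answered += 1
    if n_answered > 0:
        vals.append(n_no / n_answered)
    if "age_first_marriage" in coverage:
        if rec.age_first_marriage is not None:
            vals.append(1.0 if rec.age_first_marriage >= 18 else 0.0)
        elif not rec.currently_married:
            vals.append(1.0)
    if not vals:
        return None
    return sum(vals) / len(vals)


def oracle_employment(rec):
    vals = []
    if rec.work_regularity == "all_year":
        vals.append(1.0)
    elif rec.work_regularity == "part_year_or_seasonal":
        vals.append(0.5)
    elif rec.work_regularity == "none":
        vals.append(0.0)
    if rec.work_regularity == "none":
        vals.append(0.0)
    elif rec.payment_type == "cash":
        vals.append(1.0)
    elif rec.payment_type == "cash_and_in_kind":
        vals.append(0.75)
    elif rec.payment_type == "in_kind_only":
        vals.append(0.5)
    elif rec.payment_type == "unpaid":
        vals.append(0.0)
    if not vals:
        return None
    return sum(vals) / len(vals)


def oracle_education(rec):
    vals = []
    if rec.years_schooling is not None:
        vals.append(1.0 if rec.years_schooling >= 6 else 0.0)
    if rec.literate is not None:
        vals.append(1.0 if rec.literate else 0.0)
    if not vals:
        return None
    return sum(vals) / len(vals)


def oracle_reproductive_healthcare(rec, coverage=ALL_QUESTIONS):
    ante, deliv, post = [], [], []
    for b in rec.births_last_3y:
        if b.antenatal_visits is not None:
            if b.antenatal_visits == 0:
                ante.append(0.0)
            elif b.antenatal_visits <= 3:
                ante.append(0.5)
            else:
                ante.append(1.0)
        if b.professional_delivery is not None:
            deliv.append(1.0 if b.professional_delivery else 0.0)
        if b.postnatal_within_2mo is not None:
            post.append(1.0 if b.postnatal_within_2mo else 0.0)
    cats = []
    if ante:
        cats.append(sum(ante) / len(ante))
    if deliv:
        cats.append(sum(deliv) / len(deliv))
    if post:
        cats.append(sum(post) / len(post))
    if "age_first_birth" in coverage:
        if rec.age_first_birth is not None:
            cats.append(1.0 if rec.age_first_birth >= 18 else 0.0)
        else:
            cats.append(1.0)
    if not cats:
        return None
    return sum(cats) / len(cats)


def oracle_decision_making(rec):
    if not rec.currently_married:
        return None
    vals = []
    for a in rec.decision_answers:
        if a in ("self", "self_and_partner"):
            vals.append(1.0)
        elif a in ("partner_only", "other"):
            vals.append(0.0)
    if not vals:
        return None
    return sum(vals) / len(vals)


def oracle_family_planning(rec):
    if not rec.currently_married:
        return None
    if rec.wants_child_within_2y is not False:
        return None
    if rec.uses_modern_contraception is None:
        return None
    return 1.0 if rec.uses_modern_contraception else 0.0


def oracle_scores(rec, coverage=ALL_QUESTIONS):
    return {
        "intimate_partner_violence": oracle_ipv(rec, coverage),
        "family_planning": oracle_family_planning(rec),
        "reproductive_healthcare": oracle_reproductive_healthcare(rec, coverage),
        "employment": oracle_employment(rec),
        "education": oracle_education(rec),
        "decision_making": oracle_decision_making(rec),
    }
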