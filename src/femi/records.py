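"""Core record types for DHS-like survey microdata.

A survey bundle holds one row per woman respondent (with her recent birth
history as child records), one row per man (education/employment questions
only, used for the gender-inequality adjustment), and survey-level metadata
including which questions the survey actually asked.

All categorical answers use lowercase snake_case codes; missing answers are
``None`` at the record level and empty fields on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Domains and question vocabulary
# ---------------------------------------------------------------------------

DOMAIN_IPV = "intimate_partner_violence"
DOMAIN_FP = "family_planning"
DOMAIN_RH = "reproductive_healthcare"
DOMAIN_EMPLOYMENT = "employment"
DOMAIN_EDUCATION = "education"
DOMAIN_DECISION = "decision_making"

#: The six empowerment domains, in canonical output order.
DOMAINS = (
    DOMAIN_IPV,
    DOMAIN_FP,
    DOMAIN_RH,
    DOMAIN_EMPLOYMENT,
    DOMAIN_EDUCATION,
    DOMAIN_DECISION,
)

#: Domains whose region scores are adjusted by the women/men inequality ratio.
ADJUSTED_DOMAINS = (DOMAIN_EMPLOYMENT, DOMAIN_EDUCATION)

FEMI = "femi"

DECISION_QUESTIONS = (
    "decision_health",
    "decision_purchases",
    "decision_visits",
    "decision_food",
    "decision_money",
)

BEATING_QUESTIONS = (
    "beating_goes_out",
    "beating_neglects_children",
    "beating_argues",
    "beating_refuses_sex",
    "beating_burns_food",
)

DECISION_ANSWERS = ("self", "self_and_partner", "partner_only", "other")
#: Answers that code as empowered (the respondent has a say).
DECISION_EMPOWERED = ("self", "self_and_partner")
BEATING_ANSWERS = ("yes", "no")
WORK_REGULARITY = ("all_year", "part_year_or_seasonal", "none")
PAYMENT_TYPES = ("cash", "cash_and_in_kind", "in_kind_only", "unpaid")

#: Every question identifier a survey may or may not have asked.
ALL_QUESTIONS = frozenset(
    DECISION_QUESTIONS
    + BEATING_QUESTIONS
    + (
        "age_first_marriage",
        "age_first_birth",
        "wants_child_within_2y",
        "uses_modern_contraception",
        "years_schooling",
        "literate",
        "work_regularity",
        "payment_type",
        "antenatal_visits",
        "professional_delivery",
        "postnatal_within_2mo",
    )
)

#: Named blocks of questions, used by survey missing-question plans.
QUESTION_GROUPS = {
    "decision_making": frozenset(DECISION_QUESTIONS),
    "ipv_attitudes": frozenset(BEATING_QUESTIONS),
    "child_marriage": frozenset({"age_first_marriage"}),
    "ipv": frozenset(BEATING_QUESTIONS) | {"age_first_marriage"},
    "education": frozenset({"years_schooling", "literate"}),
    "employment": frozenset({"work_regularity", "payment_type"}),
    "family_planning": frozenset({"wants_child_within_2y", "uses_modern_contraception"}),
    "reproductive_healthcare": frozenset(
        {
            "antenatal_visits",
            "professional_delivery",
            "postnatal_within_2mo",
            "age_first_birth",
        }
    ),
}

AGE_MIN = 15
AGE_MAX = 49


class ValidationError(ValueError):
    """A record field violated its stated domain."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class BirthEvent:
    """One birth within the last three years before the interview."""

    antenatal_visits: int | None = None
    professional_delivery: bool | None = None
    postnatal_within_2mo: bool | None = None

    def validate(self) -> None:
        if self.antenatal_visits is not None and self.antenatal_visits < 0:
            raise ValidationError("antenatal_visits", "must be >= 0")


@dataclass
class WomanRecord:
    respondent_id: str
    survey_id: str
    region_id: str
    sample_weight: float
    age: int
    currently_married: bool
    age_first_marriage: int | None = None
    age_first_birth: int | None = None
    wants_child_within_2y: bool | None = None
    uses_modern_contraception: bool | None = None
    #: Answers to the five decision questions, in DECISION_QUESTIONS order.
    decision_answers: tuple = (None, None, None, None, None)
    #: Answers to the five beating-justified questions, in BEATING_QUESTIONS order.
    beating_justified: tuple = (None, None, None, None, None)
    years_schooling: int | None = None
    literate: bool | None = None
    work_regularity: str | None = None
    payment_type: str | None = None
    births_last_3y: list = field(default_factory=list)
    births_last_5y: int = 0

    def validate(self) -> None:
        if self.sample_weight < 0:
            raise ValidationError("sample_weight", "must be >= 0")
        if not AGE_MIN <= self.age <= AGE_MAX:
            raise ValidationError("age", f"must be in [{AGE_MIN}, {AGE_MAX}]")
        if len(self.decision_answers) != len(DECISION_QUESTIONS):
            raise ValidationError("decision_answers", "needs five answers")
        if len(self.beating_justified) != len(BEATING_QUESTIONS):
            raise ValidationError("beating_justified", "needs five answers")
        for a in self.decision_answers:
            if a is not None and a not in DECISION_ANSWERS:
                raise ValidationError("decision_answers", f"unknown code {a!r}")
        for a in self.beating_justified:
            if a is not None and a not in BEATING_ANSWERS:
                raise ValidationError("beating_justified", f"unknown code {a!r}")
        if self.work_regularity is not None and self.work_regularity not in WORK_REGULARITY:
            raise ValidationError("work_regularity", f"unknown code {self.work_regularity!r}")
        if self.payment_type is not None and self.payment_type not in PAYMENT_TYPES:
            raise ValidationError("payment_type", f"unknown code {self.payment_type!r}")
        if self.births_last_5y < 0:
            raise ValidationError("births_last_5y", "must be >= 0")
        for b in self.births_last_3y:
            b.validate()


@dataclass
class ManRecord:
    respondent_id: str
    survey_id: str
    region_id: str
    sample_weight: float
    years_schooling: int | None = None
    literate: bool | None = None
    work_regularity: str | None = None
    payment_type: str | None = None

    def validate(self) -> None:
        if self.sample_weight < 0:
            raise ValidationError("sample_weight", "must be >= 0")
        if self.work_regularity is not None and self.work_regularity not in WORK_REGULARITY:
            raise ValidationError("work_regularity", f"unknown code {self.work_regularity!r}")
        if self.payment_type is not None and self.payment_type not in PAYMENT_TYPES:
            raise ValidationError("payment_type", f"unknown code {self.payment_type!r}")


@dataclass
class SurveyMeta:
    """Survey-level metadata.

    ``question_coverage`` is the set of question identifiers the survey
    actually asked; questions outside it are structurally missing for every
    respondent and must be treated as unobserved, not as empowered/default.
    """

    survey_id: str
    country_code: str
    survey_year: int
    scheme_id: str
    question_coverage: frozenset = ALL_QUESTIONS

    def validate(self) -> None:
        if not 1985 <= self.survey_year <= 2020:
            raise ValidationError("survey_year", "must be in [1985, 2020]")
        unknown = set(self.question_coverage) - ALL_QUESTIONS
        if unknown:
            raise ValidationError("question_coverage", f"unknown questions {sorted(unknown)}")
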