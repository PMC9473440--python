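"""Code survey answers into the six empowerment domain scores.

Every answer is coded on [0, 1] with 0 = disempowerment and 1 = empowerment.
Domains are means of their coded components; a component that was not asked
or not answered is dropped from the mean (partial availability), and a
domain with no available component is missing for that respondent.

Two implementations are provided: per-record functions operating on
:class:`~femi.records.WomanRecord` (the reference coding path), and
vectorized frame functions used by the pipeline; both must agree exactly.

The ``coverage`` argument carries the survey's question coverage.  It
matters for questions whose absence is informative: a missing age at first
marriage means "never married" (coded empowered) only when the survey
actually asked the question.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import (
    ALL_QUESTIONS,
    ADJUSTED_DOMAINS,
    BEATING_QUESTIONS,
    DECISION_EMPOWERED,
    DECISION_ANSWERS,
    DECISION_QUESTIONS,
    DOMAIN_DECISION,
    DOMAIN_EDUCATION,
    DOMAIN_EMPLOYMENT,
    DOMAIN_FP,
    DOMAIN_IPV,
    DOMAIN_RH,
    DOMAINS,
    ManRecord,
    WomanRecord,
)
from .io import SCORES_COLUMNS

#: Auxiliary (non-domain) respondent columns emitted by :func:`score_women`.
AUX_SCORES = ("ipv_sexual",)

_REGULARITY_CODE = {"all_year": 1.0, "part_year_or_seasonal": 0.5, "none": 0.0}
_PAYMENT_CODE = {"cash": 1.0, "cash_and_in_kind": 0.75, "in_kind_only": 0.5,
                 "unpaid": 0.0}

ADULT_AGE = 18  # marriage or first birth before this age codes as disempowerment
SCHOOLING_YEARS = 6  # completed primary school
ANTENATAL_FULL = 4  # WHO-recommended number of antenatal visits


# ---------------------------------------------------------------------------
# Category coders (smallest units of the coding scheme)
# ---------------------------------------------------------------------------


def antenatal_category(visits):
    """Code a birth's number of professional antenatal visits.

    0 visits -> 0, 1-3 visits -> 0.5 (some but less than the recommended
    care), 4 or more -> 1.  ``None`` propagates.
    """
    if visits is None:
        return None
    if visits == 0:
        return 0.0
    return 1.0 if visits >= ANTENATAL_FULL else 0.5


def regularity_subscore(work_regularity):
    """Work-regularity component: year-round 1, part-year/seasonal 0.5, none 0."""
    if work_regularity is None:
        return None
    return _REGULARITY_CODE[work_regularity]


def payment_subscore(payment_type, work_regularity=None):
    """Payment-type component: cash 1, cash+in-kind 0.75, in-kind 0.5, unpaid 0.

    Respondents with no employment receive 0 regardless of payment answer.
    """
    if work_regularity == "none":
        return 0.0
    if payment_type is None:
        return None
    return _PAYMENT_CODE[payment_type]


def decision_answer_value(answer):
    """Code one decision question: 1 if the respondent has a say."""
    if answer is None or answer not in DECISION_ANSWERS:
        return None
    return 1.0 if answer in DECISION_EMPOWERED else 0.0


def _mean(values):
    present = [v for v in values if v is not None]
    if not present:
        return None
    return float(sum(present)) / len(present)


# ---------------------------------------------------------------------------
# Per-record domain scores
# ---------------------------------------------------------------------------


def score_ipv(record: WomanRecord, coverage=ALL_QUESTIONS):
    """IPV domain: mean of the physical- and sexual-violence categories.

    Physical violence is the share of answered beating-justified questions
    answered "no".  Sexual violence is indicated by child marriage: 1 if the
    respondent married at 18 or later or never married, 0 if she married
    before 18; missing when the survey did not ask the marriage-age question
    or the respondent is married with an unknown marriage age.
    """
    answered = [a for a in record.beating_justified if a in ("yes", "no")]
    physical = None
    if answered:
        physical = sum(1.0 for a in answered if a == "no") / len(answered)

    if "age_first_marriage" not in coverage:
        sexual = None
    elif record.age_first_marriage is not None:
        sexual = 1.0 if record.age_first_marriage >= ADULT_AGE else 0.0
    elif not record.currently_married:
        sexual = 1.0  # never married: no child marriage occurred
    else:
        sexual = None
    return _mean([physical, sexual])


def score_employment(record):
    """Employment domain: mean of work-regularity and payment-type components."""
    reg = regularity_subscore(record.work_regularity)
    pay = payment_subscore(record.payment_type, record.work_regularity)
    return _mean([reg, pay])


def score_education(record):
    """Education domain: mean of primary-completion and literacy components."""
    schooling = None
    if record.years_schooling is not None:
        schooling = 1.0 if record.years_schooling >= SCHOOLING_YEARS else 0.0
    literacy = None if record.literate is None else float(record.literate)
    return _mean([schooling, literacy])


def score_reproductive_healthcare(record: WomanRecord, coverage=ALL_QUESTIONS):
    """Reproductive Healthcare: mean of four categories.

    Antenatal visits (0/0.5/1), professional delivery (0/1) and postnatal
    visit within two months (0/1) are each averaged over the respondent's
    births in the last three years; adolescent childbearing codes 1 if the
    first birth was at 18 or later (or the respondent has no children).
    """
    ante = _mean([antenatal_category(b.antenatal_visits) for b in record.births_last_3y])
    deliv = _mean([None if b.professional_delivery is None
                   else float(b.professional_delivery)
                   for b in record.births_last_3y])
    post = _mean([None if b.postnatal_within_2mo is None
                  else float(b.postnatal_within_2mo)
                  for b in record.births_last_3y])
    if "age_first_birth" not in coverage:
        adolescent = None
    elif record.age_first_birth is not None:
        adolescent = 1.0 if record.age_first_birth >= ADULT_AGE else 0.0
    else:
        adolescent = 1.0  # no children: no adolescent childbearing
    return _mean([ante, deliv, post, adolescent])


def score_decision_making(record: WomanRecord):
    """Decision-Making: share of answered questions where she has a say.

    Asked of currently married women; missing otherwise.
    """
    if not record.currently_married:
        return None
    return _mean([decision_answer_value(a) for a in record.decision_answers])


def score_family_planning(record: WomanRecord):
    """Family Planning: modern contraceptive use among married women who do
    not want a child within two years; everyone else is out of the
    denominator (missing)."""
    if not record.currently_married or record.wants_child_within_2y is not False:
        return None
    if record.uses_modern_contraception is None:
        return None
    return 1.0 if record.uses_modern_contraception else 0.0


def score_woman(record: WomanRecord, coverage=ALL_QUESTIONS) -> dict:
    """All six domain scores for one woman (None = not applicable/missing)."""
    return {
        DOMAIN_IPV: score_ipv(record, coverage),
        DOMAIN_FP: score_family_planning(record),
        DOMAIN_RH: score_reproductive_healthcare(record, coverage),
        DOMAIN_EMPLOYMENT: score_employment(record),
        DOMAIN_EDUCATION: score_education(record),
        DOMAIN_DECISION: score_decision_making(record),
    }


def score_man(record: ManRecord) -> dict:
    """Education and employment scores for one man (for the inequality ratio)."""
    return {
        DOMAIN_EMPLOYMENT: score_employment(record),
        DOMAIN_EDUCATION: score_education(record),
    }


# ---------------------------------------------------------------------------
# Vectorized scoring
# ---------------------------------------------------------------------------


def _frame_mean(components):
    """Row-wise mean over available (non-NaN) component columns."""
    stack = np.column_stack([np.asarray(c, dtype=float) for c in components])
    cnt = (~np.isnan(stack)).sum(axis=1)
    total = np.nansum(np.where(np.isnan(stack), 0.0, stack), axis=1)
    return np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)


def score_women(women: pd.DataFrame, births: pd.DataFrame,
                coverage=ALL_QUESTIONS) -> pd.DataFrame:
    """Respondent-level domain scores for a women microdata frame.

    Returns one row per woman with id/region/weight/age plus the six domain
    columns and the auxiliary ``ipv_sexual`` category (used by the
    age-cohort sensitivity check).
    """
    n = len(women)
    out = women[["respondent_id", "survey_id", "region_id",
                 "sample_weight", "age"]].copy()
    married = women.currently_married.to_numpy(dtype=float) == 1.0

    # IPV
    beat = women[list(BEATING_QUESTIONS)]
    answered = beat.isin(["yes", "no"]).to_numpy()
    saidno = (beat == "no").to_numpy()
    n_ans = answered.sum(axis=1)
    physical = np.where(n_ans > 0, saidno.sum(axis=1) / np.maximum(n_ans, 1), np.nan)
    afm = women.age_first_marriage.to_numpy(dtype=float)
    if "age_first_marriage" in coverage:
        sexual = np.where(~np.isnan(afm), (afm >= ADULT_AGE).astype(float),
                          np.where(~married, 1.0, np.nan))
    else:
        sexual = np.full(n, np.nan)
    out[DOMAIN_IPV] = _frame_mean([physical, sexual])
    out["ipv_sexual"] = sexual

    # Family planning
    wants = women.wants_child_within_2y.to_numpy(dtype=float)
    contra = women.uses_modern_contraception.to_numpy(dtype=float)
    eligible = married & (wants == 0.0)
    out[DOMAIN_FP] = np.where(eligible, contra, np.nan)

    # Reproductive healthcare
    if len(births):
        b = births.copy()
        visits = b.antenatal_visits.to_numpy(dtype=float)
        b["ante_code"] = np.where(np.isnan(visits), np.nan,
                                  np.where(visits == 0, 0.0,
                                           np.where(visits >= ANTENATAL_FULL, 1.0, 0.5)))
        cats = (b.groupby(["survey_id", "respondent_id"])
                 [["ante_code", "professional_delivery", "postnatal_within_2mo"]]
                 .mean())
        cats = out[["survey_id", "respondent_id"]].join(
            cats, on=["survey_id", "respondent_id"])
        ante = cats.ante_code.to_numpy(dtype=float)
        deliv = cats.professional_delivery.to_numpy(dtype=float)
        post = cats.postnatal_within_2mo.to_numpy(dtype=float)
    else:
        ante = deliv = post = np.full(n, np.nan)
    afb = women.age_first_birth.to_numpy(dtype=float)
    if "age_first_birth" in coverage:
        adolescent = np.where(~np.isnan(afb), (afb >= ADULT_AGE).astype(float), 1.0)
    else:
        adolescent = np.full(n, np.nan)
    out[DOMAIN_RH] = _frame_mean([ante, deliv, post, adolescent])

    # Employment / education
    out[DOMAIN_EMPLOYMENT] = _employment_frame(women)
    out[DOMAIN_EDUCATION] = _education_frame(women)

    # Decision-making (married women only)
    dec = women[list(DECISION_QUESTIONS)]
    dec_ans = dec.isin(list(DECISION_ANSWERS)).to_numpy()
    dec_yes = dec.isin(list(DECISION_EMPOWERED)).to_numpy()
    n_dec = dec_ans.sum(axis=1)
    dm = np.where(n_dec > 0, dec_yes.sum(axis=1) / np.maximum(n_dec, 1), np.nan)
    out[DOMAIN_DECISION] = np.where(married, dm, np.nan)
    return out


def _employment_frame(df):
    reg = df.work_regularity.map(_REGULARITY_CODE).to_numpy(dtype=float)
    pay = df.payment_type.map(_PAYMENT_CODE).to_numpy(dtype=float)
    pay = np.where(df.work_regularity.to_numpy() == "none", 0.0, pay)
    return _frame_mean([reg, pay])


def _education_frame(df):
    sch = df.years_schooling.to_numpy(dtype=float)
    schooling = np.where(np.isnan(sch), np.nan, (sch >= SCHOOLING_YEARS).astype(float))
    literacy = df.literate.to_numpy(dtype=float)
    return _frame_mean([schooling, literacy])


def score_men(men: pd.DataFrame) -> pd.DataFrame:
    out = men[["respondent_id", "survey_id", "region_id", "sample_weight"]].copy()
    out[DOMAIN_EMPLOYMENT] = _employment_frame(men)
    out[DOMAIN_EDUCATION] = _education_frame(men)
    return out


# ---------------------------------------------------------------------------
# Aggregation and the inequality adjustment
# ---------------------------------------------------------------------------


def weighted_group_means(scores: pd.DataFrame, value_columns,
                         use_sample_weights=True) -> pd.DataFrame:
    """Weighted mean and contributor count per (survey_id, region_id).

    The mean is over non-missing respondent scores only; ``<col>_n`` counts
    contributors (unweighted).  Groups where no respondent contributes to a
    column get NaN with count 0.
    """
    w = scores.sample_weight.to_numpy(dtype=float) if use_sample_weights \
        else np.ones(len(scores))
    parts = {}
    for col in value_columns:
        v = scores[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        parts[f"{col}__wv"] = np.where(ok, w * v, 0.0)
        parts[f"{col}__w"] = np.where(ok, w, 0.0)
        parts[f"{col}__n"] = ok.astype(float)
    tmp = pd.DataFrame(parts)
    tmp["survey_id"] = scores.survey_id.to_numpy()
    tmp["region_id"] = scores.region_id.to_numpy()
    g = tmp.groupby(["survey_id", "region_id"], sort=True).sum()
    out = pd.DataFrame(index=g.index)
    for col in value_columns:
        denom = g[f"{col}__w"]
        out[col] = np.where(denom > 0, g[f"{col}__wv"] / denom.replace(0, 1), np.nan)
        out[f"{col}_n"] = g[f"{col}__n"].astype(int)
    return out.reset_index()


def adjust_for_inequality(women_score, men_score):
    """Gender-inequality adjustment for Education and Employment.

    adjusted = women x (women / men), clamped to [0, 1]: areas where both
    genders score low are unaffected, areas where men outscore women are
    penalized.  A men's score of exactly 0 leaves the women's score
    unchanged (the ratio is undefined and no male advantage is evidenced).
    """
    if men_score == 0:
        return float(women_score)
    return float(min(1.0, max(0.0, women_score * (women_score / men_score))))


def adjust_series(women_raw, men_raw):
    """Vectorized :func:`adjust_for_inequality`; NaN in either input -> NaN."""
    w = np.asarray(women_raw, dtype=float)
    m = np.asarray(men_raw, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.clip(w * w / m, 0.0, 1.0)
    adj = np.where(m == 0, w, adj)
    return np.where(np.isnan(w) | np.isnan(m), np.nan, adj)


def finalize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the ``score`` column from women_raw/men_raw components."""
    out = table.copy()
    adjusted = out.domain.isin(ADJUSTED_DOMAINS)
    out["score"] = np.where(
        adjusted,
        adjust_series(out.women_raw, out.men_raw),
        out.women_raw,
    )
    return out


def build_region_scores(women_scores: pd.DataFrame, men_scores: pd.DataFrame,
                        use_sample_weights=True) -> pd.DataFrame:
    """Aggregate respondent scores to the region score table.

    One row per (survey, region, domain) with the women's weighted mean
    (``women_raw``), the men's mean for the adjusted domains (``men_raw``),
    the final ``score`` (inequality-adjusted for Education/Employment) and
    the contributing sample size.  Domains with no contributor in a region
    are emitted as missing rows (``effective_n = 0``) so imputation sees
    them.
    """
    wagg = weighted_group_means(women_scores, list(DOMAINS), use_sample_weights)
    magg = weighted_group_means(men_scores, list(ADJUSTED_DOMAINS),
                                use_sample_weights) if len(men_scores) else None

    rows = []
    for rec in wagg.itertuples(index=False):
        for domain in DOMAINS:
            women_raw = getattr(rec, domain)
            n = getattr(rec, f"{domain}_n")
            rows.append({
                "survey_id": rec.survey_id,
                "region_id": rec.region_id,
                "domain": domain,
                "women_raw": women_raw,
                "men_raw": np.nan,
                "effective_n": n,
                "provenance": "observed" if n > 0 else "missing",
            })
    table = pd.DataFrame(rows)
    if magg is not None:
        melted = magg.melt(id_vars=["survey_id", "region_id"],
                           value_vars=list(ADJUSTED_DOMAINS),
                           var_name="domain", value_name="men_value")
        table = table.merge(melted, on=["survey_id", "region_id", "domain"],
                            how="left")
        table["men_raw"] = table.men_value
        table = table.drop(columns=["men_value"])
    table = finalize_scores(table)
    return table[SCORES_COLUMNS]
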