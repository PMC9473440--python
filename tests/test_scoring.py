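"""Domain coding rules: worked examples, oracle equivalence, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femi import io as fio
from femi import scoring
from femi.records import ALL_QUESTIONS, DOMAINS, BirthEvent, WomanRecord

from helpers import random_woman
from oracles import oracle_scores


def woman(**kw):
    base = dict(respondent_id="W1", survey_id="S1", region_id="R1",
                sample_weight=1.0, age=30, currently_married=True)
    base.update(kw)
    return WomanRecord(**base)


class TestIPV:
    def test_fully_empowered(self):
        rec = woman(beating_justified=("no",) * 5, age_first_marriage=20)
        assert scoring.score_ipv(rec) == 1.0

    def test_mixed_attitudes_child_marriage(self):
        rec = woman(beating_justified=("yes", "yes", "no", "no", "no"),
                    age_first_marriage=16)
        assert scoring.score_ipv(rec) == pytest.approx((0.6 + 0.0) / 2)

    def test_attitudes_all_missing_uses_sexual_category_alone(self):
        rec = woman(beating_justified=(None,) * 5, age_first_marriage=16)
        assert scoring.score_ipv(rec) == 0.0

    def test_never_married_codes_empowered_for_child_marriage(self):
        rec = woman(currently_married=False, beating_justified=(None,) * 5)
        assert scoring.score_ipv(rec) == 1.0

    def test_marriage_age_question_not_asked_leaves_category_missing(self):
        rec = woman(currently_married=False, beating_justified=(None,) * 5)
        coverage = ALL_QUESTIONS - {"age_first_marriage"}
        assert scoring.score_ipv(rec, coverage) is None


class TestEmployment:
    @pytest.mark.parametrize("reg,pay,expected", [
        ("all_year", "cash", 1.0),
        ("all_year", "cash_and_in_kind", 0.875),
        ("part_year_or_seasonal", "in_kind_only", 0.5),
        ("none", None, 0.0),           # unemployed: payment component is 0
        ("part_year_or_seasonal", "unpaid", 0.25),
    ])
    def test_worked_examples(self, reg, pay, expected):
        rec = woman(work_regularity=reg, payment_type=pay)
        assert scoring.score_employment(rec) == pytest.approx(expected)

    def test_both_missing_is_missing(self):
        assert scoring.score_employment(woman()) is None


class TestEducation:
    @pytest.mark.parametrize("years,lit,expected", [
        (8, True, 1.0),
        (4, True, 0.5),
        (0, None, 0.0),  # single available component
        (None, None, None),
    ])
    def test_worked_examples(self, years, lit, expected):
        rec = woman(years_schooling=years, literate=lit)
        assert scoring.score_education(rec) == expected


class TestReproductiveHealthcare:
    def test_one_birth_partial_care(self):
        rec = woman(age_first_birth=19, births_last_3y=[
            BirthEvent(antenatal_visits=2, professional_delivery=True,
                       postnatal_within_2mo=False)])
        assert scoring.score_reproductive_healthcare(rec) == \
            pytest.approx((0.5 + 1 + 0 + 1) / 4)

    def test_no_births_ever_scores_adolescent_category_alone(self):
        assert scoring.score_reproductive_healthcare(woman()) == 1.0

    def test_full_care_but_adolescent_first_birth(self):
        rec = woman(age_first_birth=17, births_last_3y=[
            BirthEvent(antenatal_visits=5, professional_delivery=True,
                       postnatal_within_2mo=True)])
        assert scoring.score_reproductive_healthcare(rec) == \
            pytest.approx((1 + 1 + 1 + 0) / 4)

    def test_antenatal_thresholds(self):
        assert scoring.antenatal_category(0) == 0.0
        assert scoring.antenatal_category(1) == 0.5
        assert scoring.antenatal_category(3) == 0.5
        assert scoring.antenatal_category(4) == 1.0


class TestDecisionMaking:
    def test_half_empowered_over_answered_questions(self):
        rec = woman(decision_answers=("self", "self_and_partner",
                                      "partner_only", "partner_only", None))
        assert scoring.score_decision_making(rec) == 0.5

    def test_all_self(self):
        rec = woman(decision_answers=("self",) * 5)
        assert scoring.score_decision_making(rec) == 1.0

    def test_single_answered_question(self):
        rec = woman(decision_answers=("self", None, None, None, None))
        assert scoring.score_decision_making(rec) == 1.0

    def test_unmarried_not_in_denominator(self):
        rec = woman(currently_married=False, decision_answers=("self",) * 5)
        assert scoring.score_decision_making(rec) is None


class TestFamilyPlanning:
    def test_married_not_wanting_child_using_modern_method(self):
        rec = woman(wants_child_within_2y=False, uses_modern_contraception=True)
        assert scoring.score_family_planning(rec) == 1.0

    def test_wanting_child_excluded_from_denominator(self):
        rec = woman(wants_child_within_2y=True, uses_modern_contraception=False)
        assert scoring.score_family_planning(rec) is None

    def test_unmarried_excluded(self):
        rec = woman(currently_married=False, wants_child_within_2y=False,
                    uses_modern_contraception=True)
        assert scoring.score_family_planning(rec) is None


class TestInequalityAdjustment:
    @pytest.mark.parametrize("w,m,expected", [
        (0.5, 0.625, 0.4),
        (0.3, 0.3, 0.3),     # equality fixed point
        (0.9, 0.5, 1.0),     # 1.62 clamps to 1
        (0.4, 0.0, 0.4),     # no male advantage evidenced
        (0.0, 0.0, 0.0),
    ])
    def test_worked_examples(self, w, m, expected):
        assert scoring.adjust_for_inequality(w, m) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(w=st.floats(0, 1), m=st.floats(0.01, 1))
    def test_direction_matches_gender_gap(self, w, m):
        adj = scoring.adjust_for_inequality(w, m)
        assert 0.0 <= adj <= 1.0
        if m >= w:
            assert adj <= w + 1e-12
        else:
            assert adj >= min(w, 1.0) - 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(m=st.floats(0.05, 1), w1=st.floats(0, 1), w2=st.floats(0, 1))
    def test_monotone_in_womens_score_before_clamp(self, m, w1, w2):
        lo, hi = sorted([w1, w2])
        assert lo * lo / m <= hi * hi / m + 1e-12


def test_every_score_matches_independent_oracle(rng):
    records = [random_woman(rng, i) for i in range(1000)]
    for coverage in (ALL_QUESTIONS,
                     ALL_QUESTIONS - {"age_first_marriage", "age_first_birth"}):
        for rec in records:
            assert scoring.score_woman(rec, coverage) == \
                oracle_scores(rec, coverage)


def test_vectorized_path_matches_per_record(tmp_path, rng):
    from femi.records import SurveyMeta
    records = [random_woman(rng, i) for i in range(400)]
    w, b, m = fio.frames_from_records(records, [])
    meta = SurveyMeta("S1", "C01", 2010, "C01:admin1")
    fio.write_survey(tmp_path, w, b, m, {"S1": meta})
    bundle = fio.read_survey(tmp_path)
    frame = scoring.score_women(bundle.women, bundle.births, ALL_QUESTIONS)
    by_id = frame.set_index("respondent_id")
    for rec in records:
        expected = scoring.score_woman(rec, ALL_QUESTIONS)
        for domain, want in expected.items():
            got = by_id.loc[rec.respondent_id, domain]
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)


def test_scores_bounded_and_order_invariant(rng):
    records = [random_woman(rng, i) for i in range(200)]
    for rec in records:
        for v in scoring.score_woman(rec).values():
            assert v is None or 0.0 <= v <= 1.0
    w, b, _ = fio.frames_from_records(records, [])
    frame = scoring.score_women(*_typed(w, b))
    shuffled = w.sample(frac=1, random_state=0).reset_index(drop=True)
    frame2 = scoring.score_women(*_typed(shuffled, b))
    a = frame.sort_values("respondent_id").reset_index(drop=True)
    c = frame2.sort_values("respondent_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, c)


def _typed(w, b):
    from femi.io import _check_columns, _women_specs, _births_specs
    tw, _ = _check_columns(w, _women_specs(), "women")
    tb, _ = _check_columns(b, _births_specs(), "births")
    return tw, tb


class TestAggregation:
    def _scores(self, vals_weights):
        rows = []
        for i, (v, w) in enumerate(vals_weights):
            rows.append({"respondent_id": f"W{i}", "survey_id": "S1",
                         "region_id": "R1", "sample_weight": w, "age": 30,
                         "education": v})
        return pd.DataFrame(rows)

    def test_equal_weights_mean(self):
        agg = scoring.weighted_group_means(self._scores([(0.4, 1), (0.6, 1)]),
                                           ["education"])
        assert agg.education.iloc[0] == pytest.approx(0.5)
        assert agg.education_n.iloc[0] == 2

    def test_weighted_mean(self):
        agg = scoring.weighted_group_means(self._scores([(1.0, 3), (0.0, 1)]),
                                           ["education"])
        assert agg.education.iloc[0] == pytest.approx(0.75)

    def test_all_missing_gives_missing_row_with_zero_n(self):
        agg = scoring.weighted_group_means(
            self._scores([(np.nan, 1), (np.nan, 1)]), ["education"])
        assert np.isnan(agg.education.iloc[0])
        assert agg.education_n.iloc[0] == 0

    def test_region_table_emits_missing_domains(self, missing_sim):
        from helpers import score_bundle
        table = score_bundle(missing_sim.bundle)
        ipv = table[(table.survey_id == "C01-2006")
                    & (table.domain == "intimate_partner_violence")]
        assert (ipv.effective_n == 0).all()
        assert ipv.score.isna().all()
        # every (survey, region) emits all six domains
        counts = table.groupby(["survey_id", "region_id"]).domain.nunique()
        assert (counts == len(DOMAINS)).all()
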