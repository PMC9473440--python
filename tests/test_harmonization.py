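"""Boundary harmonization: arithmetic, aggregate preservation, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from femi.harmonize import (
    HarmonizationError,
    aggregate_admin2,
    build_plan,
    harmonize_bracketed,
    harmonize_scores,
    harmonize_single,
)
from femi.records import DOMAINS

from helpers import score_bundle


class TestBracketed:
    def test_linear_interpolation_between_neighbours(self):
        est, raw = harmonize_bracketed(
            observed={"G": 0.48}, groups={"G": ["r1"]},
            before={"r1": 0.4}, after={"r1": 0.6},
            t0=2000, t=2004, t1=2010, weights={"r1": 1.0})
        assert raw["r1"] == pytest.approx(0.48)

    def test_adjustment_factor_rescales_members(self):
        est, raw = harmonize_bracketed(
            observed={"G": 0.55}, groups={"G": ["r1", "r2"]},
            before={"r1": 0.48, "r2": 0.52}, after={"r1": 0.48, "r2": 0.52},
            t0=2000, t=2005, t1=2010, weights={"r1": 1.0, "r2": 1.0})
        assert raw["r1"] == pytest.approx(0.48 * 1.1)
        assert raw["r2"] == pytest.approx(0.52 * 1.1)

    def test_identity_when_observed_matches_interpolated_mean(self):
        est, raw = harmonize_bracketed(
            observed={"G": 0.5}, groups={"G": ["r1", "r2"]},
            before={"r1": 0.45, "r2": 0.55}, after={"r1": 0.45, "r2": 0.55},
            t0=2000, t=2005, t1=2010, weights={"r1": 1.0, "r2": 1.0})
        assert raw["r1"] == pytest.approx(0.45)
        assert raw["r2"] == pytest.approx(0.55)

    def test_zero_observed_mean_uses_additive_shift(self):
        est, raw = harmonize_bracketed(
            observed={"G": 0.0}, groups={"G": ["r1", "r2"]},
            before={"r1": 0.02, "r2": 0.06}, after={"r1": 0.02, "r2": 0.06},
            t0=2000, t=2005, t1=2010, weights={"r1": 1.0, "r2": 1.0})
        assert raw["r1"] == pytest.approx(-0.02)
        assert est["r1"] == 0.0 and est["r2"] == pytest.approx(0.02)

    def test_bad_year_ordering_rejected(self):
        with pytest.raises(HarmonizationError, match="before"):
            harmonize_bracketed({"G": 0.5}, {"G": ["r1"]}, {"r1": 0.4},
                                {"r1": 0.6}, 2010, 2004, 2000, {"r1": 1.0})

    def test_zero_weight_members_rejected(self):
        with pytest.raises(HarmonizationError, match="weight"):
            harmonize_bracketed({"G": 0.5}, {"G": ["r1"]}, {"r1": 0.4},
                                {"r1": 0.6}, 2000, 2004, 2010, {"r1": 0.0})


class TestSinglePredictor:
    def test_offset_downscaling(self):
        est, raw = harmonize_single(
            observed={"G": 0.46}, groups={"G": ["r1", "r2"]},
            predictor={"r1": 0.38, "r2": 0.42}, weights={"r1": 1, "r2": 1})
        assert raw["r1"] == pytest.approx(0.44)
        assert raw["r2"] == pytest.approx(0.48)

    def test_identity_when_observed_equals_aggregate(self):
        est, raw = harmonize_single(
            observed={"G": 0.40}, groups={"G": ["r1", "r2"]},
            predictor={"r1": 0.38, "r2": 0.42}, weights={"r1": 1, "r2": 1})
        assert raw == pytest.approx({"r1": 0.38, "r2": 0.42})

    def test_negative_offset_clamps_at_zero(self):
        est, raw = harmonize_single(
            observed={"G": 0.0}, groups={"G": ["r1", "r2"]},
            predictor={"r1": 0.02, "r2": 0.04}, weights={"r1": 1, "r2": 1})
        assert raw["r1"] == pytest.approx(-0.01)
        assert est == pytest.approx({"r1": 0.0, "r2": 0.01})

    def test_missing_admin1_unit_named_in_error(self):
        with pytest.raises(HarmonizationError, match="r2"):
            harmonize_single({"G": 0.4}, {"G": ["r1", "r2"]},
                             {"r1": 0.38}, {"r1": 1, "r2": 1})


class TestAdmin2Aggregation:
    def test_equal_weight_mean(self):
        out = aggregate_admin2({"a": 0.2, "b": 0.4}, {"A1": ["a", "b"]},
                               {"a": 1, "b": 1})
        assert out["A1"] == pytest.approx(0.3)

    def test_single_member_identity(self):
        out = aggregate_admin2({"a": 0.7}, {"A1": ["a"]}, {"a": 2.0})
        assert out["A1"] == pytest.approx(0.7)

    def test_weighted(self):
        out = aggregate_admin2({"a": 0.2, "b": 0.4}, {"A1": ["a", "b"]},
                               {"a": 1, "b": 3})
        assert out["A1"] == pytest.approx(0.35)

    def test_unmapped_unit_is_an_error(self):
        with pytest.raises(HarmonizationError, match="b"):
            aggregate_admin2({"a": 0.2}, {"A1": ["a", "b"]}, {"a": 1, "b": 1})


@pytest.fixture(scope="module")
def scheme_tables(scheme_sim):
    table = score_bundle(scheme_sim.bundle)
    plan = build_plan(scheme_sim.bundle.metas, scheme_sim.crosswalk)
    return table, plan


def test_auto_plan_brackets_the_middle_survey(scheme_tables):
    _, plan = scheme_tables
    sp = plan.surveys["C01-2007"]
    assert sp.method == "bracketed"
    assert sp.before_survey == "C01-2000" and sp.after_survey == "C01-2014"


def test_super_region_means_preserved_to_1e9(scheme_sim, scheme_tables):
    """Pre-clamp outputs must reproduce the observed aggregates exactly."""
    table, _ = scheme_tables
    meta = scheme_sim.bundle.metas["C01-2007"]
    cw = scheme_sim.crosswalk
    pop = dict(zip(scheme_sim.population.admin1_id,
                   scheme_sim.population.female_population))
    sub = table[table.survey_id == "C01-2007"]
    groups = {g: cw.members(meta.scheme_id, g) for g in sub.region_id.unique()}
    for domain in DOMAINS:
        observed = dict(zip(sub[sub.domain == domain].region_id,
                            sub[sub.domain == domain].score))
        before = dict(zip(table[(table.survey_id == "C01-2000")
                                & (table.domain == domain)].region_id,
                          table[(table.survey_id == "C01-2000")
                                & (table.domain == domain)].score))
        after = dict(zip(table[(table.survey_id == "C01-2014")
                               & (table.domain == domain)].region_id,
                         table[(table.survey_id == "C01-2014")
                               & (table.domain == domain)].score))
        _, raw = harmonize_bracketed(observed, groups, before, after,
                                     2000, 2007, 2014, pop)
        for g, members in groups.items():
            w = np.array([pop[r] for r in members])
            v = np.array([raw[r] for r in members])
            assert abs((v * w).sum() / w.sum() - observed[g]) < 1e-9
        # offset preservation for the single-predictor variant too
        _, raw_s = harmonize_single(observed, groups, after, pop)
        for g, members in groups.items():
            w = np.array([pop[r] for r in members])
            v = np.array([raw_s[r] for r in members])
            assert abs((v * w).sum() / w.sum() - observed[g]) < 1e-9


def test_admin1_surveys_pass_through_unchanged(scheme_sim, scheme_tables):
    table, plan = scheme_tables
    out = harmonize_scores(table, scheme_sim.bundle.metas, scheme_sim.crosswalk,
                           scheme_sim.population, plan)
    for sid in ("C01-2000", "C01-2014"):
        a = table[table.survey_id == sid].reset_index(drop=True)
        b = out[out.survey_id == sid].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


def test_harmonized_values_recover_latent_truth(scheme_sim, scheme_tables):
    table, plan = scheme_tables
    out = harmonize_scores(table, scheme_sim.bundle.metas, scheme_sim.crosswalk,
                           scheme_sim.population, plan)
    h = out[out.survey_id == "C01-2007"]
    assert (h.provenance == "interpolated").all()
    assert h.region_id.nunique() == 4  # back on admin-1 units
    gt = scheme_sim.ground_truth
    truth = gt[gt.year == 2007].set_index(["admin1_id", "domain"]).latent
    est, ref = [], []
    for rec in h.itertuples(index=False):
        est.append(rec.score)
        ref.append(truth.loc[(rec.region_id, rec.domain)])
    r, _ = stats.pearsonr(est, ref)
    assert r > 0.9
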