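"""FEMI composite, weighted quantiles, correlations, regressions, cohorts."""

import numpy as np
import pandas as pd
import pytest

from femi.records import DOMAINS, FEMI
from femi.simulate import SimulationConfig, simulate
from femi.summaries import (
    SummaryError,
    cohort_sensitivity,
    compute_femi,
    country_femi,
    country_subnational_range,
    domain_correlations,
    national_regressions,
    weighted_quantiles,
)


def _estimates(domain_values, region="R1", year=2015, country="C01"):
    return pd.DataFrame([
        {"admin1_id": region, "country_code": country, "year": year,
         "domain": d, "estimate": v, "method": "direct", "n_surveys_used": 1}
        for d, v in domain_values.items()])


class TestFemi:
    def test_mean_of_six_domains(self):
        vals = dict(zip(DOMAINS, [0.3, 0.4, 0.5, 0.6, 0.7, 0.8]))
        out = compute_femi(_estimates(vals))
        femi = out[out.domain == FEMI]
        assert femi.estimate.iloc[0] == pytest.approx(0.55)

    @pytest.mark.parametrize("c", [0.0, 0.37, 1.0])
    def test_constant_domains_give_constant_femi(self, c):
        out = compute_femi(_estimates(dict.fromkeys(DOMAINS, c)))
        assert out[out.domain == FEMI].estimate.iloc[0] == pytest.approx(c)

    def test_missing_domain_is_an_error_naming_the_cell(self):
        vals = dict(zip(DOMAINS[:5], [0.5] * 5))
        with pytest.raises(SummaryError, match="R1/2015"):
            compute_femi(_estimates(vals))

    def test_median_combiner_switch(self):
        vals = dict(zip(DOMAINS, [0.0, 0.0, 0.5, 0.5, 0.5, 1.0]))
        mean_out = compute_femi(_estimates(vals), combiner="mean")
        med_out = compute_femi(_estimates(vals), combiner="median")
        assert mean_out[mean_out.domain == FEMI].estimate.iloc[0] == \
            pytest.approx(2.5 / 6)
        assert med_out[med_out.domain == FEMI].estimate.iloc[0] == \
            pytest.approx(0.5)

    def test_idempotent_and_order_invariant(self):
        vals = dict(zip(DOMAINS, [0.3, 0.4, 0.5, 0.6, 0.7, 0.8]))
        est = _estimates(vals)
        once = compute_femi(est)
        twice = compute_femi(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = est.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(compute_femi(shuffled), once)


class TestWeightedQuantiles:
    def test_equal_weights_median(self):
        assert weighted_quantiles([0.2, 0.5, 0.8], [1, 1, 1], 0.5) == 0.5

    def test_unequal_weights_hand_oracle(self):
        # cumulative normalized weights: 0.25, 0.5, 1.0 -> q=0.5 lands on 0.5
        assert weighted_quantiles([0.2, 0.5, 0.8], [1, 1, 2], 0.5) == 0.5

    def test_q_zero_is_minimum(self):
        assert weighted_quantiles([0.9, 0.1, 0.4], [1, 1, 1], 0.0) == 0.1

    def test_q_one_is_maximum(self):
        assert weighted_quantiles([0.9, 0.1, 0.4], [1, 1, 1], 1.0) == 0.9

    def test_equal_weights_match_inverted_cdf_quantile(self, rng):
        v = rng.random(101)
        for q in (0.1, 0.25, 0.5, 0.9):
            ours = weighted_quantiles(v, np.ones_like(v), q)
            ref = np.quantile(v, q, method="inverted_cdf")
            assert ours == pytest.approx(ref)

    def test_heavy_weight_dominates(self):
        assert weighted_quantiles([0.1, 0.9], [1, 100], 0.5) == 0.9

    def test_errors(self):
        with pytest.raises(SummaryError):
            weighted_quantiles([], [], 0.5)
        with pytest.raises(SummaryError):
            weighted_quantiles([1.0], [-1.0], 0.5)


class TestSubnationalRange:
    def _country(self, values, weights=None):
        n = len(values)
        est = pd.DataFrame([
            {"admin1_id": f"R{i}", "country_code": "C01", "year": 2015,
             "domain": FEMI, "estimate": v, "method": "direct",
             "n_surveys_used": 1} for i, v in enumerate(values)])
        pop = pd.DataFrame({
            "admin1_id": [f"R{i}" for i in range(n)], "country_code": "C01",
            "longitude": 0.0, "latitude": 0.0,
            "female_population": weights or [1.0] * n,
            "population_density": 10.0})
        return est, pop

    def test_identical_regions_have_zero_range(self):
        est, pop = self._country([0.4] * 5)
        out = country_subnational_range(est, pop, "C01", 2015)
        assert out.value.iloc[0] == 0.0

    def test_two_regions(self):
        est, pop = self._country([0.2, 0.8])
        out = country_subnational_range(est, pop, "C01", 2015)
        assert out.value.iloc[0] == pytest.approx(0.6)

    def test_decile_grid_matches_quantile_oracle(self):
        vals = [round(0.1 * i, 1) for i in range(1, 11)]
        est, pop = self._country(vals)
        out = country_subnational_range(est, pop, "C01", 2015)
        p10, p90 = weighted_quantiles(vals, [1] * 10, [0.1, 0.9])
        assert out.value.iloc[0] == pytest.approx(p90 - p10)

    def test_single_region_flagged(self):
        est, pop = self._country([0.4])
        out = country_subnational_range(est, pop, "C01", 2015)
        assert out.value.iloc[0] == 0.0
        assert "single-region" in out.diagnostic.iloc[0]


class TestCorrelations:
    def test_self_correlation_and_exact_linear(self, rng):
        x = rng.random(50)
        wide = pd.DataFrame({
            "education": x, "employment": 2 * x + 1,
            "family_planning": rng.random(50)})
        corr = domain_correlations(wide)
        assert corr.loc["education", "education"] == 1.0
        assert corr.loc["education", "employment"] == pytest.approx(1.0)

    def test_independent_domains_have_near_zero_correlation(self):
        """Sampling null: |r| < 0.15 at n=500 across 100 seeds."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            wide = pd.DataFrame({"education": r.random(500),
                                 "employment": r.random(500)})
            c = domain_correlations(wide).loc["education", "employment"]
            assert abs(c) < 0.15

    def test_zero_variance_domain_flagged_not_crashing(self):
        wide = pd.DataFrame({"education": [0.5, 0.5, 0.5, 0.5],
                             "employment": [0.1, 0.2, 0.3, 0.4]})
        corr = domain_correlations(wide)
        assert np.isnan(corr.loc["education", "employment"])

    def test_too_few_units_rejected(self):
        with pytest.raises(SummaryError):
            domain_correlations(pd.DataFrame({"education": [0.1, 0.2]}))


class TestNationalRegressions:
    def _cov(self, n, rng, gdp=None):
        return pd.DataFrame({
            "country_code": [f"C{i:02d}" for i in range(n)],
            "year": 2015,
            "hdi": rng.uniform(0.3, 0.7, n),
            "maternal_mortality": rng.uniform(100, 900, n),
            "gdp_per_capita": gdp if gdp is not None
            else rng.uniform(500, 20000, n),
            "gdi": rng.uniform(0.7, 1.0, n),
            "gii": rng.uniform(0.3, 0.7, n),
        })

    def test_exact_linear_relation_gives_unit_correlation(self, rng):
        cov = self._cov(10, rng)
        femi = pd.Series(0.1 + 0.8 * cov.hdi.values,
                         index=cov.country_code.values)
        out = national_regressions(femi, cov, 2015)
        hdi = out[out["index"] == "hdi"].set_index("statistic")
        assert hdi.loc["pearson_r", "value"] == pytest.approx(1.0)
        resid = out[(out["index"] == "hdi") & (out.statistic == "residual")]
        assert np.allclose(resid.value, 0.0, atol=1e-12)

    def test_degenerate_design_is_an_error(self, rng):
        cov = self._cov(5, rng)
        cov["hdi"] = 0.5
        femi = pd.Series(rng.random(5), index=cov.country_code.values)
        with pytest.raises(SummaryError, match="degenerate"):
            national_regressions(femi, cov, 2015)

    def test_log_gdp_slope_recovery(self, rng):
        n = 40
        gdp = 10 ** rng.uniform(2.5, 4.5, n)
        cov = self._cov(n, rng, gdp=gdp)
        noise = np.random.default_rng(7).normal(0, 0.01, n)
        femi = pd.Series(0.2 + 0.1 * np.log10(gdp) + noise,
                         index=cov.country_code.values)
        out = national_regressions(femi, cov, 2015)
        slope = out[(out["index"] == "log10_gdp")
                    & (out.statistic == "ols_slope")].value.iloc[0]
        assert slope == pytest.approx(0.1, abs=0.01)

    def test_country_missing_index_dropped_with_diagnostic(self, rng):
        cov = self._cov(6, rng)
        cov.loc[0, "gdi"] = np.nan
        femi = pd.Series(rng.random(6), index=cov.country_code.values)
        out = national_regressions(femi, cov, 2015)
        drop = out[(out["index"] == "gdi") & (out.statistic == "n_dropped")]
        assert drop.value.iloc[0] == 1 and "C00" in drop.country_code.iloc[0]


class TestCohortSensitivity:
    @staticmethod
    def _flat(n=2000, boost=0.0, seed=1):
        cfg = SimulationConfig(
            n_countries=1, regions_per_country=1, survey_years=(2010,),
            n_women_per_region=n, n_men_per_region=10, region_noise_sd=0.0,
            lat_gradients=dict.fromkeys(DOMAINS, 0.0),
            trends=dict.fromkeys(DOMAINS, 0.0),
            education_youth_boost=boost, country_spread=0.0)
        return simulate(cfg, seed=seed)

    def test_identical_subsamples_give_exact_zero(self):
        res = self._flat(n=800)
        w = res.bundle.women
        young = w[(w.age >= 18) & (w.age <= 30)].reset_index(drop=True)
        out = cohort_sensitivity(young, res.bundle.births)
        assert all(v == 0.0 for v in out.values())

    def test_age_homogeneous_population_has_no_cohort_effect(self):
        res = self._flat(n=50_000, seed=9)
        out = cohort_sensitivity(res.bundle.women, res.bundle.births)
        for domain, delta in out.items():
            assert abs(delta) < 0.01, (domain, delta)

    def test_injected_youth_boost_recovered(self):
        boost = 0.1
        res = self._flat(n=50_000, boost=boost, seed=13)
        w = res.bundle.women
        out = cohort_sensitivity(w, res.bundle.births)
        # the 18-49 reference sample contains the boosted 18-30 women, so
        # the expected difference is boost * (1 - share of 18-30 in 18-49)
        adult = w[w.age >= 18]
        share = (adult.age <= 30).mean()
        assert out["education"] == pytest.approx(boost * (1 - share), abs=0.02)


def test_country_femi_is_population_weighted(rng):
    est = pd.DataFrame([
        {"admin1_id": "R1", "country_code": "C01", "year": 2015,
         "domain": FEMI, "estimate": 0.2, "method": "direct", "n_surveys_used": 1},
        {"admin1_id": "R2", "country_code": "C01", "year": 2015,
         "domain": FEMI, "estimate": 0.8, "method": "direct", "n_surveys_used": 1},
    ])
    pop = pd.DataFrame({"admin1_id": ["R1", "R2"], "country_code": "C01",
                        "longitude": 0.0, "latitude": 0.0,
                        "female_population": [3.0, 1.0],
                        "population_density": 10.0})
    out = country_femi(est, pop, 2015)
    assert out["C01"] == pytest.approx(0.35)
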