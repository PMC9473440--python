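"""Region x domain estimates at fixed reference years (1995, 2005, 2015).

Per country and reference year the method is chosen by availability:

* **direct** — a survey lies within ±2 years of the reference year; its
  harmonized scores are reassigned to that year (nearest survey; ties go to
  the later fieldwork).
* **linear** — otherwise, with two or more surveys, an ordinary
  least-squares line through each region's (year, score) points is
  evaluated at the reference year.
* **rf** — with at most one survey, a Random Forest trained on all pooled
  direct/linear region-year estimates predicts from country covariates
  (HDI, maternal mortality), the region's population density, and the
  region's own survey value when one exists.

All estimates are clamped to [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io import ESTIMATES_COLUMNS
from .records import DOMAINS

DEFAULT_REFERENCE_YEARS = (1995, 2005, 2015)
DIRECT_WINDOW = 2  # +/- years around a reference year
N_TREES = 500


class EstimationError(ValueError):
    pass


def select_method(survey_years, reference_year: int) -> str:
    """The three-way rule: direct within ±2 years, else linear with >= 2
    surveys, else rf."""
    years = list(survey_years)
    if any(abs(y - reference_year) <= DIRECT_WINDOW for y in years):
        return "direct"
    if len(years) >= 2:
        return "linear"
    return "rf"


def pick_direct_survey(survey_years, reference_year: int):
    """Nearest qualifying survey year; equidistant ties pick the later one."""
    qualifying = [y for y in survey_years
                  if abs(y - reference_year) <= DIRECT_WINDOW]
    if not qualifying:
        raise EstimationError(f"no survey within {DIRECT_WINDOW} years of "
                              f"{reference_year}")
    return min(qualifying, key=lambda y: (abs(y - reference_year), -y))


def extrapolate_linear(series, reference_year: int) -> float:
    """OLS line through (year, score) points, evaluated at reference_year.

    Falls back to the plain mean when all observations share one year.
    """
    pts = [(float(y), float(v)) for y, v in series]
    if len(pts) < 2:
        raise EstimationError("linear trend needs >= 2 observations")
    years = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    if np.ptp(years) == 0:
        return float(np.clip(vals.mean(), 0.0, 1.0))
    slope, intercept = np.polyfit(years, vals, 1)
    return float(np.clip(slope * reference_year + intercept, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------


def _covariate_lookup(covariates, country, year):
    sel = covariates[(covariates.country_code == country)
                     & (covariates.year == year)]
    if not len(sel):
        raise EstimationError(f"missing covariates for {country} {year}")
    row = sel.iloc[0]
    if np.isnan(row.hdi) or np.isnan(row.maternal_mortality):
        raise EstimationError(f"missing covariates for {country} {year}")
    return float(row.hdi), float(row.maternal_mortality)


def estimate_reference_years(harmonized: pd.DataFrame, metas,
                             covariates: pd.DataFrame,
                             population: pd.DataFrame,
                             reference_years=DEFAULT_REFERENCE_YEARS,
                             seed: int = 0) -> pd.DataFrame:
    """Produce the admin-1 x reference-year x domain estimate table.

    ``harmonized`` must be on admin-1 region ids (post-harmonization) with
    no missing scores.  Every (region, reference year, domain) receives
    exactly one estimate with exactly one method label.
    """
    country_of_survey = {sid: m.country_code for sid, m in metas.items()}
    year_of_survey = {sid: m.survey_year for sid, m in metas.items()}
    h = harmonized.copy()
    h["country_code"] = h.survey_id.map(country_of_survey)
    h["survey_year"] = h.survey_id.map(year_of_survey)

    region_country = (h[["region_id", "country_code"]]
                      .drop_duplicates().set_index("region_id").country_code)
    density = population.set_index("admin1_id").population_density

    surveys_by_country = {}
    for sid, m in metas.items():
        surveys_by_country.setdefault(m.country_code, set()).add(m.survey_year)

    rows = []
    covered = set()  # (region, ref_year) pairs already estimated
    countries = sorted(population.country_code.unique())
    for country in countries:
        years_avail = sorted(surveys_by_country.get(country, ()))
        ch = h[h.country_code == country]
        for ref_year in reference_years:
            method = select_method(years_avail, ref_year)
            if method == "direct":
                use_year = pick_direct_survey(years_avail, ref_year)
                sel = ch[ch.survey_year == use_year]
                for rec in sel.itertuples(index=False):
                    covered.add((rec.region_id, ref_year))
                    rows.append({
                        "admin1_id": rec.region_id, "country_code": country,
                        "year": ref_year, "domain": rec.domain,
                        "estimate": float(np.clip(rec.score, 0.0, 1.0)),
                        "method": "direct",
                        "n_surveys_used": 1,
                    })
            elif method == "linear":
                for region in sorted(ch.region_id.unique()):
                    rsel = ch[ch.region_id == region]
                    # a region covered by fewer than two surveys (partial-
                    # coverage fieldwork) falls through to the RF branch
                    if rsel.survey_year.nunique() < 2:
                        continue
                    covered.add((region, ref_year))
                    for domain in DOMAINS:
                        pts = rsel[rsel.domain == domain]
                        series = list(zip(pts.survey_year, pts.score))
                        rows.append({
                            "admin1_id": region, "country_code": country,
                            "year": ref_year, "domain": domain,
                            "estimate": extrapolate_linear(series, ref_year),
                            "method": "linear",
                            "n_surveys_used": len(series),
                        })

    # everything not yet covered — unsurveyed countries, regions outside a
    # partial survey's footprint, or single-survey regions — goes to the RF
    rf_targets = []
    for rec in population.itertuples(index=False):
        for ref_year in reference_years:
            if (rec.admin1_id, ref_year) not in covered:
                rf_targets.append((rec.admin1_id, rec.country_code, ref_year))

    est = pd.DataFrame(rows, columns=ESTIMATES_COLUMNS)

    if rf_targets:
        est = pd.concat([est, _extrapolate_rf_table(
            est, h, rf_targets, covariates, density, region_country, seed)],
            ignore_index=True)
    return est.sort_values(["country_code", "admin1_id", "year", "domain"]) \
              .reset_index(drop=True)


def _nearest_survey_value(h, region, domain, year):
    sel = h[(h.region_id == region) & (h.domain == domain)]
    if not len(sel):
        return np.nan
    i = (sel.survey_year - year).abs().idxmin()
    return float(sel.loc[i, "score"])


def _extrapolate_rf_table(trained_est, h, targets, covariates, density,
                          region_country, seed):
    """RF branch: one model per domain, pooled over all direct/linear rows."""
    train = trained_est[trained_est.method.isin(["direct", "linear"])]
    if not len(train):
        raise EstimationError("no direct/linear estimates to train the "
                              "extrapolation forest on")
    rows = []
    for di, domain in enumerate(DOMAINS):
        tsub = train[train.domain == domain]
        feats, y = [], []
        for rec in tsub.itertuples(index=False):
            hdi, mm = _covariate_lookup(covariates, rec.country_code, rec.year)
            sv = _nearest_survey_value(h, rec.admin1_id, domain, rec.year)
            feats.append([hdi, mm, float(density.get(rec.admin1_id, np.nan)),
                          sv, 0.0 if np.isnan(sv) else 1.0])
            y.append(rec.estimate)
        X = np.asarray(feats)
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), med, X)
        rf = RandomForestRegressor(n_estimators=N_TREES,
                                   random_state=(int(seed) * 13 + di) % (2 ** 31),
                                   n_jobs=1)
        rf.fit(X, np.asarray(y))
        for region, country, ref_year in targets:
            hdi, mm = _covariate_lookup(covariates, country, ref_year)
            sv = _nearest_survey_value(h, region, domain, ref_year)
            x = np.array([[hdi, mm, float(density.get(region, np.nan)),
                           sv, 0.0 if np.isnan(sv) else 1.0]])
            x = np.where(np.isnan(x), med, x)
            n_used = int(not np.isnan(sv))
            rows.append({
                "admin1_id": region, "country_code": country,
                "year": ref_year, "domain": domain,
                "estimate": float(np.clip(rf.predict(x)[0], 0.0, 1.0)),
                "method": "rf", "n_surveys_used": n_used,
            })
    return pd.DataFrame(rows, columns=ESTIMATES_COLUMNS)
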