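"""Random-Forest imputation of missing region-level domain scores.

Surveys (older ones especially) may omit whole question blocks, leaving a
(survey, region, domain) score unobserved.  Those cells are estimated by a
Random-Forest regression pooled across all surveys, one model per score
series, trained on the observed cells.

Predictors for the women's series: survey year, country (one-hot), region
means of age at first marriage, age at first birth, years of education,
respondent age and births in the last five years, plus the region centroid
longitude/latitude.  The education model drops the years-of-education mean
(it is the outcome in disguise).  Men's Education/Employment series use
year, longitude and latitude only.

Observed cells are never altered; imputed values are clamped to [0, 1] and
flagged ``provenance = "imputed"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .records import ADJUSTED_DOMAINS, DOMAIN_EDUCATION, DOMAINS
from .scoring import finalize_scores

N_TREES = 500
MIN_OBSERVED = 20  # below this, a pooled fit is too degenerate to trust

BASE_PREDICTORS = [
    "survey_year", "country_code", "mean_age_first_marriage",
    "mean_age_first_birth", "mean_years_schooling", "longitude", "latitude",
    "mean_age", "mean_births_5y",
]
MEN_PREDICTORS = ["survey_year", "longitude", "latitude"]

FEATURE_COLUMNS = ["survey_id", "region_id"] + BASE_PREDICTORS


@dataclass
class ImputationReport:
    domain: str
    series: str  # "women" or "men"
    n_missing: int
    n_imputed: int
    proportion_imputed: float
    oob_r2: float
    predictors: tuple
    skipped: bool = False
    message: str = ""


def build_region_features(bundle, crosswalk, population) -> pd.DataFrame:
    """Per-(survey, region) predictor table from microdata and geography.

    Region centroids are the mean of the member admin-1 centroids from the
    population table, resolved through the survey's region scheme.
    """
    w = bundle.women
    feats = (w.groupby(["survey_id", "region_id"])
              .agg(mean_age_first_marriage=("age_first_marriage", "mean"),
                   mean_age_first_birth=("age_first_birth", "mean"),
                   mean_years_schooling=("years_schooling", "mean"),
                   mean_age=("age", "mean"),
                   mean_births_5y=("births_last_5y", "mean"))
              .reset_index())
    pop = population.set_index("admin1_id")
    lons, lats, years, countries = [], [], [], []
    for rec in feats.itertuples(index=False):
        meta = bundle.metas[rec.survey_id]
        members = crosswalk.members(meta.scheme_id, rec.region_id)
        if not members:
            members = [rec.region_id]
        lons.append(float(pop.loc[members, "longitude"].mean()))
        lats.append(float(pop.loc[members, "latitude"].mean()))
        years.append(meta.survey_year)
        countries.append(meta.country_code)
    feats["longitude"] = lons
    feats["latitude"] = lats
    feats["survey_year"] = years
    feats["country_code"] = countries
    return feats[FEATURE_COLUMNS]


def _design_matrix(features: pd.DataFrame, predictors):
    X = features.loc[:, [p for p in predictors if p != "country_code"]].copy()
    if "country_code" in predictors:
        X = pd.concat([X, pd.get_dummies(features.country_code,
                                         prefix="country", dtype=float)], axis=1)
    med = X.median(numeric_only=True)
    return X.fillna(med).fillna(0.0)


def _impute_series(table, features, value_col, domain, series_name,
                   predictors, seed):
    """Fill missing ``value_col`` cells for one domain; returns report."""
    sel = table.domain == domain
    sub = table.loc[sel]
    missing = sub[value_col].isna()
    n_missing = int(missing.sum())
    n_observed = int((~missing).sum())
    if n_missing == 0:
        return ImputationReport(domain, series_name, 0, 0, 0.0, np.nan,
                                tuple(predictors))
    if n_observed < MIN_OBSERVED:
        return ImputationReport(
            domain, series_name, n_missing, 0, 0.0, np.nan, tuple(predictors),
            skipped=True,
            message=f"only {n_observed} observed rows (< {MIN_OBSERVED})")

    feat = sub[["survey_id", "region_id"]].merge(
        features, on=["survey_id", "region_id"], how="left", validate="m:1")
    absent = [p for p in predictors if p not in feat.columns]
    if absent:
        raise KeyError(f"region features missing columns {absent}")
    X = _design_matrix(feat, predictors)
    y = sub[value_col].to_numpy(dtype=float)
    obs = ~missing.to_numpy()
    rf = RandomForestRegressor(n_estimators=N_TREES, oob_score=True,
                               random_state=int(seed) % (2 ** 31),
                               n_jobs=1)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small samples can starve OOB
        rf.fit(X[obs], y[obs])
        oob = float(getattr(rf, "oob_score_", np.nan))
    pred = np.clip(rf.predict(X[~obs]), 0.0, 1.0)
    idx = sub.index[missing]
    table.loc[idx, value_col] = pred
    table.loc[idx, "provenance"] = "imputed"
    return ImputationReport(domain, series_name, n_missing, n_missing,
                            n_missing / len(sub), oob, tuple(predictors))


def impute_missing(scores: pd.DataFrame, region_features: pd.DataFrame,
                   seed: int = 0):
    """Impute missing region scores; returns (table, reports).

    The women's series (``women_raw``) of every domain and the men's series
    (``men_raw``) of the adjusted domains are imputed independently; the
    final ``score`` column (inequality-adjusted where applicable) is then
    recomputed.  Observed cells are returned bit-identical.
    """
    table = scores.copy()
    reports = []
    for i, domain in enumerate(DOMAINS):
        predictors = [p for p in BASE_PREDICTORS
                      if not (domain == DOMAIN_EDUCATION
                              and p == "mean_years_schooling")]
        reports.append(_impute_series(table, region_features, "women_raw",
                                      domain, "women", predictors,
                                      seed * 97 + i))
    for j, domain in enumerate(ADJUSTED_DOMAINS):
        reports.append(_impute_series(table, region_features, "men_raw",
                                      domain, "men", MEN_PREDICTORS,
                                      seed * 97 + 50 + j))
    table = finalize_scores(table)
    return table, reports


def report_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([{
        "domain": r.domain, "series": r.series, "n_missing": r.n_missing,
        "n_imputed": r.n_imputed, "proportion_imputed": r.proportion_imputed,
        "oob_r2": r.oob_r2, "predictors": ";".join(r.predictors),
        "skipped": r.skipped, "message": r.message,
    } for r in reports])
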