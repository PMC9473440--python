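"""The FEMI composite and the study's summary statistics.

The Female Empowerment Index (FEMI) is the arithmetic mean of the six
domain estimates per region and year (a median combiner is available as a
switch).  Summary statistics are population-weighted: region scores are
weighted by female population when computing continental or national
medians and percentile bands.

The weighted quantile rule used throughout is left-continuous: quantile q
is the smallest value whose cumulative normalized weight reaches q.  With
equal weights this reduces to the "inverted CDF" empirical quantile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import DOMAINS, FEMI
from .scoring import score_women

SUMMARY_STATS = ("median", "p10", "p90", "iqr_10_90")


class SummaryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FEMI
# ---------------------------------------------------------------------------


def compute_femi(estimates: pd.DataFrame, combiner: str = "mean") -> pd.DataFrame:
    """Append FEMI rows (one per region-year) to an estimate table.

    Requires all six domains per (region, year); a missing domain is an
    error naming the offending cell.
    """
    if combiner not in ("mean", "median"):
        raise SummaryError(f"unknown combiner {combiner!r}")
    est = estimates[estimates.domain != FEMI]
    rows = []
    for (region, year), grp in est.groupby(["admin1_id", "year"], sort=True):
        present = set(grp.domain)
        missing = [d for d in DOMAINS if d not in present]
        if missing:
            raise SummaryError(f"{region}/{year}: missing domains {missing}")
        vals = grp.set_index("domain").loc[list(DOMAINS), "estimate"].to_numpy()
        if np.isnan(vals).any():
            raise SummaryError(f"{region}/{year}: NaN domain estimate")
        value = float(np.mean(vals)) if combiner == "mean" else float(np.median(vals))
        rows.append({
            "admin1_id": region,
            "country_code": grp.country_code.iloc[0],
            "year": year, "domain": FEMI, "estimate": value,
            "method": "composite",
            "n_surveys_used": int(grp.n_surveys_used.max()),
        })
    out = pd.concat([est, pd.DataFrame(rows)], ignore_index=True)
    return (out.sort_values(["country_code", "admin1_id", "year", "domain"])
               .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Weighted quantiles
# ---------------------------------------------------------------------------


def weighted_quantiles(values, weights, probs):
    """Left-continuous weighted quantiles.

    Quantile q is the smallest value v (ascending order) whose cumulative
    normalized weight is >= q.  Weights must be nonnegative with a positive
    total.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise SummaryError("empty input")
    if (w < 0).any() or w.sum() <= 0:
        raise SummaryError("weights must be nonnegative with positive total")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    out = []
    for q in np.atleast_1d(probs):
        if not 0 <= q <= 1:
            raise SummaryError(f"quantile {q} outside [0, 1]")
        idx = int(np.searchsorted(cum, q, side="left"))
        out.append(float(v[min(idx, len(v) - 1)]))
    return out if np.ndim(probs) else out[0]


def _band(values, weights):
    p10, med, p90 = weighted_quantiles(values, weights, [0.10, 0.50, 0.90])
    return {"p10": p10, "median": med, "p90": p90, "iqr_10_90": p90 - p10}


def continental_summary(estimates: pd.DataFrame,
                        population: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted median and 10th-90th percentile band per domain
    and year, across all admin-1 units."""
    pop = population.set_index("admin1_id").female_population
    rows = []
    for (year, domain), grp in estimates.groupby(["year", "domain"], sort=True):
        w = grp.admin1_id.map(pop).to_numpy(dtype=float)
        stats = _band(grp.estimate.to_numpy(), w)
        for stat, value in stats.items():
            rows.append({"grouping": "continental", "year": year,
                         "domain": domain, "statistic": stat, "value": value})
    return pd.DataFrame(rows)


def country_subnational_range(estimates: pd.DataFrame,
                              population: pd.DataFrame,
                              country: str, year: int) -> pd.DataFrame:
    """Per-domain p90 − p10 across one country's admin-1 units."""
    sel = estimates[(estimates.country_code == country)
                    & (estimates.year == year)]
    if not len(sel):
        raise SummaryError(f"no estimates for {country} {year}")
    pop = population.set_index("admin1_id").female_population
    rows = []
    for domain, grp in sel.groupby("domain", sort=True):
        diagnostic = ""
        if len(grp) < 2:
            diagnostic = "single-region country; range is 0 by construction"
        w = grp.admin1_id.map(pop).to_numpy(dtype=float)
        stats = _band(grp.estimate.to_numpy(), w)
        rows.append({"grouping": "country", "country_code": country,
                     "year": year, "domain": domain,
                     "statistic": "iqr_10_90", "value": stats["iqr_10_90"],
                     "median": stats["median"], "diagnostic": diagnostic})
    return pd.DataFrame(rows)


def all_country_ranges(estimates, population, year) -> pd.DataFrame:
    parts = [country_subnational_range(estimates, population, cc, year)
             for cc in sorted(estimates.country_code.unique())]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Domain correlations
# ---------------------------------------------------------------------------


def most_recent_survey_scores(harmonized: pd.DataFrame, metas) -> pd.DataFrame:
    """Admin-1 scores from each country's most recent survey (wide format)."""
    latest = {}
    for m in metas.values():
        cur = latest.get(m.country_code)
        if cur is None or m.survey_year > cur.survey_year:
            latest[m.country_code] = m
    keep = {m.survey_id for m in latest.values()}
    sel = harmonized[harmonized.survey_id.isin(keep)]
    wide = sel.pivot_table(index="region_id", columns="domain",
                           values="score", aggfunc="first")
    return wide.reindex(columns=list(DOMAINS))


def domain_correlations(wide_scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations over admin-1 units.

    Zero-variance domains yield NaN entries (flagged, not errors); the
    matrix is symmetric with unit diagonal.
    """
    if len(wide_scores) < 3:
        raise SummaryError("need >= 3 admin-1 units for correlations")
    corr = wide_scores.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# National-level regressions
# ---------------------------------------------------------------------------

NATIONAL_INDICES = ("hdi", "gdi", "gii", "log10_gdp")


def country_femi(estimates: pd.DataFrame, population: pd.DataFrame,
                 year: int) -> pd.Series:
    """Population-weighted national FEMI for one reference year."""
    sel = estimates[(estimates.domain == FEMI) & (estimates.year == year)]
    pop = population.set_index("admin1_id").female_population
    w = sel.admin1_id.map(pop)
    agg = (sel.assign(w=w, wx=w * sel.estimate)
              .groupby("country_code")[["w", "wx"]].sum())
    return agg.wx / agg.w


def national_regressions(femi_by_country: pd.Series,
                         covariates: pd.DataFrame, year: int) -> pd.DataFrame:
    """OLS of national FEMI on each development index (GDP log10-scaled).

    Returns slope, intercept, Pearson r and per-country residuals; countries
    missing an index are dropped from that index's fit with a diagnostic.
    """
    cov = covariates[covariates.year == year].set_index("country_code")
    rows = []
    for index_name in NATIONAL_INDICES:
        if index_name == "log10_gdp":
            x_raw = np.log10(cov.gdp_per_capita)
        else:
            x_raw = cov[index_name]
        joined = pd.DataFrame({"femi": femi_by_country, "x": x_raw}).dropna()
        dropped = sorted(set(femi_by_country.index) - set(joined.index))
        if len(joined) < 3:
            raise SummaryError(f"{index_name}: need >= 3 countries with data")
        if joined.x.nunique() < 2:
            raise SummaryError(f"{index_name}: degenerate design "
                               "(no variation in the index)")
        model = sm.OLS(joined.femi, sm.add_constant(joined.x)).fit()
        r = float(np.corrcoef(joined.x, joined.femi)[0, 1])
        for cc, resid in model.resid.items():
            rows.append({"index": index_name, "year": year,
                         "statistic": "residual", "country_code": cc,
                         "value": float(resid)})
        rows.extend([
            {"index": index_name, "year": year, "statistic": "ols_slope",
             "country_code": "", "value": float(model.params.iloc[1])},
            {"index": index_name, "year": year, "statistic": "ols_intercept",
             "country_code": "", "value": float(model.params.iloc[0])},
            {"index": index_name, "year": year, "statistic": "pearson_r",
             "country_code": "", "value": r},
            {"index": index_name, "year": year, "statistic": "n_dropped",
             "country_code": ";".join(dropped), "value": float(len(dropped))},
        ])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Age-cohort sensitivity
# ---------------------------------------------------------------------------

COHORT_DOMAINS = ("ipv_sexual", "reproductive_healthcare", "education")


def cohort_sensitivity(women: pd.DataFrame, births: pd.DataFrame,
                       coverage=None) -> dict:
    """Score difference, 18-30 minus 18-49 cohort, for the age-sensitive
    categories (child marriage, reproductive healthcare, education).

    A near-zero difference supports pooling the full 15-49 sample.
    """
    from .records import ALL_QUESTIONS
    scored = score_women(women, births,
                         ALL_QUESTIONS if coverage is None else coverage)
    young = scored[(scored.age >= 18) & (scored.age <= 30)]
    full = scored[(scored.age >= 18) & (scored.age <= 49)]
    if not len(young) or not len(full):
        raise SummaryError("empty age cohort")
    out = {}
    for col in COHORT_DOMAINS:
        out[col] = _wmean(young, col) - _wmean(full, col)
    return out


def _wmean(df, col):
    v = df[col].to_numpy(dtype=float)
    w = df.sample_weight.to_numpy(dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        raise SummaryError(f"no observations for {col}")
    return float((v[ok] * w[ok]).sum() / w[ok].sum())
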