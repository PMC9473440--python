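"""Convert region scores from historical survey schemes onto current admin-1 units.

Older surveys often reported on aggregated "super-regions" (several current
admin-1 units pooled).  Two downscaling procedures are provided:

* **bracketed** — when admin-1 surveys exist both before and after the
  non-standard survey: linearly interpolate the neighbours' admin-1 values
  to the target year, then scale each super-region's members by a common
  factor so their weighted mean reproduces the observed super-region value.
* **single-predictor** — when only one admin-1 survey exists: aggregate the
  predictor survey onto the super-regions, take the per-super-region
  difference from the observed values, and add that offset to each member.

Both preserve the observed super-region aggregates exactly before the final
clamping to [0, 1].  A super-region whose observed value is 0 uses an
additive shift in the bracketed method too (the multiplicative factor is
undefined at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SCORES_COLUMNS, RegionCrosswalk
from .records import DOMAINS


class HarmonizationError(ValueError):
    pass


@dataclass
class SurveyPlan:
    """How to bring one non-standard survey onto admin-1 units."""

    survey_id: str
    method: str  # "bracketed" | "single_predictor"
    before_survey: str | None = None
    after_survey: str | None = None
    predictor_survey: str | None = None
    #: admin-1 units in scope (partial-country surveys); None = all.
    region_subset: tuple | None = None


@dataclass
class HarmonizationPlan:
    surveys: dict = field(default_factory=dict)  # survey_id -> SurveyPlan

    def add(self, plan: SurveyPlan):
        self.surveys[plan.survey_id] = plan


# ---------------------------------------------------------------------------
# Core single-domain operations (value mappings, not tables)
# ---------------------------------------------------------------------------


def _weighted_mean(values, weights):
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    if w.sum() <= 0:
        raise HarmonizationError("super-region has zero total member weight")
    return float((v * w).sum() / w.sum())


def harmonize_bracketed(observed, groups, before, after, t0, t, t1, weights):
    """Downscale one domain of a super-region survey using two neighbours.

    Parameters
    ----------
    observed : dict super_region -> observed score at year ``t``
    groups : dict super_region -> list of member admin-1 ids
    before, after : dict admin1 -> score at years ``t0`` / ``t1``
    weights : dict admin1 -> aggregation weight (e.g. female population)

    Returns (estimates, raw) where ``estimates`` are clamped to [0, 1] and
    ``raw`` are the pre-clamp values whose super-region weighted means equal
    the observed values exactly.
    """
    if not (t0 < t < t1):
        raise HarmonizationError(f"need before.year < target < after.year "
                                 f"(got {t0}, {t}, {t1})")
    span = float(t1 - t0)
    raw = {}
    for g, members in groups.items():
        for r in members:
            if r not in before or r not in after:
                raise HarmonizationError(f"admin-1 unit {r!r} absent from a "
                                         "bracketing survey")
        vhat = {r: ((t1 - t) * before[r] + (t - t0) * after[r]) / span
                for r in members}
        w = [weights[r] for r in members]
        base = _weighted_mean([vhat[r] for r in members], w)
        obs = observed[g]
        if obs == 0 or base == 0:
            shift = obs - base  # multiplicative factor undefined at 0
            for r in members:
                raw[r] = vhat[r] + shift
        else:
            factor = obs / base
            for r in members:
                raw[r] = vhat[r] * factor
    return {r: float(np.clip(v, 0.0, 1.0)) for r, v in raw.items()}, raw


def harmonize_single(observed, groups, predictor, weights):
    """Downscale one domain using a single admin-1 predictor survey.

    Per super-region g the offset d(g) = observed(g) − weighted mean of the
    predictor over g's members is added to each member's predictor value.
    """
    raw = {}
    for g, members in groups.items():
        missing = [r for r in members if r not in predictor]
        if missing:
            raise HarmonizationError(
                f"admin-1 units absent from predictor survey: {missing}")
        w = [weights[r] for r in members]
        agg = _weighted_mean([predictor[r] for r in members], w)
        d = observed[g] - agg
        for r in members:
            raw[r] = predictor[r] + d
    return {r: float(np.clip(v, 0.0, 1.0)) for r, v in raw.items()}, raw


def aggregate_admin2(scores, mapping, weights):
    """Aggregate admin-2 scores to admin-1 by weighted mean.

    ``mapping``: admin1 -> list of admin-2 ids; ``weights``: admin2 -> weight.
    """
    out = {}
    for a1, members in mapping.items():
        missing = [m for m in members if m not in scores]
        if missing:
            raise HarmonizationError(f"unmapped admin-2 units: {missing}")
        out[a1] = _weighted_mean([scores[m] for m in members],
                                 [weights[m] for m in members])
    return out


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------


def _survey_values(table, survey_id, domain, column="score"):
    sel = table[(table.survey_id == survey_id) & (table.domain == domain)]
    return dict(zip(sel.region_id, sel[column]))


def _population_weights(population):
    return dict(zip(population.admin1_id, population.female_population))


def build_plan(metas, crosswalk: RegionCrosswalk,
               overrides: dict | None = None) -> HarmonizationPlan:
    """Derive a harmonization plan from survey metadata.

    Non-admin-1 surveys are bracketed when the same country has admin-1
    surveys both before and after; otherwise the nearest admin-1 survey is
    the single predictor.  ``overrides`` maps survey_id to SurveyPlan for
    special cases (e.g. partial-country surveys).
    """
    plan = HarmonizationPlan()
    overrides = overrides or {}
    by_country = {}
    for m in metas.values():
        by_country.setdefault(m.country_code, []).append(m)
    for cc, surveys in by_country.items():
        std = sorted([m for m in surveys if crosswalk.is_identity(m.scheme_id)],
                     key=lambda m: m.survey_year)
        for m in surveys:
            if crosswalk.is_identity(m.scheme_id):
                continue
            if m.survey_id in overrides:
                plan.add(overrides[m.survey_id])
                continue
            before = [s for s in std if s.survey_year < m.survey_year]
            after = [s for s in std if s.survey_year > m.survey_year]
            if before and after:
                plan.add(SurveyPlan(m.survey_id, "bracketed",
                                    before_survey=before[-1].survey_id,
                                    after_survey=after[0].survey_id))
            elif std:
                nearest = min(std, key=lambda s: (abs(s.survey_year - m.survey_year),
                                                  -s.survey_year))
                plan.add(SurveyPlan(m.survey_id, "single_predictor",
                                    predictor_survey=nearest.survey_id))
            else:
                raise HarmonizationError(
                    f"{m.survey_id}: no admin-1 survey available in {cc} "
                    "to downscale against")
    return plan


def harmonize_scores(table: pd.DataFrame, metas, crosswalk: RegionCrosswalk,
                     population: pd.DataFrame,
                     plan: HarmonizationPlan | None = None) -> pd.DataFrame:
    """Re-express every survey's scores on current admin-1 units.

    Surveys already on an identity (admin-1) scheme pass through unchanged;
    the rest are downscaled per the plan and flagged
    ``provenance = "interpolated"``.
    """
    if plan is None:
        plan = build_plan(metas, crosswalk)
    pop_w = _population_weights(population)
    out_parts = []
    for survey_id in sorted(metas):
        meta = metas[survey_id]
        sub = table[table.survey_id == survey_id]
        if crosswalk.is_identity(meta.scheme_id):
            part = sub.copy()
            part["region_id"] = part.region_id  # already admin-1 ids
            out_parts.append(part)
            continue
        sp = plan.surveys.get(survey_id)
        if sp is None:
            raise HarmonizationError(f"no harmonization plan for {survey_id}")
        groups = {reg: crosswalk.members(meta.scheme_id, reg)
                  for reg in sub.region_id.unique()}
        if sp.region_subset is not None:
            scope = set(sp.region_subset)
            groups = {g: [r for r in members if r in scope]
                      for g, members in groups.items()}
        rows = []
        for domain in DOMAINS:
            observed = _survey_values(table, survey_id, domain)
            if any(np.isnan(v) for v in observed.values()):
                raise HarmonizationError(
                    f"{survey_id}/{domain}: missing scores must be imputed "
                    "before harmonization")
            if sp.method == "bracketed":
                before = _survey_values(table, sp.before_survey, domain)
                after = _survey_values(table, sp.after_survey, domain)
                t0 = metas[sp.before_survey].survey_year
                t1 = metas[sp.after_survey].survey_year
                est, _ = harmonize_bracketed(observed, groups, before, after,
                                             t0, meta.survey_year, t1, pop_w)
            elif sp.method == "single_predictor":
                pred_sub = table[(table.survey_id == sp.predictor_survey)]
                n_by_region = (pred_sub[pred_sub.domain == domain]
                               .set_index("region_id").effective_n)
                weights = {r: float(n_by_region.get(r, 0.0)) or pop_w.get(r, 1.0)
                           for g in groups.values() for r in g}
                predictor = _survey_values(table, sp.predictor_survey, domain)
                est, _ = harmonize_single(observed, groups, predictor, weights)
            else:
                raise HarmonizationError(f"unknown method {sp.method!r}")
            n_of_group = {g: dict(zip(sub[sub.domain == domain].region_id,
                                      sub[sub.domain == domain].effective_n))
                          for g in groups}
            for g, members in groups.items():
                for r in members:
                    rows.append({
                        "survey_id": survey_id, "region_id": r,
                        "domain": domain, "score": est[r],
                        "effective_n": n_of_group[g].get(g, 0),
                        "women_raw": np.nan, "men_raw": np.nan,
                        "provenance": "interpolated",
                    })
        out_parts.append(pd.DataFrame(rows, columns=SCORES_COLUMNS))
    return pd.concat(out_parts, ignore_index=True)
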