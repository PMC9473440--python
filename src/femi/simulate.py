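"""Generate DHS-like multi-survey microdata with known latent domain scores.

The generator draws every respondent's answers so that the *expected* coded
respondent score under the scoring rules equals a known latent region-level
score.  Latent scores follow a spatial (latitude) gradient and a linear
annual trend, surveys can use aggregated region schemes or omit question
blocks, and men's scores differ from women's by a configurable gender gap —
so scoring, imputation, harmonization, extrapolation and the composite can
all be validated by parameter recovery against the stored ground truth.

Per-question probabilities are solved from the latent score analytically
(see docs/methods.md); for a few categories whose coding defaults to
"empowered" for structurally inapplicable respondents (never-married women,
childless women) the solution is conditioned on the realized group counts,
which keeps the region mean conditionally unbiased whenever the latent
score exceeds the inapplicable share (defaults keep latents well inside the
feasible band).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BIRTHS_COLUMNS,
    EXPECTED_COLUMNS,
    GROUND_TRUTH_COLUMNS,
    MEN_COLUMNS,
    WOMEN_COLUMNS,
    RegionCrosswalk,
    SurveyBundle,
    crosswalk_from_mapping,
    write_covariates,
    write_crosswalk,
    write_expected_observed,
    write_ground_truth,
    write_population,
    write_survey,
)
from .records import (
    ALL_QUESTIONS,
    BEATING_QUESTIONS,
    DECISION_QUESTIONS,
    DOMAIN_DECISION,
    DOMAIN_EDUCATION,
    DOMAIN_EMPLOYMENT,
    DOMAIN_FP,
    DOMAIN_IPV,
    DOMAIN_RH,
    DOMAINS,
    ADJUSTED_DOMAINS,
    FEMI,
    QUESTION_GROUPS,
    SurveyMeta,
)

TREND_REF_YEAR = 2005
ADULT_AGE = 18

#: Default latent baselines at the trend reference year (continental medians
#: of the mid-study period, per domain).
DEFAULT_BASELINES = {
    DOMAIN_IPV: 0.52,
    DOMAIN_FP: 0.45,
    DOMAIN_RH: 0.58,
    DOMAIN_EMPLOYMENT: 0.49,
    DOMAIN_EDUCATION: 0.40,
    DOMAIN_DECISION: 0.50,
}

#: Default annual trends (score units / year); roughly +0.10 per 20 years for
#: most domains, near-flat for employment.
DEFAULT_TRENDS = {
    DOMAIN_IPV: 0.0055,
    DOMAIN_FP: 0.0065,
    DOMAIN_RH: 0.005,
    DOMAIN_EMPLOYMENT: -0.001,
    DOMAIN_EDUCATION: 0.005,
    DOMAIN_DECISION: 0.0075,
}

#: Default north-to-south gradient: scores fall as latitude increases.
DEFAULT_GRADIENTS = {d: -0.012 for d in DOMAINS}



@dataclass
class SimulationConfig:
    n_countries: int = 2
    regions_per_country: int = 3
    survey_years: tuple = (2004, 2014)
    #: survey_id -> "admin1" (default) or "aggregated:k".
    schemes: dict = field(default_factory=dict)
    n_women_per_region: int = 1000
    n_men_per_region: int = 300
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    lat_gradients: dict = field(default_factory=lambda: dict(DEFAULT_GRADIENTS))
    trends: dict = field(default_factory=lambda: dict(DEFAULT_TRENDS))
    #: sd of a region x survey x domain latent perturbation (design noise).
    region_noise_sd: float = 0.01
    married_prob: float = 0.85
    wants_child_prob: float = 0.30
    recent_birth_prob: float = 0.50
    childless_prob: float = 0.10
    #: women/men latent ratio for Education and Employment (< 1: men ahead).
    gender_gap_ratio: float = 0.90
    weight_mode: str = "unit"  # or "lognormal"
    #: survey_id -> iterable of QUESTION_GROUPS names omitted by that survey.
    missing_plan: dict = field(default_factory=dict)
    #: survey_id -> iterable of admin1 ids covered (partial-country surveys).
    region_subsets: dict = field(default_factory=dict)
    education_youth_boost: float = 0.0
    #: total spread of per-country baseline offsets (between-country variation).
    country_spread: float = 0.10
    reference_years: tuple = (1995, 2005, 2015)
    seed: int = 0

    def country_codes(self):
        return [f"C{i + 1:02d}" for i in range(self.n_countries)]

    def years_for(self, country_code):
        if isinstance(self.survey_years, dict):
            return tuple(self.survey_years[country_code])
        return tuple(self.survey_years)

    def country_offset(self, country_code):
        codes = self.country_codes()
        if len(codes) == 1:
            return 0.0
        i = codes.index(country_code)
        return self.country_spread * (i / (len(codes) - 1) - 0.5)

    def validate(self):
        if self.n_countries < 1 or self.regions_per_country < 1:
            raise ValueError("need at least one country and one region")
        if self.n_women_per_region < 1:
            raise ValueError("n_women_per_region must be >= 1")
        if self.weight_mode not in ("unit", "lognormal"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        for sid, scheme in self.schemes.items():
            if scheme == "admin1":
                continue
            if scheme.startswith("aggregated:"):
                k = int(scheme.split(":")[1])
                if not 1 <= k <= self.regions_per_country:
                    raise ValueError(
                        f"{sid}: aggregated:{k} needs 1 <= k <= "
                        f"{self.regions_per_country} regions")
            else:
                raise ValueError(f"{sid}: unknown scheme {scheme!r}")
        for sid, groups in self.missing_plan.items():
            for g in groups:
                if g not in QUESTION_GROUPS:
                    raise ValueError(f"{sid}: unknown question group {g!r}")


@dataclass
class SimulationResult:
    bundle: SurveyBundle
    crosswalk: RegionCrosswalk
    covariates: pd.DataFrame
    population: pd.DataFrame
    ground_truth: pd.DataFrame
    expected_observed: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Geometry and latent surfaces
# ---------------------------------------------------------------------------


def region_geometry(config: SimulationConfig) -> pd.DataFrame:
    """Admin-1 units on a lon/lat grid: countries west-to-east, regions
    north-to-south within each country."""
    rows = []
    for ci, cc in enumerate(config.country_codes()):
        for ri in range(config.regions_per_country):
            rows.append({
                "admin1_id": f"{cc}:R{ri + 1:02d}",
                "country_code": cc,
                "region_index": ri,
                "longitude": 10.0 + 4.0 * ci,
                "latitude": 12.0 - 5.0 * ri,
            })
    return pd.DataFrame(rows)


def _latent(config, domain, latitude, year, country_code=None, youth=False):
    geometry_center = 12.0 - 5.0 * (config.regions_per_country - 1) / 2.0
    s = (config.baselines[domain]
         + config.lat_gradients[domain] * (latitude - geometry_center)
         + config.trends[domain] * (year - TREND_REF_YEAR)
         + (config.country_offset(country_code) if country_code else 0.0))
    if youth and domain == DOMAIN_EDUCATION:
        s = s + config.education_youth_boost
    return float(np.clip(s, 0.0, 1.0))


_YOUNG_SHARE = 16.0 / 35.0  # ages 15..30 out of a uniform 15..49 sample


def latent_women(config, domain, latitude, year, country_code=None):
    """Population-level women's latent score (averaging any youth boost)."""
    base = _latent(config, domain, latitude, year, country_code)
    if domain == DOMAIN_EDUCATION and config.education_youth_boost:
        young = _latent(config, domain, latitude, year, country_code, youth=True)
        return _YOUNG_SHARE * young + (1 - _YOUNG_SHARE) * base
    return base


def latent_men(config, domain, latitude, year, country_code=None):
    w = latent_women(config, domain, latitude, year, country_code)
    return float(np.clip(w / config.gender_gap_ratio, 0.0, 1.0))


def ground_truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Latent (noise-free) scores per admin-1 unit, year and domain.

    ``latent`` is the final score the pipeline targets: inequality-adjusted
    for Education/Employment, plus FEMI rows (mean of the six).
    """
    geo = region_geometry(config)
    years = sorted({y for cc in config.country_codes()
                    for y in config.years_for(cc)} | set(config.reference_years))
    rows = []
    for reg in geo.itertuples(index=False):
        for year in years:
            finals = {}
            for domain in DOMAINS:
                w = latent_women(config, domain, reg.latitude, year,
                                 reg.country_code)
                if domain in ADJUSTED_DOMAINS:
                    m = latent_men(config, domain, reg.latitude, year,
                                   reg.country_code)
                    final = w if m == 0 else min(1.0, w * w / m)
                else:
                    m = np.nan
                    final = w
                finals[domain] = final
                rows.append({"admin1_id": reg.admin1_id,
                             "country_code": reg.country_code,
                             "year": year, "domain": domain,
                             "women_latent": w, "men_latent": m,
                             "latent": final})
            rows.append({"admin1_id": reg.admin1_id,
                         "country_code": reg.country_code,
                         "year": year, "domain": FEMI,
                         "women_latent": np.nan, "men_latent": np.nan,
                         "latent": float(np.mean(list(finals.values())))})
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# Respondent generation
# ---------------------------------------------------------------------------


def _choose(rng, n, p):
    return rng.random(n) < p


def _weights(rng, n, mode):
    if mode == "unit":
        return np.ones(n)
    w = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    return w / w.mean()


def _feasible(p, lo=0.0, hi=1.0):
    return float(np.clip(p, lo, hi))


def _simulate_region_women(rng, config, survey_id, region_label, admin1_id,
                           latents):
    """One region's women frame + births frame (typed, in-memory)."""
    n = config.n_women_per_region
    age = rng.integers(15, 50, n)
    adult = age >= ADULT_AGE
    married = adult & _choose(rng, n, config.married_prob)
    weights = _weights(rng, n, config.weight_mode)

    women = pd.DataFrame({
        "respondent_id": [f"{survey_id}:{admin1_id}:W{i:05d}" for i in range(n)],
        "survey_id": survey_id,
        "region_id": region_label,
        "sample_weight": weights,
        "age": age.astype(int),
        "currently_married": married.astype(float),
    })

    # --- IPV: physical attitudes + child marriage -------------------------
    s = latents[DOMAIN_IPV]
    for q in BEATING_QUESTIONS:
        women[q] = np.where(_choose(rng, n, s), "no", "yes")
    n_marr = int(married.sum())
    afm = np.full(n, np.nan)
    if n_marr:
        # unmarried women code 1 for the sexual category; solve the married
        # probability so the region mean is conditionally unbiased
        p_adult_marriage = _feasible((n * s - (n - n_marr)) / n_marr)
        marr_adult = _choose(rng, n_marr, p_adult_marriage)
        marr_age = np.where(
            marr_adult,
            ADULT_AGE + rng.integers(0, 8, n_marr),
            13 + rng.integers(0, 5, n_marr),
        )
        marr_age = np.minimum(marr_age, age[married])
        afm[married] = marr_age
    women["age_first_marriage"] = afm

    # --- Decision-making (married women) ----------------------------------
    s = latents[DOMAIN_DECISION]
    for q in DECISION_QUESTIONS:
        col = np.full(n, None, dtype=object)
        if n_marr:
            yes = _choose(rng, n_marr, s)
            style = _choose(rng, n_marr, 0.5)
            other = _choose(rng, n_marr, 0.1)
            ans = np.where(yes, np.where(style, "self", "self_and_partner"),
                           np.where(other, "other", "partner_only"))
            col[married] = ans
        women[q] = col

    # --- Family planning ---------------------------------------------------
    s = latents[DOMAIN_FP]
    wants = np.full(n, np.nan)
    contra = np.full(n, np.nan)
    if n_marr:
        w_child = _choose(rng, n_marr, config.wants_child_prob)
        wants[married] = w_child.astype(float)
        eligible = married.copy()
        eligible[married] = ~w_child
        n_elig = int(eligible.sum())
        contra[eligible] = _choose(rng, n_elig, s).astype(float)
    women["wants_child_within_2y"] = wants
    women["uses_modern_contraception"] = contra

    # --- Reproductive healthcare -------------------------------------------
    s = latents[DOMAIN_RH]
    recent = adult & _choose(rng, n, config.recent_birth_prob)
    no_recent_adult = adult & ~recent
    childless = np.zeros(n, dtype=bool)
    childless[no_recent_adult] = _choose(rng, int(no_recent_adult.sum()),
                                         config.childless_prob)
    has_children = recent | (no_recent_adult & ~childless)
    f_a = recent.sum() / n
    f_c = (n - has_children.sum()) / n  # childless adults + minors: score 1
    f_b = 1.0 - f_a - f_c
    denom = f_a / 4.0 + f_b
    p_adol = _feasible((s * (1 - 3 * f_a / 4) - f_c) / denom) if denom > 0 else 0.0
    afb = np.full(n, np.nan)
    n_child = int(has_children.sum())
    if n_child:
        ok = _choose(rng, n_child, p_adol)
        birth_age = np.where(ok, ADULT_AGE + rng.integers(0, 7, n_child),
                             14 + rng.integers(0, 4, n_child))
        afb[has_children] = np.minimum(birth_age, age[has_children])
    women["age_first_birth"] = afb

    n_recent = int(recent.sum())
    births = pd.DataFrame(columns=BIRTHS_COLUMNS)
    if n_recent:
        visits = 2.0 * (_choose(rng, n_recent, s).astype(int)
                        + _choose(rng, n_recent, s).astype(int))
        births = pd.DataFrame({
            "respondent_id": women.respondent_id.to_numpy()[recent],
            "survey_id": survey_id,
            "birth_index": 0,
            "antenatal_visits": visits,
            "professional_delivery": _choose(rng, n_recent, s).astype(float),
            "postnatal_within_2mo": _choose(rng, n_recent, s).astype(float),
        })

    bl5 = np.zeros(n)
    bl5[has_children] = 1 + rng.poisson(0.8, n_child)
    women["births_last_5y"] = bl5

    # --- Education / employment --------------------------------------------
    s_by_age = np.where(
        age <= 30,
        latents["education_young"],
        latents["education_old"],
    )
    schooling_ok = rng.random(n) < s_by_age
    women["years_schooling"] = np.where(schooling_ok, 6 + rng.integers(0, 7, n),
                                        rng.integers(0, 6, n)).astype(float)
    women["literate"] = (rng.random(n) < s_by_age).astype(float)
    reg_col, pay_col = _employment_answers(rng, n, latents[DOMAIN_EMPLOYMENT])
    women["work_regularity"] = reg_col
    women["payment_type"] = pay_col
    return women[WOMEN_COLUMNS], births[BIRTHS_COLUMNS]


def _employment_answers(rng, n, s):
    halves = _choose(rng, n, s).astype(int) + _choose(rng, n, s).astype(int)
    reg = np.select([halves == 2, halves == 1], ["all_year", "part_year_or_seasonal"],
                    default="none").astype(object)
    employed = halves > 0
    p_cash = _feasible(s / (2.0 - s))
    cash = _choose(rng, n, p_cash)
    pay = np.full(n, None, dtype=object)
    pay[employed & cash] = "cash"
    pay[employed & ~cash] = "in_kind_only"
    return reg, pay


def _simulate_region_men(rng, config, survey_id, region_label, admin1_id,
                         latents):
    n = config.n_men_per_region
    men = pd.DataFrame({
        "respondent_id": [f"{survey_id}:{admin1_id}:M{i:05d}" for i in range(n)],
        "survey_id": survey_id,
        "region_id": region_label,
        "sample_weight": _weights(rng, n, config.weight_mode),
    })
    s_edu = latents["men_education"]
    schooling_ok = rng.random(n) < s_edu
    men["years_schooling"] = np.where(schooling_ok, 6 + rng.integers(0, 7, n),
                                      rng.integers(0, 6, n)).astype(float)
    men["literate"] = (rng.random(n) < s_edu).astype(float)
    reg_col, pay_col = _employment_answers(rng, n, latents["men_employment"])
    men["work_regularity"] = reg_col
    men["payment_type"] = pay_col
    return men[MEN_COLUMNS]


# ---------------------------------------------------------------------------
# Survey assembly
# ---------------------------------------------------------------------------


def _scheme_partition(config, cc, survey_id, admin1_ids):
    """(scheme_id, {survey_region: [admin1, ...]}) for one survey."""
    scheme = config.schemes.get(survey_id, "admin1")
    if scheme == "admin1":
        return f"{cc}:admin1", {a: [a] for a in admin1_ids}
    k = int(scheme.split(":")[1])
    groups = np.array_split(np.asarray(admin1_ids, dtype=object), k)
    mapping = {f"{cc}:G{g + 1:02d}": list(members)
               for g, members in enumerate(groups) if len(members)}
    return f"{cc}:agg:{survey_id}", mapping


def _apply_missing_plan(women, births, omitted_questions):
    women = women.copy()
    births = births.copy()
    for q in omitted_questions:
        if q in women.columns:
            if women[q].dtype == object:
                women[q] = None
            else:
                women[q] = np.nan
        if q in births.columns:
            births[q] = np.nan
    return women, births


def simulate(config: SimulationConfig, seed=None):
    """Generate the full multi-survey bundle and its ground truth.

    ``seed`` overrides ``config.seed``.  The same config and seed always
    produce byte-identical CSV output.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    geo = region_geometry(config)

    women_frames, birth_frames, men_frames = [], [], []
    metas = {}
    crosswalk_map = {}
    expected_rows = []

    for ci, cc in enumerate(config.country_codes()):
        cgeo = geo[geo.country_code == cc]
        admin1_ids = list(cgeo.admin1_id)
        crosswalk_map.setdefault(f"{cc}:admin1", {a: [a] for a in admin1_ids})
        for year in config.years_for(cc):
            survey_id = f"{cc}-{year}"
            covered = list(config.region_subsets.get(survey_id, admin1_ids))
            scheme_id, mapping = _scheme_partition(config, cc, survey_id, covered)
            crosswalk_map[scheme_id] = mapping
            region_label_of = {a: sr for sr, members in mapping.items()
                               for a in members}

            omitted_groups = config.missing_plan.get(survey_id, ())
            omitted = set()
            for g in omitted_groups:
                omitted |= QUESTION_GROUPS[g]
            metas[survey_id] = SurveyMeta(
                survey_id=survey_id, country_code=cc, survey_year=year,
                scheme_id=scheme_id,
                question_coverage=frozenset(ALL_QUESTIONS - omitted),
            )

            noise_rng = np.random.default_rng([seed, 7919, ci, year])
            for reg in cgeo.itertuples(index=False):
                if reg.admin1_id not in region_label_of:
                    continue
                latents = {}
                for domain in DOMAINS:
                    base = _latent(config, domain, reg.latitude, year, cc)
                    noisy = base + noise_rng.normal(0.0, config.region_noise_sd)
                    latents[domain] = float(np.clip(noisy, 0.0, 1.0))
                shift = latents[DOMAIN_EDUCATION] - _latent(
                    config, DOMAIN_EDUCATION, reg.latitude, year, cc)
                latents["education_young"] = float(np.clip(
                    _latent(config, DOMAIN_EDUCATION, reg.latitude, year, cc,
                            youth=True) + shift, 0.0, 1.0))
                latents["education_old"] = latents[DOMAIN_EDUCATION]
                pop_edu = (_YOUNG_SHARE * latents["education_young"]
                           + (1 - _YOUNG_SHARE) * latents["education_old"])
                for domain in ADJUSTED_DOMAINS:
                    w = pop_edu if domain == DOMAIN_EDUCATION else latents[domain]
                    latents[f"men_{domain}"] = float(np.clip(
                        w / config.gender_gap_ratio, 0.0, 1.0))

                rng = np.random.default_rng([seed, ci, year, reg.region_index])
                w_frame, b_frame = _simulate_region_women(
                    rng, config, survey_id, region_label_of[reg.admin1_id],
                    reg.admin1_id, latents)
                m_frame = _simulate_region_men(
                    rng, config, survey_id, region_label_of[reg.admin1_id],
                    reg.admin1_id, latents)
                w_frame, b_frame = _apply_missing_plan(w_frame, b_frame, omitted)
                women_frames.append(w_frame)
                birth_frames.append(b_frame)
                men_frames.append(m_frame)

                for domain in DOMAINS:
                    if domain == DOMAIN_EDUCATION:
                        expected = pop_edu
                    else:
                        expected = latents[domain]
                    expected_rows.append({
                        "survey_id": survey_id, "region_id": reg.admin1_id,
                        "domain": domain, "expected": expected})

    women = pd.concat(women_frames, ignore_index=True)
    births = (pd.concat(birth_frames, ignore_index=True)
              if birth_frames else pd.DataFrame(columns=BIRTHS_COLUMNS))
    men = pd.concat(men_frames, ignore_index=True)
    bundle = SurveyBundle(women=women, births=births, men=men, metas=metas)

    expected = pd.DataFrame(expected_rows, columns=EXPECTED_COLUMNS)
    truth = ground_truth_table(config)
    crosswalk = crosswalk_from_mapping(crosswalk_map)
    population = _population_table(geo)
    covariates = _covariates_table(config, truth)
    return SimulationResult(bundle=bundle, crosswalk=crosswalk,
                            covariates=covariates, population=population,
                            ground_truth=truth, expected_observed=expected,
                            config=config)


def _population_table(geo: pd.DataFrame) -> pd.DataFrame:
    pop = geo.copy()
    idx = np.arange(len(pop))
    pop["female_population"] = 50_000.0 * (1.0 + (idx % 5) / 4.0)
    pop["population_density"] = 40.0 + 15.0 * (idx % 7)
    return pop[["admin1_id", "country_code", "longitude", "latitude",
                "female_population", "population_density"]]


def _covariates_table(config, truth: pd.DataFrame) -> pd.DataFrame:
    """Country-year covariates deterministically linked to the latent FEMI."""
    femi = truth[truth.domain == FEMI]
    rh = truth[truth.domain == DOMAIN_RH]
    rows = []
    for cc in config.country_codes():
        years = sorted(set(config.years_for(cc)) | set(config.reference_years))
        for year in years:
            f = femi[(femi.country_code == cc) & (femi.year == year)].latent.mean()
            r = rh[(rh.country_code == cc) & (rh.year == year)].latent.mean()
            rows.append({
                "country_code": cc, "year": year,
                "hdi": float(np.clip(0.2 + 0.6 * f, 0, 1)),
                "maternal_mortality": float(50.0 + 900.0 * (1.0 - r)),
                "gdp_per_capita": float(10 ** (2.0 + 2.5 * f)),
                "gdi": float(np.clip(0.80 + 0.20 * f, 0, 1.1)),
                "gii": float(np.clip(0.75 - 0.55 * f, 0, 1)),
            })
    return pd.DataFrame(rows)


def write_simulation(result: SimulationResult, out_dir) -> None:
    """Write the full bundle plus ground truth to a directory of CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = result.bundle
    write_survey(out_dir, b.women, b.births, b.men, b.metas)
    write_crosswalk(out_dir / "crosswalk.csv", result.crosswalk)
    write_covariates(out_dir / "covariates.csv", result.covariates)
    write_population(out_dir / "population.csv", result.population)
    write_ground_truth(out_dir / "ground_truth.csv", result.ground_truth)
    write_expected_observed(out_dir / "expected_observed.csv",
                            result.expected_observed)


# ---------------------------------------------------------------------------
# Fixture catalogue
# ---------------------------------------------------------------------------

_FIXTURES = {}


def _fixture(name):
    def deco(fn):
        _FIXTURES[name] = fn
        return fn
    return deco


@_fixture("tiny-2country")
def _tiny():
    return SimulationConfig(
        n_countries=2, regions_per_country=3, survey_years=(2004, 2014),
        n_women_per_region=100, n_men_per_region=40, region_noise_sd=0.0)


@_fixture("scheme-change")
def _scheme_change():
    return SimulationConfig(
        n_countries=1, regions_per_country=4,
        survey_years=(2000, 2007, 2014),
        schemes={"C01-2007": "aggregated:2"},
        n_women_per_region=150, n_men_per_region=40, region_noise_sd=0.0,
        lat_gradients={d: -0.02 for d in DOMAINS})


@_fixture("missing-domain")
def _missing_domain():
    return SimulationConfig(
        n_countries=5, regions_per_country=6, survey_years=(2006, 2014),
        missing_plan={"C01-2006": ["ipv"]},
        n_women_per_region=150, n_men_per_region=40, region_noise_sd=0.005,
        lat_gradients={d: -0.02 for d in DOMAINS})


@_fixture("mali-split-analogue")
def _mali():
    return SimulationConfig(
        n_countries=1, regions_per_country=6, survey_years=(2000, 2012),
        schemes={"C01-2000": "aggregated:1"},
        region_subsets={"C01-2000": ["C01:R04", "C01:R05", "C01:R06"]},
        n_women_per_region=150, n_men_per_region=40, region_noise_sd=0.0,
        lat_gradients={d: -0.02 for d in DOMAINS})


@_fixture("two-survey-trend")
def _two_survey():
    return SimulationConfig(
        n_countries=1, regions_per_country=3, survey_years=(2004, 2014),
        n_women_per_region=200, n_men_per_region=60, region_noise_sd=0.0)


def fixture_names():
    return sorted(_FIXTURES)


def make_fixture(name: str, seed: int = 0, **overrides) -> SimulationResult:
    """Generate one of the canned small scenarios used by the test suite."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {fixture_names()}")
    config = _FIXTURES[name]()
    if overrides:
        config = replace(config, **overrides)
    return simulate(config, seed=seed)
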