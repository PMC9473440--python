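"""Read/write the open CSV schemas for survey microdata and derived tables.

Every table is UTF-8 CSV (RFC 4180 quoting via pandas) with a versioned tag
line ``#femi <table> v1`` above the header.  Missing values are empty fields
on disk and NaN/None in memory.  Booleans are stored as ``1``/``0``.

Derived tables (region scores, estimates, summaries) are written with fixed
6-decimal formatting and a stable column order so byte-level reproducibility
checks are meaningful; microdata values are written verbatim.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    ALL_QUESTIONS,
    BEATING_ANSWERS,
    BEATING_QUESTIONS,
    DECISION_ANSWERS,
    DECISION_QUESTIONS,
    PAYMENT_TYPES,
    WORK_REGULARITY,
    AGE_MAX,
    AGE_MIN,
    BirthEvent,
    ManRecord,
    SurveyMeta,
    WomanRecord,
)

SCHEMA_VERSION = "v1"

WOMEN_COLUMNS = (
    ["respondent_id", "survey_id", "region_id", "sample_weight", "age",
     "currently_married", "age_first_marriage", "age_first_birth",
     "wants_child_within_2y", "uses_modern_contraception"]
    + list(DECISION_QUESTIONS)
    + list(BEATING_QUESTIONS)
    + ["years_schooling", "literate", "work_regularity", "payment_type",
       "births_last_5y"]
)

MEN_COLUMNS = ["respondent_id", "survey_id", "region_id", "sample_weight",
               "years_schooling", "literate", "work_regularity", "payment_type"]

BIRTHS_COLUMNS = ["respondent_id", "survey_id", "birth_index",
                  "antenatal_visits", "professional_delivery",
                  "postnatal_within_2mo"]

META_COLUMNS = ["survey_id", "country_code", "survey_year", "scheme_id",
                "questions_omitted"]

CROSSWALK_COLUMNS = ["scheme_id", "survey_region_id", "admin1_id"]

COVARIATES_COLUMNS = ["country_code", "year", "hdi", "maternal_mortality",
                      "gdp_per_capita", "gdi", "gii"]

POPULATION_COLUMNS = ["admin1_id", "country_code", "longitude", "latitude",
                      "female_population", "population_density"]

SCORES_COLUMNS = ["survey_id", "region_id", "domain", "score", "effective_n",
                  "women_raw", "men_raw", "provenance"]

ESTIMATES_COLUMNS = ["admin1_id", "country_code", "year", "domain", "estimate",
                     "method", "n_surveys_used"]

GROUND_TRUTH_COLUMNS = ["admin1_id", "country_code", "year", "domain",
                        "women_latent", "men_latent", "latent"]

EXPECTED_COLUMNS = ["survey_id", "region_id", "domain", "expected"]


class SchemaError(ValueError):
    """Header or tag line does not match the published schema."""


class CrosswalkError(ValueError):
    """Crosswalk mappings do not partition the admin-1 units."""


@dataclass
class Diagnostic:
    """One rejected row: which file, which row (1-based data row), why."""

    table: str
    row: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table} row {self.row}: {self.field}: {self.message}"


# ---------------------------------------------------------------------------
# Low-level tagged CSV
# ---------------------------------------------------------------------------


def _tag(table: str) -> str:
    return f"#femi {table} {SCHEMA_VERSION}"


def write_table(df: pd.DataFrame, path, table: str, columns, float_format=None) -> None:
    path = Path(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing columns {missing}")
    buf = _io.StringIO()
    buf.write(_tag(table) + "\n")
    df.loc[:, columns].to_csv(buf, index=False, float_format=float_format,
                              lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_table(path, table: str, columns) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        tag = fh.readline().rstrip("\n")
        if tag != _tag(table):
            raise SchemaError(f"{path}: expected tag {_tag(table)!r}, found {tag!r}")
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    got = list(df.columns)
    if got != list(columns):
        for want, have in zip(columns, got + [None] * len(columns)):
            if want != have:
                raise SchemaError(f"{path}: first offending column: expected "
                                  f"{want!r}, found {have!r}")
        raise SchemaError(f"{path}: unexpected columns {got[len(columns):]}")
    return df


# ---------------------------------------------------------------------------
# Column validation (vectorized, row diagnostics)
# ---------------------------------------------------------------------------

_EMPTY = ""


def _check_columns(raw: pd.DataFrame, specs, table: str):
    """Return (typed frame, diagnostics, keep_mask).

    ``specs`` maps column -> (kind, required, extra).  Invalid rows are
    reported once for the first offending field and dropped; valid rows are
    converted to typed columns.  Rejecting a row never drops any other row.
    """
    n = len(raw)
    bad_field = pd.Series([None] * n, dtype=object)
    bad_msg = pd.Series([None] * n, dtype=object)

    def flag(mask, col, msg):
        new = mask & bad_field.isna()
        bad_field[new] = col
        bad_msg[new] = msg

    typed = {}
    for col, (kind, required, extra) in specs.items():
        s = raw[col].str.strip()
        empty = s == _EMPTY
        if required:
            flag(empty, col, "required value is missing")
        if kind == "str":
            typed[col] = s.where(~empty, other=None)
        elif kind in ("float", "int"):
            num = pd.to_numeric(s.where(~empty, other=np.nan), errors="coerce")
            flag(~empty & num.isna(), col, "not a number")
            lo, hi = extra
            if lo is not None:
                flag(num.notna() & (num < lo), col, f"must be >= {lo}")
            if hi is not None:
                flag(num.notna() & (num > hi), col, f"must be <= {hi}")
            if kind == "int":
                frac = num.notna() & (num != np.floor(num))
                flag(frac, col, "must be an integer")
            typed[col] = num.astype(float)
        elif kind == "bool":
            ok = s.isin(["0", "1"]) | empty
            flag(~ok, col, "must be 0 or 1 (or empty)")
            typed[col] = pd.to_numeric(s.where(s.isin(["0", "1"]), other=np.nan),
                                       errors="coerce")
        elif kind == "cat":
            allowed = extra
            ok = s.isin(list(allowed)) | empty
            flag(~ok, col, f"value not in {sorted(allowed)}")
            typed[col] = s.where(~empty & s.isin(list(allowed)), other=None)
        else:  # pragma: no cover
            raise AssertionError(kind)

    keep = bad_field.isna()
    diags = [
        Diagnostic(table, i + 1, f, m)
        for i, (f, m) in enumerate(zip(bad_field, bad_msg))
        if f is not None
    ]
    out = pd.DataFrame(typed, columns=list(specs))
    return out[keep.values].reset_index(drop=True), diags


def _women_specs():
    specs = {
        "respondent_id": ("str", True, None),
        "survey_id": ("str", True, None),
        "region_id": ("str", True, None),
        "sample_weight": ("float", True, (0.0, None)),
        "age": ("int", True, (AGE_MIN, AGE_MAX)),
        "currently_married": ("bool", True, None),
        "age_first_marriage": ("int", False, (5, AGE_MAX)),
        "age_first_birth": ("int", False, (5, AGE_MAX)),
        "wants_child_within_2y": ("bool", False, None),
        "uses_modern_contraception": ("bool", False, None),
    }
    for q in DECISION_QUESTIONS:
        specs[q] = ("cat", False, set(DECISION_ANSWERS))
    for q in BEATING_QUESTIONS:
        specs[q] = ("cat", False, set(BEATING_ANSWERS))
    specs.update({
        "years_schooling": ("int", False, (0, 30)),
        "literate": ("bool", False, None),
        "work_regularity": ("cat", False, set(WORK_REGULARITY)),
        "payment_type": ("cat", False, set(PAYMENT_TYPES)),
        "births_last_5y": ("int", True, (0, None)),
    })
    return specs


def _men_specs():
    return {
        "respondent_id": ("str", True, None),
        "survey_id": ("str", True, None),
        "region_id": ("str", True, None),
        "sample_weight": ("float", True, (0.0, None)),
        "years_schooling": ("int", False, (0, 30)),
        "literate": ("bool", False, None),
        "work_regularity": ("cat", False, set(WORK_REGULARITY)),
        "payment_type": ("cat", False, set(PAYMENT_TYPES)),
    }


def _births_specs():
    return {
        "respondent_id": ("str", True, None),
        "survey_id": ("str", True, None),
        "birth_index": ("int", True, (0, None)),
        "antenatal_visits": ("int", False, (0, 60)),
        "professional_delivery": ("bool", False, None),
        "postnatal_within_2mo": ("bool", False, None),
    }


# ---------------------------------------------------------------------------
# Survey bundles
# ---------------------------------------------------------------------------


@dataclass
class SurveyBundle:
    """All microdata for one or more surveys plus parse diagnostics."""

    women: pd.DataFrame
    births: pd.DataFrame
    men: pd.DataFrame
    metas: dict  # survey_id -> SurveyMeta
    diagnostics: list = field(default_factory=list)

    def survey_ids(self):
        return sorted(self.metas)

    def for_survey(self, survey_id: str) -> "SurveyBundle":
        return SurveyBundle(
            women=self.women[self.women.survey_id == survey_id].reset_index(drop=True),
            births=self.births[self.births.survey_id == survey_id].reset_index(drop=True),
            men=self.men[self.men.survey_id == survey_id].reset_index(drop=True),
            metas={survey_id: self.metas[survey_id]},
            diagnostics=self.diagnostics,
        )

    def woman_records(self):
        return [
            woman_record_from_row(row, self.births)
            for row in self.women.itertuples(index=False)
        ]

    def man_records(self):
        return [man_record_from_row(r) for r in self.men.itertuples(index=False)]


def _opt_int(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)


def _opt_bool(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else bool(int(v))


def woman_record_from_row(row, births: pd.DataFrame) -> WomanRecord:
    b = births[(births.respondent_id == row.respondent_id)
               & (births.survey_id == row.survey_id)]
    events = [
        BirthEvent(
            antenatal_visits=_opt_int(e.antenatal_visits),
            professional_delivery=_opt_bool(e.professional_delivery),
            postnatal_within_2mo=_opt_bool(e.postnatal_within_2mo),
        )
        for e in b.sort_values("birth_index").itertuples(index=False)
    ]
    return WomanRecord(
        respondent_id=row.respondent_id,
        survey_id=row.survey_id,
        region_id=row.region_id,
        sample_weight=float(row.sample_weight),
        age=int(row.age),
        currently_married=bool(int(row.currently_married)),
        age_first_marriage=_opt_int(row.age_first_marriage),
        age_first_birth=_opt_int(row.age_first_birth),
        wants_child_within_2y=_opt_bool(row.wants_child_within_2y),
        uses_modern_contraception=_opt_bool(row.uses_modern_contraception),
        decision_answers=tuple(getattr(row, q) for q in DECISION_QUESTIONS),
        beating_justified=tuple(getattr(row, q) for q in BEATING_QUESTIONS),
        years_schooling=_opt_int(row.years_schooling),
        literate=_opt_bool(row.literate),
        work_regularity=row.work_regularity,
        payment_type=row.payment_type,
        births_last_3y=events,
        births_last_5y=int(row.births_last_5y),
    )


def man_record_from_row(row) -> ManRecord:
    return ManRecord(
        respondent_id=row.respondent_id,
        survey_id=row.survey_id,
        region_id=row.region_id,
        sample_weight=float(row.sample_weight),
        years_schooling=_opt_int(row.years_schooling),
        literate=_opt_bool(row.literate),
        work_regularity=row.work_regularity,
        payment_type=row.payment_type,
    )


def _fmt(v):
    if v is None:
        return ""
    if isinstance(v, float):
        if np.isnan(v):
            return ""
        if v == int(v):
            return str(int(v))
        return repr(v)
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    return str(v)


def frames_from_records(women_records, men_records):
    """Build (women, births, men) string frames from record objects."""
    wrows, brows = [], []
    for w in women_records:
        w.validate()
        row = {
            "respondent_id": w.respondent_id,
            "survey_id": w.survey_id,
            "region_id": w.region_id,
            "sample_weight": _fmt(float(w.sample_weight)),
            "age": _fmt(w.age),
            "currently_married": _fmt(w.currently_married),
            "age_first_marriage": _fmt(w.age_first_marriage),
            "age_first_birth": _fmt(w.age_first_birth),
            "wants_child_within_2y": _fmt(w.wants_child_within_2y),
            "uses_modern_contraception": _fmt(w.uses_modern_contraception),
            "years_schooling": _fmt(w.years_schooling),
            "literate": _fmt(w.literate),
            "work_regularity": _fmt(w.work_regularity),
            "payment_type": _fmt(w.payment_type),
            "births_last_5y": _fmt(w.births_last_5y),
        }
        for q, a in zip(DECISION_QUESTIONS, w.decision_answers):
            row[q] = _fmt(a)
        for q, a in zip(BEATING_QUESTIONS, w.beating_justified):
            row[q] = _fmt(a)
        wrows.append(row)
        for i, b in enumerate(w.births_last_3y):
            brows.append({
                "respondent_id": w.respondent_id,
                "survey_id": w.survey_id,
                "birth_index": str(i),
                "antenatal_visits": _fmt(b.antenatal_visits),
                "professional_delivery": _fmt(b.professional_delivery),
                "postnatal_within_2mo": _fmt(b.postnatal_within_2mo),
            })
    mrows = []
    for m in men_records:
        m.validate()
        mrows.append({
            "respondent_id": m.respondent_id,
            "survey_id": m.survey_id,
            "region_id": m.region_id,
            "sample_weight": _fmt(float(m.sample_weight)),
            "years_schooling": _fmt(m.years_schooling),
            "literate": _fmt(m.literate),
            "work_regularity": _fmt(m.work_regularity),
            "payment_type": _fmt(m.payment_type),
        })
    women = pd.DataFrame(wrows, columns=WOMEN_COLUMNS).astype(str) if wrows else \
        pd.DataFrame(columns=WOMEN_COLUMNS, dtype=str)
    births = pd.DataFrame(brows, columns=BIRTHS_COLUMNS).astype(str) if brows else \
        pd.DataFrame(columns=BIRTHS_COLUMNS, dtype=str)
    men = pd.DataFrame(mrows, columns=MEN_COLUMNS).astype(str) if mrows else \
        pd.DataFrame(columns=MEN_COLUMNS, dtype=str)
    return women, births, men


def write_survey(out_dir, women, births, men, metas) -> None:
    """Write a survey bundle (string or typed frames accepted)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stringify(df, columns):
        out = df.copy()
        for c in columns:
            if c not in out.columns:
                out[c] = ""
        if len(out):
            out = out[list(columns)].map(_fmt_cell)
        else:
            out = out[list(columns)]
        return out

    write_table(stringify(women, WOMEN_COLUMNS), out_dir / "women.csv", "women",
                WOMEN_COLUMNS)
    write_table(stringify(births, BIRTHS_COLUMNS), out_dir / "births.csv", "births",
                BIRTHS_COLUMNS)
    write_table(stringify(men, MEN_COLUMNS), out_dir / "men.csv", "men", MEN_COLUMNS)
    write_survey_meta(out_dir / "survey_meta.csv", metas)


def _fmt_cell(v):
    if isinstance(v, str):
        return v
    return _fmt(v)


def write_survey_meta(path, metas) -> None:
    rows = []
    for sid in sorted(metas):
        m = metas[sid]
        m.validate()
        omitted = sorted(ALL_QUESTIONS - set(m.question_coverage))
        rows.append({
            "survey_id": m.survey_id,
            "country_code": m.country_code,
            "survey_year": str(m.survey_year),
            "scheme_id": m.scheme_id,
            "questions_omitted": ";".join(omitted),
        })
    df = pd.DataFrame(rows, columns=META_COLUMNS) if rows else \
        pd.DataFrame(columns=META_COLUMNS, dtype=str)
    write_table(df, path, "survey_meta", META_COLUMNS)


def read_survey_meta(path) -> dict:
    raw = read_table(path, "survey_meta", META_COLUMNS)
    metas = {}
    for row in raw.itertuples(index=False):
        omitted = {q for q in row.questions_omitted.split(";") if q}
        unknown = omitted - ALL_QUESTIONS
        if unknown:
            raise SchemaError(f"survey_meta: unknown questions {sorted(unknown)}")
        meta = SurveyMeta(
            survey_id=row.survey_id,
            country_code=row.country_code,
            survey_year=int(row.survey_year),
            scheme_id=row.scheme_id,
            question_coverage=frozenset(ALL_QUESTIONS - omitted),
        )
        meta.validate()
        metas[meta.survey_id] = meta
    return metas


def read_survey(in_dir) -> SurveyBundle:
    """Read a survey bundle directory, validating every row.

    Invalid rows are rejected with row-numbered :class:`Diagnostic` entries;
    valid rows are always kept (kept + rejected = input rows, per table).
    """
    in_dir = Path(in_dir)
    raw_w = read_table(in_dir / "women.csv", "women", WOMEN_COLUMNS)
    raw_b = read_table(in_dir / "births.csv", "births", BIRTHS_COLUMNS)
    raw_m = read_table(in_dir / "men.csv", "men", MEN_COLUMNS)
    women, d1 = _check_columns(raw_w, _women_specs(), "women")
    births, d2 = _check_columns(raw_b, _births_specs(), "births")
    men, d3 = _check_columns(raw_m, _men_specs(), "men")
    metas = read_survey_meta(in_dir / "survey_meta.csv")
    return SurveyBundle(women=women, births=births, men=men, metas=metas,
                        diagnostics=d1 + d2 + d3)


# ---------------------------------------------------------------------------
# Crosswalk
# ---------------------------------------------------------------------------


@dataclass
class RegionCrosswalk:
    """Mapping from survey region schemes to current admin-1 units.

    Within one scheme the survey regions must partition the admin-1 units:
    each admin-1 id belongs to exactly one survey region.
    """

    table: pd.DataFrame  # columns: scheme_id, survey_region_id, admin1_id

    def __post_init__(self):
        dup = self.table.duplicated(subset=["scheme_id", "admin1_id"], keep=False)
        if dup.any():
            bad = sorted(self.table.loc[dup, "admin1_id"].unique())
            raise CrosswalkError(
                f"admin-1 units mapped by more than one survey region: {bad}")

    def schemes(self):
        return sorted(self.table.scheme_id.unique())

    def members(self, scheme_id: str, survey_region_id: str):
        t = self.table
        sel = t[(t.scheme_id == scheme_id) & (t.survey_region_id == survey_region_id)]
        return sorted(sel.admin1_id)

    def admin1_units(self, scheme_id: str):
        return sorted(self.table[self.table.scheme_id == scheme_id].admin1_id)

    def region_of(self, scheme_id: str) -> dict:
        """admin1_id -> survey_region_id for one scheme."""
        t = self.table[self.table.scheme_id == scheme_id]
        return dict(zip(t.admin1_id, t.survey_region_id))

    def is_identity(self, scheme_id: str) -> bool:
        t = self.table[self.table.scheme_id == scheme_id]
        return bool((t.survey_region_id == t.admin1_id).all())

    def check_complete(self, scheme_id: str, admin1_ids) -> None:
        missing = set(admin1_ids) - set(self.admin1_units(scheme_id))
        if missing:
            raise CrosswalkError(
                f"scheme {scheme_id!r} does not cover admin-1 units "
                f"{sorted(missing)}")


def crosswalk_from_mapping(mapping: dict) -> RegionCrosswalk:
    """Build a crosswalk from {scheme_id: {survey_region: [admin1, ...]}}."""
    rows = [
        {"scheme_id": sch, "survey_region_id": reg, "admin1_id": a1}
        for sch, regions in mapping.items()
        for reg, members in regions.items()
        for a1 in members
    ]
    return RegionCrosswalk(pd.DataFrame(rows, columns=CROSSWALK_COLUMNS))


def identity_crosswalk(scheme_id: str, admin1_ids) -> RegionCrosswalk:
    return crosswalk_from_mapping({scheme_id: {a: [a] for a in admin1_ids}})


def write_crosswalk(path, crosswalk: RegionCrosswalk) -> None:
    df = crosswalk.table.sort_values(CROSSWALK_COLUMNS).reset_index(drop=True)
    write_table(df.astype(str), path, "crosswalk", CROSSWALK_COLUMNS)


def read_crosswalk(path) -> RegionCrosswalk:
    raw = read_table(path, "crosswalk", CROSSWALK_COLUMNS)
    return RegionCrosswalk(raw)


# ---------------------------------------------------------------------------
# Covariates / population / derived tables
# ---------------------------------------------------------------------------

_NUMERIC = {
    "covariates": (COVARIATES_COLUMNS, ["year", "hdi", "maternal_mortality",
                                        "gdp_per_capita", "gdi", "gii"]),
    "population": (POPULATION_COLUMNS, ["longitude", "latitude",
                                        "female_population",
                                        "population_density"]),
    "region_scores": (SCORES_COLUMNS, ["score", "effective_n", "women_raw",
                                       "men_raw"]),
    "estimates": (ESTIMATES_COLUMNS, ["year", "estimate", "n_surveys_used"]),
    "ground_truth": (GROUND_TRUTH_COLUMNS, ["year", "women_latent",
                                            "men_latent", "latent"]),
    "expected_observed": (EXPECTED_COLUMNS, ["expected"]),
}


def _write_numeric(df, path, table):
    columns, numeric = _NUMERIC[table]
    out = df.copy()
    for c in columns:
        if c not in out.columns:
            out[c] = np.nan if c in numeric else ""
    out = out[columns]
    for c in numeric:
        out[c] = pd.to_numeric(out[c])
    write_table(out, path, table, columns, float_format="%.6f")


def _read_numeric(path, table):
    columns, numeric = _NUMERIC[table]
    raw = read_table(path, table, columns)
    for c in numeric:
        raw[c] = pd.to_numeric(raw[c].replace("", np.nan))
    for c in ("year", "effective_n", "n_surveys_used", "survey_year"):
        if c in raw.columns:
            raw[c] = raw[c].astype(int) if raw[c].notna().all() else raw[c]
    return raw


def write_covariates(path, df):
    _write_numeric(df, path, "covariates")


def read_covariates(path):
    return _read_numeric(path, "covariates")


def write_population(path, df):
    _write_numeric(df, path, "population")


def read_population(path):
    return _read_numeric(path, "population")


def write_scores(path, df):
    _write_numeric(df, path, "region_scores")


def read_scores(path):
    return _read_numeric(path, "region_scores")


def write_estimates(path, df):
    _write_numeric(df, path, "estimates")


def read_estimates(path):
    return _read_numeric(path, "estimates")


def write_ground_truth(path, df):
    _write_numeric(df, path, "ground_truth")


def read_ground_truth(path):
    return _read_numeric(path, "ground_truth")


def write_expected_observed(path, df):
    _write_numeric(df, path, "expected_observed")


def read_expected_observed(path):
    return _read_numeric(path, "expected_observed")
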