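"""End-to-end pipeline: score -> impute -> harmonize -> estimate -> FEMI -> summarize.

Every stage reads and writes CSV artifacts (no in-memory-only handoff), so
each stage can be re-run or tested in isolation, and a JSON manifest of
input/output hashes makes byte-level reproducibility checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .estimate import DEFAULT_REFERENCE_YEARS, estimate_reference_years
from .harmonize import HarmonizationPlan, SurveyPlan, harmonize_scores
from .impute import build_region_features, impute_missing, report_frame
from .records import FEMI
from .scoring import build_region_scores, score_men, score_women
from .summaries import (
    all_country_ranges,
    compute_femi,
    continental_summary,
    country_femi,
    domain_correlations,
    most_recent_survey_scores,
    national_regressions,
)

log = logging.getLogger("femi")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    reference_years: tuple = DEFAULT_REFERENCE_YEARS
    seed: int = 0
    use_sample_weights: bool = True
    femi_combiner: str = "mean"
    plan_path: str | None = None
    log_level: str = "INFO"

    def validate(self):
        if not self.reference_years:
            raise PipelineConfigError("reference_years must be nonempty")
        if not isinstance(self.seed, int):
            raise PipelineConfigError("seed must be an integer")
        if self.femi_combiner not in ("mean", "median"):
            raise PipelineConfigError(
                f"femi_combiner must be mean|median, got {self.femi_combiner!r}")
        ind = Path(self.input_dir)
        if not ind.is_dir():
            raise PipelineConfigError(f"input directory {ind} does not exist")
        for name in ("women.csv", "men.csv", "births.csv", "survey_meta.csv",
                     "crosswalk.csv", "covariates.csv", "population.csv"):
            if not (ind / name).exists():
                raise PipelineConfigError(f"missing input file {ind / name}")
        if self.plan_path and not Path(self.plan_path).exists():
            raise PipelineConfigError(f"plan file {self.plan_path} not found")


def load_pipeline_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise PipelineConfigError(f"{path}: expected a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "reference_years" in raw:
        raw["reference_years"] = tuple(int(y) for y in raw["reference_years"])
    return PipelineConfig(**raw)


def load_plan(path) -> HarmonizationPlan:
    """Read per-survey harmonization overrides from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    plan = HarmonizationPlan()
    for sid, entry in raw.get("surveys", {}).items():
        plan.add(SurveyPlan(
            survey_id=sid,
            method=entry["method"],
            before_survey=entry.get("before_survey"),
            after_survey=entry.get("after_survey"),
            predictor_survey=entry.get("predictor_survey"),
            region_subset=tuple(entry["region_subset"])
            if entry.get("region_subset") else None,
        ))
    return plan


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class Manifest:
    seed: int
    stages: list = field(default_factory=list)

    def record(self, stage, outputs, seconds):
        self.stages.append({
            "stage": stage,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        })

    def write(self, path):
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "stages": self.stages}, indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest as a dict.

    Raises :class:`PipelineConfigError` before any stage runs if the config
    or inputs are invalid, and :class:`StageError` on stage failure.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(seed=config.seed)
    seed_impute = (config.seed * 31 + 1) % (2 ** 31)
    seed_estimate = (config.seed * 31 + 2) % (2 ** 31)

    def stage(name, fn):
        t0 = time.time()
        try:
            outputs = fn()
        except (PipelineConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named reporting
            raise StageError(name, exc) from exc
        manifest.record(name, outputs, time.time() - t0)
        manifest.write(out / "manifest.json")
        log.info("stage %s done", name)
        return outputs

    state = {}

    def load():
        bundle = fio.read_survey(config.input_dir)
        state["bundle"] = bundle
        state["crosswalk"] = fio.read_crosswalk(Path(config.input_dir) / "crosswalk.csv")
        state["covariates"] = fio.read_covariates(Path(config.input_dir) / "covariates.csv")
        state["population"] = fio.read_population(Path(config.input_dir) / "population.csv")
        if bundle.diagnostics:
            diag = pd.DataFrame([vars(d) for d in bundle.diagnostics])
            diag.to_csv(out / "input_diagnostics.csv", index=False)
            log.warning("%d input rows rejected", len(bundle.diagnostics))
        return []

    def score():
        bundle = state["bundle"]
        wparts, mparts = [], []
        for sid in bundle.survey_ids():
            sub = bundle.for_survey(sid)
            cov = bundle.metas[sid].question_coverage
            wparts.append(score_women(sub.women, sub.births, cov))
            if len(sub.men):
                mparts.append(score_men(sub.men))
        wscores = pd.concat(wparts, ignore_index=True)
        mscores = (pd.concat(mparts, ignore_index=True)
                   if mparts else pd.DataFrame(columns=["survey_id"]))
        table = build_region_scores(wscores, mscores,
                                    use_sample_weights=config.use_sample_weights)
        state["region_scores"] = table
        state["women_scores"] = wscores
        fio.write_scores(out / "region_scores.csv", table)
        return [out / "region_scores.csv"]

    def impute():
        feats = build_region_features(state["bundle"], state["crosswalk"],
                                      state["population"])
        table, reports = impute_missing(state["region_scores"], feats,
                                        seed=seed_impute)
        state["imputed"] = table
        report_frame(reports).to_csv(out / "imputation_report.csv", index=False)
        fio.write_scores(out / "imputed.csv", table)
        return [out / "imputed.csv", out / "imputation_report.csv"]

    def harmonize():
        plan = load_plan(config.plan_path) if config.plan_path else None
        table = harmonize_scores(state["imputed"], state["bundle"].metas,
                                 state["crosswalk"], state["population"],
                                 plan=plan)
        state["harmonized"] = table
        fio.write_scores(out / "harmonized.csv", table)
        return [out / "harmonized.csv"]

    def estimate():
        est = estimate_reference_years(
            state["harmonized"], state["bundle"].metas, state["covariates"],
            state["population"], reference_years=config.reference_years,
            seed=seed_estimate)
        state["estimates"] = est
        fio.write_estimates(out / "estimates_domains.csv", est)
        return [out / "estimates_domains.csv"]

    def femi():
        est = compute_femi(state["estimates"], combiner=config.femi_combiner)
        state["estimates_femi"] = est
        fio.write_estimates(out / "estimates.csv", est)
        return [out / "estimates.csv"]

    def summarize():
        # read the persisted table back so a later isolated re-run of this
        # stage sees byte-identical inputs (6-decimal CSV precision)
        est = fio.read_estimates(out / "estimates.csv")
        return summarize_stage(
            est, state["harmonized"],
            state["bundle"].metas, state["population"], state["covariates"],
            out, config.reference_years)

    stage("load", load)
    stage("score", score)
    stage("impute", impute)
    stage("harmonize", harmonize)
    stage("estimate", estimate)
    stage("femi", femi)
    stage("summarize", summarize)
    return {"seed": manifest.seed, "stages": manifest.stages}


def summarize_stage(estimates, harmonized, metas, population, covariates,
                    out_dir, reference_years):
    """Write the four report tables; separated so it can re-run alone."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []

    cont = continental_summary(estimates, population)
    cont.round(6).to_csv(out / "continental_summary.csv", index=False)
    outputs.append(out / "continental_summary.csv")

    ranges = pd.concat([all_country_ranges(estimates, population, y)
                        for y in reference_years], ignore_index=True)
    ranges.round(6).to_csv(out / "country_ranges.csv", index=False)
    outputs.append(out / "country_ranges.csv")

    if harmonized is not None and metas is not None:
        wide = most_recent_survey_scores(harmonized, metas)
        if len(wide) >= 3:
            corr = domain_correlations(wide)
            corr.round(6).to_csv(out / "domain_correlations.csv")
            outputs.append(out / "domain_correlations.csv")

    reg_parts = []
    for year in reference_years:
        femi_c = country_femi(estimates, population, year)
        if len(femi_c) >= 3:
            reg_parts.append(national_regressions(femi_c, covariates, year))
    if reg_parts:
        pd.concat(reg_parts, ignore_index=True).round(6).to_csv(
            out / "national_regressions.csv", index=False)
        outputs.append(out / "national_regressions.csv")
    return outputs


def rerun_summarize(estimates_path, population_path, covariates_path,
                    out_dir, reference_years=None):
    """Stage-isolation entry point: rebuild reports from saved estimates."""
    est = fio.read_estimates(estimates_path)
    population = fio.read_population(population_path)
    covariates = fio.read_covariates(covariates_path)
    years = (tuple(sorted(est[est.domain == FEMI].year.unique()))
             if reference_years is None else tuple(reference_years))
    return summarize_stage(est, None, None, population, covariates,
                           out_dir, years)
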