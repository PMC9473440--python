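"""Shared test utilities: random record generation and bundle scoring."""

import numpy as np
import pandas as pd

from femi.records import (
    BEATING_ANSWERS,
    DECISION_ANSWERS,
    PAYMENT_TYPES,
    WORK_REGULARITY,
    BirthEvent,
    WomanRecord,
)
from femi.scoring import build_region_scores, score_men, score_women


def random_woman(rng, i=0, survey_id="S1", region_id="R1"):
    """One random woman record spanning the full answer space incl. missing."""

    def maybe(value, p_missing=0.25):
        return None if rng.random() < p_missing else value

    age = int(rng.integers(15, 50))
    married = bool(rng.random() < 0.6)
    births = []
    for _ in range(int(rng.integers(0, 3))):
        births.append(BirthEvent(
            antenatal_visits=maybe(int(rng.integers(0, 9))),
            professional_delivery=maybe(bool(rng.integers(0, 2))),
            postnatal_within_2mo=maybe(bool(rng.integers(0, 2))),
        ))
    return WomanRecord(
        respondent_id=f"W{i:05d}",
        survey_id=survey_id,
        region_id=region_id,
        sample_weight=float(np.round(rng.uniform(0.1, 3.0), 6)),
        age=age,
        currently_married=married,
        age_first_marriage=maybe(int(rng.integers(12, age + 1))) if married else None,
        age_first_birth=maybe(int(rng.integers(12, age + 1))),
        wants_child_within_2y=maybe(bool(rng.integers(0, 2))),
        uses_modern_contraception=maybe(bool(rng.integers(0, 2))),
        decision_answers=tuple(maybe(str(rng.choice(DECISION_ANSWERS)))
                               for _ in range(5)),
        beating_justified=tuple(maybe(str(rng.choice(BEATING_ANSWERS)))
                                for _ in range(5)),
        years_schooling=maybe(int(rng.integers(0, 15))),
        literate=maybe(bool(rng.integers(0, 2))),
        work_regularity=maybe(str(rng.choice(WORK_REGULARITY))),
        payment_type=maybe(str(rng.choice(PAYMENT_TYPES))),
        births_last_3y=births,
        births_last_5y=int(rng.integers(0, 5)),
    )


def score_bundle(bundle, use_sample_weights=True):
    """Score a (multi-survey) bundle into the region score table."""
    wparts, mparts = [], []
    for sid in bundle.survey_ids():
        sub = bundle.for_survey(sid)
        cov = bundle.metas[sid].question_coverage
        wparts.append(score_women(sub.women, sub.births, cov))
        if len(sub.men):
            mparts.append(score_men(sub.men))
    women = pd.concat(wparts, ignore_index=True)
    men = (pd.concat(mparts, ignore_index=True)
           if mparts else pd.DataFrame(columns=["survey_id"]))
    return build_region_scores(women, men, use_sample_weights=use_sample_weights)
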