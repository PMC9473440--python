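# femi

Subnational estimation of women's empowerment from household survey
microdata: six domain scores and their composite, the **Female Empowerment
Index (FEMI)**, for first-level administrative subdivisions (admin-1),
carried to fixed reference years.

## Who this is for

Researchers working with DHS-style survey microdata (one record per woman
aged 15–49, plus men's education/employment records and sampling weights)
who need *subnational*, *comparable-over-time* empowerment estimates —
and anyone who needs the supporting machinery: boundary harmonization
across changing region schemes, Random-Forest imputation of omitted
question blocks, and population-weighted summary statistics.

## The model

Each respondent's answers are coded on [0, 1] (0 = disempowerment,
1 = empowerment) into six domains:

* **Family Planning** — modern contraceptive use among married women who
  do not want a child within two years;
* **Reproductive Healthcare** — mean of antenatal care (0 / 0.5 / 1 by
  visit count), professional delivery, postnatal care, and adolescent
  childbearing (first birth before 18);
* **Intimate Partner Violence** — mean of attitudes toward wife-beating
  (five questions) and child marriage (married before 18);
* **Decision-Making** — share of five household decisions in which the
  woman has a say;
* **Education** — primary completion (≥ 6 years) and literacy;
* **Employment** — work regularity and payment type.

Education and Employment are adjusted for gender inequality at region
level: `adjusted = w · (w / m)` where `w`, `m` are the women's and men's
region scores — areas where both genders score low are unaffected, areas
where men outscore women are penalized. Region scores are sample-weighted
respondent means; missing region×domain cells are imputed by a pooled
Random Forest; historical super-regions are downscaled onto current
admin-1 units preserving observed aggregates; reference-year estimates use
a three-way rule (reassign a survey within ±2 years / per-region linear
trend / Random-Forest prediction from HDI, maternal mortality and
population density); FEMI is the mean of the six domain estimates. See
`docs/methods.md` for the full specification.

A synthetic-data generator (`femi.simulate`) produces DHS-like
multi-survey bundles with known latent scores, so every stage is testable
by parameter recovery.

## Worked example

Generate a small synthetic country (3 regions, surveys in 2004 and 2014)
and run the full pipeline:

```bash
femi simulate --fixture two-survey-trend --seed 7 --out demo/in
femi run --config pipeline.yaml     # input_dir: demo/in, output_dir: demo/out,
                                    # reference_years: [2005, 2015], seed: 1
```

`demo/out/estimates.csv` then contains one estimate per region × year ×
domain (FEMI shown here):

```
admin1_id  year  domain   estimate   method
C01:R01    2005  femi     0.417390   composite
C01:R01    2015  femi     0.458197   composite
C01:R02    2005  femi     0.495138   composite
C01:R02    2015  femi     0.530742   composite
C01:R03    2005  femi     0.515773   composite
C01:R03    2015  femi     0.569057   composite
```

Both reference years were within two years of a survey, so the domain
estimates underneath each FEMI row are direct reassignments of the 2004
and 2014 surveys. FEMI rises with time (the configured annual trend) and
from north (R01) to south (R03) (the configured latitude gradient).
`demo/out/continental_summary.csv` holds the population-weighted median
and 10th–90th percentile band per domain and year — for FEMI in 2015:
median 0.531, band 0.458–0.569 — and `manifest.json` records a hash of
every artifact for reproducibility checks.

The same stages are available as library functions
(`femi.scoring.build_region_scores`, `femi.impute.impute_missing`,
`femi.harmonize.harmonize_scores`, `femi.estimate.estimate_reference_years`,
`femi.summaries.compute_femi`, …) and as individual subcommands
(`femi score`, `femi impute`, `femi harmonize`, `femi estimate`,
`femi summarize`).

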