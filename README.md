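# brcascreen

Population genetic screening for breast cancer combines three signals that
standard care usually misses: rare pathogenic variants in five moderate- to
high-penetrance genes (BRCA1, BRCA2, PALB2, ATM, CHEK2), a common-variant
polygenic risk score (PRS), and a recorded family history of breast cancer.
`brcascreen` implements the full analysis stack for studying how these
signals stratify risk in an unselected cohort of women:

* a **synthetic cohort generator** that emits an electronic-health-record-like
  population (ICD-10 diagnosis streams, carrier genotypes, raw PRS values,
  family-history codes) with known, configurable ground truth;
* an automated **variant-interpretation cascade** (ClinVar review status,
  the founder CHEK2 c.1100del allele, LOFTEE high-confidence predicted
  loss-of-function, CNV deletion rules);
* a **PRS engine** (PGS-Catalog scoring files, dosage fallbacks, percentile
  ranks computed *within* genetic-similarity groups);
* **survival models** re-implemented from first principles: Kaplan–Meier with
  Greenwood intervals, Cox proportional hazards with the Efron tie
  correction, and the two-sample log-rank test;
* **family-history timing analysis** quantifying ascertainment bias (how
  often the Z80.3 code appears only at or after the index diagnosis);
* **screening-strategy evaluation** (PPV, specificity, number needed to
  screen, false negatives) and **association statistics** (Fisher exact,
  Welch t).

The time-to-event scale is age: time zero at birth, censoring at the current
age, so Kaplan–Meier curves read directly as "% of women diagnosed by age".

## Worked example

```python
from brcascreen import (SimConfig, generate_cohort, build_analysis_frame,
                        RiskStratification)

cohort = generate_cohort(SimConfig(seed=0))      # 25,591 women, ~410 carriers
frame = build_analysis_frame(cohort)             # tidy survival frame
results = RiskStratification(frame).fit()        # Cox + KM + strategies
print(results.summary().head(10).to_string(index=False))
```

```
                                quantity    value   ci_low   ci_high
         HR BRCA1 carrier vs non-carrier 9.432310 6.243813 14.249062
         HR BRCA2 carrier vs non-carrier 7.878473 5.546662 11.190577
         HR PALB2 carrier vs non-carrier 9.117542 5.796687 14.340874
           HR ATM carrier vs non-carrier 2.548044 1.407729  4.612058
         HR CHEK2 carrier vs non-carrier 3.784508 2.406440  5.951740
                    HR BRCA1_BRCA2_PALB2 9.939984 7.849946 12.586492
                            HR ATM_CHEK2 3.700946 2.574840  5.319554
                 HR top10_PRS_noncarrier 2.589165 2.276908  2.944244
HR top-10% PRS vs average (non-carriers) 2.656861 2.297634  3.072252
               HR family history vs none 1.085084 0.893564  1.317653
```

The grouped fits recover the generating hazard multipliers (10.4 for
BRCA1/BRCA2/PALB2, 3.4 for ATM/CHEK2, 2.4 for the top PRS decile) within
their confidence intervals. The screening-strategy comparison is part of the
same results object:

```python
print(results.strategy_report[["strategy", "n_pos", "pct_of_population",
                               "ppv_at70_display", "specificity_display",
                               "nns_display", "false_negatives"]]
      .to_string(index=False))
```

```
                   strategy  n_pos  pct_of_population  ppv_at70_display  specificity_display  nns_display  false_negatives
    strategy1_fhx_genes_prs   2027                7.9              16.7                 92.6          209              601
strategy2_genes_or_top10prs   2970               11.6              24.8                 90.2          100              501
```

Strategy 1 refers women with a recorded family history, a BRCA1/BRCA2/PALB2
pathogenic variant, or an ATM/CHEK2 variant plus above-median PRS; strategy 2
ignores family history and refers any five-gene carrier or the top PRS
decile. Family-history / carrier association tests are in
`results.associations`; on the same cohort the carrier-vs-family-history
Fisher odds ratio is 3.77 (exact 95% CI 2.71–5.18), covering the generating
odds ratio 3.5.

## Command line

The `brcascreen` entry point drives the same analysis as a pipeline with a
re-entrant run manifest (completed stages are skipped on rerun; reruns with
the same seed are byte-identical):

```bash
brcascreen run --seed 0 --out-dir results/
brcascreen report --results-dir results/
```

Individual stages are also exposed: `simulate`, `classify`, `prs`,
`survival`, `fhx-timing`, `evaluate`, `associations`.

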