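# Methods note

This note documents the generative model behind the synthetic cohort, the
statistical machinery used to analyse it, the calibration choices and their
rationale, and the limits of what the generator reproduces.

## Generative model

Each simulated woman has:

* **Genetic-similarity group** drawn from fixed proportions corresponding to
  counts 499 (Africa), 3,728 (Americas), 832 (East Asia), 19,484 (Europe),
  929 (Other), 119 (South Asia) out of 25,591.
* **Current age** from a two-component normal mixture (weight 0.72 at mean
  46, sd 11; weight 0.28 at mean 74, sd 7), clipped to [19, 89] — a bimodal
  adult-biobank age structure.
* **EHR window**: a longitudinal span ~ N(12, 5) years truncated to positive,
  ending at the current age.
* **Carrier status**: independent Bernoulli per gene with expected counts
  BRCA1 70, BRCA2 89, PALB2 39, ATM 95, CHEK2 117 (~410 carriers, 1.6%).
* **Raw PRS**: group mean plus a standard normal z; percentiles are always
  computed within the group.
* **Breast-cancer onset** from a proportional-hazards model on the age scale
  with a piecewise-constant baseline over bands [0,40), [40,50), [50,60),
  [60,70), [70,90) with relative rates (0.1, 1.0, 1.4, 1.8, 2.0). The
  individual hazard is baseline × gene multiplier × exp(β·z). Onset ages are
  drawn by inverse-transform sampling of the piecewise-linear cumulative
  hazard; onsets beyond the current age are censored. A diagnosis emits an
  ICD-10 C50.911 code at the onset age.
* **Family history (Z80.3)**: logistic model
  logit p = α + ln(3.5)·carrier + 0.15·z, with α root-found so the marginal
  prevalence is 6.9%. For diagnosed FHx-positive women the code time is
  drawn from the timing mixture (below); for undiagnosed women it is uniform
  over the adult EHR window.
* **Code-timing mixture** for diagnosed FHx-positive women: with probability
  0.22 the Z80.3 code lands more than a week before the diagnosis, 0.30
  within the simultaneous window (7 days before to 30 days after), 0.48
  more than a month after. The 0.30/0.48 split is the empirical reference;
  "before" is the remainder.
* **Comparator codes** (I10 hypertension 35%, E11 type-2 diabetes 12%) and
  non-breast family-history codes (Z82.49 et al., 26.8%) populate the EHR
  stream so that timing-specificity analyses have something to compare
  against.

### Calibration

Two scalar calibrations are solved at generation time:

1. **Baseline scale.** The global hazard scale is found by `brentq` so that
   a carrier-free woman in the percentile-30–70 PRS band has a cumulative
   incidence of 9.3% by age 70; the expectation over the band is evaluated
   by quadrature over the truncated normal.
2. **PRS effect β.** The top-decile hazard ratio contrasts
   E[e^{βZ} | Z > q90] with E[e^{βZ} | q30 < Z < q70]. Both conditional
   expectations have closed forms via the truncated-normal moment-generating
   function, and β is root-found so the ratio equals 2.4 (β ≈ 0.49).

### Gene hazard multipliers: group-level defaults

The pooled analyses group BRCA1/BRCA2/PALB2 (target hazard ratio 10.4) and
ATM/CHEK2 (target 3.4). If the generator instead used per-gene multipliers
(16.2, 8.5, 6.3, 4.3, 2.6), the *pooled* Cox fit would not recover 10.4: a
pooled binary indicator over heterogeneous hazards estimates approximately
the event-weighted mean of the per-gene hazard ratios
(Σ n_g·HR_g² / Σ n_g·HR_g ≈ 12.3 for those values), biased above the
carrier-weighted mean. The defaults therefore apply the group value to every
gene in the group — 10.4 for BRCA1/BRCA2/PALB2 and 3.4 for ATM/CHEK2 — which
makes the pooled recovery target well-posed. The per-gene values remain a
drop-in alternative configuration via `SimConfig(gene_hr=...)`.

## Analysis methods

* **Kaplan–Meier**: product-limit estimator with Greenwood variance and
  plain delta-method 95% intervals, clipped to [0, 1]. Cumulative incidence
  is 1 − S(age). No left truncation: time zero is birth, censoring at the
  current age.
* **Cox proportional hazards**: Efron correction for tied event ages
  (ages recorded in whole years are heavily tied), damped Newton
  maximization (step halving on likelihood decrease), convergence tolerance
  1e-8 on the coefficients, at most 100 iterations, Wald intervals with
  z = 1.959964. Risk-set sums are computed by cumulative sums over
  descending times; untied event times use the vectorized path, tied groups
  take the explicit Efron inner loop. Indicator strata whose members have
  no events are dropped with a warning and reported as NaN (their maximum
  partial-likelihood estimate is at −∞).
* **Log-rank**: two-sample chi-square with the hypergeometric variance.
* **PRS percentiles**: average ranks within the genetic-similarity group,
  100·r/N; "top X%" means percentile strictly above 100·(1−X). Dosage
  fallback order: genotype probabilities → hard call → 2 × reference allele
  frequency; scoring variants with more than 10% of participants lacking
  both GP and GT are dropped (callability QC).
* **Screening metrics**: PPV = KM event probability by 70 among positives;
  specificity = TN/(TN+FP) with KM-weighted masses; NNS =
  1/((n_pos/n_total) × P(diagnosis by 50 | positive)); false negatives =
  women diagnosed before 50 and not flagged.
* **Associations**: Fisher's exact test (two-sided point-probability
  method) with the sample odds ratio ad/bc and the exact conditional CI;
  Welch's unequal-variance t test; Pearson chi-square without continuity
  correction for timing enrichment. These run on undiagnosed women of the
  largest genetic-similarity group with group-standardized raw scores.

## What the generator does and does not emulate

Reproduced by construction (and verified by the parameter-recovery tests):
the cohort size and group mix, carrier counts, the 9.3% baseline cumulative
incidence at 70, the grouped hazard ratios 10.4 / 3.4, the top-decile PRS
hazard ratio 2.4, the family-history prevalence 6.9% and carrier odds ratio
3.5, and the 30% / 48% simultaneous/after code-timing fractions.

Deliberately **not** emulated:

* **The family-history hazard ratio ≈ 4.9.** In real EHR data the Z80.3
  code predicts diagnosis largely *because* it is often recorded at or
  after the diagnosis (ascertainment bias). The generator ties family
  history to diagnosis only through carrier status and PRS, so its
  any-time family-history hazard ratio is close to 1.1. The timing
  machinery (classification, enrichment, debiasing) is exercised on the
  timing mixture instead.
* Empirical descriptive counts, the observed AUCs (0.63/0.66), observed
  per-strategy PPV levels, and specific figure read-outs (39.2%, 14.4%):
  these depend on the real cohort's covariance structure and are treated as
  calibration references and report-format checks only.
* **NNS for strategy 2**: from unrounded inputs the value computes to ≈215;
  the published 213 arises from intermediate rounding
  (0.114 × 0.041 → 0.0047). The package computes from unrounded inputs and
  rounds once at the end; 183 for strategy 1 reproduces exactly, 213 is
  documented here rather than asserted.

## Numerical choices

* `scipy.optimize.brentq` for the two scalar calibrations (both objectives
  are monotone; infeasible settings raise instead of silently clamping).
* Inverse-transform sampling of the piecewise-linear cumulative hazard; the
  inverse returns +∞ beyond the total integral (no event within [0, 90)).
* Deterministic generation given `SimConfig.seed` via
  `numpy.random.default_rng`; pipeline reruns with the same seed are
  byte-identical, and the run manifest stores SHA-256 digests of all
  artifacts.
* Cox log-partial-likelihood shifts the linear predictor by its maximum
  before exponentiation (overflow guard; the partial likelihood is
  invariant).

## Limitations

* Carrier status is independent across genes and of the PRS, ages are not
  cohort-entry-censored (no left truncation), and hazards are proportional
  by construction — all simplifications relative to a real population.
* The variant-interpretation cascade is intentionally automated and
  rule-based; it does not attempt diagnostic-grade ACMG classification.
* Specificity and PPV use KM-weighted masses rather than individual-level
  confusion counts, matching the evaluation definitions rather than a
  fixed-horizon cohort tally.
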