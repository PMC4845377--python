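# mdd-comorbidity

Matched case-control analysis of how chronic somatic conditions influence
the risk of a first major depressive disorder (MDD) diagnosis, built as a
fully synthetic, end-to-end testable pipeline over longitudinal EHR-style
event data.

Real EHR studies of this design cannot ship their data. This package
therefore couples every analysis stage to a synthetic-EHR generator with
*known* planted effects, so the whole chain — rule-based case phenotyping,
1:1 matching, comorbidity ascertainment, conditional logistic regression,
and gradient-boosting relative influence — can be exercised, validated
against independent oracles, and calibrated (parameter recovery, CI
coverage, type-I error) without any external data. It is aimed at
epidemiologists and methodologists who want a transparent, reproducible
reference implementation of this study design.

## The design and its statistics

1. **Phenotyping.** A patient is an MDD case when at least two of four
   criteria are met: ≥2 diagnosis codes with prefix 296.2/296.3 on distinct
   days, ≥1 antidepressant prescription (NDF-RT C8870/C8872/C8874/C8876),
   ≥1 clinical-note MDD mention, ≥1 PHQ-9 score ≥ 15. The index date is the
   first day two criteria hold (the 2nd order statistic of the criterion
   dates). Bipolar (296.1x, 296.4x–296.9x), dementia/delirium (290.x) and
   psychotic (295.x, 298.x) codes exclude; controls must carry *no*
   MDD-related record at all.
2. **Matching.** Each incident case (index in 2000–2013) is paired with one
   control on birth year (±2), sex, and an outpatient visit in the index
   year; the control's index date is its first such visit.
3. **Ascertainment.** 24 CCW-style chronic conditions are flagged when ≥2
   matching codes fall in the 5 years before the subject's own index date,
   more than 30 days apart (obesity: single code). Burden = number of
   flagged conditions.
4. **Odds ratios.** Within each age stratum (≤45, 46–60, >60), each
   condition in ≥1% of subjects gets a conditional logistic model. For 1:1
   pairs the conditional likelihood reduces to intercept-free logistic
   regression on within-pair differences `d_j = x_case − x_control`:

   `L(β) = Π_j expit(β·d_j)`

   maximized by Newton–Raphson with step-halving; Wald 95% CIs from the
   inverse observed information. For a univariate binary exposure the MLE
   equals the discordant-pair ratio `n10/n01`.
5. **Relative influence.** A from-scratch stochastic gradient-boosting
   machine (Bernoulli deviance, depth-2 trees, shrinkage 0.01, bag fraction
   0.5, 3000 trees) is fitted per stratum, with and without burden.
   Friedman relative influence sums each variable's squared split
   improvements over all trees and normalizes them to 100%.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic cohort (20,000 patients, 1994–2013, seed 42) and write the result
tables under `results/study/`:

```
$ python analysis/01_simulate_cohort.py
simulated 20000 patients (917345 coded events)
true depression onsets: 2012 (10.1%)

$ python analysis/02_phenotype_and_match.py
cohort classification: {'control_eligible': 15696, 'ineligible': 1964,
 'prevalent_case': 455, 'incident_case': 1364, 'excluded': 521}
matched 1364/1364 incident cases (0 unmatched)
pairs per stratum: {'le45': 509, '46to60': 374, 'gt60': 481}

$ python analysis/03_build_analysis_table.py
>=1 chronic condition: cases 40.8% vs controls 30.0%

$ python analysis/04_odds_ratios.py
gt60: 21 conditions >=1% prevalence, 4 significantly associated (CI excludes 1)
  gt60 heart_failure: OR 4.06 (95% CI 1.94-8.54)

$ python analysis/05_relative_influence.py
le45: top variable education (36.9%), top condition asthma (9.2%); ...
```

Reading the numbers: of 20,000 simulated patients, 1,364 first satisfy the
phenotype inside the study window and all find a matched control. Cases
carry more comorbidity than controls (40.8% vs 30.0% with ≥1 condition) —
the planted condition→depression effects propagating through the whole
pipeline. Cardiovascular conditions, which carry the largest planted
log-odds, surface with the largest adjusted ORs in the older stratum, and
educational attainment (planted as a risk gradient) takes the top relative
influence in every stratum. The same pipeline is available as a CLI
(`mdd-comorbidity run-all --seed 42 --out results/run`), including
stage-by-stage subcommands (`simulate`, `phenotype`, `match`, `ascertain`,
`analyze`).

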