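# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic cohort does and does not emulate, and where the
design was genuinely open.

## Synthetic cohort

The generator emulates a primary-care population observed over a calendar
horizon (default 1994-01-01 to 2013-12-31, study window 2000-01-01 to
2013-12-31 so every index date has a full 5-year lookback). Per patient:

* **Demographics.** Birth year uniform on 1930–1985; female with
  probability 0.55; education a 5-level categorical
  (high-school-or-less/some-college/college/post-graduate/unknown with
  probabilities 0.31/0.31/0.15/0.15/0.08); race a descriptive label only.
  Events begin at the later of the horizon start and the year the patient
  turns 18.
* **Chronic conditions.** Each of the 24 catalog conditions has an annual
  first-onset probability, age-banded for the strongly age-graded ones
  (e.g. hypertension 0.0015/yr at 18–45 rising to 0.008/yr over 60). Onset
  is an absorbing state: from onset, coded encounters recur at
  `condition_code_rate` (default 1.5/yr, one code guaranteed at onset), so
  the two-code/30-day ascertainment rule has something to find. Prostate
  cancer and BPH have rate 0 for women, endometrial cancer for men. The
  rates are package choices producing ascertained prevalences of the order
  seen in primary-care cohorts (a few percent for the common conditions);
  no public source prescribes them.
* **Depression onset.** A discrete-time yearly hazard on the log-odds
  scale: `logit(p_t) = logit(0.004) + Σ_k β_k·active_k(t) + 0.4·obese +
  edu(t)`, where `active_k(t)` means condition k began in an earlier year.
  Planted `β_k` default to 0.75 for diabetes and heart failure, 0.65 for
  ischemic heart disease and stroke, ~0.2–0.45 for most others, and exactly
  0 for the eye conditions (cataract, glaucoma), mirroring the qualitative
  pattern this design is meant to detect. Education carries a planted
  gradient (+0.30 for high-school-or-less down to −0.15 for post-graduate).
  Because effects are wired at the person-year level, they are recoverable:
  a pooled logistic fit on ground-truth person-years returns β (tested).
* **Evidence emission.** On true onset the record receives two MDD codes
  1–180 days apart, one antidepressant prescription within 60 days, and
  with probability 0.5 each a note mention and a PHQ-9 ≥ 15 within 31
  days. With probability `undercoding_prob` (default 0.10) *no* evidence is
  emitted, emulating depression that never reaches the record; such
  patients can contaminate the control pool exactly as undiagnosed
  depression does in practice. Background noise streams (antidepressants
  0.004/yr, PHQ-9 screens 0.05/yr with 5% scoring ≥ 15, note events,
  bipolar/psychotic codes at 0.0015/yr, outpatient visits Poisson 1.8/yr)
  give the exclusion and eligibility rules real work to do.

All randomness flows from one integer seed through per-patient
`SeedSequence` children, so output is byte-for-byte reproducible.

**What the generator does not emulate:** care-seeking correlated with
morbidity (visit rates are independent of health state), coding-intensity
drift over calendar time, within-pair correlation of exposures beyond the
matching variables, miscoded diagnoses, condition remission, and mortality.
Passing tests therefore demonstrate correctness of the *pipeline* under a
faithful-but-idealized data-generating process, not robustness to every
real-EHR pathology.

In addition to the full generator, two direct simulators serve the
statistical calibration studies: `simulate_matched_pairs` draws 1:1 pairs
whose case assignment follows the conditional likelihood exactly (so a
planted log-OR *is* the estimand), and `simulate_stratum_features` draws a
flat stratum with Bernoulli features and a logistic outcome.

## Phenotyping

Criterion dates: ICD2 at the second qualifying code on a *distinct* day
(same-day duplicates count once — an interpretation guarding against
duplicate billing rows); RX/NOTE/PHQ9 at their first qualifying event. The
index date is the 2nd-smallest criterion date. Exclusion codes count at any
time in the record, before or after index. A case whose index precedes the
study window is prevalent (an optional strict mode also demotes cases with
any single MDD-related record before the window); control eligibility
requires no exclusion codes,
no MDD-related record of any criterion type (strictest reading; a
`strict_control_screen=False` switch relaxes this to a full phenotype
match), and at least one outpatient visit.

## Matching

Greedy sequential nearest-birth-year matching without replacement: cases in
ascending index-date order, candidates restricted to same sex, birth year
±2 and an outpatient visit in the case's index calendar year, ties broken
by a seeded random priority drawn once for the whole pool. Greedy matching
is transparent and reproducible; optimal (network-flow) matching is out of
scope. Unmatched cases are reported, never silently dropped. An independent
post-hoc validator re-checks every constraint on every pair.

## Ascertainment

The lookback window is half-open `[index − 5y, index)` — a code on the
index date does not count, since conditions must precede the diagnosis.
"Separated by > 30 days" is evaluated on the extreme pair (max − min),
strictly greater. Obesity uses a single-code rule (the two-code rule is
stated for the 24 chronic categories; a two-code variant is available).
Inpatient and outpatient codes both count. The packaged catalog ships
*representative* ICD-9-CM prefix lists for the 24 CCW-style categories; the
official CCW lists are versioned externally, so the catalog file is a
first-class, documented input that users can replace.

## Conditional logistic regression

Newton–Raphson on the paired-difference likelihood with step-halving
(likelihood never decreases), convergence at gradient max-norm < 1e-8, max
50 iterations. Separation is flagged when any |β| exceeds 15 on the
log-odds scale and reported as non-converged rather than returned as a huge
OR. Education enters as four dummies against high-school-or-less, with
"unknown" kept as a modeled level (dropping it would discard ~8% of
subjects). Adjusters with no within-pair variation in a given stratum carry
no information and are dropped from that fit; a condition with no
discordant pairs is reported as not analyzable. No multiple-testing
correction is applied across the per-condition models; readers should treat
the CIs as per-comparison.

## Gradient boosting and relative influence

Bernoulli-deviance boosting: `F0 = logit(ȳ)`; per iteration a 50%
subsample without replacement, a least-squares tree of depth ≤ 2 (≤ 4
leaves, min 10 observations per side) fitted to residuals `y − expit(F)`,
terminal values replaced by one-step Newton estimates `Σr / Σp(1−p)` over
the bag, then `F ← F + 0.01·tree(x)` for all rows. Split search is exact
over all cut points (features are integer-encoded once; per-node statistics
reduce to cumulative bin sums), with improvement = RSS reduction recorded
at every internal node. Relative influence is the per-variable sum of these
improvements over all trees, normalized to 100%.

Defaults (3000 trees, depth 2, shrinkage 0.01, bag 0.5) follow common
practice for boosted comorbidity models; no tree-count selection is
performed, and all settings are exposed in `GbmConfig`. Sex enters as a
predictor and depth-2 trees can form sex-by-condition splits; no explicit
product terms are added. Education is ordinal (1–4) with unknown as 0 plus
its own indicator — trees handle ordinality natively, unlike the dummy
coding used in the regression. Relative influence is computed on training
data, as is conventional for this statistic. The boosting stage pools rows
and ignores the matched-pair structure; this mirrors conventional usage of
boosting on case-control tables and is a methodological caveat, not an
oversight — the matched analysis is the conditional-logistic stage.

Simulation-heavy tests and the acceptance script run the boosting stage at
300 trees with shrinkage 0.05 (and the pipeline checks at 80–100 trees);
the relative-influence ranking they verify is insensitive to tree count at
these scales, and the library defaults remain as stated above.

## Pipeline

The master seed spawns per-stage seeds by fixed offsets (simulate: +0,
match: +1, boosting: +100 + 10·stratum-index), all echoed in
`run_report.json`, so any stage can be re-run in isolation and the full run
is byte-for-byte reproducible. Result tables mirror the study's reporting
structure: cohort characteristics, per-condition frequencies (with
male-only denominators for prostate cancer and BPH and female-only for
endometrial cancer), per-stratum ORs, and per-stratum relative influences
with and without burden. Tables are CSV with ISO-8601 dates; a single flat
text format keeps the round trip exact and inspectable.

## Problem sizes

The analysis drivers use 20,000 patients; the test suite uses 500-patient
cohorts for oracle-equivalence checks, 2,000-pair designs for calibration
(200 recovery replicates, 2,000 null replicates), n = 5,000 strata for
boosting signal recovery (20 seeds), and a 6,000-patient double run for the
end-to-end determinism check. These sizes give the statistical checks
adequate Monte-Carlo precision while keeping a full suite run around a
minute of compute for the unit tests plus a few minutes for the
calibration studies.

## Known limitations

* The catalog's prefix lists are representative, not the official CCW
  versions (replaceable via YAML).
* Visit behaviour is independent of morbidity, so the matched-control
  pool is more exchangeable than in real data; matching fractions near
  100% reflect that.
* The boosting stage ignores pair structure (see above).
* Condition severity, remission and medication-based definitions are out
  of scope; note mentions are structured booleans, not NLP output.
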