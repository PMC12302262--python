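# Methods

## Data model

An ICSR (individual case safety report) carries a report id, sex, five-level
age group, vaccine type, vaccine schedule, calendar year, vaccine class
(COVID-19 vs comparator) and an ordered list of MedDRA-style preferred terms.
Two dialects are supported: `single_term` (exactly one term — the
chief-complaint convention of the German PEI export) and `multi_term` (1–5
terms, first = primary symptom, as in VAERS). For multi-term data every
counting operation takes a `scope`: `any_position` (default; a report is a
case if the term appears anywhere in its list) or `primary_only`, which
mimics the chief-complaint reduction and makes the two dialects directly
comparable.

Duplicate reports (same id, as arise when a case reaches the regulator by
several routes) are merged: covariate conflicts resolve to the first
non-missing value, else the first occurrence; term lists are unioned in
first-seen order and truncated to the dialect bound. The rule is the simplest
deterministic one consistent with "duplicates were merged" being all that is
known about the original de-duplication; merging is idempotent.

Unknown covariate codes on input degrade to an explicit `missing` category
rather than failing: passive-surveillance exports routinely contain
unclassifiable entries, and the analysis conventions below all treat
missingness explicitly.

## Vocabulary

The packaged vocabulary holds 80 oral-AE preferred terms mapped to eight
anatomo-physiological groups (taste, other sensation, lips, palate, tongue,
dentition, salivary glands, oral mucosa). Term matching is exact on
normalized strings (lower-cased, whitespace-collapsed); exclusions are
case-insensitive substring keywords that veto oral-anatomy homonyms from
contraception, congenital-malformation and oncology contexts. A keyword list
rather than a grammar is used because the selection being modelled is a
keyword search.

## Reporting rates and trimming

`ARR = 1000 · n_cases / N` (cases per 1000 ICSRs), reported to 3 decimals.
Terms with fewer than `min_trim = 3` reports in the single-term database are
trimmed — too little information for any rate comparison — and their
multi-term rows are dropped alongside, since the cross-database table is
defined on the single-term database's kept set.

## Cross-database comparison

Per term, the odds ratio of database 1 vs database 2 uses each database's
full ICSR total as denominator, with the Woolf (log-normal) 95% CI,
`SE = sqrt(1/a + 1/(n1−a) + 1/b + 1/(n2−b))`, multiplier 1.96, and **no
zero-cell correction**: a zero comparator count reports `∞` (and a zero index
count 0) with undefined interval bounds, which keeps the report faithful to
what the data can support instead of manufacturing a Haldane-corrected
estimate. Terms are tagged `db1`-dominant (CI lower bound > 1),
`db2`-dominant (CI upper bound < 1) or indeterminate. No standardization of
the two databases' covariate mixes is attempted — the comparison is of crude
reporting odds, and the accompanying characteristics tests (below) make the
mix differences explicit.

Covariate-distribution comparisons build the 2×k table over non-missing
categories (the `missing` category is excluded from both margins, matching
the convention under which the published percentages are computed) and use
Pearson chi-square without continuity correction, switching to Fisher's
exact test when any expected cell is below 5 in a 2×2; larger sparse tables
keep chi-square with a logged warning.

## Disproportionality and the SDR rule

Within the multi-term database, each term's 2×2 table against comparator
vaccines is scored with PRR, ROR and the shrinkage information component
(formulas in the README). Design choices:

* the expected count for the IC uses the **within-table margins**,
  `E = (a+c)(a+b)/N`: the analysis is confined to the vaccine-report
  database, so the table's own margins are the relevant reporting baseline;
* IC025 uses the standard two-term credibility approximation; its accuracy
  against the gamma-posterior Monte-Carlo quantile is verified in the tests
  (within 0.15 for observed counts from 3 to 100);
* qualification: a term enters classification only with `a ≥ min_covid = 3`
  exposed cases and `c ≥ min_comparator = 1` comparator cases (both
  configurable) and all three metrics computable; otherwise it is
  `disqualified`, never silently scored;
* the composite rule is deliberately conjunctive (all three statistics must
  agree) to suppress the false-positive signals that single frequentist
  metrics generate in stretched spontaneous-reporting data; under a null
  comparator the tests observe a flagged fraction far below 5%;
* report rounding is 2 decimals; the CI multiplier is fixed at 1.96.

## Subgroup analysis

The `k = 20` most-reported terms (ties broken lexicographically) are
stratified by sex, 3-level age (minors <18 = the three juvenile brackets
pooled; adults 18–59; seniors >59), year (default 2021–2023; the study
window's first and last partial years carry too few reports to stratify),
vaccine type and schedule. Records missing the variable leave both numerator
and denominator. The homogeneity test over strata × (case, non-case) is
chi-square; with any expected cell below 5 it becomes Fisher's exact test
(2×2) or, for wider tables, a Monte-Carlo permutation of the chi-square
statistic conditional on both margins (multivariate hypergeometric
redistribution of the case total, 9999 draws, fixed seed). Strata with zero
cases are listed but excluded from tests over more than two strata — a zero
row cannot inform a rate comparison and degenerates the expected counts (in
practice this removes the tiny inactivated-virus stratum). p-values are raw
per term × variable, matching the analysis being reproduced; a Bonferroni
option is intentionally not applied by default.

## Regression

Per term, logistic regression of case status on sex, 3-level age, vaccine
type and schedule (references: male, adults, mRNA, primer), listwise
deletion on the four predictors, comparator reports excluded, year not a
predictor. The fit is IRLS (Newton) with convergence at max |Δβ| < 1e-8,
cap 100 iterations; the log-likelihood is non-decreasing across iterations
(tested). CIs are Wald intervals — symmetric on the log scale, consistent
with the published tables — not profile likelihood. Predictor levels with
zero cases are suppressed before fitting (their MLE diverges) and reported
as `NA`; quasi-complete separation emerging during the fit (|β| > 15) is
flagged (`converged = False`) with the affected aORs reported as
unavailable. No Firth penalisation by default, because the analysis being
reproduced reports unpenalised estimates with `NA` cells.

## Synthetic data generator

The generator emulates the study conditions: default database sizes are the
published ICSR totals (974,931 single-term; the multi-term database is
scaled to 1,354,699 so that its COVID-19 arm matches the published
1,016,024 after a 25% comparator arm is added); covariate marginals
reproduce the published distributions with `missing` generated as an
explicit category (missing shares over the full total, category shares
conditional on non-missing — exactly the convention of the published
percentages); per-term base rates are the published single-term ARRs, with
the 20 rare vocabulary terms set to 0.001 per 1000 so they fall below the
trim threshold at full scale. Covariate effects enter per term as log-odds
offsets (female, minors, seniors, viral vector, protein subunit, booster)
on top of the logit of the base rate.

The comparator arm, whose composition the source data do not constrain, is
an engineering default: 25% of the multi-term database, with per-term
comparator rates set to base rate / published PRR (preserving each term's
observed rate ratio) where a PRR exists, else equal rates. Terms are
sampled **independently within a report** — no co-occurrence structure is
available to calibrate against — and the single-term database keeps the
first included oral term (else a generic filler symptom from a fixed
reactogenicity list, so denominators contain non-cases). In the multi-term
database the filler symptom precedes the oral terms with probability ½,
so the `primary_only`/`any_position` distinction is exercised.

What passing tests therefore show: the pipeline's estimators recover known
rates, odds ratios and planted covariate effects, and the SDR rule holds its
false-positive behaviour, under independent-term, static-in-time reporting.
What they cannot show: behaviour under within-report symptom correlation,
calendar-time reporting waves (notoriety bias), or duplicate-report
contamination — none of which the generator models.

## Numerical and testing choices

* All randomness flows from a single integer seed through named
  `numpy.random.SeedSequence` substreams; equal config + seed gives
  byte-identical outputs.
* Stochastic test sizes were fixed by a priori power analysis: the
  planted-effect recovery checks use a base rate of 5 per 1000 at
  n = 200,000 (≈1,400 female and ≈280 male cases), putting the [1.6, 2.5]
  recovery band ≈3.4 standard errors wide on each side of the true aOR 2.0;
  the null-signal check uses 100 seeds × 20 terms at n = 20,000 with a 50%
  comparator arm, yielding > 1,000 qualified term-evaluations.
* The Monte-Carlo homogeneity test is validated against exhaustive
  conditional enumeration on a small 3×2 table; the IRLS fit against an
  independent maximum-likelihood implementation (statsmodels) to 1e-6.
* Desk-scale re-derivations of the published numbers (ARRs, ORs with CIs,
  SDR calls, percentages, stratified ARRs) are compared at the printed
  precision of each value — half a unit in the last printed decimal.

## Known limitations

* Passive-surveillance caveats carry over: ARRs are reporting rates, not
  incidence; SDRs are statistical signals, not causal findings.
* The comparator arm of the synthetic multi-term database is a modelling
  convention, not an estimate of any real comparator population.
* Term matching is exact post-normalization; no MedDRA hierarchy,
  synonym handling or spelling tolerance.
* The reader targets the simplified dialect CSV layouts defined here, not
  the raw national export formats.
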