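# oralpv

Pharmacovigilance analysis of **oral adverse events (AEs)** in spontaneous-reporting
databases of individual case safety reports (ICSRs), built for vaccine-safety
analysts who work with national passive-surveillance exports such as the German
Paul-Ehrlich-Institut (PEI) download (one "chief complaint" preferred term per
report) and the U.S. VAERS datasets (up to five MedDRA preferred terms per
report, with comparator vaccines available).

The package implements the full analysis chain used in national assessments of
oral AE reporting after COVID-19 vaccination:

1. **Absolute reporting ratios (ARR)** — for term *i*,
   `ARR_i = 1000 · n_i / N`, cases per 1000 ICSRs, with trimming of terms
   reported fewer than 3 times;
2. **Cross-database comparison** — per-term odds ratio of database 1 vs
   database 2, `OR = (a/(n1−a)) / (b/(n2−b))`, Woolf 95% CI on the log scale,
   with `∞`/`0` reported for zero cells, plus χ²/Fisher comparison of the two
   databases' covariate margins;
3. **Hybrid signal detection** — within the multi-term database, each term's
   COVID-19-vs-comparator 2×2 table is scored with the proportional reporting
   ratio `PRR = (a/(a+b))/(c/(c+d))`, the reporting odds ratio `ROR = ad/bc`,
   and the Bayesian information component
   `IC = log2((a+½)/(E+½))`, `E = (a+c)(a+b)/N`, with the credibility bound
   `IC025 = IC − 3.3(a+½)^(−1/2) − 2(a+½)^(−3/2)`. A term is a **signal of
   disproportionate reporting (SDR)** only if PRR ≥ 2 with CI lower bound ≥ 1,
   ROR ≥ 2 with CI lower bound ≥ 1, and IC > 0 with IC025 > 0;
4. **Subgroup analysis** — stratified ARRs for the top-20 terms by sex,
   3-level age (minors <18 / adults 18–59 / seniors >59), year, vaccine type
   and schedule, with χ²/Fisher/Monte-Carlo homogeneity tests;
5. **Per-term multivariable logistic regression** — adjusted odds ratios for
   female sex, age group, vaccine type and booster schedule, fitted by IRLS
   with Wald CIs and explicit separation handling.

A **synthetic ICSR generator** (`oralpv.simulate`) produces paired databases in
both dialects with known ground truth (covariate marginals, per-term rates,
planted covariate effects, a comparator arm), so every stage is testable
without downloading surveillance data. The generator's default configuration
reproduces the published covariate marginals and per-term reporting rates of
the PEI/VAERS oral-AE analysis.

## Worked example

```python
from oralpv import (arr, odds_ratio, ContingencyTable2x2,
                    prr, ror, information_component, classify_sdr)

# taste disorder: 481 cases among 974,931 PEI reports; 296 among 1,016,024 VAERS reports
print("ARR  taste disorder (PEI):", round(arr(481, 974931), 3), "per 1000 ICSRs")
est = odds_ratio(481, 974931, 296, 1016024)
print(f"OR   PEI vs VAERS: {est.or_point:.2f} [{est.ci_low:.2f}-{est.ci_high:.2f}]  dominance={est.dominance}")

# disproportionality against a synthetic comparator arm (4 cases / 243,368 reports)
t = ContingencyTable2x2(a=296, b=1015728, c=4, d=243364)
p, r = prr(t), ror(t)
ic, ic025 = information_component(t)
print(f"PRR  {p.point:.2f} [{p.ci_low:.2f}-{p.ci_high:.2f}]")
print(f"IC   {ic:.2f} (IC025 {ic025:.2f})")
print("SDR :", classify_sdr(p, r, ic, ic025))
```

prints

```
ARR  taste disorder (PEI): 0.493 per 1000 ICSRs
OR   PEI vs VAERS: 1.69 [1.47-1.96]  dominance=db1
PRR  17.73 [6.61-47.54]
IC   0.29 (IC025 0.10)
SDR : yes
```

Reading: taste disorder is reported at 0.493 cases per 1000 ICSRs in the
single-term database, 1.69 times the reporting odds of the multi-term
database, and — against this comparator arm — meets all three
disproportionality criteria, so it is flagged as an SDR (a statistical
reporting signal, not a causal finding).

The command-line interface mirrors the library:

```
oralpv simulate --seed 1 --n-db1 50000 --n-db2 80000 --out-dir sim/
oralpv run --synthetic --seed 1 --n-db1 50000 --n-db2 80000 --out-dir out/
oralpv sdr counts.csv           # term,a,b,c,d -> PRR/ROR/IC/SDR table
oralpv validate                 # re-derive the published reference numbers
```

`oralpv run` writes six CSV tables (ARRs, cross-database ORs, characteristics
tests, disproportionality metrics, subgroup strata, regression aORs) plus a
JSON manifest with stage-by-stage record counts; identical config and seed
give byte-identical outputs.

## Layout

```
src/oralpv/
  vocab.py        oral-AE vocabulary (80 preferred terms, 8 anatomical groups)
  icsr.py         ICSR data model, dialect CSV readers/writers, duplicate merging
  simulate.py     synthetic paired-database generator with known ground truth
  rates.py        ARR computation and rare-term trimming
  crossdb.py      cross-database ORs and covariate-distribution tests
  signals.py      PRR / ROR / IC and the composite SDR classifier
  subgroup.py     stratified ARRs and homogeneity tests
  regression.py   per-term logistic regression (IRLS, Wald CIs)
  pipeline.py     end-to-end orchestration and report bundle
  cli.py          simulate / run / sdr / validate commands
  data/           packaged vocabulary and published reference counts
```

See `docs/methods.md` for the statistical methods, default parameters and
limitations.
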