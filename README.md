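# pvfaers

Pharmacovigilance signal detection for levodopa-induced motor complications
under the two dopa-decarboxylase inhibitors (DCIs), benserazide (BSZ) and
carbidopa (CD), from FAERS-style spontaneous adverse-event reports.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect case reports that link one patient to several drugs
(with role, route and brand/generic names) and several MedDRA preferred
terms (PTs). This package implements the full analysis chain for asking
whether motor complications — dyskinesia, wearing-off, the on-off
phenomenon and the freezing phenomenon — are reported disproportionately
often under oral levodopa/benserazide versus oral levodopa/carbidopa:

1. **I/O and deduplication** (`pvfaers.io_faers`) — parses the $-delimited
   quarterly tables (DEMO/DRUG/REAC/INDI/OUTC/RPSR), harmonizes ages,
   weights, routes, reporter and country codes, and keeps one report per
   `caseid` (highest `caseversion`, ties by highest `primaryid`).
2. **Screening cascade** (`pvfaers.screening`) — suspect-drug text search
   (brand + generic substrings, levodopa partner required), oral-route
   restriction, Parkinson's-disease indication with dementia/psychosis
   exclusions, and a system-organ-class whitelist (nervous system
   disorders; general disorders and administration site conditions), with a
   full audit trace of surviving counts.
3. **Composite endpoints** (`pvfaers.term_mapping`) — keyword composites
   for dyskinesia (dyskinesia, dystonia, hyperkinesia, ballismus, alien
   limb syndrome) and wearing-off (incomplete/shortened therapeutic
   response), exact PTs for the on-off and freezing phenomena.
4. **Disproportionality** (`pvfaers.disproportionality`) — for each drug ×
   endpoint 2×2 report table (a, b, c, d):
   * reporting odds ratio `ROR = ad/bc` with the 95% Wald interval
     `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` (Haldane–Anscombe 0.5
     correction when a cell is zero);
   * BCPNN information component `IC = log₂((a+½)/(E+½))` with
     `E = (a+b)(a+c)/N` and the closed-form lower credible bound
     `IC025 = IC − 3.3(a+½)^−1/2 − 2.0(a+½)^−3/2`;
   * MGPS: counts modelled as `a ~ Poisson(λE)` with a two-component gamma
     mixture prior on λ; the five hyperparameters (α₁, β₁, α₂, β₂, P) are
     fitted by maximizing the negative-binomial mixture marginal
     likelihood, and `EBGM = 2^E[log₂ λ | a]` with EB05/EB95 the 5th/95th
     posterior percentiles.
   * joint signal criterion: ROR ≥ 3 with CI lower bound > 1, IC025 > 0,
     and EB05 > 2 — all three must hold.
5. **Descriptives and reporting** (`pvfaers.descriptive`, `pvfaers.report`)
   — demographics/concomitant-drug/endpoint tables with their documented
   percent-denominator conventions, chi-square/Fisher subgroup contrasts,
   forest-plot output and a reproducibility manifest.
6. **Synthetic data** (`pvfaers.synthetic`) — a FAERS-dialect generator
   with planted ground truth (cohort membership per screening stage,
   realized 2×2 counts, injected drug–event rate ratios), so every stage
   and estimator is testable without any download.

## Worked example

```sh
python analysis/01_generate_data.py --seed 1      # synthetic quarter + ground truth
python analysis/02_screen_cohorts.py              # screening funnel
python analysis/04_signal_analysis.py             # three-method signal table
```

The screening step prints the audit funnel for the generated 20,000-report
quarter:

```
         stage  count
reports_loaded  20000
    drug_match   7048
    oral_route   6394
 pd_indication   5685
 soc_whitelist   2428
    cohort_BSZ    559
     cohort_CD   2024
```

and the signal step prints the two-decimal display table (excerpt):

```
drug            endpoint   a   ROR  ROR_low  ROR_high   IC  IC025  EBGM  EB05  signal
 BSZ   on_off_phenomenon  76 18.50    13.89     24.63 3.41   3.03  9.89  8.29    True
 BSZ         wearing_off  29  4.45     3.00      6.61 1.90   1.28  4.41  3.41    True
  CD         wearing_off 139 10.45     8.17     13.36 2.35   2.07  5.24  4.58    True
```

Read one row: of the 559 screened benserazide reports, 76 list the on-off
phenomenon; relative to all other deduplicated reports, that is an 18.5-fold
reporting odds (95% CI 13.9–24.6), the shrunken information component's
lower bound is 3.03 > 0, and the empirical-Bayes geometric mean is 9.9 with
EB05 = 8.3 > 2, so the pair meets the joint criterion (`signal = True`).
EBGM sits well below the ROR because the gamma-mixture prior — fitted over
all eight pairs of the run — shrinks extreme ratios toward the bulk.
All four endpoints signal for both drugs here because the generator's
default configuration injects associations for both DCIs; the *strengths*
differ by design (stronger dyskinesia/on-off amplification for benserazide,
stronger wearing-off for carbidopa).

`analysis/03_descriptive_tables.py` writes the demographic/concomitant/
endpoint tables and `analysis/05_estimator_validation.py` re-runs the
estimator validation studies (Wald coverage, prior recovery, injected-effect
recovery).

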