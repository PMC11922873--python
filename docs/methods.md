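# Methods

## Data model and deduplication

A spontaneous report is keyed by `caseid`; amendments appear as new
versions with their own `primaryid` that keys the child tables (drugs,
reactions, indications, outcomes, report sources). One `CaseReport` is kept
per case: the highest `caseversion`, ties broken by the highest
`primaryid`, carrying that version's children. This follows standard FAERS
practice; the rule is deterministic, idempotent, and never increases the
report count. Reports with no reaction rows are dropped (they cannot enter
a drug–event table).

Field harmonization: ages are converted to years from their unit code
(YR/DEC/MON/WK/DY/HR; a missing code with a value ≤ 120 is taken as years)
and banded as `<20`, `20–50`, `50–65`, `≥65`, `unknown` — the bands that
separate juvenile and early-onset Parkinson's disease from typical onset.
Weights convert LBS→kg (×0.453592) and values outside (20, 300) kg become
unknown (entry noise). Routes, reporter occupation codes and
country→region groupings ship as editable CSV maps in
`src/pvfaers/data/`; unknown codes map to `unknown`/`other` with no
exception.

## Screening cascade

Four pure predicates, applied as a funnel with an audited count per stage:

1. **Drug match** — case-insensitive substring search over the verbatim
   drug name and the active-ingredient field, requiring a target pattern
   (benserazide/carbidopa, brand names included) on a suspect-role entry
   *and* a levodopa partner pattern among suspect entries. A combination
   product row ("MADOPAR", `LEVODOPA\BENSERAZIDE`) satisfies both at once.
   Suspect roles default to primary + secondary suspect; configurable.
2. **Oral route** — the matched target and partner entries must be oral;
   unknown routes fail (conservative reading of an oral-only restriction).
   The test deliberately ignores the routes of unrelated co-medications.
3. **Indication** — a Parkinson's-disease indication on a matched *target*
   entry (checking partner entries too would let a co-reported carbidopa
   row satisfy the benserazide query), no PD term among the reactions
   (indication listed as an event suggests miscoding), and no
   dementia/psychosis-family term among reactions or indications. Term
   families are editable data files; "Parkinsonism" is deliberately not in
   the indication family.
4. **SOC whitelist** — at least one reaction in the nervous-system or
   general-disorders SOC; other reactions are masked from the analysis
   view but preserved on the case.

Because every stage is a pure predicate, permuting stages changes the trace
but not the terminal cohorts (tested). Cases matching both drug queries are
kept in both cohorts and flagged; a config switch drops them instead.

## Composite endpoints

Dyskinesia and wearing-off are keyword composites (lower-cased substring on
the PT): {dyskinesia, dystonia, hyperkinesia, ballismus, alien limb
syndrome} and {therapeutic response shortened, therapeutic response
incomplete}. The on-off and freezing phenomena match their exact PTs. The
keyword "dyskinesia" intentionally also catches e.g. "Tardive dyskinesia";
the dictionary is a data file so the net can be tightened. Endpoint member
sets are validated disjoint against the bundled PT vocabulary at load. A
case counts once per endpoint regardless of how many member PTs it lists,
and every hit is traceable to the PTs that produced it. Matching is applied
to coded PTs only, not verbatim reaction text.

## Disproportionality estimators

All three estimators read the same report-level 2×2 table: `a` target
cohort with endpoint, `b` without; `c`/`d` the same split in the
comparator. The default comparator is **all deduplicated reports outside
the target cohort**; a `within_screened` alternative restricts it to
reports that survived screening for another drug query. (Which comparator
the published analysis used is unstated; with the default, reports of the
target drug that failed screening remain in the background, which pulls
estimates toward the null when effects are injected on drug presence.)

* **ROR** `= ad/bc`, 95% Wald interval on the log scale. Any zero cell
  triggers the Haldane–Anscombe correction (+0.5 to all four cells,
  flagged). Applies to the ROR only; IC and EBGM handle zeros natively.
* **BCPNN IC** uses the widely adopted shrinkage form
  `IC = log₂((a+½)/(E+½))`, `E = (a+b)(a+c)/N`, with the closed-form
  credible-bound approximation `IC025 = IC − 3.3(a+½)^−1/2 −
  2.0(a+½)^−3/2`. The original full-Bayes variance formulation is out of
  scope.
* **MGPS** models `a ~ Poisson(λE)` with prior
  `λ ~ P·Gamma(α₁,β₁) + (1−P)·Gamma(α₂,β₂)` (shape/rate). The marginal
  likelihood is a two-component negative-binomial mixture, maximized with
  box-constrained L-BFGS-B from the classic start point
  (0.2, 0.1, 2.0, 4.0, ⅓); bounds [1e−6, 50] on shapes/rates and
  [1e−6, 1−1e−6] on P. One prior is fitted per analysis run over all
  drug–endpoint tables supplied (per-drug priors would need more tables
  than a four-endpoint run provides). On optimizer failure, or when every
  count is zero, the start prior is returned flagged `converged=False`
  with a warning. The posterior is again a gamma mixture with weight Q
  computed in log space; `EBGM = exp(E[ln λ])` via the digamma closed
  form, and EB05/EB95 solve the mixture CDF = 0.05/0.95 by bracketed Brent
  root-finding (xtol 1e−10). When a fitted shape sits at the tiny boundary
  the 5% quantile can underflow double precision; the bracket bound is
  returned in that case. No stratification of E (age/sex/quarter) is
  applied by default. No multiple-testing adjustment is made; the run
  manifest records the number of pairs tested.
* **Joint criterion**: ROR ≥ 3 with CI low > 1, IC025 > 0, EB05 > 2.

Subgroup 2×2 comparisons use Pearson's chi-square without continuity
correction when all expected cells are ≥ 5, otherwise Fisher's exact test
(two-sided); a zero margin returns p = 1 flagged degenerate. Between-drug
endpoint comparisons report both Wald-interval overlap and the chi-square
p; neither is privileged.

## Percent-denominator conventions

Demographic blocks divide by cohort size. The serious-outcomes block counts
every outcome code a report carries and divides by the **sum of code
counts**, not cohort size — unusual, but it is the convention the reference
descriptive tables follow (e.g. 906/1,959 = 46.25%). The endpoint table
counts adverse events (one hit per case per endpoint) and divides the total
row by the combined analysis-view AE total, per-drug rows by that drug's AE
total, per-sex rows by per-drug-per-sex AE totals. The concomitant-drug
ranking divides by cohort size (the reference tables' denominator for this
block is not derivable from printed numbers). Display values round half-up
to two decimals, and every emitted percent is re-derivable from its count
and documented denominator (asserted at construction).

## Synthetic data generator

Each case draws: drugs independently per vocabulary entry (marginal
probability; per-drug route/role distributions; PD-indication probability),
demographics from categorical weights shaped like a levodopa/DCI reporting
slice (about 55% aged ≥65, consumer-dominated reporters, log-normal weight
around 70 kg), an event date uniform over 82 quarters, outcome codes
independently, and each PT as an independent Bernoulli with probability
`background × rr` (capped at 0.95, logged) when a drug matching an injected
association is present. A configurable fraction of cases is re-emitted with
`caseversion` 2 and identical content to exercise deduplication. Cases with
no drawn reaction receive a filler PT in a non-whitelisted SOC so the
reactions-non-empty invariant holds without touching endpoint counts.

Ground truth records per-case stage flags computed with the same semantics
as the screening predicates, plus the realized (a, b, c, d) per drug–PT
pair under the default comparator; tests assert *exact* agreement between
pipeline output and ground truth, for any seed. `plant_flowchart` overrides
the stochastic assignments so the funnel hits requested stage counts
exactly (targets validated non-increasing and feasible).

What the generator deliberately does **not** emulate: correlation between
PTs within a report (draws are independent given drugs — adequate for
estimator testing, unrealistic for report-level multiplicity studies),
drug-name misspellings, notes-field text, or reporting-rate drift over
calendar time. Because the injected effect is a rate ratio on the PT
probability, the recoverable ROR approximates the injected value only in
the rare-event regime; the generator warns when `background × rr > 0.1`.
Passing tests therefore demonstrate correctness of the screening logic and
estimators, not robustness to real FAERS noise.

## Validation studies and problem sizes

* Wald coverage at the null: 1,000 tables with margins (200, 2,000) at a
  common reporting probability of 0.1; the 95% interval covers 1 in 93–97%
  of runs.
* MGPS recovery: 5,000 (a, E) pairs with λ ~ Gamma(2, rate 2) and E ~
  U(0.5, 20); the fitted mixture mean lands within 10% of the true mean 1.
* Injected-effect recovery uses a dedicated configuration
  (`recovery_config`) in which screening passes deterministically for
  exposed reports, frequent whitelisted background PTs keep the SOC stage
  from selecting on the endpoint, and the anchor endpoint's background is
  `0.03/rr` so exposure keeps the rare-event approximation valid at every
  strength. Interval coverage of the injected rr ∈ {2, 5, 20} is measured
  over 100 seeds at 3,000 cases; point recovery (geometric mean across 50
  seeds, within 15%) scales the case count with rr (3,000 / 7,000 / 27,000)
  so the comparator cell keeps an informative expected count — with only a
  handful of expected background hits the log-count bias and occasional
  zero-cell corrections inflate the mean ROR regardless of estimator
  quality. The geometric mean is the appropriate center because the OR
  estimate is log-scale symmetric and heavily right-skewed at small
  counts. The EBGM-below-ROR shrinkage check applies to the planted pair;
  null pairs are intentionally shrunk upward toward 1.

## Known limitations

Single-quarter file layout only (2012+ columns; legacy LAERS layouts are
out of scope). The bundled PT→SOC dictionary is a miniature stand-in
(~70 terms) for the licensed MedDRA hierarchy — real analyses must supply
their own flat PT→SOC table. LEDD dose–effect analysis, causality
assessment and time-to-onset methods are out of scope. The published
benserazide/carbidopa estimates cannot be reproduced without the complete
FAERS download; the bundled reference table is used only to exercise the
joint signal criterion on published tuples.
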