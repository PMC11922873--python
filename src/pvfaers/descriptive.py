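"""Descriptive cohort tables and subgroup contingency tests.

Percent-denominator conventions (documented because they differ by block):

* demographics (age band, reporter, sex, country group) — denominator is
  the cohort size;
* serious outcomes — a report may carry several outcome codes, each code is
  counted, and the denominator is the *sum of outcome-category counts*, not
  the cohort size;
* endpoint frequency table — the counting unit is the adverse event, i.e.
  one endpoint hit per case per endpoint; the grand total row is divided by
  the combined analysis-view AE total of all cohorts, per-drug rows by that
  drug's AE total, and per-sex rows by the per-drug-per-sex AE totals;
* concomitant drug ranking — denominator is the cohort size.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as st

from .io_faers import AGE_BANDS, DATA_DIR, CaseReport
from .screening import ConfigurationError, DrugQuery, matched_partner_entries, matched_target_entries
from .term_mapping import CompositeEndpoint, map_endpoints

OUTCOME_ORDER = ("hospitalization", "other_serious", "life_threatening", "death",
                 "disability", "congenital_anomaly")
REPORTER_ORDER = ("physician", "consumer", "other health-professional", "pharmacist",
                  "lawyer", "unknown")
COUNTRY_ORDER = ("Europe", "United States", "Japan", "South America", "other")
SEX_ORDER = ("female", "male", "unknown")


def percent(count: int, denominator: int) -> float:
    """Display percent, rounded half-up to 2 decimals (0.0 for an empty denominator)."""
    if denominator == 0:
        return 0.0
    raw = Decimal(100 * count) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FreqRow:
    variable: str
    level: str
    count: int
    percent: float
    denominator: int

    def __post_init__(self) -> None:
        if self.percent != percent(self.count, self.denominator):
            raise ValueError(
                f"{self.variable}/{self.level}: percent {self.percent} does not re-derive "
                f"from {self.count}/{self.denominator}")


def _freq(variable: str, level: str, count: int, denom: int) -> FreqRow:
    return FreqRow(variable, level, count, percent(count, denom), denom)


@dataclass
class DemographicsTable:
    rows: list[FreqRow]
    weight_median: float | None
    weight_q1: float | None
    weight_q3: float | None


def demographics_table(cohort: Sequence[CaseReport]) -> DemographicsTable:
    """Age-band / reporter / serious-outcome / country / sex frequency rows
    plus the weight median and IQR."""
    n = len(cohort)
    rows: list[FreqRow] = []
    if n == 0:
        return DemographicsTable([], None, None, None)

    for band in AGE_BANDS:
        rows.append(_freq("age", band, sum(1 for c in cohort if c.age_band == band), n))
    for rep in REPORTER_ORDER:
        rows.append(_freq("reporter", rep, sum(1 for c in cohort if c.reporter == rep), n))

    outcome_counts = {o: 0 for o in OUTCOME_ORDER}
    for case in cohort:
        for o in case.outcomes:
            outcome_counts[o] += 1
    outcome_denom = sum(outcome_counts.values())
    for o in OUTCOME_ORDER:
        rows.append(_freq("serious_outcome", o, outcome_counts[o], outcome_denom))

    for grp in COUNTRY_ORDER:
        rows.append(_freq("country", grp, sum(1 for c in cohort if c.country_group == grp), n))
    for sex in SEX_ORDER:
        rows.append(_freq("sex", sex, sum(1 for c in cohort if c.sex == sex), n))

    weights = np.array([c.weight_kg for c in cohort if c.weight_kg is not None])
    if weights.size:
        q1, med, q3 = np.percentile(weights, [25, 50, 75])
        return DemographicsTable(rows, float(med), float(q1), float(q3))
    return DemographicsTable(rows, None, None, None)


def ae_total(cases: Iterable[CaseReport]) -> int:
    """Number of adverse events in the analysis view (one per PT per case)."""
    return sum(len(c.analysis_view) for c in cases)


def endpoint_frequency_table(cohorts: Mapping[str, Sequence[CaseReport]],
                             endpoints: Sequence[CompositeEndpoint]) -> list[FreqRow]:
    """Endpoint counts with the AE-total denominator conventions above.

    Row levels: ``total`` (all cohorts), ``<label>`` (one cohort) and
    ``<label>/<sex>``.
    """
    grand_denom = sum(ae_total(cases) for cases in cohorts.values())
    rows: list[FreqRow] = []
    per_cohort_hits: dict[str, dict[str, int]] = {}
    for label, cases in cohorts.items():
        hits = {e.name: 0 for e in endpoints}
        by_sex: dict[str, dict[str, int]] = {s: {e.name: 0 for e in endpoints} for s in SEX_ORDER}
        for case in cases:
            for name in map_endpoints(case, endpoints):
                hits[name] += 1
                by_sex[case.sex][name] += 1
        per_cohort_hits[label] = {"__denom__": ae_total(cases), **hits}
        per_cohort_hits[label + "__by_sex__"] = by_sex  # type: ignore[assignment]

    for e in endpoints:
        total = sum(per_cohort_hits[label][e.name] for label in cohorts)
        rows.append(_freq(e.name, "total", total, grand_denom))
        for label, cases in cohorts.items():
            denom = per_cohort_hits[label]["__denom__"]
            rows.append(_freq(e.name, label, per_cohort_hits[label][e.name], denom))
            by_sex = per_cohort_hits[label + "__by_sex__"]
            for sex in SEX_ORDER:
                sex_cases = [c for c in cases if c.sex == sex]
                rows.append(_freq(e.name, f"{label}/{sex}", by_sex[sex][e.name],
                                  ae_total(sex_cases)))
    return rows


def load_anti_pd_drugs(path: Path | str | None = None) -> list[str]:
    path = Path(path) if path is not None else DATA_DIR / "anti_pd_drugs.csv"
    with open(path, newline="", encoding="utf-8") as fh:
        return [row["name"].strip().lower() for row in csv.DictReader(fh) if row["name"].strip()]


def concomitant_ranking(cohort: Sequence[CaseReport], query: DrugQuery,
                        anti_pd_drugs: Sequence[str] | None = None,
                        k: int = 5) -> list[tuple[str, int, float]]:
    """Top-k co-reported anti-parkinsonian drugs as (name, count, percent).

    Counts cohort cases listing each dictionary drug among any entry that is
    not a matched target/partner (levodopa) entry.  Ties sort alphabetically;
    percent denominator is the cohort size.
    """
    drugs = list(anti_pd_drugs) if anti_pd_drugs is not None else load_anti_pd_drugs()
    if not drugs:
        raise ConfigurationError("empty anti-parkinsonian drug dictionary")
    counts = {name: 0 for name in drugs}
    for case in cohort:
        excluded = {id(e) for e in matched_target_entries(case, query)}
        excluded |= {id(e) for e in matched_partner_entries(case, query)}
        listed = set()
        for entry in case.drugs:
            if id(entry) in excluded:
                continue
            text = (entry.name_raw + " " + entry.active_ingredient).lower()
            for name in drugs:
                if name in text:
                    listed.add(name)
        for name in listed:
            counts[name] += 1
    ranked = [(name, cnt) for name, cnt in
              sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])) if cnt > 0]
    n = len(cohort)
    return [(name, cnt, percent(cnt, n)) for name, cnt in ranked[:k]]


@dataclass(frozen=True)
class SubgroupTest:
    counts: tuple[tuple[int, int], tuple[int, int]]
    method: str           # chi_square | fisher | degenerate
    statistic: float | None
    p_value: float
    degenerate: bool = False


def subgroup_compare(counts: Sequence[Sequence[int]]) -> SubgroupTest:
    """Two-sided 2x2 comparison.

    Pearson chi-square without continuity correction when every expected
    cell is >= 5, otherwise Fisher's exact test.  A zero margin makes the
    comparison degenerate: p = 1.
    """
    tbl = np.asarray(counts, dtype=float)
    if tbl.shape != (2, 2) or (tbl < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    key = tuple((int(tbl[0, 0]), int(tbl[0, 1]))), tuple((int(tbl[1, 0]), int(tbl[1, 1])))
    if (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
        return SubgroupTest(key, "degenerate", None, 1.0, degenerate=True)
    expected = st.contingency.expected_freq(tbl)
    if (expected < 5).any():
        _, p = st.fisher_exact(tbl.astype(int), alternative="two-sided")
        return SubgroupTest(key, "fisher", None, float(p))
    chi2, p, _, _ = st.chi2_contingency(tbl, correction=False)
    return SubgroupTest(key, "chi_square", float(chi2), float(p))


def sex_contrast(cohort: Sequence[CaseReport], endpoint: CompositeEndpoint) -> SubgroupTest:
    """Female-vs-male comparison of one endpoint's AE share within a cohort
    (hits vs non-hit AEs, the endpoint table's per-sex convention)."""
    rows = []
    for sex in ("female", "male"):
        cases = [c for c in cohort if c.sex == sex]
        hits = sum(1 for c in cases if map_endpoints(c, (endpoint,)))
        rows.append((hits, ae_total(cases) - hits))
    return subgroup_compare(rows)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""
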