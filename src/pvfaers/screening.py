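"""The case-screening cascade that produces per-drug analysis cohorts.

Deduplicated reports flow through four stages, each a pure predicate:

1. drug match — the report names a target decarboxylase inhibitor (by brand
   or generic substring) among its suspect drugs together with levodopa;
2. oral route — the matched target/partner drug entries are oral;
3. indication — Parkinson's disease is an indication on the matched drug,
   PD is not itself listed as a reaction, and no dementia/psychosis-family
   term appears among reactions or indications;
4. SOC restriction — at least one reaction falls in a whitelisted system
   organ class; non-whitelisted reactions are masked from the analysis view
   (the original reaction list is preserved).

The cascade records a trace of surviving report counts after each stage and
terminal per-drug cohort sizes.  Because the stages are pure predicates the
terminal cohorts do not depend on stage order; only the trace does.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_faers import DATA_DIR, CaseReport, DrugEntry

SUSPECT_ROLES = ("suspect_primary", "suspect_secondary")

DEFAULT_SOC_WHITELIST = (
    "Nervous system disorders",
    "General disorders and administration site conditions",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DrugQuery:
    """Text-string search for a target drug plus a required partner.

    Matching is case-insensitive substring over both the verbatim drug name
    and the active-ingredient field, so brand names ("MADOPAR") and generic
    names ("benserazide") are both caught; a combination-product row naming
    the target and the partner satisfies both patterns at once.
    """

    target_label: str
    name_patterns: tuple[str, ...]
    required_partner_patterns: tuple[str, ...]
    required_roles: tuple[str, ...] = SUSPECT_ROLES

    def __post_init__(self) -> None:
        if not self.name_patterns or not self.required_partner_patterns:
            raise ConfigurationError(f"query {self.target_label!r}: empty pattern list")


def _entry_matches(entry: DrugEntry, patterns: Sequence[str]) -> bool:
    name = entry.name_raw.lower()
    ai = entry.active_ingredient.lower()
    return any(p in name or p in ai for p in patterns)


def matched_target_entries(case: CaseReport, query: DrugQuery) -> list[DrugEntry]:
    pats = [p.lower() for p in query.name_patterns]
    return [e for e in case.drugs
            if e.role in query.required_roles and _entry_matches(e, pats)]


def matched_partner_entries(case: CaseReport, query: DrugQuery) -> list[DrugEntry]:
    pats = [p.lower() for p in query.required_partner_patterns]
    return [e for e in case.drugs
            if e.role in query.required_roles and _entry_matches(e, pats)]


def drug_match(case: CaseReport, query: DrugQuery) -> bool:
    return bool(matched_target_entries(case, query)) and bool(matched_partner_entries(case, query))


def select_drug_reports(cases: Iterable[CaseReport], query: DrugQuery) -> list[CaseReport]:
    """Reports naming the target drug (with a required role) and the partner."""
    return [c for c in cases if drug_match(c, query)]


def oral_route_ok(case: CaseReport, query: DrugQuery) -> bool:
    """True when a matched target entry and a matched partner entry are oral.

    The route test applies to the matched entries only, not every drug in
    the report; an unknown route fails (conservative reading of an
    oral-administration-only restriction).
    """
    targets = matched_target_entries(case, query)
    partners = matched_partner_entries(case, query)
    return any(e.route == "oral" for e in targets) and any(e.route == "oral" for e in partners)


def filter_oral_route(cases: Iterable[CaseReport], query: DrugQuery) -> list[CaseReport]:
    return [c for c in cases if oral_route_ok(c, query)]


def load_pd_terms(path: Path | str | None = None) -> dict[str, set[str]]:
    """Configurable PT families: PD indication terms, PD-as-event terms and
    the dementia/psychosis exclusion families."""
    path = Path(path) if path is not None else DATA_DIR / "pd_terms.csv"
    fams: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            fams.setdefault(row["family"], set()).add(row["term"].lower())
    return fams


def indication_ok(case: CaseReport, query: DrugQuery, families: Mapping[str, set[str]]) -> bool:
    """PD indication on a matched target-drug entry; PD not reported as a
    reaction; no dementia/psychosis-family PT among reactions or indications."""
    indication_terms = families.get("indication", set())
    pd_event_terms = families.get("pd_event", set())
    excluded = families.get("dementia", set()) | families.get("psychosis", set())
    matched = matched_target_entries(case, query)
    has_pd_indication = any(ind.lower() in indication_terms
                            for e in matched for ind in e.indications)
    if not has_pd_indication:
        return False
    reactions = {pt.lower() for pt in case.reactions}
    if reactions & pd_event_terms:
        return False
    indications = {pt.lower() for pt in case.indications}
    if (reactions | indications) & excluded:
        return False
    return True


def filter_indication(cases: Iterable[CaseReport], query: DrugQuery,
                      families: Mapping[str, set[str]] | None = None) -> list[CaseReport]:
    families = families if families is not None else load_pd_terms()
    return [c for c in cases if indication_ok(c, query, families)]


def soc_ok(case: CaseReport, pt_to_soc: Mapping[str, str],
           whitelist: Sequence[str]) -> bool:
    wl = set(whitelist)
    return any(pt_to_soc.get(pt) in wl for pt in case.reactions)


def filter_soc(cases: Iterable[CaseReport], pt_to_soc: Mapping[str, str],
               whitelist: Sequence[str] = DEFAULT_SOC_WHITELIST) -> list[CaseReport]:
    """Keep cases with >=1 whitelisted-SOC reaction; restrict the analysis
    view to those reactions.  PTs absent from the mapping count as
    non-whitelisted."""
    wl = set(whitelist)
    out: list[CaseReport] = []
    for case in cases:
        view = [pt for pt in case.reactions if pt_to_soc.get(pt) in wl]
        if view:
            case.analysis_reactions = view
            out.append(case)
    return out


@dataclass(frozen=True)
class ScreeningTrace:
    """Ordered (stage name, surviving report count) pairs."""

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be non-increasing")

    def as_rows(self) -> list[dict[str, object]]:
        return [{"stage": s, "count": c} for s, c in self.stages]


@dataclass
class Cohort:
    label: str
    cases: list[CaseReport]
    trace: ScreeningTrace


@dataclass
class CascadeConfig:
    queries: tuple[DrugQuery, ...]
    pt_to_soc: Mapping[str, str]
    soc_whitelist: tuple[str, ...] = DEFAULT_SOC_WHITELIST
    pd_families: Mapping[str, set[str]] = field(default_factory=load_pd_terms)
    apply_oral: bool = True
    apply_indication: bool = True
    apply_soc: bool = True
    # cases matching several drug queries are kept in every matching cohort
    # and flagged; set True to drop them instead
    drop_dual_matches: bool = False


@dataclass
class CascadeResult:
    cohorts: dict[str, Cohort]
    trace: ScreeningTrace
    dual_match_case_ids: tuple[str, ...]
    # all cases surviving the case-level stages regardless of drug query
    screened_cases: list[CaseReport]
    # funnel stages plus the terminal per-cohort counts
    full_stages: tuple[tuple[str, int], ...] = ()


def run_cascade(cases: Sequence[CaseReport], config: CascadeConfig) -> CascadeResult:
    """Apply the staged screen and build one cohort per drug query.

    The trace counts, per stage, reports satisfying the stage's predicate
    for at least one query (matching the single funnel of a screening
    flowchart); terminal per-drug counts follow as separate stages.
    """
    if not config.queries:
        raise ConfigurationError("no drug queries configured")

    matched = {q.target_label: {id(c) for c in cases if drug_match(c, q)} for q in config.queries}
    surviving = dict(matched)
    stages: list[tuple[str, int]] = [("reports_loaded", len(cases))]
    stages.append(("drug_match", len(set().union(*surviving.values()))))

    if config.apply_oral:
        surviving = {q.target_label: {id(c) for c in cases
                                      if id(c) in surviving[q.target_label] and oral_route_ok(c, q)}
                     for q in config.queries}
        stages.append(("oral_route", len(set().union(*surviving.values()))))
    if config.apply_indication:
        surviving = {q.target_label: {id(c) for c in cases
                                      if id(c) in surviving[q.target_label]
                                      and indication_ok(c, q, config.pd_families)}
                     for q in config.queries}
        stages.append(("pd_indication", len(set().union(*surviving.values()))))
    if config.apply_soc:
        union_before = set().union(*surviving.values())
        kept = filter_soc([c for c in cases if id(c) in union_before],
                          config.pt_to_soc, config.soc_whitelist)
        kept_ids = {id(c) for c in kept}
        surviving = {label: ids & kept_ids for label, ids in surviving.items()}
        stages.append(("soc_whitelist", len(set().union(*surviving.values()))))

    all_ids = set().union(*surviving.values())
    dual = sorted({c.case_id for c in cases
                   if sum(id(c) in ids for ids in surviving.values()) > 1})
    cohorts: dict[str, Cohort] = {}
    for q in config.queries:
        ids = surviving[q.target_label]
        members = [c for c in cases if id(c) in ids]
        if config.drop_dual_matches:
            members = [c for c in members if c.case_id not in set(dual)]
        stages.append((f"cohort_{q.target_label}", len(members)))
        cohorts[q.target_label] = Cohort(q.target_label, members, ScreeningTrace(tuple()))

    # stage counts are non-increasing along the funnel; terminal per-drug
    # counts are partitions of the last funnel stage, appended afterwards
    funnel_len = len(stages) - len(config.queries)
    trace = ScreeningTrace(tuple(stages[:funnel_len]))
    full = tuple(stages)
    for cohort in cohorts.values():
        cohort.trace = trace
    screened = [c for c in cases if id(c) in all_ids]
    return CascadeResult(cohorts=cohorts, trace=trace,
                         dual_match_case_ids=tuple(dual), screened_cases=screened,
                         full_stages=full)


def default_queries() -> tuple[DrugQuery, DrugQuery]:
    """Benserazide+levodopa and carbidopa+levodopa suspect-drug queries with
    common brand names."""
    return (
        DrugQuery("BSZ",
                  name_patterns=("benserazide", "madopar", "prolopa"),
                  required_partner_patterns=("levodopa", "madopar", "prolopa")),
        DrugQuery("CD",
                  name_patterns=("carbidopa", "sinemet", "rytary", "duopa", "lodosyn"),
                  required_partner_patterns=("levodopa", "sinemet", "rytary", "duopa")),
    )
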