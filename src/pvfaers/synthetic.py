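"""Synthetic FAERS-dialect data with known ground truth.

The generator emulates the structure of spontaneous adverse-event reporting
data: one report links a case to several drugs (with role, route and
brand/combination names) and several MedDRA preferred terms, carries
demographics, serious-outcome codes, an indication table and a report-source
table, and a configurable fraction of cases is re-emitted with a bumped
``caseversion`` to exercise deduplication.

Drug-event associations of chosen strength are injected on the PT
probability: a PT's Bernoulli probability is ``background * rr`` when a
matching drug is present (capped).  Because the relative risk acts on the
rate, the recoverable reporting odds ratio approximates ``rr`` only while
``background * rr`` stays small (rare-event regime); the generator warns
when ``background * rr > 0.1``.

Every stage of the screening cascade is ground-truthed per case, and the
realized 2x2 counts per drug-endpoint pair (cohort vs all-other-reports
comparator) are recorded so pipeline output can be checked exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_faers import RawTables, load_pt_soc, write_quarter
from .screening import DEFAULT_SOC_WHITELIST, SUSPECT_ROLES
from .io_faers import ROLE_MAP

_SUSPECT_CODES = tuple(code for code, label in ROLE_MAP.items() if label in SUSPECT_ROLES)


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the vocabulary with its marginal probability and the
    distributions of its raw route / role codes."""

    name: str
    prod_ai: str
    p: float
    routes: tuple[tuple[str, float], ...] = (("ORAL", 1.0),)
    roles: tuple[tuple[str, float], ...] = (("C", 1.0),)
    pd_indication_p: float = 0.0
    target_label: str | None = None   # "BSZ"/"CD" for DCI combination products

    def matches(self, pattern: str) -> bool:
        pat = pattern.lower()
        return pat in self.name.lower() or pat in self.prod_ai.lower()


@dataclass(frozen=True)
class Association:
    """Injected drug-event association: PT probability is multiplied by
    ``rr`` when a drug matching ``drug_pattern`` is present."""

    drug_pattern: str
    pt: str
    rr: float

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("target relative risk must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    n_cases: int
    seed: int
    drugs: tuple[DrugSpec, ...]
    pt_probs: tuple[tuple[str, float], ...]
    associations: tuple[Association, ...] = ()
    age_band_weights: tuple[tuple[str, float], ...] = (
        ("<20", 0.001), ("20-50", 0.025), ("50-65", 0.13), (">=65", 0.55), ("unknown", 0.294))
    sex_weights: tuple[tuple[str, float], ...] = (("F", 0.46), ("M", 0.51), ("", 0.03))
    reporter_weights: tuple[tuple[str, float], ...] = (
        ("MD", 0.16), ("CN", 0.60), ("OT", 0.10), ("PH", 0.09), ("LW", 0.01), ("", 0.04))
    country_weights: tuple[tuple[str, float], ...] = (
        ("US", 0.50), ("DE", 0.08), ("FR", 0.06), ("GB", 0.05), ("JP", 0.06),
        ("BR", 0.03), ("IT", 0.04), ("CA", 0.05), ("AU", 0.05), ("XX", 0.08))
    outcome_probs: tuple[tuple[str, float], ...] = (
        ("HO", 0.35), ("OT", 0.30), ("LT", 0.04), ("DE", 0.08), ("DS", 0.04), ("CA", 0.001))
    weight_log_mu: float = 4.248495242049359   # ln 70 kg
    weight_log_sigma: float = 0.18
    weight_missing_p: float = 0.45
    duplicate_fraction: float = 0.10
    filler_pt: str = "Nausea"
    prob_cap: float = 0.95
    quarter: str = "24Q2"
    planted_stages: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not self.drugs or not self.pt_probs:
            raise ValueError("drug and PT vocabularies must be non-empty")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        for _, p in self.pt_probs:
            if not 0 <= p <= 1:
                raise ValueError("PT probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-case screening-stage flags, realized 2x2 counts and injected rrs."""

    cases: pd.DataFrame                      # one row per unique case, flag columns per label
    stage_counts: dict[str, int]             # funnel counts matching the cascade semantics
    counts: dict[tuple[str, str], tuple[int, int, int, int]]   # (label, pt) -> (a, b, c, d)
    lambdas: dict[tuple[str, str], float]    # (drug_pattern, pt) -> injected rr
    n_unique_cases: int
    capped_pts: tuple[str, ...] = ()


@dataclass
class GenerationResult:
    tables: dict[str, pd.DataFrame]
    ground_truth: GroundTruth
    paths: dict[str, Path] | None = None

    def as_raw_tables(self) -> RawTables:
        return RawTables(**{k: v.copy() for k, v in self.tables.items()})


def _categorical(rng: np.random.Generator, weights: Sequence[tuple[str, float]],
                 size: int) -> np.ndarray:
    values = np.array([v for v, _ in weights], dtype=object)
    probs = np.array([p for _, p in weights], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(values, size=size, p=probs)


_BAND_RANGES = {"<20": (5.0, 19.0), "20-50": (20.0, 49.0), "50-65": (50.0, 64.0),
                ">=65": (65.0, 95.0)}


def generate(config: SyntheticConfig, outdir: Path | str | None = None) -> GenerationResult:
    """Draw one synthetic quarter and its ground truth.

    All randomness comes from ``config.seed``; the same config yields
    byte-identical files.  When ``outdir`` is given the six FAERS-dialect
    files plus a ground-truth sidecar are written there.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    planted = config.planted_stages
    if planted is not None:
        _validate_stage_targets(planted, n)

    # ------------------------------------------------------------------ drugs
    present: dict[str, np.ndarray] = {}
    role_code: dict[str, np.ndarray] = {}
    route_raw: dict[str, np.ndarray] = {}
    indi_flag: dict[str, np.ndarray] = {}
    for spec in config.drugs:
        present[spec.name] = rng.random(n) < spec.p
        role_code[spec.name] = _categorical(rng, spec.roles, n)
        route_raw[spec.name] = _categorical(rng, spec.routes, n)
        indi_flag[spec.name] = rng.random(n) < spec.pd_indication_p

    if planted is not None:
        t0, t1, t2, _ = planted
        idx = np.arange(n)
        for spec in config.drugs:
            if spec.target_label is not None:
                present[spec.name] = idx < t0
                role_code[spec.name] = np.where(idx < t0, "PS", role_code[spec.name])
                route_raw[spec.name] = np.where(idx < t1, "ORAL", "TRANSDERMAL")
                indi_flag[spec.name] = idx < t0
            else:
                present[spec.name] = idx >= t0   # everyone still has >=1 drug

    # --------------------------------------------------------------- reactions
    pt_names = [pt for pt, _ in config.pt_probs]
    pt_p0 = np.array([p for _, p in config.pt_probs])
    p0_by_name = dict(config.pt_probs)
    for assoc in config.associations:
        if p0_by_name.get(assoc.pt, 0.0) * assoc.rr > 0.1:
            warnings.warn(
                f"association ({assoc.drug_pattern!r}, {assoc.pt!r}): background x rr = "
                f"{p0_by_name[assoc.pt] * assoc.rr:.3f} > 0.1; outside the rare-event "
                "regime the recoverable ROR exceeds the injected rate ratio", stacklevel=2)
    mult = np.ones((n, len(pt_names)))
    for assoc in config.associations:
        cols = [j for j, pt in enumerate(pt_names) if pt == assoc.pt]
        if not cols:
            raise ValueError(f"association PT {assoc.pt!r} not in the PT vocabulary")
        exposed = np.zeros(n, dtype=bool)
        for spec in config.drugs:
            if spec.matches(assoc.drug_pattern):
                exposed |= present[spec.name]
        for j in cols:
            mult[exposed, j] = np.maximum(mult[exposed, j], assoc.rr)
    probs = pt_p0[None, :] * mult
    capped_cols = np.unique(np.nonzero(probs > config.prob_cap)[1])
    capped = tuple(pt_names[j] for j in capped_cols)
    if capped:
        warnings.warn(f"PT probabilities capped at {config.prob_cap} for {capped}", stacklevel=2)
    probs = np.minimum(probs, config.prob_cap)
    pt_matrix = rng.random((n, len(pt_names))) < probs

    soc_map = load_pt_soc()
    whitelisted = np.array([soc_map.get(pt) in set(DEFAULT_SOC_WHITELIST) for pt in pt_names])
    pd_event = np.array([pt == "Parkinson's disease" for pt in pt_names])
    excl = np.array([pt in ("Dementia", "Psychotic disorder", "Hallucination",
                            "Hallucination visual", "Delusion") for pt in pt_names])

    if planted is not None:
        t0, t1, t2, t3 = planted
        idx = np.arange(n)
        # inside the funnel the confounding PT families are controlled exactly
        pt_matrix[:, pd_event | excl] = False
        fail_indication = (idx >= t2) & (idx < t1)
        if pd_event.any():
            pt_matrix[fail_indication[:, None] & pd_event[None, :]] = True
        pass_soc = idx < t3
        fail_soc = (idx >= t3) & (idx < t2)
        pt_matrix[fail_soc[:, None] & whitelisted[None, :]] = False
        anchor = pt_names.index("Dizziness") if "Dizziness" in pt_names else int(np.argmax(whitelisted))
        pt_matrix[pass_soc, anchor] = True

    # guarantee the reactions-non-empty invariant with a filler PT
    empty = ~pt_matrix.any(axis=1)
    if empty.any():
        if config.filler_pt in pt_names:
            pt_matrix[empty, pt_names.index(config.filler_pt)] = True
        else:
            pt_names.append(config.filler_pt)
            pt_matrix = np.hstack([pt_matrix, empty[:, None]])
            whitelisted = np.append(whitelisted, soc_map.get(config.filler_pt) in set(DEFAULT_SOC_WHITELIST))
            pd_event = np.append(pd_event, False)
            excl = np.append(excl, False)

    # ------------------------------------------------------------ demographics
    band = _categorical(rng, config.age_band_weights, n)
    age_years = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    for b, (lo, hi) in _BAND_RANGES.items():
        mask = band == b
        k = int(mask.sum())
        if not k:
            continue
        years = np.round(rng.uniform(lo, hi, size=k))
        unit = _categorical(rng, (("YR", 0.92), ("DEC", 0.06), ("MON", 0.02)), k)
        value = np.where(unit == "YR", years,
                         np.where(unit == "DEC", np.floor(years / 10), np.round(years * 12)))
        age_years[mask] = [f"{v:.0f}" for v in value]
        age_cod[mask] = unit
    sex = _categorical(rng, config.sex_weights, n)
    occp = _categorical(rng, config.reporter_weights, n)
    country = _categorical(rng, config.country_weights, n)
    wt_kg = np.exp(rng.normal(config.weight_log_mu, config.weight_log_sigma, size=n))
    wt_missing = rng.random(n) < config.weight_missing_p
    wt_lbs = rng.random(n) < 0.15
    wt = np.where(wt_lbs, wt_kg / 0.453592, wt_kg)
    wt_str = np.where(wt_missing, "", np.char.mod("%.1f", wt))
    wt_cod = np.where(wt_missing, "", np.where(wt_lbs, "LBS", "KG"))

    quarter_idx = rng.integers(0, 82, size=n)   # 2004Q1 .. 2024Q2
    day = rng.integers(0, 89, size=n)
    year = 2004 + quarter_idx // 4
    month = 1 + 3 * (quarter_idx % 4) + day // 30
    dom = 1 + day % 28
    event_dt = [f"{y}{m:02d}{d:02d}" for y, m, d in zip(year, month, dom)]

    caseid = np.array([str(10_000_000 + i) for i in range(n)], dtype=object)
    primaryid = np.array([cid + "1" for cid in caseid], dtype=object)

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "caseversion": "1",
        "event_dt": event_dt, "age": age_years, "age_cod": age_cod,
        "sex": sex, "wt": wt_str, "wt_cod": wt_cod,
        "reporter_country": country, "occp_cod": occp,
    })

    drug_parts = []
    for spec in config.drugs:
        rows = np.nonzero(present[spec.name])[0]
        if rows.size == 0:
            continue
        drug_parts.append(pd.DataFrame({
            "case_idx": rows,
            "role_cod": role_code[spec.name][rows],
            "drugname": spec.name,
            "prod_ai": spec.prod_ai,
            "route": route_raw[spec.name][rows],
            "_indi": indi_flag[spec.name][rows],
        }))
    drug = pd.concat(drug_parts, ignore_index=True).sort_values(
        ["case_idx"], kind="mergesort").reset_index(drop=True)
    drug["drug_seq"] = (drug.groupby("case_idx").cumcount() + 1).astype(str)
    drug["primaryid"] = primaryid[drug["case_idx"].to_numpy()]
    drug["caseid"] = caseid[drug["case_idx"].to_numpy()]

    indi = drug.loc[drug["_indi"], ["primaryid", "caseid", "drug_seq"]].copy()
    indi = indi.rename(columns={"drug_seq": "indi_drug_seq"})
    indi["indi_pt"] = "Parkinson's disease"
    drug = drug[["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai", "route"]]

    reac_case, reac_pt = np.nonzero(pt_matrix)
    reac = pd.DataFrame({
        "primaryid": primaryid[reac_case], "caseid": caseid[reac_case],
        "pt": np.array(pt_names, dtype=object)[reac_pt],
    })

    outc_parts = []
    for code, p in config.outcome_probs:
        rows = np.nonzero(rng.random(n) < p)[0]
        if rows.size:
            outc_parts.append(pd.DataFrame({
                "primaryid": primaryid[rows], "caseid": caseid[rows], "outc_cod": code,
                "_case_idx": rows,
            }))
    if outc_parts:
        outc = pd.concat(outc_parts, ignore_index=True).sort_values(
            ["_case_idx"], kind="mergesort").reset_index(drop=True)[
            ["primaryid", "caseid", "outc_cod"]]
    else:
        outc = pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"])

    rpsr = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid,
        "rpsr_cod": _categorical(rng, (("FGN", 0.3), ("HP", 0.4), ("CSM", 0.3)), n),
    })

    tables = {"demo": demo, "drug": drug, "reac": reac, "indi": indi,
              "outc": outc, "rpsr": rpsr}

    # ------------------------------------------------------------- duplicates
    n_dup = int(np.floor(config.duplicate_fraction * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        dup_case = set(caseid[dup_idx])
        for name, df in tables.items():
            dup_rows = df[df["caseid"].isin(dup_case)].copy()
            dup_rows["primaryid"] = dup_rows["caseid"] + "2"
            if name == "demo":
                dup_rows["caseversion"] = "2"
            tables[name] = pd.concat([df, dup_rows], ignore_index=True)

    # ------------------------------------------------------------ ground truth
    gt = _ground_truth(config, present, role_code, route_raw, indi_flag,
                       pt_matrix, pt_names, whitelisted, pd_event, excl, capped)

    paths = None
    if outdir is not None:
        paths = write_quarter(tables, outdir, config.quarter)
        gt.cases.to_csv(Path(outdir) / "ground_truth_cases.csv", index=False)
    return GenerationResult(tables=tables, ground_truth=gt, paths=paths)


def _ground_truth(config, present, role_code, route_raw, indi_flag,
                  pt_matrix, pt_names, whitelisted, pd_event, excl, capped) -> GroundTruth:
    n = config.n_cases
    labels = sorted({s.target_label for s in config.drugs if s.target_label})
    has_pd_reaction = pt_matrix[:, pd_event].any(axis=1) if pd_event.any() else np.zeros(n, bool)
    has_excl = pt_matrix[:, excl].any(axis=1) if excl.any() else np.zeros(n, bool)
    soc_ok = pt_matrix[:, whitelisted].any(axis=1)

    flags: dict[str, np.ndarray] = {}
    for label in labels:
        match = np.zeros(n, bool)
        oral = np.zeros(n, bool)
        indication = np.zeros(n, bool)
        for spec in config.drugs:
            if spec.target_label != label:
                continue
            suspect = present[spec.name] & np.isin(role_code[spec.name], _SUSPECT_CODES)
            match |= suspect
            oral |= suspect & (route_raw[spec.name] == "ORAL")
            indication |= suspect & indi_flag[spec.name]
        indication = indication & ~has_pd_reaction & ~has_excl
        flags[f"match_{label}"] = match
        flags[f"oral_{label}"] = match & oral
        flags[f"indication_{label}"] = match & oral & indication
        flags[f"eligible_{label}"] = match & oral & indication & soc_ok

    stage_counts = {
        "reports_loaded": n,
        "drug_match": int(np.any([flags[f"match_{l}"] for l in labels], axis=0).sum()),
        "oral_route": int(np.any([flags[f"oral_{l}"] for l in labels], axis=0).sum()),
        "pd_indication": int(np.any([flags[f"indication_{l}"] for l in labels], axis=0).sum()),
        "soc_whitelist": int(np.any([flags[f"eligible_{l}"] for l in labels], axis=0).sum()),
    }
    for label in labels:
        stage_counts[f"cohort_{label}"] = int(flags[f"eligible_{label}"].sum())

    assoc_pts = sorted({a.pt for a in config.associations})
    counts: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for label in labels:
        eligible = flags[f"eligible_{label}"]
        n_cohort = int(eligible.sum())
        n_bg = n - n_cohort
        for pt in assoc_pts:
            col = pt_names.index(pt)
            hit = pt_matrix[:, col]
            a = int((eligible & hit).sum())
            c = int((~eligible & hit).sum())
            counts[(label, pt)] = (a, n_cohort - a, c, n_bg - c)

    cases = pd.DataFrame({"caseid": [str(10_000_000 + i) for i in range(n)],
                          "soc_ok": soc_ok, **flags})
    lambdas = {(a.drug_pattern, a.pt): a.rr for a in config.associations}
    return GroundTruth(cases=cases, stage_counts=stage_counts, counts=counts,
                       lambdas=lambdas, n_unique_cases=n, capped_pts=capped)


def _validate_stage_targets(targets: Sequence[int], n_cases: int) -> None:
    if len(targets) != 4:
        raise ValueError("stage targets must be (drug_match, oral, indication, soc)")
    if targets[0] > n_cases:
        raise ValueError("first stage target exceeds n_cases")
    if any(t < 0 for t in targets):
        raise ValueError("stage targets must be nonnegative")
    if any(b > a for a, b in zip(targets, targets[1:])):
        raise ValueError("stage targets must be non-increasing")


def plant_flowchart(config: SyntheticConfig,
                    stage_targets: Sequence[int]) -> SyntheticConfig:
    """Return a config whose screening funnel hits ``stage_targets`` exactly
    (counts after drug match, oral route, indication and SOC stages)."""
    _validate_stage_targets(stage_targets, config.n_cases)
    return dataclasses.replace(config, planted_stages=tuple(int(t) for t in stage_targets))


# ---------------------------------------------------------------------------
# default study-like configuration


def default_drug_vocab() -> tuple[DrugSpec, ...]:
    """Levodopa/DCI combination products (benserazide about one fifth as
    frequent as carbidopa, echoing their reporting pattern), common
    anti-parkinsonian co-medications and unrelated background drugs."""
    combo_routes = (("ORAL", 0.90), ("INTRADUODENAL", 0.04), ("UNKNOWN", 0.06))
    combo_roles = (("PS", 0.78), ("SS", 0.15), ("C", 0.07))
    conc_roles = (("C", 0.85), ("SS", 0.15))
    return (
        DrugSpec("MADOPAR", "LEVODOPA\\BENSERAZIDE", 0.08, combo_routes, combo_roles,
                 pd_indication_p=0.92, target_label="BSZ"),
        DrugSpec("SINEMET", "LEVODOPA\\CARBIDOPA", 0.32, combo_routes, combo_roles,
                 pd_indication_p=0.92, target_label="CD"),
        DrugSpec("MIRAPEX", "PRAMIPEXOLE DIHYDROCHLORIDE", 0.055, (("ORAL", 1.0),), conc_roles, 0.5),
        DrugSpec("AMANTADINE", "AMANTADINE HYDROCHLORIDE", 0.04, (("ORAL", 1.0),), conc_roles, 0.5),
        DrugSpec("AZILECT", "RASAGILINE MESYLATE", 0.03, (("ORAL", 1.0),), conc_roles, 0.5),
        DrugSpec("REQUIP", "ROPINIROLE HYDROCHLORIDE", 0.028, (("ORAL", 1.0),), conc_roles, 0.5),
        DrugSpec("NEUPRO", "ROTIGOTINE", 0.022, (("TRANSDERMAL", 1.0),), conc_roles, 0.5),
        DrugSpec("COMTAN", "ENTACAPONE", 0.026, (("ORAL", 1.0),), conc_roles, 0.5),
        DrugSpec("ASPIRIN", "ASPIRIN", 0.15, (("ORAL", 1.0),), (("C", 1.0),)),
        DrugSpec("OMEPRAZOLE", "OMEPRAZOLE", 0.10, (("ORAL", 1.0),), (("C", 1.0),)),
        DrugSpec("METFORMIN", "METFORMIN HYDROCHLORIDE", 0.09, (("ORAL", 1.0),), (("C", 1.0),)),
    )


def default_pt_probs() -> tuple[tuple[str, float], ...]:
    """Background PT probabilities: a handful of frequent nonspecific terms,
    rare motor-complication terms (to be amplified by injected associations)
    and the confounder terms that exercise the exclusion filters."""
    return (
        ("Dizziness", 0.06), ("Headache", 0.05), ("Tremor", 0.04), ("Somnolence", 0.03),
        ("Fatigue", 0.06), ("Asthenia", 0.03), ("Gait disturbance", 0.03),
        ("Drug ineffective", 0.05), ("Oedema peripheral", 0.02), ("Condition aggravated", 0.02),
        ("Nausea", 0.08), ("Vomiting", 0.04), ("Constipation", 0.03), ("Diarrhoea", 0.03),
        ("Fall", 0.04), ("Insomnia", 0.03), ("Confusional state", 0.02), ("Rash", 0.02),
        ("Hypertension", 0.02), ("Orthostatic hypotension", 0.015), ("Weight decreased", 0.02),
        ("Muscle spasms", 0.02), ("Arthralgia", 0.02), ("Dyspnoea", 0.02),
        ("Vision blurred", 0.01), ("Decreased appetite", 0.015), ("Hyperhidrosis", 0.01),
        # motor-complication terms (rare background)
        ("Dyskinesia", 0.003), ("Dystonia", 0.002), ("Hyperkinesia", 0.0008),
        ("On and off phenomenon", 0.0004), ("Freezing phenomenon", 0.0004),
        ("Therapeutic response shortened", 0.003), ("Therapeutic response incomplete", 0.0015),
        # confounder terms exercising the exclusion filters
        ("Parkinson's disease", 0.01), ("Dementia", 0.008), ("Hallucination", 0.012),
    )


def default_associations() -> tuple[Association, ...]:
    """Injected effects shaped like the benserazide/carbidopa motor
    complication contrast: stronger dyskinesia and on-off amplification for
    benserazide, stronger wearing-off for carbidopa."""
    return (
        Association("benserazide", "Dyskinesia", 16.0),
        Association("benserazide", "Dystonia", 10.0),
        Association("benserazide", "On and off phenomenon", 150.0),
        Association("benserazide", "Freezing phenomenon", 100.0),
        Association("benserazide", "Therapeutic response shortened", 3.0),
        Association("carbidopa", "Dyskinesia", 13.0),
        Association("carbidopa", "Dystonia", 8.0),
        Association("carbidopa", "On and off phenomenon", 65.0),
        Association("carbidopa", "Freezing phenomenon", 90.0),
        Association("carbidopa", "Therapeutic response shortened", 7.5),
        Association("carbidopa", "Therapeutic response incomplete", 5.0),
    )


def recovery_config(rr: float, seed: int, n_cases: int = 3000) -> SyntheticConfig:
    """Configuration for injected-effect recovery studies of the estimators.

    The screening filters pass deterministically for exposed reports (oral
    combination products, certain PD indication, no confounder terms), the
    anchor endpoint's background probability is set to ``0.03 / rr`` so the
    rare-event approximation ROR ~= rr holds at every tested strength while
    the expected exposed hit count stays near 30, and frequent whitelisted
    background PTs keep the SOC stage from selecting on the endpoint.
    """
    combo_roles = (("PS", 1.0),)
    oral = (("ORAL", 1.0),)
    p0 = 0.03 / rr
    return SyntheticConfig(
        n_cases=n_cases,
        seed=seed,
        drugs=(
            DrugSpec("MADOPAR", "LEVODOPA\\BENSERAZIDE", 0.35, oral, combo_roles,
                     pd_indication_p=1.0, target_label="BSZ"),
            DrugSpec("SINEMET", "LEVODOPA\\CARBIDOPA", 0.25, oral, combo_roles,
                     pd_indication_p=1.0, target_label="CD"),
            DrugSpec("ASPIRIN", "ASPIRIN", 0.30, oral, (("C", 1.0),)),
        ),
        pt_probs=(
            ("Dizziness", 0.5), ("Fatigue", 0.5), ("Headache", 0.4), ("Tremor", 0.4),
            ("Somnolence", 0.4), ("Gait disturbance", 0.4), ("Asthenia", 0.4),
            ("Nausea", 0.05),
            ("On and off phenomenon", p0),
            ("Dyskinesia", 0.01), ("Therapeutic response shortened", 0.01),
            ("Freezing phenomenon", 0.005),
        ),
        associations=(Association("benserazide", "On and off phenomenon", rr),),
        duplicate_fraction=0.05,
    )


def default_config(n_cases: int = 20_000, seed: int = 0, **overrides) -> SyntheticConfig:
    base = dict(
        n_cases=n_cases,
        seed=seed,
        drugs=default_drug_vocab(),
        pt_probs=default_pt_probs(),
        associations=default_associations(),
    )
    base.update(overrides)
    return SyntheticConfig(**base)
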