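"""Reading, writing and deduplicating FAERS-dialect quarterly ASCII tables.

FAERS distributes each quarter as six dollar-sign-delimited text files
(DEMO, DRUG, REAC, INDI, OUTC, RPSR).  A *case* (``caseid``) may appear in
several versions (``caseversion``) across quarters as manufacturers amend
reports; every version carries its own ``primaryid`` that keys the child
tables.  This module parses the dialect, normalizes the coded fields
(routes, reporter occupation codes, country codes, age/weight units) and
collapses versions to one :class:`CaseReport` per case.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DATA_DIR = Path(__file__).parent / "data"

TABLE_NAMES = ("demo", "drug", "reac", "indi", "outc", "rpsr")

REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "caseversion", "event_dt", "age", "age_cod",
             "sex", "wt", "wt_cod", "reporter_country", "occp_cod"),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "prod_ai", "route"),
    "reac": ("primaryid", "caseid", "pt"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "rpsr": ("primaryid", "caseid", "rpsr_cod"),
}

ROLE_MAP = {
    "PS": "suspect_primary",
    "SS": "suspect_secondary",
    "C": "concomitant",
    "I": "interacting",
}

OUTCOME_MAP = {
    "HO": "hospitalization",
    "LT": "life_threatening",
    "DE": "death",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "OT": "other_serious",
    "RI": "other_serious",
}

AGE_BANDS = ("<20", "20-50", "50-65", ">=65", "unknown")


class FormatError(ValueError):
    """A mandatory column is missing or a table cannot be parsed."""


def _load_two_column_map(filename: str, key: str, value: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(DATA_DIR / filename, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row[key]] = row[value]
    return out


def load_route_map() -> dict[str, str]:
    return _load_two_column_map("route_map.csv", "raw", "canonical")


def load_reporter_map() -> dict[str, str]:
    return _load_two_column_map("reporter_map.csv", "code", "label")


def load_country_groups() -> dict[str, str]:
    return _load_two_column_map("country_groups.csv", "code", "group")


def load_pt_soc() -> dict[str, str]:
    """Flat preferred-term -> system-organ-class table (miniature dictionary)."""
    return _load_two_column_map("pt_soc.csv", "pt", "soc")


_ROUTE_MAP = load_route_map()
_REPORTER_MAP = load_reporter_map()
_COUNTRY_GROUPS = load_country_groups()


def canonical_route(raw: str) -> str:
    route = _ROUTE_MAP.get(raw.strip().upper())
    if route is None:
        route = "unknown"
    return route


@dataclass
class RawTables:
    """The six parsed tables of one quarter plus rejected orphan rows."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    rejects: dict[str, pd.DataFrame] = field(default_factory=dict)

    def row_counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLE_NAMES}


@dataclass(slots=True)
class DrugEntry:
    """One drug row of a report after vocabulary normalization."""

    name_raw: str
    active_ingredient: str
    role: str          # suspect_primary | suspect_secondary | concomitant | interacting
    route: str         # canonical route string, "unknown" when absent
    indications: tuple[str, ...] = ()


@dataclass(slots=True)
class CaseReport:
    """One deduplicated safety report with harmonized demographics."""

    case_id: str
    primary_id: str
    received_date: str            # yyyymmdd, possibly truncated
    age_years: float | None
    age_band: str                 # one of AGE_BANDS
    sex: str                      # female | male | unknown
    weight_kg: float | None
    reporter: str
    country_group: str
    outcomes: tuple[str, ...]
    drugs: list[DrugEntry]
    reactions: list[str]
    indications: list[str]
    # reactions restricted to whitelisted SOCs; set by the SOC screening stage
    analysis_reactions: list[str] | None = None

    @property
    def analysis_view(self) -> list[str]:
        return self.reactions if self.analysis_reactions is None else self.analysis_reactions


def _read_table(path: Path, name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                         encoding="utf-8", quoting=csv.QUOTE_NONE)
    except UnicodeDecodeError:
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                         encoding="latin-1", quoting=csv.QUOTE_NONE)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing} in {name.upper()} table")
    return df


def find_quarter_files(directory: Path) -> dict[str, Path]:
    """Locate DEMO/DRUG/... files in ``directory`` by their FAERS stems."""
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        hits = sorted(directory.glob(f"{name.upper()}*.txt")) + sorted(directory.glob(f"{name.upper()}*.TXT"))
        if not hits:
            raise FileNotFoundError(f"no {name.upper()}* file in {directory}")
        paths[name] = hits[0]
    return paths


def read_quarter(paths: Mapping[str, Path] | Path | str) -> RawTables:
    """Parse one quarter's six $-delimited tables.

    ``paths`` is either a directory containing files with the standard FAERS
    stems or an explicit table-name -> path mapping.  Child rows whose
    ``primaryid`` is absent from DEMO are collected into ``rejects`` rather
    than raising.
    """
    if isinstance(paths, (str, Path)):
        paths = find_quarter_files(Path(paths))
    frames = {name: _read_table(Path(paths[name]), name) for name in TABLE_NAMES}
    known = set(frames["demo"]["primaryid"])
    rejects: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES[1:]:
        df = frames[name]
        orphan = ~df["primaryid"].isin(known)
        if orphan.any():
            rejects[name] = df[orphan].copy()
            frames[name] = df[~orphan].copy()
    return RawTables(**frames, rejects=rejects)


def write_quarter(tables: Mapping[str, pd.DataFrame], directory: Path | str,
                  quarter: str = "24Q2") -> dict[str, Path]:
    """Write tables in the FAERS dialect (one header line, $ delimiter)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        path = directory / f"{name.upper()}{quarter}.txt"
        tables[name].to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# field harmonization


def age_in_years(age: str, age_cod: str) -> float | None:
    """Convert an (age, unit-code) pair to years.

    Unit codes: YR years, DEC decades, MON months, WK weeks, DY days,
    HR hours.  A missing code with a plausible-year value is treated as
    years (common FAERS entry practice).
    """
    age = age.strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    cod = age_cod.strip().upper()
    factor = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.1775,
              "DY": 1 / 365.25, "HR": 1 / 8766.0}.get(cod)
    if factor is None:
        if cod == "" and 0 <= value <= 120:
            factor = 1.0
        else:
            return None
    years = value * factor
    if years < 0 or years > 120:
        return None
    return years


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 20:
        return "<20"
    if age_years < 50:
        return "20-50"
    if age_years < 65:
        return "50-65"
    return ">=65"


_LBS_TO_KG = 0.453592


def weight_in_kg(wt: str, wt_cod: str) -> float | None:
    """Weight harmonized to kg; values outside (20, 300) kg are unknown."""
    wt = wt.strip()
    if not wt:
        return None
    try:
        value = float(wt)
    except ValueError:
        return None
    cod = wt_cod.strip().upper()
    if cod == "LBS":
        value *= _LBS_TO_KG
    elif cod not in ("", "KG", "KGS"):
        return None
    if not (20 < value < 300):
        return None
    return value


def normalize_sex(raw: str) -> str:
    return {"F": "female", "M": "male"}.get(raw.strip().upper(), "unknown")


def normalize_reporter(occp_cod: str) -> str:
    label = _REPORTER_MAP.get(occp_cod.strip().upper())
    return label if label is not None else "unknown"


def normalize_country(code: str) -> str:
    return _COUNTRY_GROUPS.get(code.strip().upper(), "other")


def normalize_outcomes(codes: Iterable[str]) -> tuple[str, ...]:
    seen: list[str] = []
    for code in codes:
        label = OUTCOME_MAP.get(code.strip().upper())
        if label is not None and label not in seen:
            seen.append(label)
    return tuple(seen)


# ---------------------------------------------------------------------------
# deduplication


def _group_children(df: pd.DataFrame, keep: set[str]) -> dict[str, list[tuple]]:
    """primaryid -> list of row tuples, restricted to retained primaryids."""
    sub = df[df["primaryid"].isin(keep)]
    out: dict[str, list[tuple]] = {}
    cols = [c for c in sub.columns]
    pid_idx = cols.index("primaryid")
    for row in sub.itertuples(index=False, name=None):
        out.setdefault(row[pid_idx], []).append(row)
    return out


def deduplicate(tables: RawTables) -> list[CaseReport]:
    """Collapse case versions: keep the highest ``caseversion`` per ``caseid``
    (ties broken by highest ``primaryid``) together with that version's
    child rows, and harmonize fields into :class:`CaseReport` objects.

    Reports with no reaction rows cannot enter a drug-event analysis and are
    dropped with a warning.
    """
    demo = tables.demo.copy()
    if demo.empty:
        return []
    demo["_cv"] = pd.to_numeric(demo["caseversion"], errors="coerce").fillna(0)
    demo["_pid"] = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(0)
    demo = demo.sort_values(["caseid", "_cv", "_pid"], kind="mergesort")
    demo = demo.drop_duplicates("caseid", keep="last")
    keep = set(demo["primaryid"])

    drug_rows = _group_children(tables.drug, keep)
    reac_rows = _group_children(tables.reac, keep)
    indi_rows = _group_children(tables.indi, keep)
    outc_rows = _group_children(tables.outc, keep)

    drug_cols = list(tables.drug.columns)
    d_seq, d_role = drug_cols.index("drug_seq"), drug_cols.index("role_cod")
    d_name, d_ai, d_route = (drug_cols.index("drugname"), drug_cols.index("prod_ai"),
                             drug_cols.index("route"))
    reac_pt = list(tables.reac.columns).index("pt")
    indi_cols = list(tables.indi.columns)
    i_seq, i_pt = indi_cols.index("indi_drug_seq"), indi_cols.index("indi_pt")
    outc_cod = list(tables.outc.columns).index("outc_cod")

    reports: list[CaseReport] = []
    n_no_reac = 0
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        reactions = [r[reac_pt] for r in reac_rows.get(pid, []) if r[reac_pt].strip()]
        if not reactions:
            n_no_reac += 1
            continue
        indi_by_seq: dict[str, list[str]] = {}
        for r in indi_rows.get(pid, []):
            if r[i_pt].strip():
                indi_by_seq.setdefault(r[i_seq], []).append(r[i_pt])
        drugs: list[DrugEntry] = []
        for r in drug_rows.get(pid, []):
            drugs.append(DrugEntry(
                name_raw=r[d_name],
                active_ingredient=r[d_ai],
                role=ROLE_MAP.get(r[d_role].strip().upper(), "concomitant"),
                route=canonical_route(r[d_route]),
                indications=tuple(indi_by_seq.get(r[d_seq], ())),
            ))
        ay = age_in_years(row.age, row.age_cod)
        reports.append(CaseReport(
            case_id=row.caseid,
            primary_id=pid,
            received_date=row.event_dt,
            age_years=ay,
            age_band=age_band(ay),
            sex=normalize_sex(row.sex),
            weight_kg=weight_in_kg(row.wt, row.wt_cod),
            reporter=normalize_reporter(row.occp_cod),
            country_group=normalize_country(row.reporter_country),
            outcomes=normalize_outcomes(r[outc_cod] for r in outc_rows.get(pid, [])),
            drugs=drugs,
            reactions=reactions,
            indications=sorted({pt for pts in indi_by_seq.values() for pt in pts}),
        ))
    if n_no_reac:
        warnings.warn(f"dropped {n_no_reac} report(s) with no reaction rows", stacklevel=2)
    return reports
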