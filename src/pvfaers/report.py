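"""Assembly of the analysis artifacts and the end-to-end pipeline.

``run_pipeline`` takes a directory of FAERS-dialect quarter files (or a
synthetic config to generate one), screens the reports into per-drug
cohorts, computes the descriptive tables, runs the three-method
disproportionality analysis with the joint signal criterion, and writes
delimited tables, a forest plot and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .descriptive import (ae_total, demographics_table, concomitant_ranking,
                          endpoint_frequency_table, sex_contrast, significance_stars,
                          subgroup_compare, SubgroupTest)
from .disproportionality import (ContingencyTable, EbgmResult, IcResult, MgpsPrior,
                                 RorResult, bcpnn_ic, build_table, ebgm, evaluate_signal,
                                 fit_mgps_prior, ror)
from .io_faers import CaseReport, deduplicate, load_pt_soc, read_quarter
from .screening import CascadeConfig, CascadeResult, default_queries, run_cascade
from .synthetic import SyntheticConfig, generate
from .term_mapping import CompositeEndpoint, load_endpoints


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up decimal rounding for display tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ForestRow:
    drug: str
    endpoint: str
    point: float
    low: float
    high: float
    significant_vs_other: bool

    def __post_init__(self) -> None:
        if not self.low <= self.point <= self.high:
            raise ValueError("interval must contain the point estimate")


def compare_drugs(r1: RorResult, t1: ContingencyTable,
                  r2: RorResult, t2: ContingencyTable) -> tuple[bool, float]:
    """Between-drug comparison for one endpoint: Wald-interval overlap and
    the 2x2 test on (endpoint hits, non-hits) across the two cohorts."""
    overlap = not (r1.ci_low > r2.ci_high or r2.ci_low > r1.ci_high)
    test: SubgroupTest = subgroup_compare([[t1.a, t1.b], [t2.a, t2.b]])
    return overlap, test.p_value


def signal_table(cohorts: Mapping[str, Sequence[CaseReport]],
                 all_cases: Sequence[CaseReport],
                 endpoints: Sequence[CompositeEndpoint],
                 comparator: str = "all_other",
                 prior: MgpsPrior | None = None) -> pd.DataFrame:
    """Full-precision disproportionality table over drug x endpoint pairs.

    ``comparator`` selects the background reports for the 2x2 tables:
    ``all_other`` (default) uses every deduplicated report outside the target
    cohort; ``within_screened`` restricts the background to reports that
    survived screening for some other drug query.  One MGPS prior is fitted
    across all the run's tables unless an explicit ``prior`` is supplied.
    """
    if comparator not in ("all_other", "within_screened"):
        raise ValueError(f"unknown comparator {comparator!r}")
    cohort_ids = {label: {id(c) for c in cases} for label, cases in cohorts.items()}
    screened_ids = set().union(*cohort_ids.values()) if cohort_ids else set()

    tables: dict[tuple[str, str], ContingencyTable] = {}
    for label, cases in cohorts.items():
        if comparator == "all_other":
            background = [c for c in all_cases if id(c) not in cohort_ids[label]]
        else:
            background = [c for c in all_cases
                          if id(c) in screened_ids and id(c) not in cohort_ids[label]]
        for endpoint in endpoints:
            tables[(label, endpoint.name)] = build_table(list(cases), background, endpoint)

    if prior is None:
        prior = fit_mgps_prior(list(tables.values()))

    rows = []
    for (label, endpoint_name), t in tables.items():
        r = ror(t)
        ic = bcpnn_ic(t)
        eb = ebgm(t, prior)
        decision = evaluate_signal(r, ic, eb)
        rows.append({
            "drug": label, "endpoint": endpoint_name,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ROR": r.ror, "ROR_low": r.ci_low, "ROR_high": r.ci_high,
            "ROR_corrected": r.corrected,
            "IC": ic.ic, "IC025": ic.ic025, "E": ic.expected,
            "EBGM": eb.ebgm, "EB05": eb.eb05, "EB95": eb.eb95,
            "signal": decision.is_signal,
            **{k: v for k, v in decision.criteria_met.items()},
        })
    df = pd.DataFrame(rows)
    df.attrs["mgps_prior"] = prior
    df.attrs["n_tests"] = len(rows)
    return df


def display_table(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Two-decimal display variant (half-up) of a full-precision table."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: round_half_up(x, decimals))
    return out


def forest_data(signals: pd.DataFrame) -> list[ForestRow]:
    """Forest-plot rows with between-drug significance per endpoint."""
    rows: list[ForestRow] = []
    for endpoint, grp in signals.groupby("endpoint", sort=False):
        recs = grp.to_dict("records")
        for rec in recs:
            others = [o for o in recs if o["drug"] != rec["drug"]]
            significant = False
            for other in others:
                r1 = RorResult(rec["ROR"], rec["ROR_low"], rec["ROR_high"], rec["ROR_corrected"])
                r2 = RorResult(other["ROR"], other["ROR_low"], other["ROR_high"],
                               other["ROR_corrected"])
                t1 = ContingencyTable(rec["a"], rec["b"], rec["c"], rec["d"])
                t2 = ContingencyTable(other["a"], other["b"], other["c"], other["d"])
                overlap, p = compare_drugs(r1, t1, r2, t2)
                significant = significant or (not overlap) or p < 0.05
            rows.append(ForestRow(rec["drug"], str(endpoint), rec["ROR"],
                                  rec["ROR_low"], rec["ROR_high"], significant))
    return rows


def forest_plot(rows: Sequence[ForestRow], path: Path | str) -> None:
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
    ys = np.arange(len(rows))[::-1]
    for y, row in zip(ys, rows):
        color = "#c0392b" if row.drug == sorted({r.drug for r in rows})[0] else "#2e6da4"
        ax.errorbar([row.point], [y],
                    xerr=[[row.point - row.low], [row.high - row.point]],
                    fmt="s", color=color, capsize=3)
    ax.axvline(1.0, color="grey", lw=1, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.endpoint} ({r.drug})" + (" *" if r.significant_vs_other else "")
                        for r in rows])
    ax.set_xscale("log")
    ax.set_xlabel("reporting odds ratio (95% CI, log scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def quarterly_counts(cohorts: Mapping[str, Sequence[CaseReport]]) -> pd.DataFrame:
    """Report counts per calendar quarter and cohort (date-trend export)."""
    rows = []
    for label, cases in cohorts.items():
        for case in cases:
            d = case.received_date.strip()
            if len(d) >= 6 and d[:6].isdigit():
                quarter = f"{d[:4]}Q{(int(d[4:6]) - 1) // 3 + 1}"
            else:
                quarter = "unknown"
            rows.append((label, quarter))
    df = pd.DataFrame(rows, columns=["drug", "quarter"])
    return (df.value_counts().rename("n_reports").reset_index()
            .sort_values(["drug", "quarter"]).reset_index(drop=True))


def _config_hash(config: SyntheticConfig | None, input_dir: Path | None) -> str:
    text = repr(config) if config is not None else str(input_dir)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(outdir: Path | str,
                 config: SyntheticConfig | None = None,
                 input_dir: Path | str | None = None,
                 cascade: CascadeConfig | None = None,
                 comparator: str = "all_other",
                 endpoints: Sequence[CompositeEndpoint] | None = None) -> dict:
    """End-to-end run; returns the manifest (also written to ``outdir``).

    Exactly one of ``config`` (synthetic generation) or ``input_dir``
    (pre-existing FAERS-dialect quarter) must be given.
    """
    if (config is None) == (input_dir is None):
        raise ValueError("give exactly one of config= or input_dir=")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config is not None:
        input_dir = outdir / "faers"
        generate(config, input_dir)
    raw = read_quarter(Path(input_dir))
    cases = deduplicate(raw)

    endpoints = list(endpoints) if endpoints is not None else load_endpoints()
    if cascade is None:
        cascade = CascadeConfig(queries=default_queries(), pt_to_soc=load_pt_soc())
    result: CascadeResult = run_cascade(cases, cascade)

    trace_df = pd.DataFrame(result.full_stages, columns=["stage", "count"])
    trace_df.to_csv(outdir / "screening_trace.csv", index=False)

    cohort_cases = {label: cohort.cases for label, cohort in result.cohorts.items()}

    demo_rows = []
    for label, cc in cohort_cases.items():
        table = demographics_table(cc)
        for row in table.rows:
            demo_rows.append({"cohort": label, "variable": row.variable, "level": row.level,
                              "count": row.count, "percent": row.percent})
        demo_rows.append({"cohort": label, "variable": "weight_kg", "level": "median",
                          "count": len(cc), "percent": None,
                          "value": table.weight_median, "q1": table.weight_q1,
                          "q3": table.weight_q3})
    pd.DataFrame(demo_rows).to_csv(outdir / "table1_demographics.csv", index=False)

    conc_rows = []
    for query in cascade.queries:
        for name, count, pct in concomitant_ranking(cohort_cases.get(query.target_label, []), query):
            conc_rows.append({"cohort": query.target_label, "drug": name,
                              "count": count, "percent": pct})
    pd.DataFrame(conc_rows).to_csv(outdir / "table2_concomitant.csv", index=False)

    freq_rows = [{"endpoint": r.variable, "level": r.level, "count": r.count,
                  "percent": r.percent, "denominator": r.denominator}
                 for r in endpoint_frequency_table(cohort_cases, endpoints)]
    freq_df = pd.DataFrame(freq_rows)
    stars = []
    for label, cc in cohort_cases.items():
        for e in endpoints:
            test = sex_contrast(cc, e)
            stars.append({"cohort": label, "endpoint": e.name, "method": test.method,
                          "p_value": test.p_value, "stars": significance_stars(test.p_value)})
    freq_df.to_csv(outdir / "table3_endpoints.csv", index=False)
    pd.DataFrame(stars).to_csv(outdir / "table3_sex_contrasts.csv", index=False)

    signals = signal_table(cohort_cases, cases, endpoints, comparator=comparator)
    signals.to_csv(outdir / "table4_signals.csv", index=False)
    display_table(signals).to_csv(outdir / "table4_signals_display.csv", index=False)

    rows = forest_data(signals)
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(outdir / "forest_data.csv", index=False)
    forest_plot(rows, outdir / "forest_plot.png")

    quarterly_counts(cohort_cases).to_csv(outdir / "quarterly_counts.csv", index=False)

    prior: MgpsPrior = signals.attrs["mgps_prior"]
    manifest = {
        "seed": config.seed if config is not None else None,
        "config_hash": _config_hash(config, Path(input_dir)),
        "comparator": comparator,
        "n_reports_loaded": len(cases),
        "n_tests": int(signals.attrs["n_tests"]),
        "mgps_prior": {"alpha1": prior.alpha1, "beta1": prior.beta1,
                       "alpha2": prior.alpha2, "beta2": prior.beta2,
                       "p_mix": prior.p_mix, "converged": prior.converged},
        "versions": {"pvfaers": __version__,
                     "python": sys.version.split()[0],
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
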