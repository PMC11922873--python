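#!/usr/bin/env python
"""Descriptive cohort tables: demographics, concomitant anti-parkinsonian
drugs and composite motor-complication endpoint frequencies with per-sex
contrasts.

    python analysis/03_descriptive_tables.py
"""

import argparse
from pathlib import Path

import pandas as pd

from pvfaers.descriptive import (concomitant_ranking, demographics_table,
                                 endpoint_frequency_table, sex_contrast, significance_stars)
from pvfaers.io_faers import deduplicate, load_pt_soc, read_quarter
from pvfaers.screening import CascadeConfig, default_queries, run_cascade
from pvfaers.term_mapping import load_endpoints


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    queries = default_queries()
    cases = deduplicate(read_quarter(args.results_dir / "faers"))
    out = run_cascade(cases, CascadeConfig(queries=queries, pt_to_soc=load_pt_soc()))
    cohorts = {label: cohort.cases for label, cohort in out.cohorts.items()}
    endpoints = load_endpoints()

    demo_rows = []
    for label, cc in cohorts.items():
        table = demographics_table(cc)
        demo_rows += [{"cohort": label, "variable": r.variable, "level": r.level,
                       "count": r.count, "percent": r.percent} for r in table.rows]
        print(f"{label}: N={len(cc)}, weight median {table.weight_median:.2f} "
              f"(IQR {table.weight_q1:.2f}, {table.weight_q3:.2f})")
    pd.DataFrame(demo_rows).to_csv(args.results_dir / "table1_demographics.csv", index=False)

    conc_rows = []
    for query in queries:
        ranking = concomitant_ranking(cohorts[query.target_label], query)
        conc_rows += [{"cohort": query.target_label, "drug": n, "count": c, "percent": p}
                      for n, c, p in ranking]
        print(f"top concomitant anti-PD drugs, {query.target_label}:",
              ", ".join(f"{n} ({c}, {p}%)" for n, c, p in ranking))
    pd.DataFrame(conc_rows).to_csv(args.results_dir / "table2_concomitant.csv", index=False)

    freq = pd.DataFrame([{"endpoint": r.variable, "level": r.level, "count": r.count,
                          "percent": r.percent, "denominator": r.denominator}
                         for r in endpoint_frequency_table(cohorts, endpoints)])
    freq.to_csv(args.results_dir / "table3_endpoints.csv", index=False)
    print(freq[freq.level == "total"].to_string(index=False))

    stars = [{"cohort": label, "endpoint": e.name,
              "p_value": (t := sex_contrast(cc, e)).p_value,
              "stars": significance_stars(t.p_value)}
             for label, cc in cohorts.items() for e in endpoints]
    pd.DataFrame(stars).to_csv(args.results_dir / "table3_sex_contrasts.csv", index=False)


if __name__ == "__main__":
    main()
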