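#!/usr/bin/env python
"""Three-method disproportionality analysis with the joint signal criterion,
forest plot data and the per-quarter report counts.

For every drug x endpoint pair, computes the reporting odds ratio with its
Wald interval, the BCPNN information component with its lower credible
bound, and the MGPS empirical-Bayes geometric mean with posterior
percentiles (one gamma-mixture prior fitted across all pairs of the run),
then applies the joint criterion ROR >= 3 & CI low > 1, IC025 > 0, EB05 > 2.

    python analysis/04_signal_analysis.py [--comparator all_other|within_screened]
"""

import argparse
from pathlib import Path

import pandas as pd

from pvfaers.io_faers import deduplicate, load_pt_soc, read_quarter
from pvfaers.report import display_table, forest_data, forest_plot, quarterly_counts, signal_table
from pvfaers.screening import CascadeConfig, default_queries, run_cascade
from pvfaers.term_mapping import load_endpoints


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--comparator", default="all_other",
                    choices=("all_other", "within_screened"))
    args = ap.parse_args()

    cases = deduplicate(read_quarter(args.results_dir / "faers"))
    out = run_cascade(cases, CascadeConfig(queries=default_queries(), pt_to_soc=load_pt_soc()))
    cohorts = {label: cohort.cases for label, cohort in out.cohorts.items()}

    signals = signal_table(cohorts, cases, load_endpoints(), comparator=args.comparator)
    signals.to_csv(args.results_dir / "table4_signals.csv", index=False)
    display_table(signals).to_csv(args.results_dir / "table4_signals_display.csv", index=False)

    rows = forest_data(signals)
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(args.results_dir / "forest_data.csv",
                                                    index=False)
    forest_plot(rows, args.results_dir / "forest_plot.png")
    quarterly_counts(cohorts).to_csv(args.results_dir / "quarterly_counts.csv", index=False)

    cols = ["drug", "endpoint", "a", "ROR", "ROR_low", "ROR_high", "IC", "IC025",
            "EBGM", "EB05", "signal"]
    print(display_table(signals)[cols].to_string(index=False))
    prior = signals.attrs["mgps_prior"]
    print(f"MGPS prior: a1={prior.alpha1:.3g} b1={prior.beta1:.3g} a2={prior.alpha2:.3g} "
          f"b2={prior.beta2:.3g} P={prior.p_mix:.3g} (converged={prior.converged}); "
          f"{signals.attrs['n_tests']} pairs tested, no multiplicity adjustment")


if __name__ == "__main__":
    main()
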