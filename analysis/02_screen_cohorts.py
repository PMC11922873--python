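#!/usr/bin/env python
"""Screen the generated quarter into the benserazide and carbidopa cohorts.

Reads the FAERS-dialect files from results/faers, deduplicates case
versions, applies the four-stage cascade (suspect-drug text match, oral
route, PD indication with dementia/psychosis exclusions, SOC whitelist) and
writes the screening trace.

    python analysis/02_screen_cohorts.py
"""

import argparse
from pathlib import Path

import pandas as pd

from pvfaers.io_faers import deduplicate, load_pt_soc, read_quarter
from pvfaers.screening import CascadeConfig, default_queries, run_cascade


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cases = deduplicate(read_quarter(args.results_dir / "faers"))
    out = run_cascade(cases, CascadeConfig(queries=default_queries(), pt_to_soc=load_pt_soc()))

    trace = pd.DataFrame(out.full_stages, columns=["stage", "count"])
    trace.to_csv(args.results_dir / "screening_trace.csv", index=False)
    print(trace.to_string(index=False))
    if out.dual_match_case_ids:
        print(f"{len(out.dual_match_case_ids)} case(s) matched both drug queries "
              "(kept in both cohorts)")


if __name__ == "__main__":
    main()
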