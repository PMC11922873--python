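#!/usr/bin/env python
"""Generate the synthetic FAERS-dialect quarter used by the downstream steps.

Emulates a levodopa/DCI reporting slice: benserazide and carbidopa
combination products with planted motor-complication associations, common
anti-parkinsonian co-medications, background drugs and duplicate case
versions.  Writes the six $-delimited tables plus the ground-truth sidecar
and prints the planted funnel so later steps can be checked against it.

    python analysis/01_generate_data.py --seed 1 [--n-cases 20000]
"""

import argparse
from pathlib import Path

from pvfaers.synthetic import default_config, generate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cases", type=int, default=20_000)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    outdir = args.results_dir / "faers"
    result = generate(default_config(n_cases=args.n_cases, seed=args.seed), outdir)
    gt = result.ground_truth

    print(f"wrote {args.n_cases} unique cases (plus duplicate versions) to {outdir}/")
    print("ground-truth screening funnel:")
    for stage, count in gt.stage_counts.items():
        print(f"  {stage:>16}: {count}")
    print("injected drug-event associations (pattern, PT -> rate ratio):")
    for (pattern, pt), rr in gt.lambdas.items():
        print(f"  {pattern:>12} x {pt}: rr={rr:g}")


if __name__ == "__main__":
    main()
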