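#!/usr/bin/env python
"""Map subcomplex combination classes and their regulatory context.

Classifies every BRG1 site by DPF2/PBRM1/BRD9 co-occupancy, quantifies
core-regulatory-factor co-binding per class, and ranks chromatin-state
associations per binding category.  The canonical expectation — CRTFs
concentrated at canonical-BAF-only (enhancer-like) sites and depleted from
PBAF-containing (promoter-like) sites — is printed from the computed
tables.
"""

import argparse

import pandas as pd

from bafmap.pipeline import RunConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    out = run(
        RunConfig(
            outdir=args.outdir, seed=args.seed,
            stages=("classify", "cooccupy", "state-enrich"),
        )
    )
    counts = pd.read_csv(out / "classify" / "class_counts.tsv", sep="\t", index_col=0)
    frac = pd.read_csv(out / "cooccupy" / "cooccupancy_fractions.tsv", sep="\t", index_col=0)
    print("sites per subcomplex class:")
    print(counts.to_string())
    print("\nCRTF co-occupancy fraction per class:")
    print(frac.round(3).to_string())
    baf = frac.loc["BAF_only", "any_CRTF"]
    pbaf = frac.loc["PBAF_only", "any_CRTF"]
    print(
        f"\nBAF-only sites carry a CRTF {baf:.0%} of the time vs {pbaf:.0%} "
        "at PBAF-only sites — canonical BAF tracks the core circuitry."
    )


if __name__ == "__main__":
    main()
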