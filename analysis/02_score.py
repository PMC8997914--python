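#!/usr/bin/env python
"""Score the simulated dose plates into sensitivity indices and calls.

Reads scratch/synthetic/plates.csv (written by 01_simulate.py), normalizes
well signals to % inhibition, sums the six-fraction ladder into the SI, and
calls each culture sensitive (SI < 250) or resistant.  Writes the SI table,
per-drug resistance fractions, and histogram bins to results/synthetic/,
and reports agreement with the generator's planted phenotypes.
"""

from pathlib import Path

import pandas as pd

from csra.plates import read_plates, score_plates
from csra.reporting import resistance_fractions, si_histogram

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    plates_path = ROOT / "scratch" / "synthetic" / "plates.csv"
    if not plates_path.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    outdir = ROOT / "results" / "synthetic"

    scored = score_plates(read_plates(plates_path))
    scored.to_csv(outdir / "si_scores.tsv", sep="\t", index=False)

    fractions = resistance_fractions(scored)
    fractions.to_csv(outdir / "resistance_fractions.tsv", sep="\t", index=False)

    annotations = pd.read_csv(outdir / "annotations.tsv", sep="\t")
    hist = si_histogram(scored.merge(annotations, on="specimen_id"))
    hist.to_csv(outdir / "si_histogram.tsv", sep="\t", index=False)

    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    merged = scored.merge(truth, on="specimen_id")
    errors = sum(
        int((merged.loc[merged.drug == d, "call"]
             != merged.loc[merged.drug == d, f"phenotype_{d}"]).sum())
        for d in merged.drug.unique()
    )
    print(fractions.to_string(index=False))
    print(f"\ncall errors vs planted phenotypes: {errors}/{len(merged)}")
    print(f"SI tables -> {outdir}")


if __name__ == "__main__":
    main()
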