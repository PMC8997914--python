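#!/usr/bin/env python
"""Build the specimen x gene mutation matrix for the simulated cohort.

Restricts the simulated variant table to the six-gene apoptosis panel,
derives each specimen's Mut+/Mut- status, writes the binary matrix and the
oncoplot-style co-occurrence table (genes + per-drug calls), and checks the
matrix against the generator's planted truth.
"""

from pathlib import Path

import pandas as pd

from csra.reporting import oncoplot_matrix, write_oncoplot
from csra.synthetic import fixture_panel
from csra.variants import build_mutation_matrix, mutation_status, parse_variants

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    outdir = ROOT / "results" / "synthetic"
    variants = parse_variants(outdir / "variants.tsv", fmt="tsv")
    annotations = pd.read_csv(outdir / "annotations.tsv", sep="\t")
    calls = pd.read_csv(outdir / "si_scores.tsv", sep="\t")

    matrix = build_mutation_matrix(
        variants, fixture_panel(), annotations.specimen_id.tolist()
    )
    matrix.to_csv(outdir / "mutation_matrix.tsv", sep="\t")
    write_oncoplot(
        oncoplot_matrix(matrix, calls, annotations), outdir / "oncoplot.tsv"
    )

    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    status = mutation_status(matrix).reindex(truth.specimen_id)
    agree = (status.to_numpy() == truth.mut_status.to_numpy()).all()
    print(f"Mut+: {int(status.sum())}/{len(status)}; matrix matches planted truth: {agree}")
    print(f"matrix + oncoplot -> {outdir}")


if __name__ == "__main__":
    main()
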