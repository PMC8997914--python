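#!/usr/bin/env python
"""Simulate a synthetic sarcoma cohort at the study conditions.

Draws 25 UPS + 12 SS specimens with 27% apoptosis-panel mutation
prevalence and a planted mutation->doxorubicin-resistance odds ratio of
~8.4, then synthesizes raw dose plates (six-step TDC ladder, triplicate
wells, Gaussian reader noise) for all six drugs.  Bulky raw plate signals
go to scratch/synthetic/; the ground-truth and annotation tables go to
results/synthetic/.
"""

import argparse
from pathlib import Path

from csra.plates import plates_to_frame
from csra.synthetic import SyntheticCohortConfig, gen_cohort
from csra.variants import variants_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SyntheticCohortConfig(seed=args.seed)
    cohort = gen_cohort(cfg)

    scratch = ROOT / "scratch" / "synthetic"
    scratch.mkdir(parents=True, exist_ok=True)
    plates_to_frame(cohort.plates).to_csv(scratch / "plates.csv", index=False)

    outdir = ROOT / "results" / "synthetic"
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    variants_to_frame(cohort.variants).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    cohort.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    n_mut = int(cohort.truth.mut_status.sum())
    n = len(cohort.truth)
    dox_r = (cohort.truth.phenotype_Dox == "resistant")
    print(f"cohort: {n} specimens ({cfg.n_ups} UPS, {cfg.n_ss} SS), seed={cfg.seed}")
    print(f"mutated: {n_mut}/{n} ({100*n_mut/n:.0f}%; generative prevalence 27%)")
    print(f"Dox resistant: Mut+ {int((dox_r & cohort.truth.mut_status).sum())}/{n_mut}, "
          f"Mut- {int((dox_r & ~cohort.truth.mut_status).sum())}/{n - n_mut}")
    print(f"plates: {len(cohort.plates)} -> {scratch/'plates.csv'}")
    print(f"truth/variants/annotations -> {outdir}")


if __name__ == "__main__":
    main()
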