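"""Synthetic cohorts with known ground truth, and the published-count fixture.

Two generators live here:

* :func:`gen_cohort` draws a fully synthetic sarcoma cohort — histotypes,
  apoptosis-panel mutation status, a planted odds ratio linking mutation to
  doxorubicin resistance, and raw dose plates synthesized from a Hill
  dose-response curve with additive Gaussian well noise — so that every
  pipeline stage can be exercised against a known truth table.

* :func:`gen_table4_fixture` rebuilds the motivating study's 37-specimen
  cohort from its printed summary tables: the eleven panel variants with
  their specimen assignments, and per-drug sensitive/resistant/NA calls that
  reproduce the published per-histotype count cells.  Specimen identifiers
  for the 27 unmutated cultures are synthetic placeholders, and the
  within-group assignment of calls and missing assays is an arbitrary
  deterministic choice consistent with the printed margins.

The default :class:`SyntheticCohortConfig` encodes the study conditions:
25 UPS + 12 SS specimens, 27% panel-mutation prevalence, and the doxorubicin
effect implied by the published contingency table (baseline resistance
14/27 among unmutated specimens, odds ratio (9/1)/(14/13) ~ 8.36).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .plates import LADDER, DosePlate, plates_to_frame
from .variants import GenePanel, VariantRecord, build_mutation_matrix, variants_to_frame

DRUGS = ("Dox", "Ifo", "Dox+Ifo", "Doc", "Gem", "Doc+Gem")

#: The six apoptosis-pathway genes altered in the motivating cohort.
PANEL_GENES = ("TP53", "ATM", "PIK3CB", "PIK3R1", "NTRK1", "CSF2RB")


def fixture_panel() -> GenePanel:
    """Apoptosis-panel genes observed in the published cohort."""
    return GenePanel("KEGG_APOPTOSIS_hits", frozenset(PANEL_GENES))


# ---------------------------------------------------------------------------
# Fully synthetic cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response curve: inhibition(c) = imax * c^h / (ec50^h + c^h).

    ``c`` and ``ec50`` are in TDC-fraction units (1.0 = 100% TDC), ``imax``
    in % inhibition, ``h`` the (positive) slope.
    """

    imax: float
    ec50: float
    h: float

    def inhibition(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.imax * c**self.h / (self.ec50**self.h + c**self.h)


@dataclass
class SyntheticCohortConfig:
    """Generative parameters for a synthetic CSRA cohort."""

    n_ups: int = 25
    n_ss: int = 12
    mut_prevalence: float = 0.27
    odds_ratio: float = (9 / 1) / (14 / 13)  # planted Dox effect
    baseline_resistance_prob: float = 14 / 27
    hill_sensitive: HillParams = field(default_factory=lambda: HillParams(95.0, 0.10, 1.0))
    hill_resistant: HillParams = field(default_factory=lambda: HillParams(60.0, 0.35, 1.0))
    noise_sd: float = 500.0
    vehicle_mean: float = 20000.0
    blank_mean: float = 1000.0
    replicates: int = 3
    drugs: Sequence[str] = DRUGS
    effect_drug: str = "Dox"  # the odds ratio applies to this drug only
    panel_genes: Sequence[str] = PANEL_GENES
    seed: int = 0

    def __post_init__(self) -> None:
        self.drugs = tuple(self.drugs)
        self.panel_genes = tuple(self.panel_genes)

    def validate(self) -> None:
        if self.n_ups < 0 or self.n_ss < 0 or self.n_ups + self.n_ss == 0:
            raise ConfigError("cohort must contain at least one specimen")
        for name in ("mut_prevalence", "baseline_resistance_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if not self.odds_ratio > 0:
            raise ConfigError("odds_ratio must be positive")
        if self.baseline_resistance_prob == 1.0 and self.odds_ratio != 1.0:
            raise ConfigError("baseline resistance of 1 admits no odds-ratio effect")
        for hp in (self.hill_sensitive, self.hill_resistant):
            if not (hp.ec50 > 0 and hp.h > 0 and 0 <= hp.imax <= 100):
                raise ConfigError(f"invalid Hill parameters {hp}")
        if not self.vehicle_mean > self.blank_mean:
            raise ConfigError("vehicle_mean must exceed blank_mean")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    @property
    def resistance_prob_mut(self) -> float:
        """Resistance probability for Mut+ specimens (odds multiplied by OR)."""
        base = self.baseline_resistance_prob
        if base in (0.0, 1.0):
            return base
        odds = base / (1.0 - base) * self.odds_ratio
        return odds / (1.0 + odds)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("hill_sensitive", "hill_resistant"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = HillParams(**raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")


def true_si(hill: HillParams) -> float:
    """Noiseless sensitivity index implied by a Hill curve on the ladder."""
    fractions = np.asarray(LADDER) / 100.0
    return 600.0 - float(hill.inhibition(fractions).sum())


def sample_phenotypes(config: SyntheticCohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent truth table: histotype, mutation status, per-drug phenotype.

    Separated from plate synthesis so that simulation studies of the exact
    test (type-I error, power) can run without generating well signals.
    """
    config.validate()
    n = config.n_ups + config.n_ss
    specimens = [f"SYN{i:03d}" for i in range(1, n + 1)]
    histotype = ["UPS"] * config.n_ups + ["SS"] * config.n_ss
    mut = rng.random(n) < config.mut_prevalence
    genes = rng.choice(list(config.panel_genes), size=n)
    truth = pd.DataFrame(
        {
            "specimen_id": specimens,
            "histotype": histotype,
            "mut_status": mut,
            "mutated_gene": np.where(mut, genes, ""),
        }
    )
    p_mut = config.resistance_prob_mut
    p_base = config.baseline_resistance_prob
    for drug in config.drugs:
        p = np.where(mut, p_mut, p_base) if drug == config.effect_drug else np.full(n, p_base)
        resistant = rng.random(n) < p
        truth[f"phenotype_{drug}"] = np.where(resistant, "resistant", "sensitive")
    return truth


def _plate_for(
    config: SyntheticCohortConfig,
    specimen_id: str,
    drug: str,
    hill: HillParams,
    rng: np.random.Generator,
) -> DosePlate:
    window = config.vehicle_mean - config.blank_mean
    fractions = np.asarray(LADDER) / 100.0
    mean_signal = config.blank_mean + window * (1.0 - hill.inhibition(fractions) / 100.0)
    treated = {}
    for frac, mu in zip(LADDER, mean_signal):
        sig = mu + rng.normal(0.0, config.noise_sd, size=config.replicates)
        treated[frac] = np.clip(sig, 0.0, None).tolist()  # readers report non-negative signals
    vehicle = np.clip(
        config.vehicle_mean + rng.normal(0.0, config.noise_sd, size=3), 0.0, None
    ).tolist()
    blank = np.clip(
        config.blank_mean + rng.normal(0.0, config.noise_sd, size=3), 0.0, None
    ).tolist()
    return DosePlate(specimen_id, drug, treated, vehicle, blank)


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    truth: pd.DataFrame
    plates: list[DosePlate]
    variants: list[VariantRecord]
    annotations: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Write plates.csv, variants.tsv, annotations.tsv, truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "plates": outdir / "plates.csv",
            "variants": outdir / "variants.tsv",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.tsv",
        }
        plates_to_frame(self.plates).to_csv(paths["plates"], index=False)
        variants_to_frame(self.variants).to_csv(paths["variants"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def gen_cohort(config: SyntheticCohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort: truth, dose plates, variants, annotations.

    Identical (config, seed) pairs produce identical output, byte for byte
    once written.  ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = sample_phenotypes(config, rng)

    plates = []
    for _, row in truth.iterrows():
        for drug in config.drugs:
            hill = (
                config.hill_resistant
                if row[f"phenotype_{drug}"] == "resistant"
                else config.hill_sensitive
            )
            plates.append(_plate_for(config, row.specimen_id, drug, hill, rng))

    variants = [
        VariantRecord(
            specimen_id=row.specimen_id,
            gene=row.mutated_gene,
            genomic_change=f"g.synthetic:{1000 + i}A>G",
            protein_change=f"p.X{100 + i}Y",
            consequence=str(rng.choice(["missense", "nonsense"])),
        )
        for i, row in enumerate(truth.itertuples())
        if row.mut_status
    ]
    annotations = truth[["specimen_id", "histotype"]].copy()
    return SyntheticCohort(config, truth, plates, variants, annotations)


# ---------------------------------------------------------------------------
# Published-count fixture
# ---------------------------------------------------------------------------

#: The eleven published panel variants (specimen, gene, genomic change,
#: protein change, consequence, COSMIC id).  AFN111b carries two.
TABLE3_VARIANTS: tuple[VariantRecord, ...] = (
    VariantRecord("AF50b", "TP53", "g.chr17:7675234G>C", "p.Y126*", "nonsense", "COSM10862"),
    VariantRecord("AF53b", "TP53", "g.chr17:7674954G>A", "p.H193Y", "missense", "COSM10672"),
    VariantRecord("AF93b", "TP53", "g.chr17:7674191delC", "p.E258fs", "frameshift", "COSM7340859"),
    VariantRecord("AF98b", "TP53", "g.chr17:7670678A>C", "p.L344R", "missense", "COSM46303"),
    VariantRecord("AFN119b", "TP53", "g.chr17:7670685G>A", "p.R342*", "nonsense", "COSM11073"),
    VariantRecord("AFN120b", "TP53", "g.chr17:7675218T>A", "p.K132*", "nonsense", "COSM44641"),
    VariantRecord("AF85b", "CSF2RB", "g.chr22:36936630A>G", "p.S516G", "missense", ""),
    VariantRecord("AFN111b", "ATM", "g.chr11:108335029C>T", "p.R2691C", "missense", "COSM922745"),
    VariantRecord("AFN111b", "NTRK1", "g.chr1:156879231G>T", "p.V639L", "missense", ""),
    VariantRecord("AFN128b", "PIK3R1", "g.chr5:68294573A>G", "p.N125S", "missense", "COSM6960758"),
    VariantRecord("AFN80b", "PIK3CB", "g.chr3:138714521T>C", "p.T417A", "missense", "COSM419799"),
)

#: TP53 p.L344R retains partial tetramerization, hence partial pathway function.
DEFAULT_LOF_OVERRIDES: tuple[tuple[str, str, str, str], ...] = (
    ("AF98b", "TP53", "p.L344R", "partial"),
)

#: Published pooled-cohort and per-histotype contingency counts
#: (mut_sensitive, mut_resistant, nomut_sensitive, nomut_resistant).
#: These are input data for recomputing the published exact tests.
TABLE4_COUNTS: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("Dox", "UPS"): (1, 6, 7, 11),
    ("Dox", "SS"): (0, 3, 6, 3),
    ("Dox", "STS"): (1, 9, 13, 14),
    ("Ifo", "UPS"): (2, 5, 5, 8),
    ("Ifo", "SS"): (1, 2, 1, 3),
    ("Ifo", "STS"): (3, 7, 6, 11),
    ("Dox+Ifo", "UPS"): (4, 3, 7, 6),
    ("Dox+Ifo", "SS"): (1, 2, 3, 1),
    ("Dox+Ifo", "STS"): (4, 5, 12, 6),
    ("Doc", "UPS"): (1, 6, 7, 11),
    ("Doc", "SS"): (1, 2, 2, 7),
    ("Doc", "STS"): (2, 8, 9, 18),
    ("Gem", "UPS"): (4, 3, 7, 11),
    ("Gem", "SS"): (2, 1, 2, 7),
    ("Gem", "STS"): (6, 4, 9, 18),
    ("Doc+Gem", "UPS"): (5, 2, 10, 8),
    ("Doc+Gem", "SS"): (2, 1, 3, 6),
    ("Doc+Gem", "STS"): (7, 3, 13, 14),
}

# Per-group (sensitive, resistant, NA) counts from the per-histotype columns.
# The pooled Dox+Ifo column is inconsistent with its histotype columns in the
# source table; the fixture follows the histotype columns (see TABLE4_COUNTS
# for the pooled counts as printed).
_GROUP_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    #          UPS Mut+     UPS Mut-     SS Mut+     SS Mut-
    "Dox":     {"UPS+": (1, 6, 0), "UPS-": (7, 11, 0), "SS+": (0, 3, 0), "SS-": (6, 3, 0)},
    "Ifo":     {"UPS+": (2, 5, 0), "UPS-": (5, 8, 5),  "SS+": (1, 2, 0), "SS-": (1, 3, 5)},
    "Dox+Ifo": {"UPS+": (4, 3, 0), "UPS-": (7, 6, 5),  "SS+": (1, 2, 0), "SS-": (3, 1, 5)},
    "Doc":     {"UPS+": (1, 6, 0), "UPS-": (7, 11, 0), "SS+": (1, 2, 0), "SS-": (2, 7, 0)},
    "Gem":     {"UPS+": (4, 3, 0), "UPS-": (7, 11, 0), "SS+": (2, 1, 0), "SS-": (2, 7, 0)},
    "Doc+Gem": {"UPS+": (5, 2, 0), "UPS-": (10, 8, 0), "SS+": (2, 1, 0), "SS-": (3, 6, 0)},
}

#: Mutated specimens by histotype: six TP53-mutated UPS plus the CSF2RB
#: carrier are UPS; the ATM/NTRK1, PIK3R1 and PIK3CB carriers are SS.
UPS_MUT_SPECIMENS = ("AF50b", "AF53b", "AF93b", "AFN119b", "AFN120b", "AF85b", "AF98b")
SS_MUT_SPECIMENS = ("AFN111b", "AFN128b", "AFN80b")

#: Placeholder identifiers for the 27 unmutated cultures (not published).
UPS_NOMUT_SPECIMENS = tuple(f"SYN-U{i:02d}" for i in range(1, 19))
SS_NOMUT_SPECIMENS = tuple(f"SYN-S{i:02d}" for i in range(1, 10))


@dataclass
class Table4Fixture:
    """The published cohort rebuilt from its summary tables."""

    variants: tuple[VariantRecord, ...]
    panel: GenePanel
    annotations: pd.DataFrame
    calls: pd.DataFrame  # long: specimen_id, drug, call in {sensitive, resistant, NA}
    matrix: pd.DataFrame
    lof_overrides: tuple[tuple[str, str, str, str], ...]


def _assign_calls(group: Sequence[str], counts: tuple[int, int, int]) -> dict[str, str]:
    n_s, n_r, n_na = counts
    assert n_s + n_r + n_na == len(group)
    out = {}
    for i, spec_id in enumerate(group):
        out[spec_id] = "sensitive" if i < n_s else ("resistant" if i < n_s + n_r else "NA")
    return out


def gen_table4_fixture() -> Table4Fixture:
    """Rebuild the 37-specimen published cohort from printed counts.

    Calls within each histotype x mutation-status group are assigned in a
    fixed deterministic order; missing assays (NA) fall on unmutated
    specimens, matching the published per-drug totals.  For doxorubicin the
    single sensitive mutated specimen is AF98b, the partial loss-of-function
    TP53 carrier, as reported.
    """
    groups = {
        "UPS+": list(UPS_MUT_SPECIMENS),
        "UPS-": list(UPS_NOMUT_SPECIMENS),
        "SS+": list(SS_MUT_SPECIMENS),
        "SS-": list(SS_NOMUT_SPECIMENS),
    }
    rows = []
    for drug in DRUGS:
        for key, group in groups.items():
            if drug == "Dox" and key == "UPS+":
                calls = {s: ("sensitive" if s == "AF98b" else "resistant") for s in group}
            else:
                calls = _assign_calls(group, _GROUP_COUNTS[drug][key])
            rows.extend((s, drug, c) for s, c in calls.items())
    calls = pd.DataFrame(rows, columns=["specimen_id", "drug", "call"])

    specimens = (
        list(UPS_MUT_SPECIMENS)
        + list(UPS_NOMUT_SPECIMENS)
        + list(SS_MUT_SPECIMENS)
        + list(SS_NOMUT_SPECIMENS)
    )
    histotypes = ["UPS"] * 25 + ["SS"] * 12
    annotations = pd.DataFrame({"specimen_id": specimens, "histotype": histotypes})
    panel = fixture_panel()
    matrix = build_mutation_matrix(TABLE3_VARIANTS, panel, specimens)
    return Table4Fixture(
        TABLE3_VARIANTS, panel, annotations, calls, matrix, DEFAULT_LOF_OVERRIDES
    )
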