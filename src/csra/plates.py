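"""Plate normalization and sensitivity-index scoring for the CSRA.

The chemosensitivity/chemoresistance assay (CSRA) exposes primary tumor
cells to each drug at six concentrations — 6.25, 12.5, 25, 50, 100 and
200% of a pharmacokinetically chosen test drug concentration (TDC) — with
vehicle-control and medium-only blank wells on the same plate.  Viability
signals are normalized to per-fraction % inhibition, and the sensitivity
index is

    SI = 600 - sum of % inhibition over the six TDC fractions,

so SI ranges from 0 (complete kill at every dose) to 600 (no effect).
Cultures with SI below 250 are called sensitive; 250 and above, resistant
(the threshold itself is assigned to the resistant side, the conservative
choice for a resistance phenotype).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    FormatError,
    IncompleteLadderError,
    InvalidScoreError,
)

#: The six TDC fractions of the dose ladder, in percent of 100% TDC.
LADDER: tuple[float, ...] = (6.25, 12.5, 25.0, 50.0, 100.0, 200.0)

#: SI threshold separating sensitive (below) from resistant (at or above).
SENSITIVITY_THRESHOLD: float = 250.0

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass(frozen=True)
class DrugSpec:
    """A drug (or fixed combination) and its 100% test drug concentration.

    ``tdc_100`` is carried with its unit as configured and never converted;
    for combinations it is the sum of the component TDCs and ``components``
    lists the individual (name, tdc_100) pairs.
    """

    name: str
    tdc_100: float
    unit: str = "mg/mL"
    components: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.tdc_100 > 0:
            raise ValueError(f"tdc_100 must be positive, got {self.tdc_100}")
        if self.components and len(self.components) < 2:
            raise ValueError("a combination needs at least 2 components")

    @property
    def is_combination(self) -> bool:
        return len(self.components) >= 2


#: Default drug panel: first/second-line sarcoma agents and their combinations.
DEFAULT_DRUGS: dict[str, DrugSpec] = {
    d.name: d
    for d in (
        DrugSpec("Dox", 1.0),
        DrugSpec("Ifo", 3.0),
        DrugSpec("Dox+Ifo", 4.0, components=(("Dox", 1.0), ("Ifo", 3.0))),
        DrugSpec("Doc", 11.3),
        DrugSpec("Gem", 25.0),
        DrugSpec("Doc+Gem", 36.3, components=(("Doc", 11.3), ("Gem", 25.0))),
    )
}


@dataclass
class DosePlate:
    """Raw well signals for one specimen x drug across the dose ladder."""

    specimen_id: str
    drug: str
    treated_signals: Mapping[float, Sequence[float]]
    vehicle_signals: Sequence[float]
    blank_signals: Sequence[float]

    def validate(self) -> None:
        missing = [f for f in LADDER if f not in self.treated_signals]
        if missing:
            raise IncompleteLadderError(
                f"{self.specimen_id}/{self.drug}: missing TDC fractions {missing}"
            )
        extra = set(self.treated_signals) - set(LADDER)
        if extra:
            raise IncompleteLadderError(
                f"{self.specimen_id}/{self.drug}: unexpected fractions {sorted(extra)}"
            )
        for f in LADDER:
            if len(self.treated_signals[f]) < 1:
                raise IncompleteLadderError(
                    f"{self.specimen_id}/{self.drug}: no replicate at {f}% TDC"
                )
        if len(self.vehicle_signals) < 1 or len(self.blank_signals) < 1:
            raise DegenerateControlError(
                f"{self.specimen_id}/{self.drug}: missing control wells"
            )


@dataclass
class InhibitionProfile:
    """Per-fraction % inhibition, both raw and clamped to [0, 100]."""

    specimen_id: str
    drug: str
    raw: dict[float, float] = field(default_factory=dict)
    clamped: dict[float, float] = field(default_factory=dict)


@dataclass
class SensitivityResult:
    specimen_id: str
    drug: str
    si: float
    call: str  # "sensitive" | "resistant"


def compute_inhibition(plate: DosePlate) -> InhibitionProfile:
    """Normalize a plate's signals to per-fraction % inhibition.

    inhibition(c) = 100 * (1 - (mean(treated_c) - mean(blank))
                               / (mean(vehicle) - mean(blank)))

    Replicates are aggregated by arithmetic mean; a single mean blank is
    subtracted from all wells.  The raw value is kept unclamped for audit;
    the clamped value is restricted to [0, 100].
    """
    plate.validate()
    blank = float(np.mean(plate.blank_signals))
    vehicle = float(np.mean(plate.vehicle_signals))
    window = vehicle - blank
    if window <= 0:
        raise DegenerateControlError(
            f"{plate.specimen_id}/{plate.drug}: vehicle mean ({vehicle}) does not "
            f"exceed blank mean ({blank})"
        )
    profile = InhibitionProfile(plate.specimen_id, plate.drug)
    for frac in LADDER:
        treated = float(np.mean(plate.treated_signals[frac]))
        inh = 100.0 * (1.0 - (treated - blank) / window)
        profile.raw[frac] = inh
        profile.clamped[frac] = min(100.0, max(0.0, inh))
    return profile


def compute_si(profile: InhibitionProfile, use_clamped: bool = True) -> SensitivityResult:
    """Sum the six per-fraction inhibitions into the sensitivity index."""
    values = profile.clamped if use_clamped else profile.raw
    if sorted(values) != sorted(LADDER):
        raise IncompleteLadderError(
            f"{profile.specimen_id}/{profile.drug}: profile does not cover the "
            f"six-fraction ladder"
        )
    si = 600.0 - sum(values[f] for f in LADDER)
    return SensitivityResult(profile.specimen_id, profile.drug, si, classify(si))


def classify(si: float) -> str:
    """Sensitive below the SI threshold of 250; resistant at or above it."""
    if not math.isfinite(si):
        raise InvalidScoreError(f"non-finite sensitivity index: {si}")
    return SENSITIVE if si < SENSITIVITY_THRESHOLD else RESISTANT


# ---------------------------------------------------------------------------
# Plate CSV I/O (long form) and cohort-level scoring
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["specimen_id", "drug", "well_role", "tdc_fraction", "replicate", "signal"]


def read_plates(path) -> list[DosePlate]:
    """Read long-form plate CSV into one :class:`DosePlate` per specimen x drug.

    Expected columns: specimen_id, drug, well_role in {treated, vehicle,
    blank}, tdc_fraction (empty for vehicle/blank wells), replicate, signal.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate CSV is missing columns: {missing}")
    plates = []
    for (specimen, drug), grp in df.groupby(["specimen_id", "drug"], sort=True):
        treated: dict[float, list[float]] = {}
        for _, row in grp[grp.well_role == "treated"].iterrows():
            treated.setdefault(float(row.tdc_fraction), []).append(float(row.signal))
        plates.append(
            DosePlate(
                specimen_id=str(specimen),
                drug=str(drug),
                treated_signals=treated,
                vehicle_signals=grp.loc[grp.well_role == "vehicle", "signal"].tolist(),
                blank_signals=grp.loc[grp.well_role == "blank", "signal"].tolist(),
            )
        )
    return plates


def plates_to_frame(plates: Iterable[DosePlate]) -> pd.DataFrame:
    """Serialize plates back to the long-form table (inverse of read_plates)."""
    rows = []
    for p in plates:
        for frac in LADDER:
            for i, s in enumerate(p.treated_signals[frac], start=1):
                rows.append((p.specimen_id, p.drug, "treated", frac, i, s))
        for i, s in enumerate(p.vehicle_signals, start=1):
            rows.append((p.specimen_id, p.drug, "vehicle", "", i, s))
        for i, s in enumerate(p.blank_signals, start=1):
            rows.append((p.specimen_id, p.drug, "blank", "", i, s))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def score_plates(plates: Iterable[DosePlate], clamp: bool = True) -> pd.DataFrame:
    """Score a collection of plates into the per-specimen-x-drug SI table.

    Returns a DataFrame with one row per plate: the six inhibition columns
    (clamped values), ``si_raw`` (from unclamped inhibition), ``si_clamped``
    and the call.  The call is made from ``si_clamped`` unless ``clamp`` is
    False, in which case ``si_raw`` decides.
    """
    rows = []
    for plate in plates:
        prof = compute_inhibition(plate)
        si_raw = 600.0 - sum(prof.raw[f] for f in LADDER)
        si_clamped = 600.0 - sum(prof.clamped[f] for f in LADDER)
        call = classify(si_clamped if clamp else si_raw)
        rows.append(
            {
                "specimen_id": plate.specimen_id,
                "drug": plate.drug,
                **{f"inhibition_{f:g}": prof.clamped[f] for f in LADDER},
                "si_raw": si_raw,
                "si_clamped": si_clamped,
                "call": call,
            }
        )
    return pd.DataFrame(rows)
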