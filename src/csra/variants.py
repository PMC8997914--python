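"""Apoptosis-panel somatic variants and the specimen x gene mutation matrix.

Upstream exome processing (alignment, calling, annotation) is out of scope;
this module ingests already-annotated variants from a simplified MAF-like
TSV or an annotated VCF, restricts them to a user-supplied gene panel (the
apoptosis signaling pathway in the motivating study), and derives each
specimen's binary mutation status.  A variant qualifies when its consequence
is protein-altering: missense, nonsense, frameshift or splice.  Pathogenicity
databases are not consulted; an optional ``require_cosmic`` switch keeps only
records carrying a COSMIC identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyPanelError, FormatError, UnknownSpecimenError

CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "other")

#: Consequence classes that make a specimen Mut+ in a panel gene.
QUALIFYING_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice"})

LOF_CLASSES = ("total", "partial", "unknown")

#: Mapping from common annotation vocabularies (Sequence Ontology / SnpEff)
#: to the closed consequence set used here.
_SO_TO_CONSEQUENCE = {
    "missense_variant": "missense",
    "missense": "missense",
    "stop_gained": "nonsense",
    "nonsense": "nonsense",
    "nonsense_variant": "nonsense",
    "frameshift_variant": "frameshift",
    "frameshift": "frameshift",
}


def map_consequence(term: str) -> str:
    """Map an annotation term to {missense, nonsense, frameshift, splice, other}."""
    term = term.strip().lower()
    if term in _SO_TO_CONSEQUENCE:
        return _SO_TO_CONSEQUENCE[term]
    if term.startswith("splice"):
        return "splice"
    if term in CONSEQUENCES:
        return term
    return "other"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant in one specimen."""

    specimen_id: str
    gene: str
    genomic_change: str = ""
    protein_change: str = ""
    consequence: str = "other"
    cosmic_id: str = ""
    lof_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.lof_class not in LOF_CLASSES:
            raise ValueError(f"unknown lof_class {self.lof_class!r}")


@dataclass(frozen=True)
class GenePanel:
    """A named set of HGNC gene symbols (stored upper-cased)."""

    name: str
    genes: frozenset[str]

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.genes


def load_panel(path, name: str | None = None) -> GenePanel:
    """Load a panel file: one HGNC symbol per line, ``#`` comments allowed."""
    path = Path(path)
    symbols = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line.upper())
    if not symbols:
        raise EmptyPanelError(f"panel file {path} contains no gene symbols")
    return GenePanel(name or path.stem, frozenset(symbols))


VARIANT_COLUMNS = ["specimen_id", "gene", "genomic_change", "protein_change", "consequence"]


def parse_variants_tsv(path) -> list[VariantRecord]:
    """Parse the simplified MAF-like variant TSV.

    Required columns: specimen_id, gene, genomic_change, protein_change,
    consequence.  Optional: cosmic_id, lof_class.  The consequence column
    may use either the closed set or SO-style terms (stop_gained, ...).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant TSV is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantRecord(
                specimen_id=row["specimen_id"],
                gene=row["gene"].strip(),
                genomic_change=row["genomic_change"],
                protein_change=row["protein_change"],
                consequence=map_consequence(row["consequence"]),
                cosmic_id=row.get("cosmic_id", ""),
                lof_class=row.get("lof_class", "") or "unknown",
            )
        )
    return records


def parse_variants_vcf(path, specimen: str | None = None) -> list[VariantRecord]:
    """Parse an annotated VCF (SnpEff/VEP-style ANN or CSQ INFO field).

    The first annotation entry per record is used (gene symbol, consequence
    term, HGVS.p).  The specimen is the single sample in the VCF header, or
    ``specimen`` when the VCF carries no sample column.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    if specimen is None:
        if len(vcf.samples) != 1:
            raise FormatError(
                "VCF must contain exactly one sample, or pass specimen= explicitly"
            )
        specimen = vcf.samples[0]
    records = []
    for rec in vcf:
        ann = rec.INFO.get("ANN") or rec.INFO.get("CSQ")
        if ann is None:
            continue
        first = str(ann).split(",")[0].split("|")
        if len(first) < 4:
            raise FormatError(f"unparseable annotation field at {rec.CHROM}:{rec.POS}")
        term, gene = first[1], first[3]
        protein = first[10] if len(first) > 10 else ""
        records.append(
            VariantRecord(
                specimen_id=specimen,
                gene=gene.strip(),
                genomic_change=f"g.{rec.CHROM}:{rec.POS}{rec.REF}>{rec.ALT[0]}"
                if rec.ALT
                else f"g.{rec.CHROM}:{rec.POS}{rec.REF}",
                protein_change=protein,
                consequence=map_consequence(term.split("&")[0]),
            )
        )
    return records


def parse_variants(path, fmt: str = "tsv", specimen: str | None = None) -> list[VariantRecord]:
    if fmt == "tsv":
        return parse_variants_tsv(path)
    if fmt == "vcf":
        return parse_variants_vcf(path, specimen=specimen)
    raise FormatError(f"unknown variant format {fmt!r}")


def qualifying_variants(
    variants: Iterable[VariantRecord],
    panel: GenePanel,
    require_cosmic: bool = False,
) -> list[VariantRecord]:
    """Restrict variants to panel genes with protein-altering consequences."""
    out = []
    for v in variants:
        if v.gene.strip().upper() not in panel.genes:
            continue
        if v.consequence not in QUALIFYING_CONSEQUENCES:
            continue
        if require_cosmic and not v.cosmic_id:
            continue
        out.append(v)
    return out


def build_mutation_matrix(
    variants: Iterable[VariantRecord],
    panel: GenePanel,
    cohort_specimens: Sequence[str],
    require_cosmic: bool = False,
) -> pd.DataFrame:
    """Binary specimen x gene matrix over the whole cohort.

    Rows cover every cohort specimen (all-zero rows retained for Mut-
    specimens); columns are the panel genes hit by at least one qualifying
    variant, ordered by mutation count (descending) then symbol.  A cell is
    1 when the specimen carries >=1 qualifying variant in that gene.
    """
    cohort = list(dict.fromkeys(cohort_specimens))
    known = set(cohort)
    qualified = qualifying_variants(variants, panel, require_cosmic=require_cosmic)
    for v in qualified:
        if v.specimen_id not in known:
            raise UnknownSpecimenError(
                f"variant specimen {v.specimen_id!r} not in cohort annotation"
            )
    genes = sorted({v.gene.strip().upper() for v in qualified})
    matrix = pd.DataFrame(0, index=pd.Index(cohort, name="specimen_id"), columns=genes, dtype=int)
    for v in qualified:
        matrix.loc[v.specimen_id, v.gene.strip().upper()] = 1
    if genes:
        order = matrix.sum().sort_values(ascending=False, kind="stable").index
        matrix = matrix[order]
    return matrix


def mutation_status(matrix: pd.DataFrame) -> pd.Series:
    """Per-specimen Mut+ status: row-wise OR of the matrix."""
    if matrix.shape[1] == 0:
        return pd.Series(False, index=matrix.index, name="mut_status")
    return (matrix.sum(axis=1) > 0).rename("mut_status")


def apply_lof_overrides(
    variants: Sequence[VariantRecord],
    overrides: Iterable[tuple[str, str, str, str]],
) -> list[VariantRecord]:
    """Replace lof_class on variants matched by (specimen, gene, protein_change).

    Unmatched overrides emit a warning rather than an error: loss-of-function
    annotations typically come from literature review and may reference
    specimens absent from a particular cohort subset.
    """
    out = list(variants)
    for spec_id, gene, protein, lof in overrides:
        if lof not in LOF_CLASSES:
            raise ValueError(f"unknown lof_class {lof!r}")
        hit = False
        for i, v in enumerate(out):
            if (
                v.specimen_id == spec_id
                and v.gene.strip().upper() == gene.strip().upper()
                and v.protein_change == protein
            ):
                out[i] = replace(v, lof_class=lof)
                hit = True
        if not hit:
            warnings.warn(
                f"LOF override matched no variant: {spec_id}/{gene}/{protein}",
                stacklevel=2,
            )
    return out


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen_id": v.specimen_id,
                "gene": v.gene,
                "genomic_change": v.genomic_change,
                "protein_change": v.protein_change,
                "consequence": v.consequence,
                "cosmic_id": v.cosmic_id,
                "lof_class": v.lof_class,
            }
            for v in variants
        ],
        columns=VARIANT_COLUMNS + ["cosmic_id", "lof_class"],
    )
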