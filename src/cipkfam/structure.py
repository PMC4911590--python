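"""Gene models, exon/intron structure and the gene catalog.

CIPK families in plants split sharply by gene architecture: an intron-rich
clade (more than 8 introns per gene) and an intron-poor clade (fewer than 3
introns per gene).  This module parses gene models from GFF3, counts introns
(exons minus one on the selected transcript), classifies genes into those
clades, and reads/writes/validates catalog tables whose columns mirror the
published per-gene summary (coordinates, gene length, amino-acid length, pI,
MW, exon count, CDS length).

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "GeneRecord",
    "CladeLabel",
    "INTRON_POOR_BELOW",
    "INTRON_RICH_ABOVE",
    "parse_gff3",
    "count_introns",
    "classify_intron_clade",
    "gene_length",
    "aa_from_cds",
    "read_catalog",
    "write_catalog",
    "load_soybean_catalog",
    "validate_catalog",
    "write_validation_report",
]

CladeLabel = Literal["intron_poor", "intron_rich", "intermediate"]

# Clade thresholds on introns per gene: <3 poor, >8 rich.  Counts of 3..8
# fall in neither published class and are labelled "intermediate".
INTRON_POOR_BELOW = 3
INTRON_RICH_ABOVE = 8

CATALOG_COLUMNS = [
    "name", "gene_id", "chromosome", "start", "end", "gene_length_bp",
    "aa_length", "pi", "mw_kd", "exon_count", "cds_length_bp",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene with the exon structure of its selected transcript."""

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_length_bp: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon {start}..{end} reversed")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneRecord:
    """One catalog row."""

    name: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    gene_length_bp: int
    aa_length: int
    pi: float
    mw_kd: float
    exon_count: int
    cds_length_bp: int


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS features).

    When a gene carries several mRNAs the transcript with the longest total
    CDS is selected.  An exon extending outside its gene span is an error.
    Models are returned sorted by (chromosome, start, gene id).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
            )
            exons = sorted(
                (e.start, e.end) for e in db.children(mrna, featuretype="exon")
            )
            if best is None or cds_len > best[0]:
                best = (cds_len, mrna.id, exons)
        if best is None:
            continue
        cds_len, _, exons = best
        for start, end in exons:
            if start < gene.start or end > gene.end:
                raise ValueError(
                    f"{gene.id}: exon {start}..{end} outside gene span "
                    f"{gene.start}..{gene.end}"
                )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds_length_bp=cds_len,
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.span[0], m.gene_id))
    return models


def count_introns(model: GeneModel) -> int:
    """Number of introns of the selected transcript: exons − 1."""
    return len(model.exons) - 1


def classify_intron_clade(
    n_introns: int,
    poor_below: int = INTRON_POOR_BELOW,
    rich_above: int = INTRON_RICH_ABOVE,
) -> CladeLabel:
    """Classify a gene by intron count.

    ``< poor_below`` introns → ``intron_poor``; ``> rich_above`` →
    ``intron_rich``; the counts in between → ``intermediate``.  With the
    default thresholds (<3, >8) the three labels partition the non-negative
    integers as in published CIPK surveys.
    """
    if n_introns < 0:
        raise ValueError("intron count must be >= 0")
    if not 0 < poor_below <= rich_above:
        raise ValueError("need 0 < poor_below <= rich_above")
    if n_introns < poor_below:
        return "intron_poor"
    if n_introns > rich_above:
        return "intron_rich"
    return "intermediate"


def gene_length(start: int, end: int) -> int:
    """Genomic span in bp of 1-based inclusive coordinates: |end−start|+1.

    Reversed coordinates are tolerated (normalized) with a warning, since
    published tables occasionally print them swapped.
    """
    if start <= 0 or end <= 0:
        raise ValueError("coordinates must be positive")
    if start > end:
        warnings.warn(
            f"reversed coordinates {start}..{end} normalized", stacklevel=2
        )
    return abs(end - start) + 1


def aa_from_cds(cds_length_bp: int) -> int:
    """Protein length implied by a CDS: cds/3 − 1 (the stop codon encodes
    no residue)."""
    if cds_length_bp <= 0 or cds_length_bp % 3:
        raise ValueError(f"CDS length {cds_length_bp} not a positive multiple of 3")
    return cds_length_bp // 3 - 1


# ---------------------------------------------------------------------------
# Catalog I/O and validation
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> list[GeneRecord]:
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return [
        GeneRecord(
            name=str(r.name_), gene_id=str(r.gene_id), chromosome=str(r.chromosome),
            start=int(r.start), end=int(r.end),
            gene_length_bp=int(r.gene_length_bp), aa_length=int(r.aa_length),
            pi=float(r.pi), mw_kd=float(r.mw_kd),
            exon_count=int(r.exon_count), cds_length_bp=int(r.cds_length_bp),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_catalog(path: str | Path) -> list[GeneRecord]:
    """Read a catalog TSV (published column order)."""
    return _records_from_frame(pd.read_csv(path, sep="\t"))


def write_catalog(records: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=CATALOG_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def load_soybean_catalog() -> list[GeneRecord]:
    """The published 52-gene soybean CIPK catalog bundled with the package.

    Values are kept exactly as printed, including two rows whose printed
    gene length disagrees with their coordinate span (see
    :func:`validate_catalog`).
    """
    with resources.files("cipkfam.data").joinpath(
        "soybean_cipk_catalog.tsv"
    ).open() as fh:
        return _records_from_frame(pd.read_csv(fh, sep="\t"))


def normalize_record(record: GeneRecord) -> GeneRecord:
    """Return the record with start <= end (swapping if printed reversed)."""
    if record.start > record.end:
        return replace(record, start=record.end, end=record.start)
    return record


@dataclass(frozen=True)
class CatalogFlag:
    name: str
    field: str
    message: str


def validate_catalog(records: Iterable[GeneRecord]) -> list[CatalogFlag]:
    """Flag internally inconsistent catalog rows.

    Checks per row: reversed coordinates (start > end); printed gene length
    vs the coordinate span |end−start|+1; printed amino-acid length vs
    cds/3−1; CDS length divisible by 3.
    """
    flags: list[CatalogFlag] = []
    for r in records:
        if r.start > r.end:
            flags.append(
                CatalogFlag(r.name, "coordinates",
                            f"reversed coordinates {r.start}..{r.end}")
            )
        span = abs(r.end - r.start) + 1
        if span != r.gene_length_bp:
            flags.append(
                CatalogFlag(
                    r.name, "gene_length_bp",
                    f"printed length {r.gene_length_bp} != coordinate span {span}",
                )
            )
        if r.cds_length_bp % 3:
            flags.append(
                CatalogFlag(r.name, "cds_length_bp",
                            f"CDS length {r.cds_length_bp} not divisible by 3")
            )
        else:
            implied = r.cds_length_bp // 3 - 1
            if implied != r.aa_length:
                flags.append(
                    CatalogFlag(
                        r.name, "aa_length",
                        f"printed aa length {r.aa_length} != cds/3-1 = {implied}",
                    )
                )
    return flags


def write_validation_report(flags: Iterable[CatalogFlag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tfield\tmessage\n")
        for f in flags:
            fh.write(f"{f.name}\t{f.field}\t{f.message}\n")
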