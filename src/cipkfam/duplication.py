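"""Chromosomal distribution and gene-duplication analysis.

Two duplication modes drive gene-family expansion in paleopolyploid genomes
like soybean:

* **tandem duplication** — an array of two or more family genes on the same
  chromosome, with consecutive genes separated by fewer than ``max_gap`` bp
  (100 kb by default) and, when a full genome annotation is available, by at
  most ``max_intervening`` non-family genes;
* **segmental duplication** — family genes lying on paired duplicated
  chromosomal blocks.  Block coordinates come from an external synteny
  resource and are ingested as a table, not computed here.

The gap of a tandem pair is measured from the end of the upstream gene to
the start of the downstream gene.  Without an annotation the
intervening-gene condition is vacuously satisfied (distance-only mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .structure import GeneRecord, normalize_record

__all__ = [
    "DuplicationBlock",
    "TandemArray",
    "SegmentalResult",
    "chromosome_counts",
    "find_tandem",
    "assign_segmental",
    "read_blocks",
    "write_blocks",
    "write_tandem_table",
    "write_bed",
]

DEFAULT_MAX_GAP = 100_000
DEFAULT_MAX_INTERVENING = 5


@dataclass(frozen=True)
class DuplicationBlock:
    """One pair of duplicated chromosomal ranges (1-based inclusive)."""

    block_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError(f"block {self.block_id}: start > end")


@dataclass(frozen=True)
class TandemArray:
    """A maximal run of tandemly duplicated family genes."""

    chromosome: str
    members: tuple[str, ...]
    gaps_bp: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem array needs >= 2 members")
        if len(self.gaps_bp) != len(self.members) - 1:
            raise ValueError("need one gap per consecutive pair")


@dataclass(frozen=True)
class SegmentalResult:
    """Outcome of mapping family genes onto duplicated blocks."""

    pairs: tuple[tuple[str, str], ...]        # partner genes across one block
    genes_in_blocks: tuple[str, ...]
    singletons: tuple[str, ...]
    n_in_blocks: int
    n_blocks_hit: int
    n_outside: int


def chromosome_counts(genes: Iterable[GeneRecord]) -> dict[str, int]:
    """Genes per chromosome; chromosomes without genes are omitted.

    Returned sorted by chromosome label; counts sum to the number of genes.
    """
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    return dict(sorted(counts.items()))


def find_tandem(
    genes: Sequence[GeneRecord],
    annotation: Sequence[GeneRecord] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[TandemArray]:
    """Detect maximal tandem arrays among family genes.

    Consecutive family genes on one chromosome (by normalized start) are
    linked when the gap end-of-upstream → start-of-downstream is strictly
    below ``max_gap`` and, if ``annotation`` (the full gene complement of
    the genome) is given, at most ``max_intervening`` non-family genes lie
    strictly between them.  Linked runs merge into arrays, so arrays are
    maximal by construction.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    family = [normalize_record(g) for g in genes]
    family_names = {g.name for g in family}
    others: list[GeneRecord] = []
    if annotation is not None:
        others = [
            normalize_record(g)
            for g in annotation
            if g.name not in family_names
        ]

    def n_intervening(chrom: str, left_end: int, right_start: int) -> int:
        return sum(
            1
            for g in others
            if g.chromosome == chrom and g.start > left_end and g.end < right_start
        )

    arrays: list[TandemArray] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in family:
        by_chrom.setdefault(g.chromosome, []).append(g)

    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.name))
        run = [ordered[0]]
        gaps: list[int] = []
        for prev, nxt in zip(ordered, ordered[1:]):
            gap = nxt.start - prev.end
            linked = gap < max_gap and (
                annotation is None
                or n_intervening(chrom, prev.end, nxt.start) <= max_intervening
            )
            if linked:
                run.append(nxt)
                gaps.append(gap)
            else:
                if len(run) >= 2:
                    arrays.append(
                        TandemArray(chrom, tuple(g.name for g in run), tuple(gaps))
                    )
                run, gaps = [nxt], []
        if len(run) >= 2:
            arrays.append(TandemArray(chrom, tuple(g.name for g in run), tuple(gaps)))
    return arrays


def assign_segmental(
    genes: Sequence[GeneRecord], blocks: Sequence[DuplicationBlock]
) -> SegmentalResult:
    """Map family genes onto duplicated blocks.

    A gene is block-assigned when its (normalized) span lies entirely within
    either side of a block.  Genes assigned to the two sides of the same
    block are reported as duplicate partners; a gene inside a block with no
    family partner on the mate side still counts as "in a duplicated
    block".  Genes touching no block are singletons, so
    ``n_in_blocks + n_outside`` equals the number of genes.
    """
    normalized = [normalize_record(g) for g in genes]
    side_hits: dict[str, dict[str, list[str]]] = {}
    in_blocks: set[str] = set()
    for block in blocks:
        for side, chrom, start, end in (
            ("a", block.chrom_a, block.start_a, block.end_a),
            ("b", block.chrom_b, block.start_b, block.end_b),
        ):
            for g in normalized:
                if g.chromosome == chrom and g.start >= start and g.end <= end:
                    side_hits.setdefault(block.block_id, {}).setdefault(
                        side, []
                    ).append(g.name)
                    in_blocks.add(g.name)

    pairs: list[tuple[str, str]] = []
    for block_id in sorted(side_hits):
        sides = side_hits[block_id]
        for ga in sorted(sides.get("a", [])):
            for gb in sorted(sides.get("b", [])):
                if ga != gb:
                    pairs.append(tuple(sorted((ga, gb))))

    names = [g.name for g in normalized]
    singles = tuple(n for n in names if n not in in_blocks)
    return SegmentalResult(
        pairs=tuple(sorted(set(pairs))),
        genes_in_blocks=tuple(sorted(in_blocks)),
        singletons=singles,
        n_in_blocks=len(in_blocks),
        n_blocks_hit=len(side_hits),
        n_outside=len(singles),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

BLOCK_COLUMNS = [
    "block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
]


def read_blocks(path: str | Path) -> list[DuplicationBlock]:
    df = pd.read_csv(path, sep="\t")
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    return [
        DuplicationBlock(
            block_id=str(r.block_id),
            chrom_a=str(r.chrom_a), start_a=int(r.start_a), end_a=int(r.end_a),
            chrom_b=str(r.chrom_b), start_b=int(r.start_b), end_b=int(r.end_b),
        )
        for r in df.itertuples(index=False)
    ]


def write_blocks(blocks: Iterable[DuplicationBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BLOCK_COLUMNS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.chrom_a}\t{b.start_a}\t{b.end_a}"
                f"\t{b.chrom_b}\t{b.start_b}\t{b.end_b}\n"
            )


def write_tandem_table(arrays: Iterable[TandemArray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tmembers\tgaps_bp\n")
        for a in arrays:
            fh.write(
                f"{a.chromosome}\t{','.join(a.members)}"
                f"\t{','.join(map(str, a.gaps_bp))}\n"
            )


def write_bed(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Gene positions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in (normalize_record(x) for x in genes):
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.name}\n")
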