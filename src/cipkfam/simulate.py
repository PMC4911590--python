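"""Synthetic genome, domain and expression fixtures with known ground truth.

Every downstream stage of the pipeline can be exercised without any genome
or expression download: this module plants a gene family whose properties
are known exactly and emits the same file formats the real analysis
consumes (protein FASTA, GFF3 gene models, a catalog TSV, a
segmental-block TSV, stage-ratio matrices and a qPCR Ct table), together
with a YAML truth record describing what was planted.

What is emulated
----------------
* family membership by domain co-occurrence: member proteins carry a
  mutated copy of a fixed 20-residue kinase consensus followed by a fixed
  20-residue NAF consensus; decoys carry exactly one of the two;
* intron-poor / intron-rich gene architecture via planted intron counts;
* tandem arrays (consecutive members under 100 kb apart) and segmental
  pairs (paired duplicated blocks around two member genes);
* drought expression: planted per-stage log2 ratios and planted qPCR fold
  changes encoded in Ct values with independent Gaussian replicate noise.

All randomness flows from one :func:`numpy.random.default_rng` stream per
generator call, so a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .expression import CtObservation, StageMatrix, write_ct_table, write_stage_matrix
from .family import (
    AMINO_ACIDS,
    Pssm,
    ProteinRecord,
    compute_mw,
    compute_pi,
    write_fasta,
)
from .structure import GeneRecord, classify_intron_clade, write_catalog
from .duplication import DuplicationBlock, write_blocks

__all__ = [
    "KINASE_CONSENSUS",
    "NAF_CONSENSUS",
    "default_pssms",
    "FamilyConfig",
    "FamilyFixture",
    "generate_family",
    "ExpressionConfig",
    "ExpressionFixture",
    "generate_expression",
    "planted_stage_ratios",
]

# Fixed 20-mer consensus motifs standing in for the kinase catalytic core
# and the NAF (CBL-binding) module.  Their exact letters are arbitrary but
# frozen: the PSSM scanner and the generator must agree on them.
KINASE_CONSENSUS = "HRDLKPENLLLDARGNLKIS"
NAF_CONSENSUS = "NAFDIISLSEGFDLSGLFEK"

#: reference-gene cycle-threshold baseline (cycles); recorded in the truth
REFERENCE_CT_BASELINE = 20.0


def default_pssms(threshold_fraction: float = 0.5) -> list[Pssm]:
    """The two scanner PSSMs matching the planted consensus motifs."""
    return [
        Pssm.from_consensus("Pkinase", KINASE_CONSENSUS,
                            threshold_fraction=threshold_fraction),
        Pssm.from_consensus("NAF", NAF_CONSENSUS,
                            threshold_fraction=threshold_fraction),
    ]


def _default_intron_counts(n: int) -> list[int]:
    """Roughly 60/40 intron-poor vs intron-rich, mirroring the skew of real
    CIPK families."""
    n_poor = max(1, round(0.6 * n))
    poor = [(0, 0, 1, 2)[i % 4] for i in range(n_poor)]
    rich = [(10, 11, 13, 9)[i % 4] for i in range(n - n_poor)]
    return poor + rich


@dataclass
class FamilyConfig:
    """Layout of the synthetic gene family.

    ``tandem_clusters`` lists (chromosome index (1-based), cluster size,
    max intra-cluster gap in bp); intra-cluster gaps stay below 100 kb so
    the declared clusters are tandem by construction, while unrelated
    neighbours are spaced at least 150 kb apart.
    """

    n_members: int = 10
    n_decoys_kinase_only: int = 5
    n_decoys_naf_only: int = 5
    n_chromosomes: int = 3
    tandem_clusters: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(1, 2, 50_000)]
    )
    segmental_pairs: int = 2
    intron_counts: list[int] | None = None
    motif_mutation_rate: float = 0.05
    chromosome_length_bp: int = 30_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.intron_counts is None:
            self.intron_counts = _default_intron_counts(self.n_members)
        if len(self.intron_counts) != self.n_members:
            raise ValueError("intron_counts must have one entry per member")
        if any(c < 0 for c in self.intron_counts):
            raise ValueError("intron counts must be >= 0")
        if not 0.0 <= self.motif_mutation_rate < 1.0:
            raise ValueError("motif_mutation_rate must be in [0, 1)")
        total_cluster = 0
        for chrom, size, gap in self.tandem_clusters:
            if not 1 <= chrom <= self.n_chromosomes:
                raise ValueError(f"tandem cluster on unknown chromosome {chrom}")
            if size < 2:
                raise ValueError("tandem clusters need >= 2 genes")
            if not 0 < gap < 100_000:
                raise ValueError("intra-cluster gap must be in (0, 100000) bp")
            total_cluster += size
        if total_cluster > self.n_members:
            raise ValueError("tandem clusters use more genes than n_members")
        if self.segmental_pairs < 0:
            raise ValueError("segmental_pairs must be >= 0")


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return motif
    out = []
    for aa in motif:
        if rng.random() < rate:
            choices = [c for c in AMINO_ACIDS if c != aa]
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)
    )


@dataclass
class _Gene:
    name: str
    chromosome: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_length: int
    protein: ProteinRecord
    is_member: bool


@dataclass
class FamilyFixture:
    """In-memory synthetic family plus the ground-truth record."""

    proteins: list[ProteinRecord]
    catalog: list[GeneRecord]
    blocks: list[DuplicationBlock]
    gff3: str
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit proteins.fasta, genes.gff3, catalog.tsv, blocks.tsv and
        truth.yaml into ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "gff3": outdir / "genes.gff3",
            "catalog": outdir / "catalog.tsv",
            "blocks": outdir / "blocks.tsv",
            "truth": outdir / "truth.yaml",
        }
        write_fasta(self.proteins, paths["fasta"])
        paths["gff3"].write_text(self.gff3)
        write_catalog(self.catalog, paths["catalog"])
        write_blocks(self.blocks, paths["blocks"])
        paths["truth"].write_text(
            yaml.safe_dump(self.truth, sort_keys=True, default_flow_style=False)
        )
        return paths


def generate_family(config: FamilyConfig) -> FamilyFixture:
    """Generate the synthetic family (see module docstring for the layout).

    Raises :class:`ValueError` when the requested layout cannot fit on the
    configured chromosome length.
    """
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_members)))
    member_names = [
        f"SynCIPK{i + 1:0{width}d}" for i in range(config.n_members)
    ]
    decoy_k = [
        f"DecoyKin{i + 1:02d}" for i in range(config.n_decoys_kinase_only)
    ]
    decoy_n = [f"DecoyNaf{i + 1:02d}" for i in range(config.n_decoys_naf_only)]

    # --- protein sequences -------------------------------------------------
    proteins: dict[str, ProteinRecord] = {}
    for name in member_names:
        seq = (
            _random_seq(int(rng.integers(90, 140)), rng)
            + _mutate(KINASE_CONSENSUS, config.motif_mutation_rate, rng)
            + _random_seq(int(rng.integers(40, 80)), rng)
            + _mutate(NAF_CONSENSUS, config.motif_mutation_rate, rng)
            + _random_seq(int(rng.integers(20, 60)), rng)
        )
        proteins[name] = ProteinRecord(name, seq)
    for name in decoy_k:
        seq = (
            _random_seq(int(rng.integers(90, 140)), rng)
            + _mutate(KINASE_CONSENSUS, config.motif_mutation_rate, rng)
            + _random_seq(int(rng.integers(60, 140)), rng)
        )
        proteins[name] = ProteinRecord(name, seq)
    for name in decoy_n:
        seq = (
            _random_seq(int(rng.integers(150, 220)), rng)
            + _mutate(NAF_CONSENSUS, config.motif_mutation_rate, rng)
            + _random_seq(int(rng.integers(20, 60)), rng)
        )
        proteins[name] = ProteinRecord(name, seq)

    # --- chromosome layout -------------------------------------------------
    # Units are placed left to right; a unit is either one gene or one whole
    # tandem cluster.  Units are separated by >150 kb, cluster members by
    # the configured intra-cluster gap (< 100 kb).
    member_queue = list(member_names)
    cluster_units: list[tuple[int, list[str], int]] = []
    for chrom_idx, size, gap in config.tandem_clusters:
        taken, member_queue = member_queue[:size], member_queue[size:]
        cluster_units.append((chrom_idx, taken, gap))
    singles = list(member_queue)

    intron_of = dict(zip(member_names, config.intron_counts))
    for name in decoy_k + decoy_n:
        intron_of[name] = int(rng.integers(0, 14))

    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    layout: dict[str, list[tuple[list[str], int | None]]] = {
        c: [] for c in chrom_names
    }
    for chrom_idx, names, gap in cluster_units:
        layout[chrom_names[chrom_idx - 1]].append((names, gap))
    for i, name in enumerate(singles + decoy_k + decoy_n):
        layout[chrom_names[i % config.n_chromosomes]].append(([name], None))

    genes: dict[str, _Gene] = {}
    for chrom in chrom_names:
        cursor = 50_000
        for unit_names, intra_gap in layout[chrom]:
            for pos, name in enumerate(unit_names):
                protein = proteins[name]
                cds_len = 3 * (len(protein) + 1)
                n_exons = intron_of[name] + 1
                exon_lens = _split_lengths(cds_len, n_exons)
                intron_lens = (
                    rng.integers(200, 2000, size=n_exons - 1).tolist()
                    if n_exons > 1
                    else []
                )
                start = cursor
                exons: list[tuple[int, int]] = []
                at = start
                for k, el in enumerate(exon_lens):
                    exons.append((at, at + el - 1))
                    at += el
                    if k < len(intron_lens):
                        at += int(intron_lens[k])
                end = exons[-1][1]
                genes[name] = _Gene(
                    name, chrom, start, end, exons, cds_len, protein,
                    name in member_names,
                )
                if pos < len(unit_names) - 1:
                    gap = int(rng.integers(500, max(501, intra_gap)))
                    cursor = end + gap
                else:
                    cursor = end + 150_000 + int(rng.integers(0, 100_000))
        if cursor > config.chromosome_length_bp:
            raise ValueError(
                f"layout on {chrom} needs {cursor} bp but chromosomes are "
                f"{config.chromosome_length_bp} bp: impossible layout"
            )

    # --- segmental blocks --------------------------------------------------
    if 2 * config.segmental_pairs > len(singles):
        raise ValueError(
            "not enough non-tandem members to plant "
            f"{config.segmental_pairs} segmental pairs"
        )
    seg_pairs: list[tuple[str, str]] = []
    blocks: list[DuplicationBlock] = []
    half = config.segmental_pairs
    for i in range(half):
        a, b = singles[i], singles[i + half]
        seg_pairs.append((a, b))
        ga, gb = genes[a], genes[b]
        blocks.append(
            DuplicationBlock(
                block_id=f"block{i + 1:02d}",
                chrom_a=ga.chromosome,
                start_a=max(1, ga.start - 5_000), end_a=ga.end + 5_000,
                chrom_b=gb.chromosome,
                start_b=max(1, gb.start - 5_000), end_b=gb.end + 5_000,
            )
        )

    # --- catalog (members only, like a published family table) -------------
    catalog: list[GeneRecord] = []
    for name in member_names:
        g = genes[name]
        catalog.append(
            GeneRecord(
                name=name, gene_id=f"{name}.g", chromosome=g.chromosome,
                start=g.start, end=g.end,
                gene_length_bp=g.end - g.start + 1,
                aa_length=g.cds_length // 3 - 1,
                pi=round(compute_pi(g.protein.sequence), 2),
                mw_kd=round(compute_mw(g.protein.sequence), 2),
                exon_count=len(g.exons),
                cds_length_bp=g.cds_length,
            )
        )

    gff3 = _render_gff3(
        [genes[n] for n in member_names + decoy_k + decoy_n],
        config.chromosome_length_bp,
    )

    truth = {
        "seed": config.seed,
        "members": member_names,
        "decoys_kinase_only": decoy_k,
        "decoys_naf_only": decoy_n,
        "intron_counts": {n: int(intron_of[n]) for n in member_names},
        "clade_labels": {
            n: classify_intron_clade(intron_of[n]) for n in member_names
        },
        "tandem_arrays": [names for _, names, _ in cluster_units],
        "segmental_pairs": [list(p) for p in seg_pairs],
        "kinase_consensus": KINASE_CONSENSUS,
        "naf_consensus": NAF_CONSENSUS,
        "motif_mutation_rate": config.motif_mutation_rate,
    }
    return FamilyFixture(
        proteins=[proteins[n] for n in member_names + decoy_k + decoy_n],
        catalog=catalog,
        blocks=blocks,
        gff3=gff3,
        truth=truth,
    )


def _split_lengths(total: int, parts: int) -> list[int]:
    """Split ``total`` bp into ``parts`` positive chunks (deterministic)."""
    if parts > total:
        raise ValueError(f"cannot split {total} bp into {parts} exons")
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _render_gff3(gene_list: Sequence[_Gene], chrom_len: int) -> str:
    """One gene / one mRNA per locus; exons double as CDS (no UTRs)."""
    lines = ["##gff-version 3"]
    for chrom in sorted({g.chromosome for g in gene_list}):
        lines.append(f"##sequence-region {chrom} 1 {chrom_len}")
    for g in sorted(gene_list, key=lambda x: (x.chromosome, x.start)):
        gid, mid = g.name, f"{g.name}.m1"
        lines.append(
            f"{g.chromosome}\tcipkfam_sim\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
            f"ID={gid};Name={g.name}"
        )
        lines.append(
            f"{g.chromosome}\tcipkfam_sim\tmRNA\t{g.start}\t{g.end}\t.\t+\t.\t"
            f"ID={mid};Parent={gid}"
        )
        phase = 0
        for k, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                f"{g.chromosome}\tcipkfam_sim\texon\t{s}\t{e}\t.\t+\t.\t"
                f"ID={mid}.exon{k};Parent={mid}"
            )
            lines.append(
                f"{g.chromosome}\tcipkfam_sim\tCDS\t{s}\t{e}\t.\t+\t{phase}\t"
                f"ID={mid}.cds;Parent={mid}"
            )
            phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Expression fixtures
# ---------------------------------------------------------------------------

@dataclass
class ExpressionConfig:
    """Planted drought-expression design.

    ``planted_log2fc`` maps gene → {(tissue, timepoint) → log2 fold
    change}; combinations not listed (and everything at day 0) are planted
    at fold 1.  The reference gene must not appear with a non-zero effect.

    When ``mean_unbiased`` is on (default) and noise is non-zero, treated
    Ct means are offset by ``0.5·Var(ΔΔCt)·ln 2`` so that the *expected*
    value of the downstream 2^−ΔΔCt estimator (arithmetic mean of replicate
    folds against the mean control ΔCt) equals the planted fold exactly,
    rather than carrying the lognormal bias of raw Gaussian Ct noise.
    """

    planted_log2fc: Mapping[str, Mapping[tuple[str, int], float]] = field(
        default_factory=dict
    )
    ct_noise_sd: float = 0.3
    reference_gene: str = "RefS20e"
    n_bio_reps: int = 3
    tissues: tuple[str, ...] = ("leaf", "stem", "root")
    timepoints: tuple[int, ...] = (0, 4, 8, 12)
    stage_ratios: Mapping[str, Mapping[str, float]] | None = None
    mean_unbiased: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_bio_reps < 2:
            raise ValueError("n_bio_reps must be >= 2")
        for key, effects in self.planted_log2fc.items():
            for (tissue, tp), fc in effects.items():
                if not math.isfinite(fc):
                    raise ValueError(f"non-finite planted effect for {key}")
                if tissue not in self.tissues or tp not in self.timepoints:
                    raise ValueError(
                        f"planted effect for unknown cell ({tissue}, {tp})"
                    )
                if tp == 0 and fc != 0.0:
                    raise ValueError(
                        "day 0 is the fold-1 baseline; planted day-0 effects "
                        "are not allowed"
                    )
        ref_effects = self.planted_log2fc.get(self.reference_gene, {})
        if any(fc != 0.0 for fc in ref_effects.values()):
            raise ValueError(
                "reference gene must have zero planted effect"
            )


@dataclass
class ExpressionFixture:
    observations: list[CtObservation]
    stages: tuple[StageMatrix, StageMatrix]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ct": outdir / "ct_table.tsv",
            "stage1": outdir / f"stage_{self.stages[0].stage}.tsv",
            "stage2": outdir / f"stage_{self.stages[1].stage}.tsv",
            "truth": outdir / "expression_truth.yaml",
        }
        write_ct_table(self.observations, paths["ct"])
        write_stage_matrix(self.stages[0], paths["stage1"])
        write_stage_matrix(self.stages[1], paths["stage2"])
        paths["truth"].write_text(
            yaml.safe_dump(self.truth, sort_keys=True, default_flow_style=False)
        )
        return paths


def generate_expression(
    config: ExpressionConfig, genes: Sequence[str]
) -> ExpressionFixture:
    """Generate a qPCR Ct table and two stage-ratio matrices for ``genes``.

    Ct structure: the reference gene sits at a fixed baseline of
    ``REFERENCE_CT_BASELINE`` cycles; each target gene gets a
    deterministic baseline in 24–30 cycles; drought Ct values are lowered
    by the planted log2 fold change (plus the unbiasedness offset, see
    :class:`ExpressionConfig`); iid Gaussian noise of sd ``ct_noise_sd``
    is added to every single Ct measurement.
    """
    if config.reference_gene in genes:
        raise ValueError("reference gene is generated implicitly; do not list it")
    rng = np.random.default_rng(config.seed)
    baselines = {
        g: 24.0 + 6.0 * float(rng.random()) for g in genes
    }
    var_ddct = 2.0 * config.ct_noise_sd**2 * (1.0 + 1.0 / config.n_bio_reps)
    offset = 0.5 * var_ddct * math.log(2.0) if config.mean_unbiased else 0.0

    def noise() -> float:
        return float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd else 0.0

    observations: list[CtObservation] = []
    for tissue in config.tissues:
        for tp in config.timepoints:
            for condition in ("control", "drought"):
                for rep in range(1, config.n_bio_reps + 1):
                    observations.append(
                        CtObservation(
                            config.reference_gene, tissue, tp, condition, rep,
                            REFERENCE_CT_BASELINE + noise(),
                        )
                    )
                    for g in genes:
                        fc = 0.0
                        if condition == "drought" and tp != 0:
                            fc = config.planted_log2fc.get(g, {}).get(
                                (tissue, tp), 0.0
                            )
                        shift = (-fc + offset) if (
                            condition == "drought" and tp != 0
                        ) else 0.0
                        observations.append(
                            CtObservation(
                                g, tissue, tp, condition, rep,
                                baselines[g] + shift + noise(),
                            )
                        )

    if config.stage_ratios is not None:
        names = list(config.stage_ratios)   # preserve declared stage order
        stages = tuple(
            StageMatrix(name, dict(config.stage_ratios[name])) for name in names
        )
    else:
        last = max(config.timepoints)
        leaf = config.tissues[0]
        derived = {
            g: config.planted_log2fc.get(g, {}).get((leaf, last), 0.0)
            for g in genes
        }
        stages = (
            StageMatrix("vegetative", derived),
            StageMatrix("reproductive", dict(derived)),
        )

    truth = {
        "seed": config.seed,
        "reference_gene": config.reference_gene,
        "reference_ct_baseline": REFERENCE_CT_BASELINE,
        "target_baselines": {g: round(b, 6) for g, b in baselines.items()},
        "ct_noise_sd": config.ct_noise_sd,
        "n_bio_reps": config.n_bio_reps,
        "unbiasedness_offset_cycles": round(offset, 6),
        "planted_folds": {
            g: {
                f"{tissue}:{tp}": float(2.0**fc)
                for (tissue, tp), fc in effects.items()
            }
            for g, effects in config.planted_log2fc.items()
        },
    }
    return ExpressionFixture(observations, stages, truth)


def planted_stage_ratios(
    genes: Sequence[str],
    n_both_up: int = 18,
    n_both_down: int = 13,
    n_up_down: int = 2,
    n_down_up: int = 15,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Two-stage log2-ratio pattern with a planted cross-stage structure.

    The four group sizes must sum to the number of genes; magnitudes are
    drawn uniformly from 0.3–3.0 log2 units with the sign of the group.
    Defaults mirror the drought-microarray structure of the soybean family:
    48 probed genes of which 20 up / 28 down at the vegetative stage,
    33 up / 15 down at the reproductive stage, overlapping as 18 both-up,
    13 both-down and 17 opposite.
    """
    if n_both_up + n_both_down + n_up_down + n_down_up != len(genes):
        raise ValueError("group sizes must sum to the number of genes")
    rng = np.random.default_rng(seed)
    signs = (
        [(1, 1)] * n_both_up
        + [(-1, -1)] * n_both_down
        + [(1, -1)] * n_up_down
        + [(-1, 1)] * n_down_up
    )
    stage1: dict[str, float] = {}
    stage2: dict[str, float] = {}
    for gene, (s1, s2) in zip(genes, signs):
        stage1[gene] = s1 * float(0.3 + 2.7 * rng.random())
        stage2[gene] = s2 * float(0.3 + 2.7 * rng.random())
    return {"vegetative": stage1, "reproductive": stage2}
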