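"""End-to-end orchestration of the gene-family characterization pipeline.

A :class:`PipelineConfig` names the inputs (any subset of: protein FASTA,
domain table or built-in PSSM scanner, GFF3 gene models, a catalog table,
segmental blocks, an aligned FASTA for the phylogeny, stage-ratio matrices
and a qPCR Ct table) plus the thresholds of every stage.  Stages whose
inputs are absent are skipped.  :func:`run_pipeline` runs the enabled
stages, writes their reports into the output directory, echoes every
threshold actually used into ``run.log`` and returns a machine-readable
summary (also written as ``summary.json``).

Any stage failure aborts the run with the stage name and cause, and the
partially written outputs of this run are removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import duplication as dup
from . import expression as expr
from . import family as fam
from . import phylogeny as phylo
from . import structure as struct

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "cipkfam_out"
    # inputs (None disables the stage needing them)
    fasta: str | None = None
    domain_table: str | None = None
    use_pssm_scanner: bool = False
    gff3: str | None = None
    catalog: str | None = None
    use_builtin_catalog: bool = False
    blocks: str | None = None
    alignment: str | None = None
    stage1_matrix: str | None = None
    stage2_matrix: str | None = None
    ct_table: str | None = None
    # thresholds
    require_domains: tuple[str, ...] = ("Pkinase", "NAF")
    max_evalue: float = 1e-5
    intron_poor_below: int = struct.INTRON_POOR_BELOW
    intron_rich_above: int = struct.INTRON_RICH_ABOVE
    tandem_max_gap: int = dup.DEFAULT_MAX_GAP
    tandem_max_intervening: int = dup.DEFAULT_MAX_INTERVENING
    regulation_threshold: float = 0.0
    reference_gene: str = "RefS20e"
    control_condition: str = "control"
    bootstrap_reps: int = 1000
    distance_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intron_poor_below", "intron_rich_above",
                     "tandem_max_gap", "tandem_max_intervening",
                     "bootstrap_reps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "require_domains" in raw:
            raw["require_domains"] = tuple(raw["require_domains"])
        return cls(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = ["# cipkfam run log", "## config"]
    for key, value in asdict(config).items():
        log_lines.append(f"{key} = {value!r}")
    summary: dict[str, Any] = {"stages_run": []}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    current_stage = "setup"
    try:
        # -- identification --------------------------------------------------
        if config.fasta:
            current_stage = "identify"
            proteins = fam.read_fasta(config.fasta)
            if config.domain_table:
                hits = fam.parse_domain_table(
                    config.domain_table, max_evalue=config.max_evalue
                )
            elif config.use_pssm_scanner:
                from .simulate import default_pssms

                pssms = default_pssms()
                hits = [
                    h for p in proteins for h in fam.scan_motifs(p, pssms)
                ]
            else:
                raise ValueError(
                    "identification needs domain_table or use_pssm_scanner"
                )
            members = fam.select_family(
                proteins, hits, require=config.require_domains
            )
            member_set = set(members)
            member_proteins = [p for p in proteins if p.id in member_set]
            stats = [fam.protein_stats(p) for p in member_proteins]
            emit("members.fasta", lambda p: fam.write_fasta(member_proteins, p))
            emit("member_stats.tsv", lambda p: fam.write_stats_table(stats, p))
            summary["stages_run"].append("identify")
            summary["n_proteins_screened"] = len(proteins)
            summary["n_members"] = len(members)
            summary["members"] = members

        # -- catalog / gene structure ---------------------------------------
        records: list[struct.GeneRecord] | None = None
        if config.use_builtin_catalog:
            records = struct.load_soybean_catalog()
        elif config.catalog:
            records = struct.read_catalog(config.catalog)

        clade_rows: list[tuple[str, int, str]] = []
        if config.gff3:
            current_stage = "structure"
            models = struct.parse_gff3(config.gff3)
            for model in models:
                n = struct.count_introns(model)
                clade_rows.append(
                    (model.gene_id, n,
                     struct.classify_intron_clade(
                         n, config.intron_poor_below, config.intron_rich_above))
                )
        elif records is not None:
            current_stage = "structure"
            for r in records:
                n = r.exon_count - 1
                clade_rows.append(
                    (r.name, n,
                     struct.classify_intron_clade(
                         n, config.intron_poor_below, config.intron_rich_above))
                )
        if clade_rows:
            def _write_clades(path: Path) -> None:
                with open(path, "w") as fh:
                    fh.write("gene\tn_introns\tclade\n")
                    for gene, n, clade in clade_rows:
                        fh.write(f"{gene}\t{n}\t{clade}\n")

            emit("clade_table.tsv", _write_clades)
            summary["stages_run"].append("structure")
            summary["n_intron_poor"] = sum(
                1 for _, _, c in clade_rows if c == "intron_poor"
            )
            summary["n_intron_rich"] = sum(
                1 for _, _, c in clade_rows if c == "intron_rich"
            )
            summary["n_intermediate"] = sum(
                1 for _, _, c in clade_rows if c == "intermediate"
            )

        if records is not None:
            current_stage = "validate"
            flags = struct.validate_catalog(records)
            emit("validation_report.tsv",
                 lambda p: struct.write_validation_report(flags, p))
            summary["n_genes"] = len(records)
            summary["n_catalog_flags"] = len(flags)
            pis = [r.pi for r in records]
            summary["pct_pi_above_7"] = round(
                100.0 * sum(1 for x in pis if x > 7.0) / len(pis), 2
            )
            summary["aa_range"] = [
                min(r.aa_length for r in records),
                max(r.aa_length for r in records),
            ]
            summary["mw_range_kd"] = [
                min(r.mw_kd for r in records),
                max(r.mw_kd for r in records),
            ]

        # -- phylogeny -------------------------------------------------------
        if config.alignment:
            current_stage = "tree"
            aln = phylo.read_alignment_fasta(config.alignment)
            dm = phylo.alignment_distance_matrix(aln, config.distance_model)
            emit("distances.tsv", lambda p: phylo.write_distance_matrix(dm, p))
            tree = phylo.bootstrap_support(
                aln, n_reps=config.bootstrap_reps, seed=config.seed,
                model=config.distance_model,
            )
            emit("tree.nwk", lambda p: tree.write_newick(p))
            summary["stages_run"].append("tree")
            summary["n_taxa"] = aln.n_taxa
            summary["bootstrap_reps"] = config.bootstrap_reps

        # -- duplication -----------------------------------------------------
        if records is not None:
            current_stage = "duplication"
            counts = dup.chromosome_counts(records)
            arrays = dup.find_tandem(
                records, max_gap=config.tandem_max_gap,
                max_intervening=config.tandem_max_intervening,
            )
            emit("tandem_arrays.tsv", lambda p: dup.write_tandem_table(arrays, p))
            emit("genes.bed", lambda p: dup.write_bed(records, p))
            summary["stages_run"].append("duplication")
            summary["chromosome_counts"] = counts
            summary["n_chromosomes"] = len(counts)
            summary["max_genes_per_chromosome"] = max(counts.values())
            summary["n_tandem_arrays"] = len(arrays)
            summary["n_tandem_genes"] = sum(len(a.members) for a in arrays)
            if config.blocks:
                blocks = dup.read_blocks(config.blocks)
                seg = dup.assign_segmental(records, blocks)

                def _write_seg(path: Path) -> None:
                    with open(path, "w") as fh:
                        fh.write("gene_a\tgene_b\n")
                        for a, b in seg.pairs:
                            fh.write(f"{a}\t{b}\n")

                emit("segmental_pairs.tsv", _write_seg)
                summary["n_segmental_pairs"] = len(seg.pairs)
                summary["n_genes_in_blocks"] = seg.n_in_blocks
                summary["n_blocks_hit"] = seg.n_blocks_hit
                summary["n_genes_outside_blocks"] = seg.n_outside

        # -- expression ------------------------------------------------------
        if config.stage1_matrix and config.stage2_matrix:
            current_stage = "expression"
            s1 = expr.read_stage_matrix(config.stage1_matrix, "stage1")
            s2 = expr.read_stage_matrix(config.stage2_matrix, "stage2")
            calls1 = expr.classify_regulation(s1, config.regulation_threshold)
            calls2 = expr.classify_regulation(s2, config.regulation_threshold)
            cross = expr.cross_stage_summary(s1, s2, config.regulation_threshold)
            summary["stages_run"].append("expression_microarray")
            summary["stage1_up"] = sum(1 for c in calls1.values() if c == "up")
            summary["stage1_down"] = sum(1 for c in calls1.values() if c == "down")
            summary["stage2_up"] = sum(1 for c in calls2.values() if c == "up")
            summary["stage2_down"] = sum(1 for c in calls2.values() if c == "down")
            summary["cross_stage"] = {
                k: v for k, v in cross.items() if k != "n_common"
            }
        if config.ct_table:
            current_stage = "expression"
            obs = expr.read_ct_table(config.ct_table)
            results = expr.delta_delta_ct(
                obs, config.reference_gene,
                control_condition=config.control_condition,
            )
            report = expr.fold_change_report(results)
            emit(
                "fold_changes.tsv",
                lambda p: report.to_csv(p, sep="\t", index=False,
                                        float_format="%.4f"),
            )
            summary["stages_run"].append("expression_qpcr")
            summary["n_fold_changes"] = len(report)
            summary["n_significant"] = int(
                (report["significant"] == "*").sum()
            )

        current_stage = "summary"
        emit(
            "summary.json",
            lambda p: p.write_text(json.dumps(summary, indent=2, sort_keys=True)),
        )
        log_lines.append("## outputs")
        log_lines.extend(str(p) for p in written)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(current_stage, err) from err
    return summary
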