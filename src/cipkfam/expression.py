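"""Drought-expression analysis: microarray regulation calls and 2^−ΔΔCt
qRT-PCR quantification.

Microarray side: per-stage log2(drought/control) ratios are classified as
up- or down-regulated by sign (an optional dead-band threshold marks small
ratios unchanged), and calls from two developmental stages are intersected
into both-up / both-down / opposite counts.

qRT-PCR side: the relative-quantification (Livak) method.  Per biological
replicate,

    ΔCt      = Ct_target − Ct_reference            (same sample)
    ΔΔCt_rep = ΔCt_treated,rep − mean(ΔCt_control)
    fold_rep = 2^−ΔΔCt_rep

The reported fold change is the mean of the replicate folds with its
standard error; significance comes from a two-sample Student's t-test on
the ΔCt values (log scale, variance-stabilized) of treated vs control
replicates at P < 0.05.  A Welch test and per-replicate control pairing are
available as options.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StageMatrix",
    "CtObservation",
    "FoldChangeResult",
    "classify_regulation",
    "cross_stage_summary",
    "delta_delta_ct",
    "fold_change_report",
    "read_ct_table",
    "write_ct_table",
    "read_stage_matrix",
    "write_stage_matrix",
]

RegulationCall = Literal["up", "down", "unchanged"]
ALPHA = 0.05


@dataclass(frozen=True)
class StageMatrix:
    """Per-gene log2(drought/control) ratios for one developmental stage."""

    stage: str
    ratios: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, r in self.ratios.items() if not math.isfinite(r)]
        if bad:
            raise ValueError(f"stage {self.stage!r}: non-finite ratios for {bad}")


@dataclass(frozen=True)
class CtObservation:
    """One qPCR cycle-threshold measurement."""

    gene: str
    tissue: str
    timepoint: int
    condition: str
    bio_replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"{self.gene}: Ct must be positive")
        if self.bio_replicate < 1:
            raise ValueError("replicate index is 1-based")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    tissue: str
    timepoint: int
    fold: float
    se: float
    p_value: float | None
    significant: bool

    def __post_init__(self) -> None:
        if self.fold <= 0 or self.se < 0:
            raise ValueError("fold must be positive and se non-negative")


def classify_regulation(
    stage: StageMatrix, threshold: float = 0.0
) -> dict[str, RegulationCall]:
    """Sign-rule regulation calls on log2 ratios.

    ratio > threshold → up; ratio < −threshold → down; otherwise unchanged
    (at the default threshold of 0 only an exact zero is unchanged).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    calls: dict[str, RegulationCall] = {}
    for gene, ratio in stage.ratios.items():
        if ratio > threshold:
            calls[gene] = "up"
        elif ratio < -threshold:
            calls[gene] = "down"
        else:
            calls[gene] = "unchanged"
    return calls


def cross_stage_summary(
    stage1: StageMatrix, stage2: StageMatrix, threshold: float = 0.0
) -> dict[str, int]:
    """Intersect regulation calls of two stages over their common genes.

    Returns counts of genes up in both stages, down in both, and with
    opposite calls; genes unchanged in either stage are excluded from all
    three classes, so both_up + both_down + opposite = number of common
    genes with an up/down call in both stages.
    """
    calls1 = classify_regulation(stage1, threshold)
    calls2 = classify_regulation(stage2, threshold)
    common = sorted(set(calls1) & set(calls2))
    if not common:
        warnings.warn("stage matrices share no genes", stacklevel=2)
    both_up = both_down = opposite = 0
    for gene in common:
        a, b = calls1[gene], calls2[gene]
        if "unchanged" in (a, b):
            continue
        if a == b == "up":
            both_up += 1
        elif a == b == "down":
            both_down += 1
        else:
            opposite += 1
    return {
        "both_up": both_up,
        "both_down": both_down,
        "opposite": opposite,
        "n_common": len(common),
    }


def delta_delta_ct(
    observations: Sequence[CtObservation],
    reference_gene: str,
    control_condition: str = "control",
    pairing: Literal["mean_control", "paired"] = "mean_control",
    equal_var: bool = True,
) -> list[FoldChangeResult]:
    """Fold changes by the 2^−ΔΔCt method with replicate statistics.

    Every (gene, tissue, timepoint, condition, replicate) cell must have a
    reference-gene Ct in the same sample; a missing one is an error naming
    the cell.  ``pairing='mean_control'`` subtracts the mean control ΔCt
    from each treated replicate (default); ``'paired'`` subtracts the
    control ΔCt of the matching replicate index.  With fewer than 2
    replicates in either condition no p-value is computed and the result is
    flagged non-significant.
    """
    df = pd.DataFrame([vars(o) for o in observations])
    if df.empty:
        return []
    ref = df[df.gene == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index(["tissue", "timepoint", "condition", "bio_replicate"]).ct

    targets = df[df.gene != reference_gene]
    results: list[FoldChangeResult] = []
    group_cols = ["gene", "tissue", "timepoint"]
    for (gene, tissue, timepoint), grp in targets.groupby(group_cols, sort=True):
        dct: dict[str, dict[int, float]] = {}
        for row in grp.itertuples(index=False):
            key = (row.tissue, row.timepoint, row.condition, row.bio_replicate)
            if key not in ref_ct.index:
                raise ValueError(
                    f"missing reference Ct for sample (tissue={row.tissue}, "
                    f"timepoint={row.timepoint}, condition={row.condition}, "
                    f"replicate={row.bio_replicate})"
                )
            dct.setdefault(row.condition, {})[row.bio_replicate] = (
                row.ct - float(ref_ct.loc[key])
            )
        control = dct.get(control_condition, {})
        if not control:
            raise ValueError(
                f"no {control_condition!r} observations for "
                f"({gene}, {tissue}, {timepoint})"
            )
        treated_conditions = [c for c in sorted(dct) if c != control_condition]
        for cond in treated_conditions:
            treated = dct[cond]
            if pairing == "paired":
                missing = set(treated) - set(control)
                if missing:
                    raise ValueError(
                        f"paired mode: control replicate(s) {sorted(missing)} "
                        f"missing for ({gene}, {tissue}, {timepoint})"
                    )
                ddct = np.array(
                    [treated[r] - control[r] for r in sorted(treated)]
                )
            else:
                baseline = float(np.mean(list(control.values())))
                ddct = np.array(
                    [treated[r] - baseline for r in sorted(treated)]
                )
            folds = np.power(2.0, -ddct)
            n = len(folds)
            fold = float(folds.mean())
            se = float(folds.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            t_ct = np.array(sorted(treated.values()))
            c_ct = np.array(sorted(control.values()))
            if len(t_ct) >= 2 and len(c_ct) >= 2:
                if float(np.var(t_ct) + np.var(c_ct)) == 0.0:
                    # degenerate: identical replicates; the t statistic is
                    # undefined, the difference of means decides
                    p = 1.0 if np.isclose(t_ct.mean(), c_ct.mean()) else 0.0
                else:
                    p = float(
                        stats.ttest_ind(t_ct, c_ct, equal_var=equal_var).pvalue
                    )
                results.append(
                    FoldChangeResult(gene, tissue, int(timepoint), fold, se,
                                     p, p < ALPHA)
                )
            else:
                warnings.warn(
                    f"({gene}, {tissue}, {timepoint}): <2 replicates, "
                    "no p-value", stacklevel=2,
                )
                results.append(
                    FoldChangeResult(gene, tissue, int(timepoint), fold, se,
                                     None, False)
                )
    return results


def fold_change_report(results: Iterable[FoldChangeResult]) -> pd.DataFrame:
    """Long-format report: one row per gene × tissue × timepoint with fold,
    SE, p-value and a significance star."""
    rows = [
        {
            "gene": r.gene,
            "tissue": r.tissue,
            "timepoint": r.timepoint,
            "fold": r.fold,
            "se": r.se,
            "p_value": r.p_value if r.p_value is not None else float("nan"),
            "significant": "*" if r.significant else "",
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["gene", "tissue", "timepoint", "fold", "se", "p_value",
                 "significant"],
    )
    return df.sort_values(["tissue", "timepoint", "gene"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CT_COLUMNS = ["gene", "tissue", "timepoint", "condition", "bio_replicate", "ct"]


def read_ct_table(path: str | Path) -> list[CtObservation]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return [
        CtObservation(
            gene=str(r.gene), tissue=str(r.tissue), timepoint=int(r.timepoint),
            condition=str(r.condition), bio_replicate=int(r.bio_replicate),
            ct=float(r.ct),
        )
        for r in df.itertuples(index=False)
    ]


def write_ct_table(observations: Iterable[CtObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CT_COLUMNS) + "\n")
        for o in observations:
            fh.write(
                f"{o.gene}\t{o.tissue}\t{o.timepoint}\t{o.condition}"
                f"\t{o.bio_replicate}\t{o.ct:.4f}\n"
            )


def read_stage_matrix(path: str | Path, stage: str) -> StageMatrix:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "log2_ratio"} <= set(df.columns):
        raise ValueError("stage matrix needs columns: gene, log2_ratio")
    return StageMatrix(
        stage, {str(r.gene): float(r.log2_ratio) for r in df.itertuples(index=False)}
    )


def write_stage_matrix(matrix: StageMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2_ratio\n")
        for gene in sorted(matrix.ratios):
            fh.write(f"{gene}\t{matrix.ratios[gene]:.4f}\n")
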