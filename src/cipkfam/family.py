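"""Domain-based identification of CIPK family members and protein statistics.

A CIPK (CBL-interacting protein kinase) is defined by the co-occurrence of
two domains on one protein: an N-terminal serine/threonine kinase domain and
the C-terminal self-inhibitory NAF domain through which CBL calcium sensors
bind.  Membership is therefore decided purely by requiring at least one
scored hit for *every* required domain label.

Domain evidence can come from two sources:

* a per-domain tabular report in the ``hmmscan --domtblout`` dialect
  (:func:`parse_domain_table`), for users who ran a profile-HMM search
  against e.g. Pfam themselves, or
* the built-in position-specific scoring matrix (PSSM) scanner
  (:func:`scan_motifs`), a lightweight log-odds window scorer used with the
  synthetic fixtures shipped with this package.

The module also computes the two per-protein descriptors reported in
gene-family surveys: average molecular weight (sum of residue masses plus
one water) and isoelectric point (the pH at which the Henderson–Hasselbalch
net charge vanishes, found by bisection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "ProteinStats",
    "Pssm",
    "read_fasta",
    "write_fasta",
    "parse_domain_table",
    "scan_motifs",
    "select_family",
    "compute_mw",
    "net_charge",
    "compute_pi",
    "protein_stats",
    "write_stats_table",
    "AMINO_ACIDS",
    "RESIDUE_MASSES",
    "WATER_MASS",
    "PKA_TABLE",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Average (isotope-abundance weighted) residue masses in Da, i.e. the mass
# each amino acid contributes inside a peptide chain (free amino acid minus
# one water).  One water is added back per chain.
RESIDUE_MASSES: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
# 'X' (unknown residue) contributes the mean residue mass to MW and is
# excluded from the charge model.
MEAN_RESIDUE_MASS = sum(RESIDUE_MASSES.values()) / len(RESIDUE_MASSES)

# Side-chain and termini pKa values (EMBOSS-style set, as used by the common
# web pI calculators).  Positive groups: N-terminus, H, K, R; negative:
# C-terminus, D, E, C, Y.
PKA_TABLE: Mapping[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("C", "D", "E", "Y")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; uppercase, 20 canonical letters with X tolerated."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(seq) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: unknown residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One scored domain match on a protein (1-based inclusive coordinates)."""

    protein_id: str
    domain_label: str
    ali_start: int
    ali_end: int
    bit_score: float
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"hit {self.protein_id}/{self.domain_label}: bad alignment "
                f"coordinates {self.ali_start}..{self.ali_end}"
            )
        if self.e_value < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class ProteinStats:
    id: str
    length_aa: int
    mw_kd: float
    pi: float


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file."""
    return [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# hmmscan per-domain table
# ---------------------------------------------------------------------------

def parse_domain_table(path: str | Path, max_evalue: float = 1e-5) -> list[DomainHit]:
    """Parse a per-domain tabular report (``hmmscan --domtblout`` dialect).

    The format is whitespace-delimited with ``#`` comment lines and at least
    23 columns; the trailing free-text description may contain spaces.
    Column 1 is the matched profile (domain) name, column 4 the query
    protein, column 13 the independent E-value, column 14 the domain bit
    score and columns 18–19 the 1-based inclusive alignment coordinates on
    the protein.

    Rows whose independent E-value exceeds ``max_evalue`` are dropped
    (``max_evalue=None`` keeps everything).  Malformed rows raise
    :class:`ValueError` naming the offending line.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=23 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[3],
                    domain_label=fields[0],
                    ali_start=int(fields[17]),
                    ali_end=int(fields[18]),
                    bit_score=float(fields[13]),
                    e_value=float(fields[12]),
                )
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
            if max_evalue is None or hit.e_value <= max_evalue:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# PSSM scanning (stand-in for a profile-HMM search on synthetic data)
# ---------------------------------------------------------------------------

class Pssm:
    """A fixed-width log-odds position-specific scoring matrix.

    Column scores are ``log2(p(aa | position) / background(aa))``.  The
    window score of a sequence stretch is the sum of per-position scores;
    :func:`scan_motifs` reports the maximal-scoring window when it reaches
    ``threshold``.
    """

    def __init__(self, label: str, matrix: np.ndarray, threshold: float):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != len(AMINO_ACIDS):
            raise ValueError("PSSM matrix must be width x 20")
        self.label = label
        self.matrix = matrix
        self.threshold = float(threshold)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable score: the sum of per-column maxima."""
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls,
        label: str,
        consensus: str,
        match_prob: float = 0.9,
        threshold_fraction: float = 0.5,
    ) -> "Pssm":
        """Build a PSSM from a consensus string over a uniform background.

        Each column gives probability ``match_prob`` to the consensus letter
        and spreads the remainder evenly over the other 19; the background is
        uniform (1/20).  The acceptance threshold defaults to half the
        maximal score, which tolerates a handful of point mutations while
        rejecting unrelated sequence.
        """
        if not consensus or set(consensus) - set(AMINO_ACIDS):
            raise ValueError("consensus must be non-empty canonical amino acids")
        if not 0 < match_prob < 1:
            raise ValueError("match_prob must be in (0, 1)")
        w = len(consensus)
        probs = np.full((w, 20), (1.0 - match_prob) / 19.0)
        for i, aa in enumerate(consensus):
            probs[i, AA_INDEX[aa]] = match_prob
        matrix = np.log2(probs / (1.0 / 20.0))
        pssm = cls(label, matrix, threshold=0.0)
        pssm.threshold = threshold_fraction * pssm.max_score
        return pssm

    def best_window(self, sequence: str) -> tuple[float, int] | None:
        """Return (score, 1-based start) of the best window, or None if the
        sequence is shorter than the PSSM."""
        n = len(sequence)
        if n < self.width:
            return None
        best_score, best_start = -math.inf, 1
        for start in range(n - self.width + 1):
            score = 0.0
            for offset in range(self.width):
                aa = sequence[start + offset]
                idx = AA_INDEX.get(aa)
                if idx is None:  # X: neutral, background odds
                    continue
                score += self.matrix[offset, idx]
            if score > best_score:
                best_score, best_start = score, start + 1
        return best_score, best_start


def scan_motifs(protein: ProteinRecord, pssms: Sequence[Pssm]) -> list[DomainHit]:
    """Scan a protein with each PSSM; report the maximal-scoring window per
    PSSM when its score reaches the PSSM threshold.

    A sequence shorter than a PSSM simply yields no hit for it.
    """
    hits: list[DomainHit] = []
    for pssm in pssms:
        found = pssm.best_window(protein.sequence)
        if found is None:
            continue
        score, start = found
        if score >= pssm.threshold:
            hits.append(
                DomainHit(
                    protein_id=protein.id,
                    domain_label=pssm.label,
                    ali_start=start,
                    ali_end=start + pssm.width - 1,
                    bit_score=score,
                    e_value=0.0,
                )
            )
    return hits


def select_family(
    proteins: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    require: Sequence[str] = ("Pkinase", "NAF"),
) -> list[str]:
    """Select family members: proteins with >=1 hit for *every* required label.

    Returns member ids sorted lexicographically.  The operation is a pure
    filter — idempotent and independent of input order.
    """
    required = set(require)
    if not required:
        raise ValueError("at least one required domain label is needed")
    ids = {p.id for p in proteins}
    seen: dict[str, set[str]] = {}
    for hit in hits:
        if hit.protein_id in ids:
            seen.setdefault(hit.protein_id, set()).add(hit.domain_label)
    return sorted(pid for pid, labels in seen.items() if required <= labels)


# ---------------------------------------------------------------------------
# Protein statistics
# ---------------------------------------------------------------------------

def compute_mw(sequence: str) -> float:
    """Average molecular weight in kilodaltons.

    Sum of average residue masses plus one water.  ``X`` contributes the
    mean residue mass; any other non-canonical letter is an error.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in seq:
        if aa == "X":
            total += MEAN_RESIDUE_MASS
        else:
            try:
                total += RESIDUE_MASSES[aa]
            except KeyError:
                raise ValueError(f"unknown residue {aa!r}") from None
    return total / 1000.0


def net_charge(sequence: str, ph: float, pka: Mapping[str, float] = PKA_TABLE) -> float:
    """Henderson–Hasselbalch net charge of a protein at a given pH.

    Counts the free termini plus the titratable side chains (D, E, C, Y
    negative; H, K, R positive).  ``X`` residues are not titratable.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def compute_pi(
    sequence: str,
    pka: Mapping[str, float] = PKA_TABLE,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: the pH at which the net charge is zero.

    The net charge is strictly decreasing in pH (every term is), positive at
    pH 0 and negative at pH 14 thanks to the free termini, so the root is
    unique; it is bracketed on [0, 14] and found by bisection to ``tol``.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_stats(protein: ProteinRecord) -> ProteinStats:
    return ProteinStats(
        id=protein.id,
        length_aa=len(protein),
        mw_kd=compute_mw(protein.sequence),
        pi=compute_pi(protein.sequence),
    )


def write_stats_table(stats: Iterable[ProteinStats], path: str | Path) -> None:
    """Write a protein statistics TSV (id, length aa, pI, MW in kD)."""
    with open(path, "w") as fh:
        fh.write("id\tlength_aa\tpi\tmw_kd\n")
        for s in stats:
            fh.write(f"{s.id}\t{s.length_aa}\t{s.pi:.2f}\t{s.mw_kd:.2f}\n")
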