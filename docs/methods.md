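# Methods

This note documents the models, parameter choices and numerical details
behind `cipkfam`, and what the synthetic fixtures do and do not emulate.

## Family identification

Membership is domain co-occurrence: a protein is a family member iff it has
at least one accepted hit for every required domain label (default
`Pkinase` + `NAF`). The operation is a pure filter — idempotent and
order-independent — and deliberately has no score competition between
overlapping kinase-domain variants; the label set is configurable so that
e.g. `Pkinase_Tyr` can be accepted alongside `Pkinase`.

Two evidence sources are supported:

* **hmmscan per-domain tables.** Rows above the per-domain independent
  E-value cutoff are dropped. The cutoff defaults to 1e-5; published
  family surveys rarely state one, so it is explicit and configurable
  (`max_evalue=None` disables filtering).
* **Built-in PSSM scanner.** A stand-in for a profile-HMM search when only
  synthetic data are in play. Each matrix column scores
  `log2(p(aa|pos)/background)` with `p = 0.9` on the consensus letter,
  the remainder spread over the other 19 letters, and a uniform 1/20
  background. The reported hit is the maximal-scoring window; the
  acceptance threshold defaults to half the maximal score, which tolerates
  roughly five point mutations in a 20-mer while rejecting unrelated
  sequence by a wide margin (a random window scores far below zero on
  average). This scanner makes no claim to HMMER's sensitivity; it exists
  to preserve the co-occurrence logic on planted motifs.

### Molecular weight

Average isotopic masses: MW = Σ residue masses + 18.0153 Da for the
terminal water, reported in kD. `X` contributes the mean of the 20
residue masses and any other non-canonical letter is an error. MW is
additive: `mw(a+b) = mw(a) + mw(b) − water`.

### Isoelectric point

Henderson–Hasselbalch net charge with the EMBOSS-style pKa set
(N-terminus 8.6, C-terminus 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1); positive groups N-terminus/H/K/R, negative groups
C-terminus/D/E/C/Y; `X` is not titratable. Net charge is strictly
decreasing in pH and changes sign on [0, 14] because of the two termini,
so the root is unique; it is bracketed and bisected to 1e-4 pH units.
The test suite checks the bisection against an independent 1e-5 pH-grid
scan. Different web calculators use slightly different pKa sets, so
published pI columns are reproduced only approximately; correctness here
means "root of the stated charge model", not agreement with any one web
tool.

## Gene structure

Gene models come from GFF3 (1-based inclusive coordinates). When a gene
has several mRNAs the transcript with the largest summed CDS length is
selected; intron count is `len(exons) − 1` of that transcript's exon
features (not its CDS segments — the two agree for the UTR-free synthetic
models and for the published exon counts).

Clade thresholds follow the plant CIPK literature: **intron-poor < 3**,
**intron-rich > 8** introns. The published thresholds leave 3–8 introns
undefined; those counts are labelled `intermediate` so that the three
labels partition every possible count. No gene of the bundled soybean
catalog falls there, but synthetic inputs may.

Catalog validation re-derives per-row arithmetic — coordinate span
`|end − start| + 1` vs printed gene length, `cds/3 − 1` vs printed protein
length, reversed coordinates — and flags mismatches without guessing
corrections. The bundled catalog is stored exactly as printed; its rows
GmCIPK29 (degenerate coordinates with a 5830-bp printed length) and
GmCIPK52 (reversed coordinates whose span also disagrees with the printed
length) are intentionally preserved as validator test material. Reversed
coordinates are normalized (with a warning) before any positional
analysis.

## Phylogeny

Distances: p-distance with **pairwise deletion** (sites with a gap in
either row are excluded per pair) and the **Poisson correction**
`d = −ln(1 − p)`, which assumes equal substitution rates across sites and
no back-substitution bias — the standard choice for within-family protein
trees. A saturated pair (`p = 1`) or a pair with no shared ungapped site
is an error rather than a silently infinite distance. Plain p-distance is
available as an option.

Neighbor-joining is the canonical Saitou–Nei agglomeration. Determinism:
taxa are processed in lexicographic id order and ties in the Q matrix
resolve to the first (row-major) minimal pair, so permuting the input
yields the identical tree. Negative branch-length estimates (possible on
non-additive data) are clamped to zero; the summed deficit is kept on the
tree object (`clamped_deficit`) instead of being silently discarded. On
additive matrices NJ provably recovers the generating topology and branch
lengths; the tests verify this against exhaustive least-squares topology
search up to 7 taxa and on random additive trees up to 12 taxa.

Bootstrap: alignment columns are resampled with replacement from one
seeded RNG stream; supports are mapped onto the bipartitions of the
original tree (not a consensus tree), as mainstream phylogenetics GUIs
do. A replicate that produces an undefined distance is redrawn, at most
10 times. `return_replicates=True` exposes the exact column index lists
so supports can be recounted independently; the suite asserts identity.
1000 replicates is the conventional default; tests and the acceptance
script use 50–200 on toy alignments to keep runtimes in seconds.

Subgroup assignment: each unanchored leaf takes the label of the smallest
clade (side of an edge of the unrooted tree) containing it together with
anchors of exactly one subgroup; if every anchor-containing clade around a
leaf mixes subgroups the leaf stays unassigned. Clades are scanned
smallest-first with a content-based tie-break for determinism.

## Duplication

The tandem rule is "an array of ≥ 2 family genes on one chromosome,
consecutive genes separated by < 100 kb and by ≤ 5 intervening genes".
The gap is measured **end of upstream gene → start of downstream gene**;
on the bundled soybean catalog this choice reproduces exactly the six
published tandem pairs and no extras. Without a full genome annotation
the intervening-gene condition cannot be evaluated and is vacuously true
(distance-only mode). Qualifying runs merge, so reported arrays are
maximal, and shrinking the gap threshold can only remove arrays.

Segmental duplication is ingested, not inferred: a block table of paired
chromosome ranges (as exported from a synteny browser) is the input. A
gene counts as "in a duplicated block" when its span lies entirely within
either side of a block, even when no family partner sits on the mate side
— this matches the gene-wise bookkeeping of published family surveys.
Genes on the two sides of one block are reported as duplicate partners.

## Expression

Microarray calls use the sign of the log2(drought/control) ratio with an
optional symmetric dead band (default 0, since published up/down counts
state no cutoff). The cross-stage summary partitions genes called in both
stages into both-up / both-down / opposite.

qRT-PCR uses the Livak 2^−ΔΔCt estimator. Per biological replicate,
ΔCt = Ct_target − Ct_reference within the same sample; ΔΔCt subtracts the
**mean control ΔCt** (per-replicate pairing is an option; the published
protocols rarely say which was used). The reported fold is the arithmetic
mean of replicate folds with SE = sd/√n. Significance: two-sample
Student's *t* on the ΔCt values — the log scale is variance-stabilizing
and standard — at α = 0.05, equal variances by default with Welch as an
option. With identical replicate values in both groups the t statistic is
undefined (0/0); the implementation then reports p = 1 for equal means
and p = 0 otherwise rather than NaN. Day-0 samples are their own
baseline, so day-0 folds are 1 by construction.

## Synthetic fixtures

The family generator defaults describe a small but structurally faithful
study: 10 members (roughly 60 % intron-poor / 40 % intron-rich, matching
the 2:1 skew of real CIPK families), 5 kinase-only plus 5 NAF-only
decoys, 3 chromosomes of 30 Mb, one tandem cluster of two genes with
< 50 kb spacing, two segmental pairs, and a motif point-mutation rate of
0.05 per position (≈ 1 mutation per 20-mer, far above the PSSM acceptance
threshold yet clearly non-identical sequences). Unrelated neighbouring
genes are spaced > 150 kb apart so planted tandem arrays are exactly the
arrays the < 100-kb rule recovers. Gene models are UTR-free with
one mRNA per gene; CDS length is 3·(protein length + 1).

The expression generator plants fold changes in Ct space: the reference
gene sits at 20 cycles in every sample, each target at a deterministic
24–30-cycle baseline, drought Ct values are lowered by the planted log2
fold change, and iid Gaussian noise (default sd 0.3 cycles, 3 biological
replicates) is added to every measurement. Because the arithmetic mean of
per-replicate folds is a lognormal-biased estimator under Gaussian Ct
noise, treated Ct means additionally carry a `+0.5·Var(ΔΔCt)·ln 2` offset
(with `Var(ΔΔCt) = 2σ²(1 + 1/n)`) so that the **expected value of the
downstream estimator equals the planted fold exactly**. The offset is
recorded in the truth file and can be disabled (`mean_unbiased=False`).
One consequence, accepted deliberately: for a planted fold of 1 the
treated ΔCt mean is offset by ≈ 0.08 cycles, so the *t*-test null is only
approximate there — at the default noise level its measured type-I error
remains statistically indistinguishable from 0.05.

Default two-stage microarray ratios plant the cross-stage structure of
the soybean drought study (48 genes: 18 both-up, 13 both-down, 2 up-down,
15 down-up, giving 20/28 and 33/15 per-stage calls) with magnitudes drawn
uniformly from 0.3–3.0 log2 units.

What the fixtures do **not** emulate: realistic sequence evolution (no
indels, no rate variation — unsuitable for dN/dS or alignment testing),
microarray probe-level noise and normalization artifacts, isoforms, and
genome-scale gene density. Passing the planted-truth tests therefore
demonstrates the correctness of the decision rules and estimators, not
robustness to the full messiness of real annotation pipelines.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: the 52-gene
bundled catalog; 20-protein synthetic families; NJ-vs-oracle checks on
4–7 taxa (the exhaustive topology space at 7 taxa is already 945 trees)
and additive recovery to 12 taxa; 200-replicate bootstraps on 5-taxon
alignments; 200 Monte-Carlo seeds for fold recovery and 1000 null tables
for *t*-test calibration. These sizes give sub-minute wall times while
leaving every statistical check adequately powered.

## Known limitations

* The PSSM scanner is positional and ungapped; it cannot find split or
  indel-containing domains.
* Published pI/MW columns computed with other tools reproduce only to
  within the differences between pKa/mass tables.
* Bootstrap supports are attached to the original topology; a consensus
  tree is not built.
* Segmental-duplication results are only as good as the supplied block
  table; the package does not compute synteny.
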