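# Methods

This note documents the models and procedures `allokit` implements, the
parameter defaults and their rationale, what the synthetic-data generator
does and does not emulate, and the numerical conventions and design
choices made where the design was genuinely open.

## Analysis model

### Synteny and 1:1 pairing

Homology hits (12-column tabular, outfmt-6 dialect) are kept only at
e-value ≤ 1e-5 with self-hits dropped.  The **cscore** of a hit (q, s) is
`score(q,s) / max(best(q), best(s))`, the established definition of the
parameter: a hit survives iff its cscore is ≥ `cscore_min` (default
0.90).  Survivors are then forced 1:1 — a hit is retained iff it is the
best surviving hit of *both* its genes, with ties broken
lexicographically — so no gene appears in two pairs.

Chaining works per (chromosome A, chromosome B) pair on gene-order ranks.
A valid chain has strictly increasing `rank_a`, strictly monotone
`rank_b` (increasing = same orientation, decreasing = inverted; the
inverted case is found by negating `rank_b`), and consecutive gaps ≤
`block_gap_genes` (20) in both coordinates.  The dynamic program tracks
chain length capped at `min_anchor_pairs` (4), so it maximizes summed
bitscore *subject to* the four-anchor floor — this makes it provably
equal to a brute-force maximum-collinear-subset search, which the test
suite verifies on all instances up to 12 anchors.  Blocks are extracted
greedily by descending chain score; anchors belong to at most one block.
Chain score is the sum of anchor bitscores (monotone in evidence; any
positive per-anchor weighting would give the same maximal chains).

The 20-gene block gap and the five-pair homolog search window are
distinct constants and are kept as separate thresholds.

### Gene-loss filter chain

The filter order is fixed and no state skips a stage:

    potential_loss -> rescued_misannotation -> partial_loss / pseudogene
                   -> dna_loss_candidate -> confirmed_loss
                   -> genotype_difference

*Potential losses.*  "Within five syntenic gene pairs" is interpreted
geometrically: for an unpaired blocked ancestral gene, the derived-side
search interval is spanned by the derived partners of its five nearest
anchored neighbours upstream and downstream (fewer at block edges).  A
homolog is any e-value-passing hit to a derived gene overlapping that
interval.  Ancestral genes outside all blocks are potential losses with
no window.

*Rescue.*  A candidate is rescued when a re-predicted derived gene model
matches it at identity ≥ 95 % with alignment coverage ≥ 90 % of **both**
query and subject and lies inside the window.  Out-of-block candidates
have no window; for them the identity/coverage thresholds apply without a
positional constraint, mirroring how out-of-block candidates are
validated "in the same way" as blocked ones.

*Partial / pseudogene.*  Consumed as a precomputed report per candidate
(`has_region`, `has_start`, `has_stop`, `frameshift`) rather than
re-running splice-aware protein-to-DNA alignment, which is an external
engine; the simulator emits this report.  Missing start or stop ⇒ partial
loss; frameshift ⇒ pseudogene; no homologous region ⇒ DNA-loss candidate.
A region that is intact on all three counts also falls through to the
DNA-loss candidate pool (it then fails depth confirmation, since intact
DNA carries coverage).

*Depth confirmation.*  Boundary semantics are strict everywhere: a gene
at exactly 1.0× depth or exactly 5 % breadth is **not** lost.  Breadth is
the fraction of gene-body bases with ≥ 1 read.

*Genotype exclusion.*  A confirmed loss that is also absent (same rule)
from the resequenced actual parent line reflects accession-level
difference, not polyploidization, and is relabelled.  Without parental
data the step logs a warning and passes records through.

### Attribution across generations

Presence per generation is `NOT(depth < 1x AND breadth < 5%)` over the
ordered samples F1, S0, S4…S13.  Attribution is by first absence: F1 ⇒
hybridization (with a `restored` flag when the gene is present again at
S0), S0 ⇒ duplication, S_n ⇒ diploidization(S_n).  Sporadic patterns
beyond the F1→S0 restoration (absent, later present again) are attributed
by first absence and flagged `unstable`, reflecting individual differences
within generations rather than a separate rule.  Stage counts sum to the
number of ever-absent genes.

### Homoeologous exchange

Depth windows of `he_window_bp` = 5000 bp are classed by fold-coverage
bands tied to the ~50× study mean: deleted [0, 25], duplicated [75, 150]
(both closed; 150.1 is an outlier), otherwise normal.  When a sample's
observed mean is supplied, the bands scale by `observed_mean / 50`.
Trailing partial windows are excluded from segment formation (fixed-width
windows are undefined at chromosome ends).  "Within ten distant windows"
is read as an intervening gap of ≤ 10 windows (≤ 50 kb) and exposed as
`he_link_gap_windows`; linking is idempotent.  Candidate duplications
additionally require a mean long-read mapped fraction strictly > 30 %
over the segment (computed upstream by a long-read mapper; this package
does not run one).

For confirmation, SubC↔SubH blocks on the same chromosome pair are merged
when < 20 kb apart, a duplicated segment's homologous interval on the
other subgenome is spanned by the partner genes of the anchors it
overlaps (nearest flanking anchors when none overlap, padded by one
window), and an overlapping deleted segment plus a sequence-identity
record for the region pair yields a confirmed call.  Direction points
from the deleted subgenome's parent toward the duplicated one: a deletion
on SubH with the duplicated homolog on SubC means CC content replaced HH
(`CC_to_HH`).

### Expression bias

The upstream count-model differential-expression gate is replaced by a
pseudocount fold rule with an expression floor: pairs with both copies
below 1 unit are `not_expressed`; otherwise `(x_C + 1)/(x_H + 1)` ≥ 2 is
C-dominant and ≤ ½ H-dominant, with exactly twofold counting as biased.
Both knobs (`pseudocount`, `expression_floor`) are configurable; the
floor prevents noise-driven classes at vanishing expression.  The
genome-wide summary reports class counts (conserving the total),
histograms of log2(x+1) for the dominant copies, and a two-sided
Mann-Whitney rank-sum comparison of C- vs H-dominant dominant-copy
expression, skipped when either class is empty.

### cp variants and SVs

Each cp variant takes the stage of its first presence along the ordered
samples.  Variants that disappear after appearing and return are flagged
anomalous and counted in their own bucket, so stage counts + anomalous =
total per variant type; the F1 fraction is computed from first appearance
regardless of the flag.  The variant-calling itself is upstream; inputs
are per-sample VCFs whose non-reference genotypes mean presence.  Indels
are bounded to a 2–50 bp allele span by the calling contract.

SV verdicts apply in order: length ≤ 25 bp ⇒ `too_small` (strictly
"> 25 bp" is required); no soft-clip breakpoint support ⇒ `unverified`;
actual-parent-line read support ⇒ `genotype_difference`; else `true_sv`.
Verdicts are per-record and order-independent.

### Summaries

N-x is the length at which the cumulative sorted-descending sequence
length first reaches x % of the total; L-x the count to that point.
Missing bases (%) = gap length / total assembly size × 100.  All reported
ratios round half-even at the requested decimal count, which reproduces
every checked printed percentage.  One published statistics table prints
0.83 % missing bases for a column whose own gap (9,893,587 bp) over its
own total (540,738,094 bp) is 1.83 %; the implementation reports the
formula result and treats the printed cell as a typo.  TE density near
genes uses the standard metagene convention: fixed-width flank bins plus
a gene body length-normalized to a fixed bin count, profiles oriented by
strand and averaged per subgenome.

## Synthetic-data generator

The generator emulates the study design end to end: two diploid parents
sharing an ancestral gene order (default 2 chromosomes × 250 genes each;
gene length U(600, 1200) bp, spacing U(900, 1500) bp — compact desk-scale
genes that keep chromosomes ~0.9 Mb while preserving every rate the
pipeline measures), the HH-like parent more TE-rich (45 % vs 30 %); a
tetraploid whose subgenomes copy the parental orders with injected
events; depth tracks for F1, S0, S4…S13 plus the deeply analysed S14
reference generation and two parental resequencing controls; cp variant
VCFs; expression; SV candidates.  Defaults follow the stated study
conditions: 30 stage-stamped DNA losses (8 SubC / 22 SubH, 14 in F1, 2
restored at S0), 4 misannotations, 3 partial losses, 3 pseudogenes, 2
parental genotype differences, 5 HE events ≥ 25 kb (3 CC→HH, 2 HH→CC,
emulating CC-biased conversion), 50× mean depth, 195 cp SNPs (144 stamped
F1 → 73.85 %) and 100 indels (73 stamped F1), and expression dominance at
fold 4, dispersion 0.1, with 15 % C-biased and 10 % H-biased pairs.

Design choices that deserve explanation:

- **Depth model.**  Coverage is emitted as read-length-sized chunks
  (150 bp) whose mean depth is drawn `Poisson(chunk_len · λ)/chunk_len`.
  Because sums of independent Poisson variables are Poisson, every
  windowed or gene-body *mean* the pipeline computes has exactly the
  distribution per-base Poisson coverage would give, while the bedGraph
  stays ~150 bp-resolution text.  The model has no read-length
  autocorrelation beyond the chunk and no mappability structure.
- **Deleted regions emit no coverage.**  Under the strict < 1× depth and
  < 5 % breadth confirmation rule, even a 0.1× residual defeats
  detection: expected breadth at per-base rate 0.1 is 1 − e^(−0.1) ≈
  9.5 %, and a single 150 bp stray read over a ~1 kb gene already exceeds
  5 % breadth.  Unique-mapping filters make truly deleted sequence
  essentially read-free in practice, so the default residual is 0, with a
  `contamination_depth` knob to add sparse stray reads when studying the
  rule's failure mode.
- **Restored losses.**  A gene absent in F1 but present from S0 onward
  would not be missing from the S14 assembly, so it could never enter the
  confirmed-loss set whose presence matrix drives attribution.  Restored
  genes are therefore stamped absent in F1 *and* in S14 (lost again after
  S13) but present S0–S13, which makes the restoration pattern
  recoverable end to end.
- **HE regions transplant gene models.**  A replaced segment keeps gene
  content from the donor subgenome at the receiving coordinates, and the
  hit tables include homology between the displaced genes and the
  transplants.  Consequently the loss caller correctly retains the
  displaced genes (their homolog sits inside the anchor window) instead
  of miscounting exchanges as losses, and the SubC↔SubH blocks stay
  continuous across exchange regions for HE confirmation.
- **Expression values are means of 3 negative-binomial replicates**,
  matching replicated normalized-expression estimates; a single draw at
  dispersion 0.1 has CV ≈ 0.32, which is the between-replicate spread,
  not the spread of a reported expression value.
- Event genes are drawn away from the first/last 8 genes of each
  chromosome so the five-anchor windows always exist, and events never
  overlap (overlapping configurations are rejected).

Everything is driven by one `numpy` generator in a fixed order, so a seed
determines all outputs byte-for-byte.

What the generator does **not** emulate — hence what green tests do not
show about real data: sequence-level alignment artifacts (hits and
identity tables are emitted directly rather than recomputed from
sequence), mappability and repeat-driven coverage structure, segmental
duplications that are not HEs, partially degraded genes with intermediate
depth, annotation errors beyond clean gene-model absence, and population
heterogeneity within a generation (each generation is one individual, as
in the study design).

## Problem sizes and runtime

The default verification design uses 500 genes per subgenome (~0.9 Mb per
parent genome), 13 depth samples × 2 reference genomes, and ~460 homeolog
expression pairs — sizes chosen so the full simulate-and-analyse cycle
runs in a few seconds and the whole test suite in well under a minute,
while every threshold still operates at its study value (50× depth, 5 kb
windows, 20-gene gaps).  Recovery at these sizes is exact across seeds
for losses (30/30, correct stages), HE (5/5, correct directions) and cp
fractions (noise-free presence), and ≥ 95 % for expression-bias classes.

## Known limitations

- Subgenome assignment of assembly sequences is taken as given input; the
  assignment procedure itself is not reconstructed.
- The HE caller's homologous-interval mapping is anchor-based (gene
  resolution, padded by one window), not base-level; exchanges much
  shorter than the intergenic pitch or falling in anchor deserts can be
  missed or imprecisely bounded.
- The expression gate is a fold rule, not a count-model test; very low
  expressed pairs are handled by the floor rather than by shrinkage.
- BAM/CRAM and FASTA handling are out of scope: depth arrives as
  bedGraph, homology as tabular hits, frameshift evidence as a report.
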