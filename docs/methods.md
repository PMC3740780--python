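# Methods

`symevol` reimplements, end to end and at desk scale, a comparative analysis
of protein evolution among the four *Symbiodinium* clades (A–D) commonly
hosted by reef-building corals, together with the upstream steps that produce
its inputs: quantification of mixed clade-C/D symbiont communities from
marker-mapped sequencing reads, reference-guided contig joining, multi-taxa
ortholog group construction, and the downstream multiple-testing and GO
enrichment layers.  Every stage is exercised against synthetic data with
known ground truth; nothing in the package requires the original sequencing
data.

## Codon substitution model

The core is the Goldman–Yang (GY94) codon model on the 61 sense codons of the
universal code.  For codons *i* → *j* differing at exactly one nucleotide,

    q_ij = pi_j · kappa^[transition] · omega^[nonsynonymous]

with `q_ij = 0` for multi-step changes, diagonal entries set so rows sum to
zero, and each branch class's matrix rescaled so the stationary mean rate
`-sum_i pi_i q_ii` is 1.  Branch lengths are therefore in expected
substitutions per codon, which makes fitted tree lengths directly comparable
to the tree-length cutoffs used for filtering.

Transition probabilities use the reversible symmetrisation
`S = diag(sqrt(pi)) Q diag(1/sqrt(pi))`, a symmetric eigendecomposition, and
`P(t) = diag(1/sqrt(pi)) V e^(Lambda t) V' diag(sqrt(pi))`, with negative
entries (rounding noise) clipped at zero.  Likelihoods are computed by
Felsenstein pruning over unique codon site patterns; the model is reversible,
so the rooting of the (conceptually unrooted) tree is arbitrary and the code
verifies root invariance.

### Branch models and fitting

Two model classes are fitted: `one_ratio` (a single omega for the whole
tree) and `two_ratio` (a separate omega on branches tagged foreground —
here always the terminal branch leading to clade C or clade D).  Parameters
(branch lengths, kappa, omega per class) are optimised on log scale with
bounded L-BFGS-B.  Initial branch lengths come from a codon p-distance
heuristic (terminal branches at half the closest-neighbour distance);
kappa starts at 2 and omega at 0.4, with multiplicative log-normal jitter
across restarts (3 by default, seeded).  Omega and kappa are bounded in
[1e-6, 999]; an omega estimate at the upper bound is reported as infinite,
matching the reporting convention of the codeml program this component
replaces.  For two-leaf alignments only the path between the leaves is
identifiable, so one branch is optimised and the other pinned near zero.

Codon frequencies support `equal`, `F1x4` and `F3x4` (position-specific
empirical nucleotide frequencies; the default, as in codeml).  A small floor
(1e-8 before renormalisation) keeps codons observed in short alignments off
zero frequency.

The branch test fits both models and refers `2(lnL_alt − lnL_null)` to
chi-square with one degree of freedom (one-sided; no mixture correction).
Negative differences from numerical noise clip to zero.  Type-I error of
this procedure is checked by simulation under the one-ratio null: the
empirical rejection rate at nominal p < 0.05 must fall in [0.03, 0.07]
over 500 replicates of 300-codon alignments.

### Pairwise dN/dS

For two-sequence ortholog groups, (t, kappa, omega) are fitted by ML on the
single connecting branch, and t is decomposed into dN and dS using the
substitution-flux split of the fitted matrix and the site proportions implied
by the omega = 1 matrix: `dN = t·rhoN / (3·rhoN1)`, `dS = t·rhoS / (3·rhoS1)`.
Identical sequences report dN = dS = 0 with an undefined ratio; dS = 0 with
dN > 0 reports an infinite ratio.  The ML route (rather than a counting
method) is an assumption; the published analysis does not state which
pairwise mode it used.

## Synthetic codon alignments

The simulator inverts the inference model: root codons are drawn from pi and
each branch applies the exact transition kernel `exp(Qt)` of its omega
class, sampling child codons directly from transition-matrix rows.  This is
exact and fast; no stop codons can be emitted because the chain lives on the
61 sense codons.  An auxiliary Gillespie mode simulates the jump chain
explicitly and records realized synonymous/nonsynonymous substitution counts
per branch — used only in tests that compare realized flux against the
expectation `sum_i pi_i q_ij` computed directly from the rate matrix.

The fixed 4-taxon topology is ((B,C),D,A) with default branch lengths of 0.2
substitutions per codon — the magnitude that puts 4-taxon tree lengths near
1, comfortably inside the tree-length filter, while leaving enough
substitutions for recovery tests.

## Community profiling

Six synthetic marker references (ITS1, ITS2, cp23S for each of clades C and
D) stand in for the clade-diagnostic loci: 320–702 bp, ~15% pairwise
divergence between clades, with deliberately unequal lengths per locus so
the estimator's length normalisation is genuinely exercised.  They are
generated deterministically and are not biological sequences.

Reads are classified by best ungapped alignment over every start position on
both strands of all six references.  Acceptance requires:

* mismatch fraction ≤ 0.10 (the "about 10% divergence" mapping tolerance),
* aligned length ≥ 25 bp (reads under 20 bp are discarded upstream),
* the winning reference beats the best alternative by ≥ 2 mismatches.

The last rule is a surrogate for a mapping-quality ≥ 30 cutoff: MAPQ
expresses uniqueness of placement, and a mismatch margin is the ungapped
analogue.  Duplicates are defined as identical (locus, clade, strand,
5′ start) — the operative criterion of MarkDuplicates for single-end reads —
keeping the longest read, then the lexicographically first id.

Per-locus clade-D proportions are length-normalised count ratios
`(n_D/L_D) / (n_C/L_C + n_D/L_D)`.  A library's profile is the arithmetic
mean and sample (n−1) SD across the loci with data; loci with no accepted
reads are omitted from the mean rather than counted as zero.  Libraries
averaging ≥ 95% of one clade with ≥ 25 accepted reads are pooled for that
clade's assembly; below 25 reads the assignment is flagged low-confidence
(the published analysis excluded a 20-read library without stating a
threshold; 25 is configurable).

The read simulator draws a read's clade per locus with probability
proportional to mixture weight × reference length, uniform start positions,
uniform substitution errors (no indels, no quality model), and emits a
configurable fraction of exact duplicate copies.

**Known limitation — dedup at saturating coverage.**  Position-keyed
duplicate removal is correct at the coverage of real libraries (tens to
hundreds of marker reads) but breaks down when reads saturate the ~300–650
valid start positions of these short loci: non-duplicate counts then pin at
the number of occupied starts and every proportion estimate is driven toward
0.5.  This is a property of position-based deduplication itself, not of the
implementation.  The estimator-calibration suite therefore simulates without
PCR duplication and profiles with `deduplicate=False`, isolating
classification plus normalisation, while dedup behaviour is tested
separately at realistic coverage where the planted duplicate fraction is
recoverable.

## Contig joining

Contigs are placed by their single top-scoring qualifying hit (≥ 100 bp,
≥ 85% identity; ties break to the longer hit, then the lexicographically
smaller reference).  Within a reference group, sorted by interval start,
contigs merge left-to-right when intervals overlap or abut with a gap of
exactly zero bases — "directly adjacent" is read literally; any positive gap
blocks joining — and any overlap region is ≥ 95% identical.  Overlap
identity is computed on reference-coordinate-aligned segments without
realignment, since the hits already fix the alignment frame.  Disagreements
within an overlap resolve toward the member with the higher hit identity
(ties toward the left).  Minus-strand placements are reverse-complemented
before grouping; groups mixing orientations are left unjoined.

## Ortholog pipeline

ORFs are the longest stop-free codon run over all six frames (no start-codon
requirement, since transcript fragments are usually incomplete).  A call is
kept only if it has homology support or is ≥ 200 aa — the two retention
categories of the original protocol.

Orthology is unique reciprocal best hits: a pair is kept only when each
sequence is the other's single best-scoring match, and ties discard the gene
(paralog-safe).  This deliberately does not reproduce InParanoid's inparalog
clustering or bootstrap scores — only top-pair relations feed the group
rules.  CD pairs grow to BCD when both members share one clade-B best hit,
and to ABCD when they additionally share one clade-A hit; a B or A sequence
already claimed by another group causes a logged fallback so that every
sequence belongs to at most one group.  An optional outgroup filter drops
pairs whose outgroup similarity exceeds the within-pair similarity.

Protein alignment is global Needleman–Wunsch with BLOSUM62 and affine gaps
(open 11, extend 1; a gap of length k costs 11 + k), with a deterministic
traceback preference of match over gap-in-second over gap-in-first.  The
multiple case merges profiles progressively in the fixed order D, C, B, A —
a documented simplification of guide-tree progressive alignment, chosen for
determinism.  Codon threading back-translates the protein alignment,
removes every column containing a gap, and removes codon columns where any
taxon carries an in-frame stop, after verifying that each protein translates
its CDS exactly.

The tree-length filter runs one-ratio fits and admits a group when total
tree length ≤ 2 × n_taxa substitutions per codon (8/6/4 for 4/3/2 taxa),
cascading 4 → 3 → 2 taxa by dropping clade A then clade B, and excluding
groups that fail the 2-taxon bound.

Pairwise divergence counts transitions P and transversions Q over positions
where both rows are unambiguous A/C/G/T (any other symbol, including IUPAC
codes and gaps, excludes the position) and reports the raw distance P + Q and
the Kimura 2-parameter distance `d = −½ ln((1 − 2P − Q)·sqrt(1 − 2Q))`,
flagging saturation when the log argument is nonpositive.  Substitution
rates divide divergence by twice the divergence time; per-generation values
are reported under both conversions — the dimensionally correct
`per_year × g/365.25` and the generations-per-year convention
`per_year × 365.25/g` — because published per-generation figures for these
divergences follow the latter, and no intent is guessed.

## Multiple testing and enrichment

BH FDR uses the standard step-up with enforced monotonicity (via
statsmodels).  SGoF counts F = #{p ≤ alpha} and declares one discovery at a
time while the exact binomial tail P(X ≥ F | n, alpha) remains ≤ alpha,
decrementing F after each declaration; discoveries are the smallest raw
p-values with id-order tie-breaking.  The exact binomial metatest is used
rather than the large-n G-test of the original SGoF software; at desk scale
exactness is preferable and the difference vanishes for large n.  GO
enrichment is an upper-tail hypergeometric test per term with ≥ 1 study hit,
BH-adjusted across terms; annotation maps are treated as flat — no
propagation up the GO graph, which a full GO tool would perform.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the study's inputs — mixture
reads with error and duplication, codon alignments under the fitted model
family, planted ortholog universes and tiling contig layouts — under the
study's thresholds.  They do not emulate real Illumina error profiles,
indels, rRNA copy-number variation between clades, expression-level
differences, assembly artefacts, or alignment error between highly diverged
taxa.  Passing tests therefore demonstrate that the implementation is
correct and calibrated under its model assumptions, not that those
assumptions hold for any particular real dataset.  Transcriptome-scale
published results (numbers of significant orthologs, median divergences)
require the original sequencing data and are out of scope; what is
reproduced exactly is the arithmetic of the published per-library community
table and the method-level calibrations above.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to make
the statistical checks decisive: 500 null replicates of 300 codons for LRT
calibration (the script reports a 300-replicate rate), 10 replicates of
2,000 codons for omega recovery, 5,000 reads per locus for the community
grid, and 1,000 random p-vectors for the SGoF oracle comparison.
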