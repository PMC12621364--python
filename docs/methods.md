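# Methods

## Data model and coordinates

The package analyses a hybrid trio of clonally propagated cultivars:
parents CF (haplotypes CF1, CF2) and SB (SB1, SB2), and their progeny
CS whose phased haplotypes CSCF and CSSB descend from CF and SB
respectively. All six haplotypes are paths of one sequence graph per
chromosome; a node is a sequence segment, an oriented walk over nodes
spells a haplotype. Internally every coordinate is 0-based half-open on
a haplotype path; the 1-based conventions of CX reports and GFF3 are
converted at the I/O boundary, BED stays 0-based half-open.

Position projection between paths goes through the node containing the
source position: if that node occurs exactly once on the target path,
the within-node offset is carried over (mirrored under opposite
orientation); otherwise the projection is *none*. Returning none for
repeated nodes, rather than picking the first occurrence, is a
deliberate choice — an ambiguous mapping is discarded, not guessed.

## The synthetic trio generator

The generator is the package's ground-truth instrument, not a fixture.
An ancestral chromosome (default GC content 0.40) is mutated
independently into the four parental haplotypes: per-bp SNPs (default
5·10⁻³ per haplotype), small indels (5·10⁻⁴, geometric lengths ≤ 10 bp)
and a configurable number of structural indels (50–150 bp). Overlapping
events are resolved greedily left-to-right, and the terminal bases stay
unmutated so every path begins and ends on a shared node. CSCF copies
one CF haplotype and CSSB one SB haplotype whole (no within-chromosome
recombination by default; optional breakpoints exist behind a config
flag). The graph is built directly from the event table: shared
ancestral segments become shared nodes and each distinct allele at an
event becomes a branch node, so the truth coordinate maps between
haplotypes are exact by construction and serve as oracles for
projection, variant extraction, porting, and window geometry.

Methylation is a two-level mixture: a cytosine in the methylated state
reports at 80% (μ_m), an unmethylated one at 2% (μ_u). State
assignment is per site and per haplotype, Bernoulli with per-context
probabilities (defaults CG 0.5, CHG 0.3, CHH 0.05 — free parameters of
the generator chosen to give abundant CG/CHG methylation and sparse CHH
methylation as in typical plant methylomes; they are not estimates of
any real genome). CS sites inherit the state of the copied parental
haplotype and flip with the epimutation probability ε (default 0.01).
Per clone, the site level is perturbed by N(0, 2 pp) and clipped to
[0, 100]; coverage is Poisson (mean 30) and methylated counts binomial.
The two-level mixture (rather than a beta distribution) makes truth
differentials unambiguous: a planted parental differential is exactly
μ_m − μ_u = 78 points.

Scenario switches layer on this base:

- `state_block_bp` draws one state per 200 bp ancestral block, context
  and haplotype (regional methylation), which makes whole windows
  uniformly methylated or not;
- `planted_diff_fraction` forces a fraction of blocks to a full
  parental differential (CF methylated / SB unmethylated, or hap1/hap2
  within each parent in `intra` mode), CS inheriting as usual;
- `ancestral_block_states` draws a single state per ancestral block
  shared by *all* haplotypes and contexts — the no-differential null
  and the substrate for the bias scenario;
- `ct_snp_fraction` plants C>T (G>A on the minus strand) transitions on
  the SB lineage at cytosines of methylated blocks, emulating the
  deamination-derived substitution load that makes single-reference
  methylation calls misleading.

What the generator does **not** emulate: read-level bisulfite data (no
FASTQ, no mapper, no conversion failure — conversion is assumed
perfect), sequencing error, M-bias, clone-private genotypes (clones
share the genotype by default), centromeres/repeat expansions, and
realistic linkage between methylation and sequence composition beyond
the context probabilities. Passing tests therefore demonstrate that the
pipeline's logic recovers known truth under its stated model, not that
the model captures every property of real bisulfite data.

## Single-reference bias emulation and correction

Mapping a sample onto a diverged linear reference is emulated at the
call level through the positional alignment of the two haplotypes
(shared segments, identical alleles, and equal-length substituted
alleles): reference cytosines at aligned positions keep the sample's
counts; where the sample carries the C>T (G>A) transition of a
reference cytosine all reads are emitted as unmethylated (coverage
drawn at the sample's mean); reference positions that are deleted,
inserted-only, or carry a non-transition substitution are dropped. The
correction tiles the reference into 200 bp chunks, projects them
through the graph onto the sample's own haplotype (projected length
150–250 bp, ambiguity dropped), and replaces the chunk's
single-reference calls with the sample's own. Region groups follow the
pre/post contrast: *corrected* (≥ 75% only after porting, delta ≥ 20),
*original* (≥ 75% only before), otherwise *low delta* (< 20) or *high
delta*. Region means are computed per context and over all contexts;
both are emitted.

In the evaluation, a "truly-methylated biased region" is one whose
sample-side truth level is ≥ 75% *and* whose planted substitutions are
expected to depress the single-reference estimate by at least the
20-point delta of the grouping (truth level × hidden-cytosine
fraction ≥ 20). Regions that are methylated but barely hit by
substitutions are not biased in any detectable sense and are excluded
from the recovery denominator.

## The differential methylation test

The sample unit is the clone: per window and context, counts are summed
over all united cytosines in the cultivar's projected intervals on both
of its haplotypes, giving three (m, n) pairs per cultivar (single
haplotype in the intra-cultivar mode; this pooling is the central
modelling decision — the alternative of testing CS haplotypes
separately is available through explicit group definitions). The test
is the binomial logistic likelihood-ratio: the full model fits one
pooled proportion per group, the null one overall proportion; the
deviance is referred to χ²₁ after division by the Pearson
overdispersion estimate φ (computed under the fitted group proportions
with N−2 degrees of freedom) whenever φ > 1. Degenerate 0·log 0 terms
are defined as 0, so fully separated and fully identical windows get
exact answers (p → 0 and p = 1). Multiple testing uses
Benjamini–Hochberg per comparison × context. Calls require q < 0.01
and a context-specific absolute differential: 20 points for CG and
CHG, 10 for CHH.

Window geometry: 200 bp tiles on both CS haplotypes (a terminal tile is
kept from 150 bp), each projected endpoint-wise onto every haplotype;
a window is dropped when any projection fails, any projected length
leaves [150, 250] bp, or any haplotype has fewer than 3 united
cytosines. Windows reachable from both CS haplotypes are deduplicated
by the identity of their covered node range, CSCF tiling first.

Inherited sets: iCF contains windows significant with the same sign in
CS-vs-SB and CF-vs-SB; iSB the same for CS-vs-CF and SB-vs-CF. With
whole-haplotype inheritance and a parental differential, the diploid CS
level is intermediate, so a planted window typically qualifies for both
sets; the evaluation counts assignment to either as correct.
Intra-cultivar concordance compares, for each within-parent DMR, the CS
level on the CS haplotype derived from that cultivar (CSCF for the CF
comparison) against both parental haplotype levels; the DMR is
concordant when the smaller delta is below the context differential
threshold.

## Node classification

Nodes (chopped to ≤ 200 bp) are classified among the haplotypes that
contain them — or, in methylation mode, among the haplotypes in which
the node is methylated. "Methylated in a haplotype" means at least one
united cytosine in the node with across-clone mean level ≥ 20%; the
node-level rule is a package decision (the region-level literature uses
site thresholds) and the threshold is configurable. Presence classes:
*core* (all six haplotypes), *private* (haplotypes of one cultivar),
*dispensable* (anything between — two or more cultivars without
reaching all six; spanning three cultivars with fewer than six
haplotypes counts as dispensable so the partition stays exhaustive).
Cultivar classes follow the all / intra / inter legend. A cultivar-level
(three-group) reduction is also emitted, since both reductions are
useful and neither is canonical.

## Gene-level rules

gbM: mean exonic CG level ≥ 20% with exonic CHG and CHH below 20%.
teM: mean ≥ 5% in all three contexts and not already gbM. Genes missing
exonic sites in a required context are classed *other* and flagged.
Metagene profiles use 100 bins per segment (upstream 1 kb, body,
downstream 1 kb), strand-aware, averaging site levels per bin within a
gene and then across genes; empty bins stay missing, and genes shorter
than the bin count simply get fractional bin widths. The promoter is
3 kb upstream of the TSS, clipped at the sequence start. DMR annotation
uses the priority exon > intron > promoter > repeat > intergenic for the
single-label summary — a decision, since exclusive category counts need
a precedence — and emits the raw per-feature overlap flags so any other
precedence can be recomputed. SV proximity pairs DMRs with indels
≥ 50 bp within 1 kb (overlap = *within*, otherwise *proximal*) and runs
a Fisher test of TE-containing DMRs against large-deletion impact.
Allelic pairs project each gene's span onto the other haplotype,
require ≥ 50% overlap of the projected span with a native gene, and
keep only reciprocal matches; unpaired genes are categorized
unprojectable / no_overlap / unidirectional.

## Numerical and design choices

- Benjamini–Hochberg is used for q-values throughout
  (`scipy.stats.false_discovery_control`).
- The Fisher enrichment test for C>T (plus G>A) in the corrected group
  is one-sided (greater), against all other groups pooled.
- Variant extraction anchors on nodes that occur exactly once on both
  paths; bubbles whose interior still contains nodes shared by both
  paths are reported as OTHER rather than recursively decomposed.
  Adjacent simulated variants (no shared base between them) merge into
  a single MNP/INDEL record; the evaluation therefore scores
  non-adjacent variants, where recovery is exact.
- GFA: v1 S/L/P records; GFA 1.1 W lines are accepted on read and
  normalized to paths named `sample#haplotype#sequence`. L lines are
  inferred from path adjacency when absent.
- Coverage normalization across clones (median-ratio scaling) is not
  applied by default; uniting keeps per-clone counts untouched because
  the test consumes raw counts.
- Problem sizes in the evaluation suite: 50 kb × 2 chromosomes for the
  50-trio graph-integrity sweep; 450 kb for the null calibration
  (≈ 4,200 retained windows); 100 kb for inheritance, intra-cultivar
  and bias scenarios; 250 kb / 100 genes for the classifier check;
  30 kb × 20 replicates for the node-sharing signal. These sizes give
  stable rates with comfortable statistical margins while keeping a
  full run around a minute.

## Known limitations

- The graph builder assumes non-overlapping events on the ancestral
  axis; truly nested variation only arises in hand-built graphs, where
  it is classified OTHER but not decomposed.
- `project_position` is exact but node-granular: positions inside a
  shared node project even when flanking context differs; there is no
  base-level realignment.
- The overdispersion correction reproduces the standard
  McCullagh–Nelder scaling, not any specific package's internals
  bit-for-bit; the stated formula is the contract and the tests enforce
  it against an independent likelihood oracle.
- With per-site independent states the null of "no *systematic*
  differential" still contains sporadic real differences at
  haplotype-private sites; the calibration scenario therefore uses
  block states shared by all haplotypes, which is the exact null.
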