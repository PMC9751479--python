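# Methods

`ervkit` characterizes HML2 (HERV-K) endogenous retroviruses in primate
genomes: it finds proviral loci, assigns them to cross-species orthology
categories, dates their integration from LTR divergence, annotates
their structure and residual coding capacity, classifies env subtypes
and variants, detects env recombination with the HML8 LTR MER11A, and
builds bootstrapped neighbor-joining trees.  Because the real primate
assemblies this kind of analysis runs on are far beyond desk scale, the
package ships a cohort simulator that plants proviruses with a complete
truth table; every stage is validated against that truth.

## The reference provirus model

The model mirrors the canonical HML2 prototype: an 8,000-nt internal
coding region flanked by two identical 968-nt LTRs.  Gene coordinates on
the internal sequence are the published prototype values (1-based
inclusive): gag 156–2,297, pro 2,063–3,082, pol 3,037–5,785, env
5,624–7,951; the gene overlaps are real features of the prototype and
are preserved.  Protein domains (MA/CA/NC in gag, RT/RH/IN in pol,
SU/TM and the Rec portion with its NLS and NES in env) are fixed,
documented intervals nested in their genes.  The sequence itself is
synthetic: random DNA at the observed 41 % GC, constrained so that all
four gene frames are stop-free, the nucleocapsid carries exactly two
zinc-knuckle motifs (CX2CX4HX4C), and Rec carries exactly one NLS and
one NES peptide.  Because the published sources do not print the motif
peptide sequences, NLS ("RKQRRSRRK") and NES ("LQLPPLERLTL") are fixed
synthetic peptides recorded in the model so that motif scanning is
well-defined.  Two documented placements are choices of this package:
the Rec portion sits at env codons 60–160 (downstream of the pol/env
overlap, so pol-frame constraints cannot disturb its motifs), and the
292-nt type-I env deletion is anchored at internal position 5,800 so
that it guts the 3′ half of Rec — type-I proviruses thereby lose Rec
capacity, as they do in reality.

The LTR is generated CpG-free.  Primate DNA is strongly CpG-depleted,
and this choice makes the CpG-masked LTR clock exact on simulated data:
masking removes nothing from an LTR pair, so a planted divergence is
recovered bit-for-bit (see Dating).  The internal region keeps CpGs, so
the masking code is exercised there and in unit tests on constructed
strings.

## The cohort simulator

A locus is built in three steps.

1. **Lineage profile.**  The reference internal sequence receives the
   lineage's signature edits: macaque copies get the recurrent 12-nt
   deletion at gag 156–167 and a 96-nt insertion anchored at reference
   position 745 (printed as "between 745–838"; implemented as 96 novel
   nucleotides at the 745 anchor — an interpretation, documented here);
   human copies get the insertion with probability 0.27 and no
   deletion.  Env edits: type I (human only) deletes 292 nt at the
   fixed anchor; variant 2 inserts 191 novel nt in the transmembrane
   region; variant 3 (macaque only) replaces the env interior — all but
   a 150-nt 5′ stub and a 120-nt 3′ stub — with a contiguous 673-nt
   stretch of the synthetic MER11A parent.
2. **Clock divergence.**  Each carrier species' copy accumulates
   substitutions at 0.34 %/nt/Myr for the locus age T.  Each LTR copy
   receives exactly round(968·0.0034·T) substitutions, site sets
   disjoint between the two LTRs and no site hit twice, so the 5′–3′
   LTR p-distance equals 2·0.0034·T up to rounding and dating is exact
   by construction; a real saturation correction is deliberately out of
   scope.  Substitutions never create a CpG in their own sequence,
   never fall inside planted motifs, and never create stop codons in
   frames the locus is meant to keep open — a minimal stand-in for the
   purifying selection that keeps such features recognizable.  An
   optional CpG-boost factor adds extra C→T hits at internal CpG sites
   to exercise the masking logic; it is off by default so the
   acceptance arithmetic stays clean.
3. **Insertion.**  The provirus is wrapped in a 6-nt target-site
   duplication and 200-nt flanks.  Orthologous copies share ancestral
   flanks, then each species' flank is mutated at a fixed per-lineage
   neutral divergence (human 3 %, each macaque 0.75 %), giving ≈6 %
   human–macaque and ≈1.5 % macfas–rhesus pairwise flank divergence —
   the values flank-based orthology calling faces in real assemblies.
   (Running the 0.34 %/Myr clock on flanks for 32 Myr would give ≈22 %
   pairwise divergence, far beyond both reality and any workable flank
   identity threshold; the clock is a dating convention, not a model of
   total neutral divergence over deep time.)  Loci are embedded on one
   contig per species in random spacer DNA, random strand per copy;
   solo LTRs are planted as single mutated LTR copies.

The default cohort is 12 human-shared, 46 macaque-shared and 19
macfas-specific loci (the published per-category pattern) at the
published macfas median ages 32.4, 15.7 and 5.6 Myr, plus one solo LTR.
The truth table records, per planted copy: interval, strand, category,
age, env type/variant, planted indels, recombination span, solo-LTR
flag, and coding-intactness flags (a configurable fraction of copies
gets a premature stop planted in gag CA or pol RT; env of variants
1 receives one in TM, since no individual macaque env was found
coding-competent, while the Rec portion is always left intact for
variants 1–2).

**What the simulator does not model** — and what passing tests
therefore do not show about real data: multiple hits and saturation;
rate heterogeneity; shared pre-speciation lineage mutations (each copy
diverges independently from the ancestor, so old categories are
internally diffuse rather than clade-like — the category-separation
test uses the young-vs-old contrast that survives this); segmental
duplication and tandem repeats; realistic base composition beyond the
GC target; solo-LTR formation by recombination (solo LTRs are planted
directly).

## Discovery and orthology

Discovery is seed-and-extend: every 16-mer of the reference LTR and
internal sequence (both strands) is indexed; exact matches in the
genome are chained within a 2-kb gap, and a chain is kept if its
matched internal span reaches 500 nt or its matched LTR span reaches
300 nt with at least 3 seeds.  The LTR-span/seed-count floor is what
drives chance seeds to zero: a megabase of random DNA yields a handful
of isolated 16-mer hits, and all are rejected.  Exact seeding suffices
because even 25 % divergence leaves abundant intact 16-mers in a 10-kb
element.  Locus boundaries are estimated from the seeds' implied
element edges — taken from the LTR seeds of each side, which carry no
indels, with internal seeds as fallback — so boundary error is zero on
simulated cohorts even for rearranged loci.

Orthology follows the flanking-sequence logic: strand-aware 200-nt
flanks are extracted, candidate cross-species pairs are screened for a
shared exact 24-mer, screened pairs are aligned by edit distance
(edlib), and pairs whose mean up/downstream flank identity reaches 0.9
are merged single-linkage (the transitive closure makes grouping an
equivalence relation).  A group containing the outgroup (human) is
human-shared; a multi-species group without it is macaque-shared;
singletons are species-specific; loci whose flanks run off the contig
are flagged unclassifiable rather than dropped.

## Alignment and projection

All structural comparisons go through a reference-anchored pairwise
projection instead of a progressive multiple alignment: each locus is
globally aligned to the reference provirus with an affine-gap Gotoh
aligner and laid out in reference coordinate space (per reference
position: locus base or gap; novel bases in an insertion store keyed by
anchor).  This is a deliberate divergence from MSA-based workflows and
is adequate because every downstream comparison is locus-vs-reference
or column-wise over shared reference positions.

The pairwise aligner scores match +2, mismatch −3, gap open −5, gap
extend −2 (a gap of length L costs open + L·extend), with deterministic
traceback tie-breaking; 'N' mismatches everything.  For long sequences
the DP runs in a banded corridor around the length-scaled diagonal; the
default half-width (800 nt, widened by the length difference) was
verified against wider bands on the largest planted rearrangement.
Projection alignments raise the gap-open penalty to −16: a long novel
insertion must stay one event rather than fragment around chance
few-base matches to the reference, which is what indel cataloging
depends on (the same reason structure-aware MSA tools use stiff gap
costs).  Indel calls take maximal gap runs as deletions and insertion-
store runs as insertions; anchors are reported in the conventional
1-based internal coordinates with a documented ±2-nt alignment
ambiguity.

## Dating

p-distance uses pairwise deletion (sites gapped or 'N' in either
sequence are excluded) and CpG masking: any position that is part of a
CG dinucleotide in *either* sequence is excluded from sites and
mismatches (a reference-only variant is available by flag).  The clock
is T = D%/0.34, halved for LTR-vs-LTR because both LTRs mutate
independently.  Four estimators are implemented: LTR-vs-LTR,
single-LTR-vs-consensus (the two LTRs' estimates averaged),
gag-vs-consensus and pol-vs-consensus.  Consensus building is plurality
per reference column among non-gap members, ties broken toward the
reference base, columns gapped in a majority emitted as gap.  Age
summaries report n, median, quartiles (linear interpolation, numpy's
default) and range per category.  The single-site quantum of the
968-nt LTR pair is ≈0.15 Myr; calibration over ages uniform in (1, 35)
Myr shows mean signed error within ±2 % for the LTR estimators.
Jukes–Cantor/Kimura corrections and confidence intervals are
out of scope.

## Coding capacity and env classification

ORF integrity reads each gene in the frame of the reference gene start
mapped through the projection: premature stops are counted in the
observed (indel-spliced) sequence; "frameshift" is defined as net
in-gene indel length not divisible by three (the net-phase definition
makes the flag invariant to where the indels sit); a gene is intact iff
it has no premature stop, no frameshift, and ≥95 % coverage.  Domain
presence is ≥90 % coverage of the domain span.  Rec detection requires
≥95 % Rec coverage and net phase 0 inside Rec (Rec is read anchored at
its own codon-aligned start, mirroring the spliced rec message), then
scans the Rec translation for the NLS and NES peptides.

Env classification, in precedence order: a parent-B (MER11A) run of
≥300 nt from the recombination segmentation calls variant 3 (the
replacement destroys the other signals' context); else a 150–250-nt
insertion inside TM calls variant 2 (window tolerates alignment
slippage around the printed 191); else variant 1.  Independently, a
280–300-nt deletion within 50 nt of the type-I anchor calls type I,
else type II.  Conflicting evidence keeps the precedence result and
flags the call.

## Recombination segmentation

Both parents (HML2 env reference; MER11A) are aligned to the query;
each query position costs 0 if it matches the active parent's aligned
base, 1 otherwise (parent gap = mismatch, keeping the DP alphabet-
free).  A two-state DP with switch penalty σ (default 3.0 ≈ four
informative sites per switch; no published parameterization exists to
copy) yields the minimal-cost labeling; forward/backward costs identify
runs where either label is optimal, and breakpoints falling in such
runs are reported at the run midpoint with the ambiguity interval
retained — if midpoint placement would change the total cost, the
canonical traceback stands.  An exhaustive oracle over all ≤2-switch
labelings verifies the DP on small instances.  Statistical significance
of recombination (permutation p-values) is out of scope.

## Phylogenetics

Distance matrices are pairwise-deletion p-distances over shared
reference columns.  Neighbor joining is the Saitou–Nei agglomeration
with deterministic lowest-index tie-breaking; negative branch-length
estimates are clamped to zero with a warning.  On additive matrices the
generating topology and path lengths are recovered exactly (tested
against a tree-path oracle and cross-checked against scikit-bio's NJ).
Bootstrap resamples reference-projected columns (one shared coordinate
space; per-sequence CpG masks are computed on the original adjacency
and carried through resampling), default 500 replicates; support is the
percentage of replicate trees containing each split, written as
internal-node labels in Newick.  Trees are emitted unrooted.

## Problem sizes and reproducibility

All randomness flows from one explicit seed through named substreams
(stable under stage reordering); reruns of any stage, or of the whole
pipeline, are byte-identical.  The test suite exercises cohorts of
10–20 loci and genomes up to one megabase; the acceptance script
simulates single loci for the structural targets and, for the dating
targets, cohorts of 12/46/19 LTR pairs across ten seeds — sizes chosen
so the planted medians are estimated from the same per-category locus
counts the published analysis reports.  All thresholds (seed length,
span floors, flank identity, coverage cut-offs, length windows, σ,
bootstrap replicates) live in the flat YAML config; unknown keys are
errors, and each run directory serializes its config, seed and stage
log for provenance.
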