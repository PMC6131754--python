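# Methods

## Coordinate model

All internal coordinates are 0-based, half-open intervals on the forward
strand; conversion happens only at the I/O boundary.  UCSC chain records
with a `-` query strand are flipped to forward-strand query coordinates
during parsing (within a flipped block, reference base *r+k* pairs with
query base *q+size−1−k*); writing restores the original representation,
and inverting a chain swaps the reference/query roles exactly.  Repeat
content is taken from soft-masking: the repeat fraction of an interval is
its lowercase fraction.  This is the standard carrier of repeat
annotation in distributed genome FASTA and avoids a second input track;
the 75 % threshold below is exposed rather than hard-coded.

## Enhancer filtering

Peaks distributed as point calls are re-centred to a fixed width (1000 bp
by default) around `floor((start+end)/2)`, clipped at sequence boundaries
(clipped records are flagged and may be shorter than requested).  Records
longer than `max_length` (default 3000 bp) or with repeat fraction above
`max_repeat_fraction` (default 0.75) are removed; both thresholds are
*inclusive* — a record exactly at the limit is kept, because only strict
exceedance ("longer than", "more than") is a removal criterion.  Every
rejection is logged with the rule that fired.

All interval intersections throughout the pipeline use a minimum overlap
of `min_overlap` bp (default 50).

## Orthology projection

An interval is projected through the single best-scoring chain
overlapping it (ties broken by lower reference start, then chain id); no
chain stitching is attempted, which matches the situation of pre-netted
alignments where one best chain per region is the norm.  Every reference
base inside an aligned block is mapped, and the projection is the minimal
query interval spanning the mapped bases together with the count of
aligned bases.  "Does not align" means zero projected bases; an enhancer
projecting even one base proceeds to overlap testing, where the 50 bp
rule governs functional overlap — we deliberately avoid inventing a
second aligned-fraction threshold for "aligns", and expose the aligned
base count so users can filter on it as a sensitivity analysis.

## FCE / RPE / EG classification

Genome-wide, per source enhancer, in precedence order:

1. no projected base → **EG**;
2. the projection overlaps (≥ `min_overlap`) a destination enhancer in at
   least one tissue *not* in the source tissue set → **RPE**, recording
   those tissues;
3. the projection overlaps destination enhancers only in shared tissues
   → **FCE**;
4. the projection overlaps nothing → **EG**.

RPE takes precedence over FCE because reprogramming is defined by a
*partially or fully* different tissue set.

The tissue-pair procedure is implemented literally as set algebra: within
each species, enhancers shared between tissues A and B (≥ `min_overlap`
overlap) are dropped to give non-overlapping subsets A₁/B₁; the
source-species subsets are projected (failures → EG); projections
overlapping the same-tissue destination subset are FCEs and their
destination partners are removed; the remaining source-A projections are
intersected with the remaining destination-B pool to give the enhancers
reprogrammed A→B (and symmetrically); everything left joins the EGs.
Note the two procedures can legitimately disagree on *partially*
reprogrammed enhancers (ortholog active in a shared **and** a novel
tissue): genome-wide they are RPEs, while the pair algebra drops their
multi-tissue orthologs in the non-overlap step.  Both views are exposed.

Raising `min_overlap` monotonically shrinks the genome-wide RPE count and
the combined FCE+RPE count; individual FCE counts and the pair-algebra
sets are not monotone (the non-overlapping input subsets grow with the
threshold), which is why only the provable monotonicities are asserted in
the tests.

## Motif scanning and enrichment

Scanning scores every window on both strands with the motif's log2-odds
matrix, regularised as `p' = (p + κ·bg) / (1 + κ)` with pseudocount
κ = 0.001.  Per-position scores are rounded once to an integer grid of
10⁻³ bits; windows are scored **on that grid**, and the null score
distribution under the background model is computed by position-wise
convolution on the same grid.  The p-value of a window is therefore the
exact upper-tail word probability for the discretised matrix, and the
scanner is testable against full 4^w enumeration.  Windows containing N
are skipped; a palindromic motif yields two hits (one per strand) at a
matching position — deduplication is off by default.  The default hit
threshold is p ≤ 10⁻⁴.

Overrepresentation of a motif in a region set is tested against random
control regions matched per input region for length (exactly), GC
(± 0.02) and repeat fraction (± 0.05), drawn by rejection sampling
outside the input regions (1000 attempts, then tolerances double, at most
5 times, before an explicit error).  With λ the control hit total
rescaled by region-bp / control-bp, the p-value is the Poisson upper tail
P(X ≥ observed), Bonferroni-corrected over the motifs tested; a motif is
overrepresented when the corrected p ≤ α (default 0.05).  λ is scaled by
base pairs rather than region counts so unequal control multiplicities
remain valid; a zero λ with positive observations is floored at 10⁻⁹ and
flagged.  Overlapping hits of one motif count individually, matching a
plain scanner hit count.  The non-redundant subsetting of a large motif
library is out of scope — the library is an input.

Because λ is estimated from finite controls, the realised false-call rate
under the null sits above the nominal per-test level but remains within
α after Bonferroni at the tested scales (see the calibration tests).

## TFBS evolutionary categories

Each source-side hit in an orthologous enhancer pair receives exactly one
label, precedence C > R > H > G (mapping evidence outranks presence
evidence):

- **TFBSC** — ≥ `min_mapped_fraction` (default 0.5) of the site's bases
  project, and the projection overlaps (≥ 1 bp) a destination hit of the
  same motif;
- **TFBSR** — maps, but onto a destination hit of a different motif;
- **TFBSH** — no positional counterpart, yet the same motif occurs
  elsewhere in the destination enhancer;
- **TFBSG** — none of the above.

"Same TF" is operationalised as same motif identifier; a TF-to-motif
mapping table can be applied upstream when several motifs represent one
factor.  Densities are sites per kb, pooled over all enhancers of a group
(per-enhancer means are also computable from the per-site output; pooled
is the default as it weights enhancers by length).  RPE and FCE densities
are compared per tissue pair and category with a relative tolerance of
1 % defining "equal" — without a band, equality would be measure-zero for
continuous densities.

## Gene loci and expression

Locus boundaries sit at the midpoint of the intergenic gap between
consecutive genes (`(prev_end + next_start) // 2`, which also handles
overlapping genes by splitting their overlap); first/last loci run to the
sequence ends, so loci tile each sequence.  Enhancers attach to the locus
they overlap by ≥ 50 bp, straddlers to the larger overlap (ties to the
lower-coordinate locus).  "Flanking gene" is the gene whose locus
contains the enhancer.

Expression is normalised per tissue by the median over all genes (zero
medians are an error naming the tissue).  The reprogramming shift
statistic for a tissue pair is the ratio of median normalised expression
in the tissue where the focal species' RPEs are active versus the partner
tissue, over genes whose loci contain ≥ 1 of those RPEs, with a one-sided
Wilcoxon rank-sum p-value: exact enumeration when both groups have ≤ 8
untied observations, otherwise the normal approximation with continuity
correction.  Results from fewer than 2 genes are flagged unreliable.
Locus bins pool counts above `max_bin` (default 20); the seLoci test
builds, per category, a 2×2 table of (enhancer in a single-enhancer locus
vs in a multi-enhancer locus) × (category vs not) and applies a two-sided
Fisher exact test, reporting the observed seLoci fraction next to the
overall fraction as the chance expectation.

## The synthetic scenario generator

The generator emulates the *statistical structure* of a two-species
enhancer landscape, not its biology.  Each enhancer (or small group
sharing a gene locus) occupies a unit: an optional species-A-only gap, an
optional species-B-only gap, and an aligned segment laid out as
`pad | gene | enhancers | desert` — the desert mirrors the enhancer block
so that every enhancer falls inside its own gene's midpoint-bounded
locus, and gap-hosted enhancers sit near the gap's tail for the same
reason.  Aligned segments are copied A→B with i.i.d. substitutions and
short indels (length min(Geom(0.5), 5), half insertions half deletions);
the chain blocks fall out of the copy.  Defaults: 200 enhancers of
200–800 bp on 2 × 300 kb sequences, 4 tissues, category mix
FCE/RPE/EG = 0.02/0.42/0.56 (the published human breakdown), alignment
coverage 0.7, zero divergence, 10 % multi-tissue enhancers, half of RPEs
partially (rather than fully) switched, expression fold-change 1.4 with
log-normal noise of σ = 0.5 on a common baseline of 100.  Category
counts are apportioned by largest-remainder rounding, so realised
fractions match requests up to rounding.  EGs split 50/50 between
unalignable-gap placement and aligned-but-inactive placement (all aligned
when coverage is 1).

Motif sites are planted per orthologous pair from a generated library of
sharp-consensus motifs (default 6 × 8 bp, consensus probability 0.97,
pairwise consensus Hamming distance ≥ 3 including reverse complements):
conserved sites write the same consensus at aligned positions in both
species, reused sites write two different consensi at the same aligned
span (equivalent to minimal rewiring mutations; the alignment is
untouched), reshuffled sites write one consensus at non-corresponding
positions, gained sites write into species A only.  Events in one
enhancer use distinct motifs and non-overlapping slots inside fully
aligned runs; events that do not fit are skipped and counted.  Expression
elevates each gene in the tissues where its locus enhancer is active in
that species, which reproduces the concordant-shift pattern at
RPE-flanking genes in both species.

A single RNG stream seeded from the config drives every draw in
documented order; a config reproduces its file bundle byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic neutral evolution or repeat families,
linked enhancer turnover, motif libraries with correlated/overlapping
motifs, expression count noise or mappability artefacts, and >2 species.
Recovery rates on planted truth are upper bounds for performance on real
genomes.

## Problem sizes and calibration runs

The test suite and the acceptance script use scenarios of 150–700
enhancers on 0.2–1.2 Mb toy genomes, 500 random instances (≤ 30
enhancers) for brute-force equivalence of the pair algebra, 200 simulated
datasets for the null calibration of the enrichment and shift tests, and
100 seeded runs for planted-motif power.  These sizes give stable
statistics while keeping the full suite in the low minutes on one CPU.

## Known limitations

- One best chain per region: split or rearranged orthologies project
  partially.
- The Poisson enrichment treats control counts as fixed when forming λ.
- The pair algebra intentionally mirrors the stepwise published
  procedure, including its removal semantics (FCE-matched destination
  enhancers are unavailable as reprogramming partners); a joint
  assignment could differ at contested loci.
- Percentage-of-tissue-pair verdict summaries are sensitive to the 1 %
  equality band when densities are nearly identical.
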