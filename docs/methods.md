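# Methods

## Problem and model

A coding-region VNTR is a tandem array of a unit u (here 10–1000 bp)
whose copy number differs between two assemblies of the same gene. In a
dot plot of the two alleles the array produces a family of ungapped local
matches on diagonals spaced by |u|; the block's extent on each axis is the
array span on that allele, and the span ratio r is a direct proxy for
copy-number change. `vntrscope` works on this geometry in exact sequence
space. The raster (750×750 plot area, 830×830 with axis margins) is kept
for visualization and as the interface for any external image-based block
detector; the shipped detector never quantizes to pixels, because pixel
resolution (~13 bp/px on a 10 kb window) is coarser than the period
estimate needs.

## Anchors

Anchors are found by exact 12-mer seeding followed by ungapped X-drop
extension with match +5, mismatch −4, X-drop 30, minimum segment score 70
and minimum identity 0.7. N (and any non-ACGT code) neither seeds nor
matches. Two implementation notes:

* Extension is realized as run merging: on one diagonal, maximal exact
  match runs separated by at most 7 mismatches are chained (8 consecutive
  mismatches drop the running score by 32 > 30, terminating any X-drop
  extension), and maximal-scoring sub-segments are peeled from each chain
  by a prefix-sum scan that starts and ends segments on match runs. For
  the ≥ 70-score, ≥ 0.7-identity regime this yields the same segments as
  seed-by-seed extension, deterministically and symmetrically (the
  (a,b) → (b,a) transpose maps results onto each other).
* Per diagonal, scanning is restricted to the neighborhood (±2 kb) of the
  seed hits on that diagonal. A qualifying segment at ≥ 0.7 identity
  contains an exact 12-run every few hundred bases in expectation, so the
  restriction does not lose segments; it only avoids re-scanning long
  chance diagonals end to end.

The scoring constants follow the published aligner invocation the
pipeline emulates; its four-valued, transition-aware mismatch scheme is
collapsed to a uniform −4 because nothing downstream distinguishes
transitions. The goal is equivalent sensitivity, not bit-compatibility
with any particular aligner's output.

## Chunking

Windows are 10 kb. Shorter CDS are centre-padded with N (odd remainder to
the right — an arbitrary deterministic tie-break); longer CDS are split
into full windows, a 0.1–10 kb tail is centre-padded, and a tail under
100 bp is dropped with a log message (no detectable repeat fits in it).
All chunk pairs of an ortholog pair are compared and anchors are mapped
back to whole-CDS coordinates before detection, so arrays straddling a
chunk boundary re-join: candidate regions are built in global coordinates
and bridged across sub-500 bp gaps, and adjacent candidates closer than
max(2 × unit, 500 bp) with compatible periods are merged (this same rule,
read in the other direction, keeps genuinely separate arrays — e.g. two
arrays split by a 2 kb unique spacer — as distinct blocks).

## Block detection

A position on either axis belongs to a candidate block iff anchors on at
least two distinct diagonals cover it. This is the operational definition
of "parallel lines": a unique segment, even one displaced by an indel,
lies on a single diagonal and can never enter a block, which is what
keeps shifted unique flanks out of cross-allele plots. Candidate runs
shorter than 20 bp are discarded as noise.

The fundamental period is estimated from diagonal offsets relative to the
block's dominant diagonal (largest summed anchor length; ties toward
smaller |d| — the main diagonal in a self-comparison). Candidate periods
are the distinct offsets and their consecutive differences; the smallest
candidate whose nonzero multiples explain ≥ 90% of the anchor-length
weight within ±2 bp wins, falling back to maximal coverage with ties
toward smaller period. Candidates at or below twice the tolerance are
excluded as unresolvable.

Copy numbers are span/unit per axis. Block edges are first snapped to the
unit-phase lattice voted by the off-backbone anchor endpoints (weighted
circular mode, ±2 bp) when that mode holds a majority, and the snap never
moves an edge by more than the seed length — chance extension of an
anchor past an array boundary is bounded by the crossable mismatch gap,
so larger corrections indicate a polluted vote (e.g. chunk-boundary
truncation), not a fuzzy edge. A few bases of flank that genuinely
continue the repeat period remain part of the span, which is why reported
copies can carry a small fraction (11.1 for a planted 11).

Annotation criteria:

1. more than 5 copies, strictly, counted as whole repeats
   (round(max(copies across the two alleles)) > 5), so a 5-copy array is
   rejected and boundary fractions cannot promote one;
2. regions separated by more than max(2 × unit, 500 bp) are different
   blocks (see chunking above);
3. blocks whose off-backbone anchors average under half a unit in length
   *and* cover under 30% of the bounding box are rejected as scatter.
   The judgement deliberately ignores the backbone diagonal, which is
   long regardless of whether a real array is present. The two thresholds
   quantify "ultra-short lines and points with no clear outline"; they
   are this package's choice.

Confidence is deterministic: (observed distinct diagonals of the family
{d0 + k·u} within ±2 bp) / (expected ⌊spanA/u⌋ + ⌊spanB/u⌋ − 1), times
the mean anchor coverage of the bounding box on the two axes, clamped to
[0, 1]. A noiseless exact array scores 1.0. Calls are flagged when a
block with confidence strictly above 0.80 has r < 0.9 or r > 1.1, with
r = strain span / reference span. Note the band is not symmetric under
allele swap (r → 1/r), so orientation is fixed and recorded; the swap
property is tested.

## Repeat statistics

Units are cut from a block span at the phase (0..u−1) maximizing mean
pairwise per-site unit identity, computed by column base counts; ties go
to the smallest phase. For exact arrays any rotation of the span yields
the same number of units in the same cyclic class. Overhang bases count
toward the fractional copy number only where they continue the periodic
pattern.

π is the average over unordered unit pairs of per-site differences, with
no finite-sample correction; sites where either unit carries N are
excluded from that pair's numerator and denominator. Units of unequal
length (indel-containing arrays) are compared by global (Needleman-
Wunsch) edit distance normalized by the mean of the two lengths, and the
result is marked alignment-based. GC is (G+C)/(A+C+G+T) with ambiguous
bases excluded. GC enrichment of repeat sequence over background coding
sequence uses Welch's unequal-variance two-sided t-test (the safer choice
when only "two-tailed t test" is specified); two zero-variance samples
with equal means return t = 0, p = 1 by convention.

Per-gene summaries report min/max unit length and copy number across
strains with the reference allele as a pseudo-strain. Merging of
homologous gene families into one summary block is out of scope;
summaries are strictly per gene ID.

## Haplotype painting

Queries are sliced into 100 kb fragments (a tail ≥ 10 kb stands alone,
shorter tails join the previous fragment). Each fragment is anchored to
each donor; fragment positions are counted once, under the best-scoring
anchor that reaches them, and substitutions (never indels) are counted in
non-overlapping 10 kb windows — tiled, not sliding, since density is
assessed per 10 kb. Windows with under 50% anchored coverage get an
infinite sentinel and can never qualify. A window qualifies for a donor
with strictly fewer than 3 substitutions; among qualifying donors ranked
above the query in the hierarchy (default b→k→d→a→q→c→g→z, fully
configurable), the highest wins, otherwise the window keeps the query's
label. Adjacent same-label windows merge into segments, which partition
the query.

## Synthetic data

All randomness flows through numpy's PCG64 (`np.random.default_rng`), a
stable, portable generator; identical seeds give byte-identical fixtures.
The generator plants what the scan is built to find: a shared ancestral
unit tandemly repeated with i.i.d. per-site substitutions at a stated
per-copy divergence, embedded in flanks shared between alleles and
rejection-sampled to contain no repeated 12-mer internally or against the
array — negative controls are therefore truly negative at the seed scale.
Genome pairs place single- and multi-exon genes on both strands with
random introns and intergenic spacers; the stated fraction of genes gets
a copy-number difference of at least 3 units (r well outside the band),
the rest differ only by background SNPs at 0.1%. Mosaic haplotypes
concatenate syntenic donor segments and plant an exact per-window number
of noise substitutions.

What the generator does not emulate: real base composition and repeat
landscape (transposons, low-complexity runs), unit indels by default
(an indel rate would exercise the alignment-based π path), assembly
errors, or annotation noise. Passing tests therefore demonstrate the
geometry and the rules, not robustness to dirty assemblies.

Problem sizes used by the test suite and acceptance script are chosen to
exercise the stated parameter ranges at desk scale: recovery runs sample
unit lengths 10–990 and copy numbers 6–600 jointly with arrays capped
near 12 kb (so both marginal extremes appear and chunk-boundary merging
is exercised), 1 kb flanks, and divergence up to 5% per unit; painter
runs use 100–200 kb donors with ~20–25 private SNPs per 10 kb.

## Known limitations

* Units shorter than the seed scale (< ~7 bp, and microsatellites
  generally) are invisible by design; the method targets VNTRs long
  enough to draw visible lines.
* Two arrays of the *same* unit separated by a unique spacer shorter
  than the gap rule merge into one block; distinct units do not.
* r is computed on spans, so a fixed-length insertion inside an array
  (not a copy-number change) also perturbs r; the confidence term damps
  but does not eliminate such cases.
* Copy numbers inherit a boundary ambiguity of a few bases where flank
  sequence happens to continue the repeat period; accuracy is ±0.5 copy
  across the tested ranges but the fractional part is not meaningful
  below that scale.
* The painter assumes donors are syntenic and colinear with the query at
  the window scale; rearranged donors surface as unaligned windows, not
  as errors.
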