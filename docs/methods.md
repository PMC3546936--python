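# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, the design of the synthetic-data generator,
and the known limitations.

## Conventions

* Internally every sequence is canonicalised to the uppercase DNA alphabet
  (U → T); RNA-convention output (e.g. substitution classes `A-to-G`,
  tail bases) converts back at the boundary.
* Genomic coordinates are 1-based inclusive on the forward strand.  The
  printed locus string is `ref∶start.end:strand` (with the ratio character
  U+2236 as the first separator); the parser also accepts an ASCII colon
  and Unicode minus signs, so published coordinate strings round-trip.
* All randomness flows from one master seed.  Per-stage generators are
  spawned with `numpy.random.SeedSequence`, so adding a stage never
  perturbs the streams of existing stages.

## Read preprocessing

The 3' adapter is located as the leftmost position where the read matches
a prefix of the adapter, requiring at least 6 matched bases; matching is
exact.  Reads without an adapter hit, with ambiguous (N) bases, or with
inserts outside the 15–26 nt window are discarded into named accounting
categories; remaining reads are collapsed to unique tags and tags with
fewer than two copies are dropped (`min_copies=2`; configurable).  The
accounting object enforces `raw = clean + Σ removals` with an assertion —
read conservation is a run-time invariant, not just a test.

## ncRNA filtering and genome mapping

Both stages use ungapped matching on both strands.  Candidate alignment
positions come from an exact pigeonhole argument: a tag aligned with at
most *k* substitutions must contain one of *k*+1 contiguous chunks
verbatim, so chunk lookups followed by base-by-base verification
enumerate exactly the loci an exhaustive scan would.  The test suite and
the acceptance script verify this equivalence against an independent
full-window scan.

Mapping tolerates ≤ 1 substitution overall and ≤ 1 in the first 18 nt of
the tag (as read, i.e. strand-aware).  Tags mapping to more than
`max_loci` (default 10) positions keep the best ten and are flagged as
multimapping.  ncRNA annotation removes tags matching a labelled
reference (`id|class` headers) with ≤ 1 substitution; ties are broken by
a fixed class priority (rRNA > tRNA > snoRNA > snRNA > other).

## Secondary structure: Nussinov base-pair maximization

The precursor criterion is stated in paired-base counts (≥ 18 pairs in
the stem-loop), which a Nussinov-style maximum-matching dynamic program
tests directly.  Allowed pairs are A:U, G:C and the G:U wobble; hairpin
loops must contain at least 3 unpaired bases.  The O(n³) fill is
JIT-compiled with numba when available, with a semantically identical
pure-Python fallback.

Optimal structures are massively degenerate.  The traceback is made
deterministic by a greedy rule — the leftmost pairable base is paired
with its smallest optimal partner — rather than by materialising the
lexicographically smallest dot-bracket string, which would require
carrying tie sets through the DP for no analytical gain; the pair *count*
(the quantity the criterion uses) is identical either way, and the
returned structure is always one of the optimal structures (validated
against an independent memoized recursion).

In place of a thermodynamic free energy, a weighted pair score
−(3·GC + 2·AU + 1·GU) ranks candidate windows (threshold −25 by
default).  It is monotone in stem content and cheap; a nearest-neighbour
energy model can be slotted in behind the same contract.

## Novel miRNA calling

Around every mapped leftover-tag locus two windows are excised — tag as
5' arm (15 nt upstream pad, 70 nt downstream flank) and tag as 3' arm
(mirrored) — folded, and accepted when the window holds ≥ 18 pairs, the
energy clears the threshold, and every paired base of the tag points to
one side (the tag lies wholly in one arm and does not straddle the
loop).  Overlapping accepted windows on the same reference are merged
into one call regardless of strand: the arms of a hairpin are
near-reverse-complements, so the same candidate gene can surface on both
strands, and treating the strands separately would double-count loci.
Windows overlapping a mapped known mature (± 150 nt) are excluded — those
tags are isomiRs or star strands of known genes, not new ones.

Because the excised window is anchored on the most abundant tag, it can
clip a few flank bases of the true precursor while still containing the
full mature arm; recovery against ground truth is therefore judged on the
mature-arm locus (`mirforge.evaluate.recovered_novel_precursors`).

## IsomiR decomposition

A tag is aligned to the precursor context (precursor plus templated
flanks) with its 5' end within ±5 nt of the mature 5' end; the best
alignment minimises (substitutions, tail length, |5' offset|).  The 3'
non-template tail is the maximal run of trailing mismatches (≤ 3 nt); a
trailing mismatch followed by matching bases is an internal substitution,
not a tail.  Decomposition is exactly invertible (`reconstruct` is tested
as a round-trip identity).  Substitution spectra are reported over the 12
directed RNA classes, read-weighted or tag-weighted.  Dominant cleavage
sites are read-weighted modes of the end offsets, ties breaking toward
the reference end (offset 0).

Star detection takes the most abundant opposite-arm tag and accepts the
duplex when both ends show a 3' overhang of 2 ± 2 nt, computed from the
pairing partners of the mature and star 5' ends in the predicted
structure.

## Expression and clustering

Relative expression is 2^−ΔCt with ΔCt = Ct(miRNA) − Ct(5S rRNA) per
tissue and replicate; replicates are averaged on the linear scale by
default (`mean_ct` averages ΔCt first, which is the better estimator when
re-deriving planted ΔCt effects).  Clustering uses scipy average linkage
on 1 − Pearson correlation of log2 expression; constant profiles have no
defined correlation and are assigned distance 1 with a warning.  A miRNA
is tissue-specific when its top tissue carries ≥ 50% of its summed
expression.

## Target prediction

The pattern is the reverse complement of the mature miRNA; every
transcript window is scanned (numpy sliding windows, bit-identical to a
per-position loop, verified against one).  A site allows ≤ 1 non-wobble
mismatch and ≤ 2 G:U wobbles, with zero non-wobble mismatches in the
miRNA seed (positions 2–8); `seed_perfect` additionally requires a
wobble-free seed.  Sites score −(3·GC + 2·AU + 1·GU) + 1 per mismatch.

## Synthetic-data generator

Planted precursors are inverted repeats: a stem of (arm + 2) pairs around
an 8–12 nt loop, which guarantees the 18-pair criterion and gives the
mature:star duplex canonical 2-nt 3' overhangs at both ends.  Two G:U
wobbles are planted in the 3' arm: natural stems are imperfect, and the
wobbles break the strand symmetry of a perfect palindrome, whose arms
would otherwise occur verbatim on both genome strands and be called as
two loci.  G:U still counts as paired, so the pair criterion is
unaffected.  The base templated immediately 3' of each arm is fixed to G
while non-template tails are drawn from A/U/C, so every planted tail is
recognisably non-templated; a tailed read suppresses templated 3'
extension, as a tail replaces it chemically.

Reads are generated as unique-tag events with geometric copy counts
(mean 8 by default) until the read budget is met: precursor arm reads
(weights ∝ 1/rank; 15% star strand) with independent 5'/3' end shifts
(80% canonical, ±1 at 8%, ±2 at 2%), a 2% per-read internal substitution
rate and a 10% 3'-tailing rate; 10% ncRNA contaminant fragments; 5%
random background.  Every event is recorded in a provenance list, so the
planted rates are recoverable as binomial proportions (exactly so when
`copy_mean=1`, the setting used for parameter-recovery checks).  Ct
tables are triplicate with N(0, 0.15²) well noise and a planted
stomach-specific ΔCt contrast of −7 for one designated miRNA.

Default problem sizes (8 precursors, 4 × 15 kb chromosomes, 10,000
reads) are chosen so that the full pipeline runs in a few seconds while
every downstream stage still sees non-trivial input; they are this
package's choice, not a property of any dataset.

## Published study tables

The bundled `published_counts.json` and the two novel-miRNA TSVs hold the
printed accounting numbers and discovery tables of a channel catfish
small-RNA study whose raw data were never deposited.  They are inputs,
not outputs: the package checks the arithmetic they imply (retained reads
= clean − ncRNA-removed; 18 + 27 = 45 novel miRNAs) and parses their
coordinate strings with the same locus format the pipeline emits.

## Limitations

* Ungapped matching only: no indel tolerance in mapping, ncRNA filtering,
  or target search.
* Base-pair maximization over-pairs long random windows relative to a
  thermodynamic model; the ≥ 18-pair criterion is therefore necessary but
  weak on ~100-nt windows, and the weighted-score threshold carries most
  of the specificity.  A nearest-neighbour energy engine would be the
  natural upgrade.
* The miRNA* overhang test uses the single predicted structure; ensemble
  base-pair probabilities would be more robust near the loop.
* The generator plants near-perfect stems; it does not model bulges,
  multi-loop precursors, clustered/polycistronic miRNAs, or sequencing
  quality-score error profiles.
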