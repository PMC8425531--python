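# Methods

## The event model

A tandem repeat region is modelled as the outcome of a history that
starts from a *root* pattern of length p (1–10 nt) and applies two kinds
of events:

* **single-block tandem duplication** — one existing block is copied and
  the copy inserted immediately to its right;
* **point mutation** — substitution, insertion or deletion of one
  nucleotide anywhere in the current sequence.

Events interleave freely, so a mutation applied before a duplication
propagates into every later copy of the mutated block. The *error
number* m of an observed region is the minimal total number of point
mutations over all histories generating it; the *copy number* d is the
number of pattern-period blocks. The pair (m, d) is the region's
mutation index, and the coordinate-ordered vector of (m, d) over all of
a sample's regions is its mutation profile.

Patterns are canonicalized to their lexicographically smallest rotation
throughout: a tandem pattern is only defined up to cyclic rotation.

## Tandem repeat detection

The detector is self-contained (no external binary): for each period
p = 1..10 a doubled p-mer seeds a candidate, which is extended outward
per position while a running identity of at least 0.75 holds. The raw
interval is then reduced to the best contiguous window of whole pattern
copies: per-copy scores against the column-majority consensus
(+2 per matching position, −7 per mismatch, the weights Tandem Repeat
Finder uses) are maximized over contiguous copy windows and start
offsets, which trims noise the greedy extension picked up at the flanks.
Regions scoring below 14 are not reported — low enough that a 7-nt
homopolymer run is still called, high enough that dinucleotide chance
repeats in random sequence are not. Overlapping candidates across
periods are resolved in favour of the longer region, then the shorter
period, then the leftmost start; a consensus that is itself periodic is
reduced to its primitive period.

Reported regions therefore span a whole number of copies and carry an
integer copy count; fractional copy numbers only enter through imported
Tandem Repeat Finder tables (`read_trf_table`, which also drops records
violating the period ≤ 10 / copies ≤ 100 / length < 1000 limits).
Candidate windows containing N are skipped.

## Estimating the mutation index

`partition_blocks` aligns a region against cyclic repetitions of its
pattern (every rotation, repetition counts near length/period; edlib
computes the alignments) and cuts the optimal path at copy boundaries;
d is the resulting block count. Ties prefer the repetition count closest
to length/period, then the smaller count, then the lexicographically
smaller rotation, and insertions sitting exactly on a copy boundary are
attached to the following copy — the alternative left-attachment is also
explored internally by the estimator, since either convention can be the
one that exposes the cheapest history.

`estimate_index_exact` (guarded to regions ≤ 24 nt with period ≤ 4)
searches backwards from the observed region: un-duplication merges equal
adjacent blocks at no cost, un-mutation applies a single edit at cost 1,
restricted to edits that bring a block strictly closer to another block.
Two exchange arguments justify the restriction: merging equal adjacent
blocks immediately is never suboptimal (identical mutations in both
copies could have been made once before the duplication), and any
optimal history can be reordered so each reversed mutation precedes the
merge it enables. Iterative deepening on the mutation budget, with the
largest adjacent-pair distance as an admissible bound (every edit
separating two merging lineages is a distinct event), gives the minimum;
the greedy estimate caps the deepening. A search from a single block of
length L to a root of length p costs exactly |L − p| indels because the
root's content is free.

`estimate_index` is the polynomial-time estimator used on real-size
regions. It builds a set of candidate block partitions:

* the near-optimal (rotation, copy count) partitions of the pattern's
  own period, under both boundary-insertion attachments;
* partitions against sampled substrings and phase-consensus strings of
  periods p±2 — an indel in the root propagates into every copy and
  shifts the true period;
* partitions that excise maximal exact tandem runs of shifted-period
  units — singly with phase alternatives and edge-copy hand-offs,
  jointly across periods, and as phase-switch splits cut against two
  different run units — because a propagated variant appears as a long
  perfect run of a unit one or two edits away from the pattern, and an
  indel rotates the phase of everything duplicated after it;
* a segmentation that cuts the region wherever total block-to-vocabulary
  edit distance is minimized.

Each partition is costed by an interval dynamic program over its
run-compressed blocks: reducing an interval to a single block of some
variant v costs the cheapest combination of splits (equal blocks merge
free) and whole-interval re-edits, over a variant vocabulary of the
observed blocks plus the candidate periods; the root may sit at any
variant, paying one indel per unit of length difference from p. Every
combination the DP scores corresponds to a replayable history, so the
minimum over all candidates is a true upper bound on the exact m. A
final hill-climbing pass perturbs cut points of the leading partitions
by one or two bases and tries fusing adjacent blocks. The classic greedy
chain contraction (merge the adjacent pair with minimal edit distance —
both leftmost and rightmost tie-breaks are evaluated — deleting the
member farther from the pattern, ties to the right) remains as the
fallback when a partition compresses to more than ten distinct runs.

On random small instances the estimator equals the exact minimum in
well over 90% of cases (the acceptance suite reports the rate). It is
*not* provably bounded by the mutation count of the particular history
that generated a synthetic region: rare multi-variant structures — two
or more distinct propagated-indel units interleaved by later
duplications — can cost the estimator one extra event (roughly 1–2 per
1000 generated regions at the default simulation rates). The exact
search has no such gap but is exponential in region length.

If a region is a perfect repeat of some p-mer unrelated to its cataloged
pattern, the estimator reports m ≥ 1 (distances are anchored at the
cataloged pattern); such inputs do not arise from the detector, whose
pattern is the region's own consensus.

## Profile alignment

Patterns drift and regions drop out, so two samples' profiles rarely
share a region list. Each profile is aligned against the reference
profile (computed by running detection + indexing on the reference
sequence) by a global dynamic program over the coordinate-ordered
entries: pairing two entries costs the normalized edit distance between
their patterns (Levenshtein distance divided by mean pattern length,
range [0, 2]), leaving an entry unpaired costs a flat 0.4. Two patterns
closer than 0.4 are effectively treated as equal, and pairing is
preferred to double gaps whenever the distance is below 0.8. Cost ties
break toward fewer gaps, then a fixed backtrack order (pair, then
reference gap, then query gap), making the alignment deterministic.

Alignment is monotone and runs independently per sequence id; when the
query and reference are single contigs with different ids (the synthetic
single-record-per-sample layout) the two entry streams are aligned
directly. Query entries with no reference counterpart are omitted;
unmatched reference slots become (0, 0). The resulting matrix has
2R columns for R reference regions, interleaved as m then d per region,
with columns named `<seq>:<start>-<end>_m` / `_d`.

## Classification

Two steps, both with stratified 4-fold cross-validation (fixed seed,
shuffled, same split in both steps):

1. **feature extraction** — depth-2 gradient-boosted trees (xgboost,
   100 rounds, learning rate 0.3, single thread) per training fold;
   feature importance is total split gain summed over trees and averaged
   over folds; the top 30 features are kept, ties broken by column
   order;
2. **classification** — depth-1 boosted trees on the selected columns,
   one model per fold; validation-fold AUC (rank statistic), accuracy,
   and sensitivity/specificity at probability threshold 0.5 are
   reported per fold, plus a model refit on all samples for scoring new
   profiles.

A binary classifier is trained for every unordered class pair (features
re-selected on the pair's samples only), and a `multi:softprob`
multiclass model with the same two-step scheme produces out-of-fold
class-probability profiles (rows renormalized to sum to one, absorbing
float32 rounding) and an argmax confusion matrix. No class reweighting
is applied by default.

Feature selection is deliberately **not** nested inside the evaluation
folds: both steps run on the full (pair) cohort with fold-averaged
importances. Cross-validated metrics therefore carry selection-leakage
optimism; any null-calibration check must push permuted labels through
the *entire* two-step pipeline so the reference distribution carries the
same bias — the packaged calibration test does exactly that (200
permutations, 95% interval).

## Synthetic cohorts

`CohortSpec` defaults mirror a multi-class blood-derived whole-exome
study: 11 classes with sizes (344, 153, 396, 393, 440, 513, 411, 432,
316, 190, 255), 100 regions per sample, patterns of length 1–10 drawn
primitive, copy numbers from Poisson duplication counts (expectation 9,
clipped to [1, 99] duplications so every region has at least two
copies), and per-region mutation counts from Poisson with expectation 1.
One designated class carries additive shifts of the mutation and/or
duplication expectation in a planted subset of regions (defaults: +3
mutations in 10 regions) — the situation where a handful of repeat loci
separate one class from the rest. Regions drop out of a sample with
probability 0.05, and with probability 0.02 a sample's root pattern for
a region is a one-edit variant.

Regions are assembled with 35-nt spacers that are rejection-sampled
until the detector finds nothing in them and their boundary bases cannot
extend an adjacent region's periodicity — so planted boundaries are
exact and detector recall is measurable. The reference (ancestor)
sequence carries every region as a perfect repeat at the expected copy
number with the same spacers. Ground truth records, per sample × region,
presence, the witness mutation count, the final block count, coordinates
and the full replayable event history.

What the generator does **not** emulate: read-level sequencing (coverage,
base errors, mapping), linked or interspersed repeats, locus-specific
mutation-rate heterogeneity beyond the planted shift, and any biological
model of somatic repeat evolution — the Poisson/additive-shift process
is a testbed, not a claim about tumours. Passing tests demonstrate that
the pipeline recovers structure it is designed to represent, not that
the real study's effect sizes are reproducible.

## Problem sizes in the shipped test suite

Cohort-level checks use sizes chosen for a single CPU: the planted-signal
recovery runs three 3-class cohorts of 100 samples/class × 100 regions
(shift 0, 1, 3); null calibration uses a 2-class, 30 samples/class,
40-region cohort with 200 label permutations; the witness-bound and
estimator-equality checks use a 2-class 30/class × 60-region cohort and
1000 random guarded instances respectively; the 55-pair combinatorial
check uses 12 samples/class × 20 regions.

## Known limitations

* `estimate_index` is an upper bound; on adversarial multi-variant
  histories it can exceed the true minimum (and the generating witness
  count) by one event.
* The detector's mismatch-tolerant extension does not model indels
  within the scan; a region interrupted by an indel may be reported as
  truncated or split (downstream, alignment treats the lost part as
  dropout).
* Exact reproduction of any real-data study metrics is out of scope:
  controlled-access exomes are required, and boosted-tree defaults vary
  across library versions.
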