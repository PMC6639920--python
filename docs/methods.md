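# Methods

## Coordinate conventions

Residue indices and MSA columns are both 1-based; intervals are
closed.  Both `-` and `.` are read as gaps and normalised to `-`;
lowercase residues (Stockholm insert states) are uppercased and kept
as residues.  Duplicate sequence ids within one alignment keep the
first record (logged).  Mapping residues to columns is injective, and
`column_of_residue` / `residue_at_column` are mutually inverse on
non-gap positions; both directions are property-tested on fuzzed
sequences.

## The similarity statistic

For binding-residue sets projected onto shared MSA columns,
`similarity(X, Y) = 100·|X ∩ Y| / max(|X|, |Y|)`.  Normalising by the
larger set penalises asymmetric annotation coverage: a protein with
one shared residue out of ten annotated scores 10%, not 100%.  The
statistic is symmetric, bounded in [0, 100], and reaches 100 exactly
when the two column sets are identical.  Family scores average over
all unordered pairs of annotated members; members without annotations
are excluded before pairing (a pair with an empty set has undefined
similarity and is never formed).

Aggregation conventions, used everywhere:

* similarity statistics aggregate **per family**; prediction metrics
  aggregate **per protein**;
* the standard error is the sample standard deviation (denominator
  n−1) divided by √(n−1), and requires n ≥ 2 units;
* undefined per-protein metric values are excluded from averages, and
  each metric reports its own count of contributing units.

Internal computation is kept at full precision; only reports round.

## Random-family floor

Random families are sampled without replacement within a family and
with replacement across families, so one random family never contains
the same protein twice while the pool can be reused.  Families are
aligned by center-star progressive alignment: all pairwise global
affine-gap alignments (Biopython's `PairwiseAligner`; BLOSUM62, gap
open 10, gap extend 0.5 by default) select the center with maximal
summed score (ties broken by input order), and the remaining
sequences are merged onto the center under "once a gap, always a
gap".  Every output row, with gaps deleted, equals its input
sequence; the pairwise step is verified against an independent Gotoh
dynamic-programming oracle.  The aligner is a utility, not a
contribution — any externally computed MSA can be used instead by
constructing a `FamilyAlignment` from it.

For *k* binding residues uniform over *L* positions the overlap of
two proteins is hypergeometric with mean k²/L, so the expected floor
is 100·k/L.  This closed form presumes that the MSA maps position *i*
to position *i* — which a correct alignment does when the pool
sequences are mutually alignable.  `template_pool` therefore draws
pool sequences as point-mutated copies (default 20% of sites) of one
random template, like distant relatives of one structural
superfamily, with annotations independent and uniform; center-star
then recovers the gap-free alignment and the oracle is exact.  With
*fully random* letters instead, the optimal-score alignment of
unrelated 100-mers contains many spurious gaps (MSAs of 150+
columns), which scatters the column mapping and pushes the measured
floor *below* 100·k/L — a property of alignment on noise, not of the
statistic.  The gap-free case is the one the closed form describes,
and the one asserted at full scale.

## Annotation transfer

Transfer carries the source's binding residues along columns; a
target gap absorbs (drops) the label.  Each transfer is scored
against the **recipient's own observed annotation** over the
recipient's ungapped length.  The alternative reading — scoring the
transferred labels against the source's annotation — is degenerate
(always perfect, since the labels are copies) and is therefore
rejected, not merely disfavoured.  All ordered pairs are evaluated;
a protein's score is the mean over the transfers it receives, and the
summary aggregates per protein.

## Consensus filter

The vote fraction at a column counts only members without a gap
there ("aligned at that position"); columns gapped in every member
are never consensus-binding.  The comparison is ≥, not strict >:
a strict comparison would make the documented unanimity setting
(threshold 1.0) unsatisfiable.  Members of the alignment missing from
the prediction table are treated as predicting non-binding everywhere
but still occupy denominators at their non-gap columns, because
occupancy is a property of the alignment, not of predictor coverage.

Consequences asserted as properties: the consensus set shrinks
monotonically in the threshold; a threshold ≤ 1/M yields the union of
member predictions and 1.0 the non-gap intersection; with
independent per-residue false positives at rate *f* and conserved
truth, the expected number of non-planted columns surviving unanimity
in a family of M members is (L−B)·f^M (binomial over the L−B
non-binding columns), which the simulation reproduces within
Monte-Carlo error.

Proteins whose projected consensus prediction is empty keep
contributing to recall and accuracy but drop out of the precision
average (TP+FP = 0 makes precision undefined); coverage is reported
separately as the mean number of predicted residues per protein and
the fraction of proteins with at least one prediction.

## Metrics

Precision, recall and accuracy are percentages; F1 is the harmonic
mean of precision and recall, identical to 100·2TP/(2TP+FP+FN)
(asserted on fuzzed counts).  MCC is the standard Matthews
correlation coefficient on [−1, 1] with the product denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), undefined when any factor is zero.
No percentage scaling is applied to MCC: reported MCC values near
0.36 for transfers of this kind only make sense on the unit scale.
ROC/AUC is deliberately absent: the consensus emits binary labels
with no score to threshold.

## Synthetic generator

Each family plants `n_binding_columns` binding columns uniformly
among `n_columns`.  Each member draws i.i.d. gaps per cell
(`p_gap`), is annotated at each non-gap planted column with
probability `p_conserved` and at each non-gap non-planted column
with probability `p_extra`, and is redrawn until its annotation is
non-empty (mirroring the exclusion of unannotated proteins from
similarity analyses).  Predictions corrupt annotations per residue:
annotated residues are missed at `fn_rate`, non-annotated residues
added at `fp_rate`.  All-gap columns are dropped and the planted
truth remapped.  Letters are uniform random amino acids: all scores
in scope depend only on columns, gaps and label sets, so random
letters keep the generator minimal and the analytic oracles exact.

Defaults describe the intended study conditions: families of 4
members (annotated real functional families average ≈3.9 members),
100 columns with 5 planted binding columns (≈5% binding residues,
matching the ≈5% random floor), `p_conserved=0.8`, `p_extra=0.02`,
`p_gap=0.05`, `fp_rate=0.05`, `fn_rate=0.2`.  Conservation at 0.8
with sparse private annotations puts family similarity near 45%, the
regime where the filter's precision/recall trade-off is informative.

`expected_similarity` is the generator's independent oracle: it
draws annotation pairs directly from the gap-free label model and
averages their similarity (vectorised Monte Carlo with rejection of
empty draws, matching the generator's resampling).
`expected_random_similarity(k, L)` returns the exact hypergeometric
floor.

What the generator does **not** emulate: phylogenetic correlation
between members, indel evolution, composition bias, binding-site
spatial clustering along the chain, and systematic (non-independent)
predictor errors.  Passing tests therefore demonstrate correctness of
the statistics and the filter under independence assumptions, not
performance on any real protein dataset.

## Problem sizes

The test suite and `scripts/acceptance.py` run at sizes chosen to
make Monte-Carlo checks sharp while staying desk-scale: 10,000 fuzz
pairs for the similarity oracle, 500 synthetic families for the
consensus-limit and noise-suppression checks, a 300-protein pool with
500 random families of 3 for the floor, and 200 families of 4 for
the end-to-end pipeline numbers.  Statistical assertions use
three-standard-error bands.

## Known limitations

* The center-star aligner is O(M²·L²) per family and intended for
  the small families (M ≲ 10) this analysis targets.
* `cross_subset` picks representatives with Python's seeded PRNG over
  sorted ids; reproducibility holds for identical input tables, not
  across differently ordered supersets.
* Multi-domain proteins with several family assignments are treated
  as independent (family, protein) pairs; the package does not
  arbitrate between assignments.
* Stockholm output is minimal (no per-column annotation lines).
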