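# bindfam

Binding-residue coherence of protein functional families, and a
family-consensus filter for per-residue binding predictions.

## The problem

Functional classifications of proteins (CATH FunFams, Pfam families,
PROSITE patterns, EC numbers) claim to group proteins that work alike.
One way to test that claim without circular reliance on function
annotations is to ask a molecular question: **do members of the same
group bind their ligands through the same residues?**  Residues that
contact a ligand are annotated per protein as 1-based sequence
positions; if a grouping is functionally coherent, those positions
should line up in a multiple sequence alignment (MSA) of the group.

`bindfam` provides the statistics for this analysis and a practical
application of it, the consensus filter:

* **Similarity.** For two proteins with binding-residue sets *X*, *Y*
  projected onto the columns of a shared MSA,

  ```
  similarity(X, Y) = 100 · |X ∩ Y| / max(|X|, |Y|)     (percent)
  ```

  A family of *M* annotated members scores the mean over all
  *M(M−1)/2* pairs; a set of families is summarised as mean ± SE of
  per-family scores (SE = sample SD / √(n−1)).

* **Random floor.** Randomly grouped proteins define the similarity
  floor.  The package samples "random families" that mimic a real
  size distribution, aligns each with a built-in center-star
  progressive aligner (affine-gap Needleman–Wunsch pairwise steps,
  BLOSUM62), and scores them identically.  For *k* binding residues
  placed uniformly over *L* positions the expected floor is the
  hypergeometric overlap, 100·k/L.

* **Annotation transfer.** Within a family, one member's observed
  binding residues are carried along alignment columns to every other
  member and scored against the recipient's own annotation
  (precision, recall, F1, accuracy, MCC, aggregated per protein).

* **Consensus filter.** Given noisy per-residue binding *predictions*
  for each member, an MSA column is consensus-binding when the
  fraction of members predicting binding there — among members not
  gapped at that column — reaches a threshold *t ∈ (0, 1]*.  Sweeping
  *t* from 0.01 (any single vote) to 1.0 (unanimity) trades recall
  against precision; unanimity suppresses independent false positives
  at rate *f* down to ≈ (L−B)·f^M surviving columns per family.

A seeded synthetic-family generator (planted binding columns,
tunable conservation, gaps and prediction noise) makes every pipeline
testable without any database download.

## Worked example

```python
from bindfam import (SyntheticConfig, generate, family_similarity,
                     group_similarity, sweep_thresholds, evaluate_transfer)

cfg = SyntheticConfig(n_families=50, family_size=4, n_columns=100,
                      n_binding_columns=5, p_conserved=0.8, p_extra=0.02,
                      p_gap=0.05, fp_rate=0.05, fn_rate=0.2, seed=42)
ds = generate(cfg)

per_family = [family_similarity(f, ds.family_annotations(f)) for f in ds.families]
stat = group_similarity(per_family)
print(f"family similarity: {stat.mean:.1f} +/- {stat.se:.1f}% over {stat.n_units} families")

res = evaluate_transfer(ds.families[0], ds.family_annotations(ds.families[0]))
print(f"transfer F1 (one family): {res.summary['f1'].mean:.1f} +/- {res.summary['f1'].se:.1f}%")

sweep = sweep_thresholds(ds.families, ds.predictions, ds.annotations, [0.01, 0.5, 1.0])
for _, row in sweep.iterrows():
    print(f"threshold {row['threshold']:.2f}: "
          f"precision {row['precision_mean']:.1f}%, recall {row['recall_mean']:.1f}%, "
          f"{row['mean_predicted_per_protein']:.1f} predicted residues/protein")
```

prints

```
family similarity: 47.5 +/- 1.7% over 50 families
transfer F1 (one family): 56.1 +/- 6.1%
threshold 0.01: precision 23.1%, recall 94.1%, 23.7 predicted residues/protein
threshold 0.50: precision 63.5%, recall 67.2%, 6.0 predicted residues/protein
threshold 1.00: precision 99.2%, recall 14.7%, 0.8 predicted residues/protein
```

Families generated with 80% conservation of five planted binding
columns agree in ~48% of their binding residues — far above the ~5%
random floor for 5 binding residues over 100 positions.  The
threshold sweep shows the filter's precision/recall dial: a single
member's vote recovers almost all binding residues at low precision,
while unanimity keeps under one predicted residue per protein but is
almost always right.

## Command line

Each subcommand writes TSV tables plus a `summary.json` recording the
seed:

```bash
bindfam simulate --out data/ --seed 7 --n-families 50
bindfam similarity data/alignments --annotations data/annotations.tsv --out sim/
bindfam cumulative --values sim/family_similarity.tsv --out cum/
bindfam baseline --sequences pool.fasta --annotations annot.tsv --sizes 3,3,4 --out base/
bindfam transfer data/alignments --annotations data/annotations.tsv --out tr/
bindfam consensus data/alignments --predictions data/predictions.tsv \
    --annotations data/annotations.tsv --out cons/
bindfam evaluate data/alignments --predictions data/predictions.tsv \
    --annotations data/annotations.tsv --out ev/
```

Alignments are FASTA or Stockholm (`--format`); annotation and
prediction tables are TSVs with `protein_id` and either a `position`
column (one row per residue) or a comma-joined `positions` column.

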