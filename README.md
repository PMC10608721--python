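# fuzzysd

Evolutionary fuzzy **subgroup discovery** for small, imbalanced
NMR-metabolomics bucket tables.

## The problem

Rare-disease metabolomics studies routinely produce tables of a few dozen
urine or serum samples × a few dozen integrated NMR spectral buckets, with a
small patient class facing a larger control class (e.g. 12 Niemann–Pick type
C1 patients vs 40 heterozygous carriers, imbalance ratio 3.33). Standard
classifiers struggle at this scale, and clinicians need *interpretable*
output. Subgroup discovery sits between prediction and description: it mines
rules

```
R: IF bucket_i = label AND ... THEN class
```

whose covered samples show an unusual class distribution relative to the
whole cohort. Here each continuous bucket is covered by three uniform
triangular linguistic labels (*low*, *normal*, *high*), so a rule reads the
way a biochemist would phrase it ("normal hippurate and low nicotinate").

## What the package does

- **Preprocessing** (`fuzzysd.preprocess`): creatinine-style reference
  normalisation, cube-root transform, Pareto scaling
  ((x − x̄)/√s), ppm-window selection.
- **Fuzzy semantics** (`fuzzysd.fuzzy`): Ruspini triangular partitions
  (adjacent memberships sum to 1), min t-norm rule compatibility, crisp
  coverage at the zero-cut.
- **Quality measures** (`fuzzysd.quality`): from the crisp confusion matrix,
  accuracy (TP+TN)/N, TPrate = TP/n_pos, FPrate = FP/n_neg, single-point
  AUROC = (1 + TPrate − FPrate)/2, weighted relative accuracy
  WRAcc = ((TP+FP)/N)·(TP/(TP+FP) − p₀), its normalisation to [0, 1]
  (*unusualness*, 0.5 = no association), fuzzy confidence
  Σ_pos μ / Σ_all μ, and the **exact two-sided Fisher test** (minimum-
  likelihood definition, exact rational arithmetic) used to screen rules at
  α = 0.10.
- **Rebalancing** (`fuzzysd.smote`): Safe-Level-SMOTE oversampling of the
  minority class, with the full five-case gap table.
- **Search** (`fuzzysd.engine`): NSGA-II-style multi-objective evolution over
  rule genomes (one gene per bucket: a label or *not participating*),
  generality-biased initialisation and mutation, stall-triggered
  reinitialisation from uncovered examples, Fisher screening of the decoded
  Pareto front.
- **Validation** (`fuzzysd.evaluation`): stratified 5-fold CV with per-fold
  AUROC, ROC-space filtering of rules close to the diagonal.
- **Benchmarking** (`fuzzysd.synthetic`): generator for 12/40 × 54
  imbalanced tables with planted fuzzy-label subgroups and a recovery scorer.
- **Pathway context** (`fuzzysd.ora`): hypergeometric over-representation
  analysis of metabolite hit lists against GMT metabolite sets, with
  enrichment ratios and Benjamini–Hochberg FDR.

## Worked example

```python
import fuzzysd as f

# a 52-sample, 54-bucket benchmark with one planted 2-conjunct NPC1 rule
table, truth = f.generate(f.GeneratorConfig(seed=2))
print(table.n_samples, table.n_features, round(table.imbalance_ratio, 2))
# 52 54 3.33

part = f.build_partitions(table)
rules = f.evolve(table, "NPC1", f.EvolutionConfig(seed=2), part)
rec = f.evaluate_recovery(rules, truth, table, part)[0]
print(rec["match"])
print(round(rec["jaccard"], 2), round(rec["tp_rate"], 3), round(rec["fp_rate"], 3))
# IF 6.71-6.76=high AND 6.76-6.81=low THEN NPC1
# 1.0 0.917 0.2
```

The mined rule is exactly the planted subgroup (antecedent Jaccard 1.0): it
covers 11 of the 12 minority samples (TPrate 0.917) at the planted background
leak (FPrate 0.2), and survives Fisher screening at α = 0.10.

Quality measures reproduce published-style reports directly from counts:

```python
from fuzzysd.quality import reconstruct_counts_from_rates, unusualness
c = reconstruct_counts_from_rates(1.000, 0.400, n_pos=12, n_neg=40)
print(c.tp, c.fp, round(unusualness(c), 3))
# 12 16 0.8
```

A command-line interface wraps the same pipeline:

```sh
fuzzysd generate --out synth.csv --truth truth.json --seed 7
fuzzysd discover --table synth.csv --class-col Class --target NPC1 \
                 --seed 42 --out rules.csv
```

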