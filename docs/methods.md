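# Methods

## Data model

A bucket table is a samples × buckets matrix of non-negative NMR intensities
with one binary class label per sample. The positive (target) class is named
explicitly per run and never inferred from minority status, because rules are
mined for both classes in turn. Loading rejects missing or non-numeric
cells, more or fewer than two classes, and negative intensities; later
transformations (Pareto scaling) may legitimately produce negative values and
set a `processed` flag instead.

## Preprocessing

The chain is fixed in order: optional ppm-window selection → reference
normalisation → cube-root → Pareto scaling. Design points:

- **Region membership by bucket midpoint.** Bucket names are ppm ranges
  ("6.71-6.75", hyphen or en-dash); a bucket belongs to a window when its
  midpoint does. Midpoints make boundary buckets unambiguous.
- **Reference normalisation** divides row-wise by the chosen reference
  bucket (urinary creatinine in the motivating workflow) and drops it; a
  non-positive reference value in any sample is an error naming the sample.
- **Pareto scaling** uses the sample (n−1) standard deviation and divides
  the centred feature by √s. Constant features are an error listing their
  names rather than silently yielding NaN.
- The chain refuses to run twice on the same table (`processed` flag):
  cube-root and Pareto are not idempotent and re-running them is always a
  pipeline bug, not an analysis choice.

## Fuzzy rule semantics

Each feature gets a uniform triangular (Ruspini) partition over its observed
training-data domain: with L labels, apexes at min + i·(max−min)/(L−1), end
triangles shouldered at the edges, and values outside the domain clamped to
edge membership (needed when test folds exceed the training range). Adjacent
memberships sum to one everywhere, so the default three labels (*low*,
*normal*, *high*) tile the domain without gaps.

A rule's compatibility with a sample is the minimum of its antecedent
memberships (product available behind a switch); a sample is *covered* iff
compatibility is strictly positive (zero-cut). Two consequences worth
keeping in mind:

- a `low`/`high` conjunct excludes roughly the opposite half of a feature's
  domain, while a `normal` conjunct excludes (almost) nothing crisply — it
  matters only through membership degrees;
- compatibility is monotone non-increasing under specialisation, so crisp
  coverage can only shrink as conjuncts are added.

## Quality measures

All reported measures derive from the crisp confusion matrix under zero-cut
coverage with positives = the rule's target class; only fuzzy confidence
uses membership degrees. Unusualness is WRAcc mapped affinely from its
attainable range [−p₀(1−p₀), +p₀(1−p₀)] onto [0, 1]; 0.5 therefore means
"rule confidence equals the class prior", and the map makes rules mined for
differently sized target classes comparable. Raw WRAcc is kept in the JSON
sidecar of every report.

The screening statistic is the exact two-sided Fisher test in its
minimum-likelihood form: with both margins fixed, sum the hypergeometric
probabilities of every table whose point probability does not exceed the
observed one. The implementation works in exact integer/rational arithmetic
(`math.comb` + `Fraction`), so tie comparisons are exact and the result is
reproducible to machine precision; the tests cross-check it against an
independent margin-enumeration oracle (different pmf factorisation) and
against `scipy.stats.fisher_exact` away from near-ties, where scipy's
floating-point tie tolerance can legitimately differ.

Report files round all measures to 3 decimals except the Fisher p-value,
which is *truncated* to 3 decimals, matching the print convention of the
quality tables this format mirrors; full precision lives in the sidecar.

## Safe-Level-SMOTE

Safe levels (minority count among the k = 5 nearest neighbours, Euclidean,
self excluded) are measured against all samples; synthesis partners are the
seed's k nearest *minority* neighbours. The five gap cases (skip /
duplicate-seed / U(0,1) / U(0, sl_n/sl_p) / U(1−sl_p/sl_n, 1)) are the
normative contract; the target ratio defaults to 1:1, so the 12/40 study
shape yields exactly 28 synthetic rows. Neither k nor the ratio has a
stated study value; k = 5 and 1:1 are the community defaults and both are
config-exposed. Oversampling is applied inside CV training folds only.

## Evolutionary search

One genome gene per feature (label index or NOT_PARTICIPATING); NSGA-II
machinery: fast non-dominated sort, crowding distance, binary tournament on
(rank, crowding), two-point crossover (p = 0.6), per-gene mutation
(p = 0.1; half of mutations drop the variable, half re-draw its label);
75 % of the initial population is biased to at most 25 % participating
variables; a stall of 5 % of the evaluation budget without newly covered
target examples reinitialises non-elite individuals seeded from uncovered
target examples. Defaults: population 100, 10 000 evaluations.

Two design choices depart from the most literal reading of the algorithm
family and deserve justification:

- **Fuzzy fitness.** During search, the objective pair (default: normalized
  unusualness and fuzzy confidence) is computed from *membership-degree
  sums*, not crisp counts. With crisp objectives on a 52-sample table with
  dozens of uninformative buckets, the search reliably overfits: a handful
  of noise conjuncts can excise exactly the covered negatives, and the
  resulting rule's crisp unusualness genuinely exceeds that of the true
  subgroup on the realised sample. Fuzzy evaluation makes every added
  conjunct pay (the min t-norm erodes compatibility), which is an intrinsic
  generality pressure and matches how fuzzy subgroup-discovery systems
  score candidates internally. All *reported* measures remain crisp.
- **Generalization paths.** Each decoded Pareto-front rule is expanded into
  the sequence of rules obtained by repeatedly deleting the conjunct whose
  removal least degrades fuzzy unusualness, down to one variable. The whole
  pool — originals plus generalizations — is deduplicated and Fisher
  screened at α = 0.10 (strict inequality). This keeps parsimonious
  subgroups available even when the front holds only their overfitted
  specialisations; screening, not the pruner, decides what survives.

Classification (for CV validation) assigns the class of the maximally
compatible rule; exact ties go to the class with the larger training prior,
and samples firing no rule fall back to the majority class. If screening
rejects every rule in a fold, the fold's classifier degenerates to
majority-class prediction (AUROC 0.5), which is the honest null behaviour.

## Cross-validation

Stratified k-fold (default 5) via scikit-learn's splitter with a fixed
seed; fold AUROC is the single-operating-point form (1 + TPrate − FPrate)/2
— deliberately *not* a score-ranking ROC, because the rule-based classifier
has one operating point. Fuzzy domains and SMOTE are computed per training
fold. The ROC-space filter keeps rules with TPrate − FPrate ≥ δ (default
0.1); the threshold is a package choice, as "close to the diagonal" has no
canonical numeric value.

## Synthetic benchmark

The generator emulates the study shape: 12 minority vs 40 majority samples,
54 positive-valued buckets named as contiguous ppm ranges over the aromatic
window (6.71–9.43 ppm), log-normal baseline intensities with
feature-specific scales (right-skewed, like creatinine-normalised urinary
buckets). One 2-conjunct minority rule ({first bucket: high, second bucket:
low}, penetrance 0.9, background leak 0.2) is planted by default.

Placement is exact-count: round(penetrance·n_target) target samples and
round(leak·n_other) non-target samples are drawn uniformly inside the
antecedent's label cells (the third of each feature's range where that label
dominates); every other sample has one antecedent feature forced into the
label's zero-membership half, so the planted rule's compatibility with it is
exactly zero. This makes the planted rule's crisp counts deterministic
(TP = 11/12, FP = 8/40 at defaults) rather than binomially noisy, which is
what a recovery benchmark needs. Planting a `normal` label is rejected,
since its support covers the whole domain and zero-compatibility placement
is impossible. What the generator does *not* emulate: bucket-to-bucket
correlation, peak overlap, chemical-shift drift, or dilution variance — so
passing recovery tests demonstrates algorithmic correctness, not field
performance on real spectra.

Recovery scoring matches each planted rule to the found rule with maximal
antecedent Jaccard on (feature, label) pairs, breaking ties toward the rule
with the largest TPrate − FPrate margin, and reports that rule's realised
rates.

## Over-representation analysis

Upper-tail hypergeometric per metabolite set, with p = P(X ≥ max(obs, 1))
so empty intersections report p = 1; enrichment ratio = observed/expected =
obs·|U|/(|hits|·|set|); Benjamini–Hochberg across sets. The universe
defaults to the union of all sets and can be supplied explicitly (detected
metabolites vs library membership is a study-level choice, so it is a flag,
not a constant). Matching is exact case-insensitive string comparison.

## Problem sizes and determinism

Engine defaults (population 100, 10 000 evaluations) run a full discovery
on the 52 × 54 benchmark in about a second; the test suite uses a compact
configuration (population 20, 400 evaluations) for CV toys, which is ample
for 4-feature problems. Every stochastic component (generator, SMOTE,
engine, CV splitting) takes an explicit seed, and derived per-fold seeds are
deterministic functions of the run seed, so all results in the README are
bit-reproducible.

## Known limitations

- The two classes are mined independently; no rule-set–level redundancy
  control exists beyond duplicate collapsing and the ROC-space filter.
- Unusualness normalisation assumes a non-degenerate prior (both classes
  present); single-class tables are rejected rather than special-cased.
- The exact Fisher implementation is O(min(row, column) margin) per rule —
  negligible here, but the enumeration-based two-sided definition is not
  the only convention in the wild (mid-p and conditional-likelihood
  variants will disagree).
- Safe-Level-SMOTE duplicates the seed when the partner's safe level is
  zero; with a pathological all-noise minority the output may contain fewer
  synthetic rows than requested (reported via a warning).
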