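# Methods

`hdweight` re-implements, as a tested pipeline over synthetic cohorts, an
analysis strategy for associating non-motor clinical factors with severe
weight loss in premanifest Huntington's disease (HD): longitudinal weight
change, expert ordinal categorization, class association rule (CAR) mining
with a six-measure validation suite and redundancy pruning, self-organizing
map (SOM) summaries, and mutual-information dependence analysis.  The real
cohort this models (a large multi-centre observational HD platform) is
access-restricted, so every stage is driven and validated through a seeded
synthetic generator that emulates its structure.

## Weight change

Each subject contributes one baseline visit and several annual follow-ups.
The per-subject percentage weight change is

    delta_w = (w_f - w_b) / w_b * 100

with `w_b` the baseline weight and `w_f` the weight at the follow-up with
the largest visit sequence number.  Subjects lacking a baseline or any
follow-up are excluded and counted.  The consolidated record's factor
values are taken from the last follow-up visit by default (it is
contemporaneous with `w_f`); a `factors_from="baseline"` switch selects the
baseline instead, since either convention is defensible.

Cleaning precedes consolidation: rows with any missing analysis value are
dropped, then rows outside the Tukey boxplot fences `[Q1 - 1.5 IQR,
Q3 + 1.5 IQR]` of any screened factor (default: tfcscore, indepscl,
irascore, motscore, depscore) are dropped.  Fences are computed once on the
input table (linear-interpolated quartiles), not iteratively: re-fencing a
cleaned table would shrink the fences and keep trimming, so single-pass
semantics are part of the contract and are what the tests assert.

## Expert categorization

Raw scores map to small ordinal severity scales through fixed interval
tables (`scheme.default_scheme`).  Conventions worth noting:

* All intervals are half-open `[lo, hi)` except the weight categories.
* `wtCat` spans -3 (loss of more than 20 % of body weight) through 0
  (within 5 %) to +3; boundary values at exactly -20/-10/-5 % belong to the
  more severe loss category, and gains mirror losses symmetrically (+2 is a
  10-20 % gain, etc.).
* The cognitive tests (mmsetotal, sdmt1) are reverse-scored: lower raw
  values mean higher severity codes.  The sdmt1 raw value 26, which falls
  between the printed severe (0-25) and moderate (27-34) ranges, is
  absorbed into the severe range.
* The independence scale rows "81-95" (mild) and ">=95" (normal) overlap at
  95; 95 is assigned to mild, so normal starts above 95.
* Open-topped rows (e.g. tfcscore > 12) accept arbitrarily large raw
  values; categorization errors fire only for values outside every declared
  interval and name the factor and value.

Any raw value drawn inside a category's interval categorizes back to that
category — the round-trip property the synthetic planter relies on, checked
by a property test.

## Synthetic cohorts

The generator (`synthetic.generate_cohort`) emulates the study conditions:
one baseline plus 3-5 annual follow-ups per subject; baseline weight
Normal(75, 12) kg; follow-up weights follow i.i.d. multiplicative annual
drift with 2 %/yr standard deviation, so the natural weight-change
distribution concentrates in the stable category.  Factor scores are drawn
category-first from per-factor ordinal marginals (defaults are illustrative
unimodal, healthy-skewed vectors — the source study reports its real
marginals only graphically) and then placed uniformly on the integers of
the category's raw interval.  Age increments annually across visits
(floored at 18, the youngest accepted adult age).

Planted rules make downstream mining testable: a configurable stratum of
subjects is forced into the antecedent categories, and every subject whose
factors match the full antecedent — planted or by chance — has their final
weight solved from the weight-change formula to hit the midpoint of the
consequent weight category with the configured probability (otherwise their
natural trajectory stands, resampled to stable if it would accidentally
land in the consequent).  Applying the dependency to all matchers rather
than only the forced stratum keeps the conditional confidence equal to the
target in expectation, which is what parameter-recovery tests measure.

Missingness is completely at random over factor cells only; injected
outliers displace factor cells beyond the upper Tukey fence by a
configurable multiple of the IQR.  One `numpy` Generator seeded once per
cohort drives everything, so identical configs give identical cohorts.

What the generator does **not** model: CAG repeat length, progressive
disease dynamics, realistic inter-factor clinical correlations beyond the
planted dependencies, informative missingness, or measurement error in
weight.  Passing tests therefore demonstrate that the pipeline recovers
structure of this idealized kind, not that it would find the same rules in
real registry data.

## Class association rules

Mining is a from-scratch level-wise Apriori over the one-item-per-factor
transaction matrix, with the consequent constrained to a single weight
category.  Candidate k-itemsets join (k-1)-itemsets sharing a prefix and
are pruned when any (k-1)-subset is infrequent.  Rule filtration follows
the source analysis where stated: minimum confidence 0.9, total rule length
(antecedent plus consequent) 2-5.  The analysis does not state its support
threshold; the default is 0.01 of records, exposed as a parameter.

Each rule carries six measures computed from the 2x2 antecedent-by-
consequent table (a = joint, b = X-only, c = Y-only, d = neither):

* support `a/N` and confidence `a/(a+b)`;
* lift `s(XY) / (s(X) s(Y))` — 1 at independence;
* conviction `(1 - s(Y)) / (1 - c)` — 1 at independence, +inf at c = 1;
* Pearson chi-square with 1 df and no continuity correction, with its
  upper-tail p-value (degenerate margins report chi2 = 0, p = 1);
* strength, implemented as the odds ratio `ad/bc` — the standard measure
  with the stated behaviour 0 for never-co-occurring, 1 at independence,
  +inf for perfect positive association (conventions 0/0 = 1, x/0 = +inf).

Redundancy pruning removes a rule exactly when a strictly more general rule
with the same consequent reaches at least its confidence; the operation is
idempotent and order-preserving.  Output order is deterministic (lift desc,
confidence desc, lexicographic antecedent).  On small datasets the miner is
tested for exact equality — rules and all six measures — against a
brute-force enumerator of every antecedent subset, whose metric formulas
are written independently (closed-form `erfc` chi-square tail).

## Self-organizing map

A rectangular grid (default 4x4 = 16 nodes) of codebook vectors is trained
online: per record, the best matching unit (BMU) is the node minimizing
Euclidean distance (ties to the lowest index), and all nodes within the
current radius move toward the record by `lr * exp(-d2/(2 r2))` of the gap.
Learning rate (0.05 -> 0.01) and radius (max(grid)/2 -> 1) decay linearly
over the epochs (default 500); records are presented in a seeded reshuffled
order each epoch; codebooks initialize uniformly within each feature's
observed range.  These hyperparameters are package choices — the analysis
being emulated reports only a 16-node map — and all are configurable.
Ordinal codes enter as raw numeric coordinates (their numeric ordering is
meaningful); optional min-max scaling is available.  Updates are convex
combinations, so codebook components never leave the data range, and the
per-epoch quantization error (mean record-to-BMU distance) is traced.
Tests train at 10-100 epochs on small fixtures, where the qualitative
guarantees (determinism, decreasing quantization error, coherent mapping of
16 well-separated clusters onto a 4x4 grid) already hold.

Map summaries mirror the usual SOM reporting: per-node record counts,
per-node class (wtCat) distributions, per-factor component heatmaps, and
the full codes profile, all as plot-ready tables (no rendered graphics).
Nodes are numbered 1..rows*cols row-major from the bottom-left corner.

## Dependence analysis

Plug-in (maximum-likelihood) estimates in bits: conditional entropy
`H(Y|X) = sum_x p(x) H(Y|X=x)` and mutual information
`I(X;Y) = H(Y) - H(Y|X)`, with `0 log 0 = 0`.  Log base 2 is a package
choice; no bias correction is applied.  Joint dependence of a factor set
uses the exact composite variable (the tuple of categories, factorized to
integer codes), never a chain-rule approximation — so
`I(Y; {X1,X2}) >= I(Y; X1)` holds exactly for the plug-in estimate.
Chi-square tests of independence run on the full contingency table
(`(r-1)(c-1)` df, no continuity correction); zero-margin rows/columns are
dropped with a warning.  Note the plug-in MI is biased upward on small
samples; at the cohort sizes used here (>= 1000 records) the bias is well
below the effect sizes of planted dependencies.

## Pipeline and reproducibility

`run_pipeline` executes generate -> preprocess -> categorize -> mine -> som
-> info for each study group (premanifest and family control) as fully
independent instances; a single global seed derives every per-group stream,
and re-running a config reproduces byte-identical artifacts.  The manifest
records row/subject accounting at every stage (in = retained + dropped) and
echoes all parameters.  `scripts/acceptance.py` rebuilds the constructed
transaction sets with exactly factorizing and never-co-occurring
antecedent/consequent counts and reports the lift/conviction/strength
identities computed by the package's own counting and metrics path.

## Known limitations

* The expert interval tables are fixed; no data-driven breakpoint learning.
* Confidence/support thresholds interact with the synthetic marginals; very
  rare planted antecedents can fall below the support floor after cleaning.
* The SOM offers no U-matrix clustering, hexagonal lattice, or batch mode.
* MI has no permutation p-values; chi-square p-values rely on asymptotics
  and are approximate for sparse contingency tables.
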