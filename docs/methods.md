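# Methods

## Data model

A transaction database is an ordered list of prescriptions, each a non-empty
set of acupoint codes matching `[A-Z]{2,3}[0-9]{1,2}` after uppercasing.
Codes are opaque tokens: no nomenclature aliasing (RN/CV, DU/GV) is applied,
because the corpus this package targets uses the RN/DU convention throughout
and mapping between conventions is a curation decision, not a mining one.
Duplicate items within a prescription are deduplicated with a warning
(transactions are sets in all mining mathematics); transaction order is
preserved for reproducible I/O but is never semantically meaningful, and the
test suite asserts that every mining result is invariant to permutation.

## Thresholds and arithmetic

Support and confidence thresholds are inclusive and are applied on exact
integer counts: an itemset is frequent iff its count ≥ ⌈min_support · N⌉,
with the threshold fraction taken as the decimal literal the caller wrote
(`Fraction(str(x))`), never as a binary float. With N = 33 and min_support
0.24 the count threshold is 8. All four rule metrics are `fractions.Fraction`
values internally; report rounding is half-up on the exact rational
(`⌊x·10^d + 1/2⌋ / 10^d`), which matters in practice: the lift
(11/14)/(13/33) = 1.99450549… rounds to 1.995 on the rational but to 1.994
through a binary double. Reports print support/confidence/lift to 3 decimals
and expected confidence to 2, the conventions of the published tables.

## Mining

Apriori is the classical level-wise algorithm: sorted-prefix join of
frequent k-itemsets, subset-based pruning, then counting. FP-growth builds a
prefix tree over items ordered by descending frequency (ties lexicographic —
the ordering is an implementation detail and the output is provably
order-independent, which a relabelling test checks) and mines conditional
pattern bases recursively, with the single-path shortcut; a flag disables the
shortcut so tests can show it never changes output. The two implementations
are algorithmically independent and every run of the test suite checks them
against each other and against a third oracle, direct subset enumeration, on
randomized databases. Rule generation emits L ⇒ Z∖L for every non-empty
proper subset L of every frequent itemset of size ≥ 2, keeping rules with
confidence ≥ min_confidence; optional filters restrict consequent size
(`max_rhs_len=1` reproduces the single-consequent behaviour of the classical
R `arules` implementation, which is what published rule tables in this
literature show) or minimum lift (the published FP-growth rule list excludes
the low-lift PC6/ST36 rules; `min_lift` reproduces that exclusion when set).
Ranking sorts by descending support, then confidence, then lift, with a
lexicographic tie-break for run-to-run stability.

## Clustering

Acupoints are profiled as binary membership vectors over the N transactions.
For binary vectors the squared Euclidean distance is the number of
transactions on which two points disagree; Jaccard distance is provided as an
alternative. The default metric/linkage pair — squared Euclidean with
between-groups (average) linkage — follows the historical defaults of the
SPSS hierarchical-clustering procedure, the tool conventionally used for
this analysis step; both are configurable. Agglomeration and tree cutting
are delegated to `scipy.cluster.hierarchy` (`linkage`, `cut_tree`); an
independent naive O(n³) agglomeration that recomputes every linkage value
from the raw distances serves as the oracle in tests, compared on merge
heights over random continuous matrices (where ties have probability zero;
on exact ties the tie-break is scipy's). Cuts undo the last k−1 merges, so
the cut at k+1 always refines the cut at k. Dendrograms export to Newick
with branch lengths equal to merge-height differences. Reports emit both the
k = 3 and k = 6 cuts by default, the two granularities at which this corpus
is conventionally read.

The inclusion rule for "commonly used" points is a configurable minimum
count. On the reconstructed corpus `min_count = 2` selects exactly the 21
published cluster points — by construction, since the fixture assigns count
2 to the clustered non-core points and count 1 to the rest (the publication
states no explicit rule).

## Corpus reconstruction

The raw 33-formula database was never deposited. The reconstruction treats
every published statistic as a constraint on the joint distribution of the
seven core acupoints (ST36, RN12, SP6, RN4, PC6, HT7, DU20):

* each published pattern count is an exact linear equality over the 2⁷
  membership patterns;
* each published rule's (support, confidence) pair pins its antecedent's
  unprinted singleton count through integer search: the unique pair (a, b)
  with |a/33 − s| ≤ 5·10⁻⁴ and |a/b − c| ≤ 5·10⁻⁴ (e.g. 0.364/0.923 forces
  12/13, so RN4 appears in 13 formulas); ambiguity or absence of a solution
  raises an "inconsistent table" error;
* confidence-1.0 rules imply containment (every HT7 formula contains RN12);
* upper bounds cap unprinted core combinations below the levels at which
  they would have produced additional publishable rules (support ≥ 9/33 with
  confidence ≥ 0.75), since the published rule list is exhaustive down to
  support 9/33. One bound is forced the other way: inclusion–exclusion on
  |PC6| = 13, PC6∩RN12 = 9, PC6∩ST36 = 11 forces PC6∩RN12∩ST36 ≥ 7, so that
  triple is capped at exactly 7, just below the frequency threshold.

The resulting integer feasibility problem (128 variables, ~30 constraints)
is solved exactly by HiGHS through `scipy.optimize.milp`, with a seeded
random objective selecting one vertex of the (non-unique) solution set;
`verify` re-checks every constraint against the materialized database.
Filler acupoints then complete the 38-item universe: the 14 non-core
clustered points at count 2 and 17 further points at count 1, spread
greedily onto the smallest prescriptions, which lands the median
prescription size at the published value of 4. Because every filler count is
≤ 7 < 8, fillers can never enter frequent-pattern output. The database is
deterministic given the seed; different seeds give different, equally valid
databases, and every published metric is identical across them because the
constraints pin it.

The published rule table contains three expected-confidence cells (0.72 for
the ST36 consequent; 0.39 twice for the SP6 consequent) that contradict the
table's own lift column, which is consistent with the defining identity
lift = confidence / supp(R) only for 24/33 → 0.73 and 14/33 → 0.42. The
package computes expected confidence by its definition, so those three
cells reproduce as 0.73 and 0.42; every other published cell reproduces at
print precision.

## Synthetic generator

Each transaction is drawn independently (the real formulas come from
distinct trials, so no study-level correlation is modelled): core items
enter by their marginal probabilities — defaulting to the real corpus'
frequencies, e.g. ST36 at 24/33 ≈ 0.73 and RN12 at 22/33 ≈ 0.67 — then each
planted rule (L, R, p_cond) resamples the membership of R as
Bernoulli(p_cond) whenever L is fully present, so the conditional
probability of R given L is exactly p_cond; filler items enter at a
background rate of 0.04, chosen so that ~1.2 filler items on top of ~3.2
expected core items put the median prescription size at the published 4.
Empty transactions are rejected and redrawn (negligible probability under
the defaults, and ignored in the closed forms). Defaults plant one
deterministic dependency (HT7 ⇒ RN12 at p = 1) and one strong stochastic one
(RN4 ⇒ SP6 at 11/13), mirroring the real corpus' structure.

Closed-form support/confidence/lift are available for singleton pairs
covered by at most one planted rule — e.g. for planted (a ⇒ b, p): the
marginal of b becomes p_a·p + (1−p_a)·p_b, confidence is exactly p, and lift
is p over that marginal; pairs touched by overlapping rules raise a
"no closed form" error. Monte-Carlo agreement with these forms at
n = 100,000 (within 3 standard errors) and parameter recovery by mining at
n = 10,000 are part of the test suite.

What the generator does *not* emulate: syndrome-differentiation structure,
meridian theory, study-level clustering of formulas, or any dependence among
filler items. Passing tests therefore demonstrate correctness of the mining
machinery on independently drawn transactions with planted pairwise
structure, not fidelity to the full generative process of real prescription
corpora.

## Problem sizes

The regression corpus is the reconstructed 33-transaction database. The
randomized cross-checks use 200 databases of up to 15 items and 24
transactions (mining, against two oracles), 10 random matrices up to 12
items × 3 linkages (clustering), and generator draws of 10,000 and 100,000
transactions (parameter recovery and closed-form agreement); the whole suite
runs in a few seconds on one CPU.

## Known limitations

* The reconstruction is observationally equivalent to the original database
  with respect to the published statistics, not equal to it; statistics the
  publication does not constrain (e.g. counts of the 8th–10th most frequent
  points) are fixed at documented plausible values and should not be read as
  findings.
* The exact dendrogram of the original analysis is not reproducible — the
  metric, linkage and inclusion rule were not published; the defaults here
  are a best-evidence reconstruction and the cluster tests are structural
  (oracle agreement, refinement, monotonicity), not a pixel match.
* Exact-rational arithmetic is O(frequent itemsets × 2^size) in rule
  generation; this is intended for corpora of tens to hundreds of
  prescriptions, not for large retail-scale baskets.
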