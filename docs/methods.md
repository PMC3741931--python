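# Methods

## The analysis in one paragraph

An operation-centric OSCC cohort (every retained patient's treatment
sequence begins with surgery) is discretized into categorical attributes,
split at 36 months of survival, and the long-survivor stratum is mined for
association rules over four analysis attributes: grade/differentiation,
clinical stage group (early = stages 0–3, late = stage 4), primary site,
and group (OP vs non-OP).  Mining is level-wise Apriori with hash-tree
candidate counting; rules are scored by confidence, lift, leverage and
conviction and ranked by lift.  A univariate layer cross-tabulates each
attribute against the survival dichotomy with Pearson chi-square tests.

## Discretization

Interior bins are closed on both ends, outer bins open:

* age: `<30`, `[30, 50]`, `(50, 70]`, `>70` years;
* tumor sizes: `<2 cm`, `[2, 4] cm`, `>4 cm` (so a 2.0 cm tumor is `2~4 cm`);
* nodes examined: `<5`, `[5, 10]`, `>10`;
* stage codes 0–4 collapse to `early` (0–3) / `late` (4);
* treatment sequences map to surgical-modality groups `01` (surgery only),
  `02` (surgery → intra-arterial chemotherapy), `03` (surgery followed by
  any other recorded chemo/radiotherapy pattern); unrecognized sequences
  are flagged missing rather than guessed.

The bin-boundary convention is a documented package choice; none of the
benchmark quantities depend on it.  Missing values always carry the
explicit `missing` marker and are excluded listwise per analysis — never
imputed — matching transaction semantics, where a patient either
contributes all selected items or none.

## Mining engine

`min_support` defaults to 0.09: every benchmark rule has support
27/271 ≈ 0.0996, and 0.09 is the coarsest round threshold that admits them.
The hash tree defaults to branching constant `T = 3` and leaf capacity 8,
with leaves at depth k (all items consumed) absorbing overflow; these
parameters only shape the counting structure, and an invariant test
verifies the mined counts are identical for `T ∈ {2, 3, 5}` and leaf
capacities `{1, 4, 16}`.  Transactions shorter than k are skipped at level
k since they cannot contain a k-subset.  Mining output is exact: on small
random databases it is tested equal to exhaustive enumeration of all
vocabulary subsets.

## Rule metrics and the conviction variant

Lift is computed in the symmetric count form `n_XY · N / (n_X · n_Y)`, so a
rule and its mirror get bitwise-identical lift — mathematically equal
mirrors must tie exactly during ranking, and this form guarantees it
without rounding.  Conviction defaults to the Laplace-smoothed count form

    n_X (N − n_Y) / (N (n_X − n_XY + 1)),

the variant under which the package's benchmark table reproduces; the
unsmoothed form `n_X (N − n_Y) / (N (n_X − n_XY))` (infinite for exact
rules) is available and always at least as large.

## Canonical rule order

Rules are ranked by the sort metric descending with a *stable* sort over a
deterministic generation order: frequent itemsets by level then id order,
and within an itemset every body enumerated by ascending bitmask over the
itemset's id-sorted items.  Item ids follow the attribute order given to
`encode_transactions` (values lexicographic within an attribute), so with
the canonical attribute order (grade, clinical stage group, primary site,
group) the report's row order — including the order within tied mirror
pairs — is fully reproducible.  A metric-based tie-break (e.g. confidence
descending) was deliberately not used: no such rule orders the benchmark's
tied pairs consistently, whereas generation order does.

## Univariate layer

Pearson chi-square without continuity correction on the category ×
outcome table, after dropping all-zero rows/columns; df = (r−1)(c−1).
Degenerate tables (fewer than two informative rows or columns) return a
no-test status instead of raising.  Expected cells below 5 attach a warning
but do not switch to an exact test.  Type-I calibration is checked by
simulation: on 1000 independent 3×2 multinomial tables (n = 400) the
0.05-level rejection rate must lie in 5% ± 1.5%.  The 5-year survivor flag
is survival > 60 months, `False` only for deaths at ≤ 60 months, and
unknown for patients alive but censored earlier.

## Synthetic cohort generator

The generator emulates the reference cohort's study conditions: 493
patients, 271 above / 222 at-or-below 36 months, and per-stratum category
counts assigned **exactly** from the reference marginals (shortfalls —
e.g. clinical stage recorded for only 431 of 493 — become missing values).
Attributes are assigned independently of one another within a stratum;
raw values (age, sizes, node counts, stage codes, treatment sequences) are
drawn uniformly inside the assigned category.  Survival months are uniform
on (36, 120] and [1, 36] in the two strata; vital status is alive with
probability 0.65 (long survivors) / 0.15 (short survivors).  These last
choices are cosmetic realism for round-tripping, not calibrated quantities.

A planted association replaces independent sampling for the planted
attributes in the long-survivor stratum: a share λ of patients receives
the full planted combination and the rest draw each planted indicator
independently with probability (p_j − λ)/(1 − λ), with λ solved by
bisection so the joint probability equals `planted_boost` times the
independence product while every marginal p_j is preserved exactly.
Boosts implying a joint above the smallest involved marginal are rejected
with the violated bound.

What the generator does *not* emulate: any between-attribute dependence of
the real registry beyond the planted itemset, calendar time, follow-up
censoring patterns, or per-category 5-year survival percentages (which
cannot be reconstructed jointly across attributes from marginals alone).
Tests that pass on synthetic cohorts therefore establish correctness of
the pipeline's counting, testing and ranking — not clinical conclusions.

## The deterministic benchmark fixture

The benchmark surface is a 271-transaction database over the four analysis
attributes whose item and joint counts satisfy eleven published constraints
(e.g. grade=02 in 60 transactions, tongue in 88, the full four-item
combination in 27).  These constraints fix six of the sixteen cells of the
binary joint distribution; the free cells are set by a generic search for
the lexicographically smallest non-negative integer solution (constraint
propagation plus backtracking), giving the frozen cell vector
`[0,0,0,150,5,13,5,38,2,9,3,19,0,0,0,27]` and a fully deterministic
fixture.  All eleven constraints are re-asserted at build time.  Every
metric of the top-10 rule benchmark depends only on the constrained
counts, so the fixture reproduces the benchmark exactly even though its
free cells (in particular the early/late and OP/non-OP margins) are not
registry quantities.

## Planted-rule recovery

`recovery_experiment` draws the four analysis attributes for an n-patient
stratum with the four-item combination planted at a target boost
(marginals fixed to the benchmark stratum's: 60/271, 88/271, 242/271,
256/271), mines each draw, and counts a success when the two top
lift-ranked rules lie entirely inside the planted itemset.  Rules over
strict subsets of the planted items count as recovery: they carry the same
planted signal and their population lifts (≈1.78 at boost 1.9) sit within
sampling noise of the full partitions' (≈1.83).  The ranking uses a lift
filter of 1.0 so that recovery measures ranking, not filter passage.  At
the benchmark conditions (n = 271, boost 1.9 ≈ planted lift 1.9) recovery
is ≥ 95% over 200 seeds; at boost 1.0 it falls to chance, and at n in the
thousands it reaches 1.0.

## Problem sizes and numerical notes

The acceptance-grade checks run on small instances by design: oracle
equivalence uses 100 random databases of ≤ 25 transactions and ≤ 8 items
(where exhaustive enumeration is exact and instant), calibration uses 1000
simulated tables, and recovery uses 200 seeds of 271 transactions — the
stratum size of the reference analysis.  Display rounding is
half-away-from-zero to 2 decimals (1-dp for survival percentages);
internal computations are full double precision, with exact-integer count
arithmetic wherever a quantity is a ratio of counts.

## Known limitations

* The mining engine is the classic three-pass algorithm only — no
  FP-growth, no out-of-core or parallel counting; it targets cohort-scale
  categorical data (hundreds to tens of thousands of rows, few attributes).
* Chi-square P values for tables with very sparse categories rely on the
  asymptotic distribution; the package warns rather than substituting an
  exact test.
* The synthetic generator's independence-between-attributes assumption
  means multivariate structure beyond a single planted itemset is absent.
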