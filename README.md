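# clinrules

Association-rule mining for categorical clinical cohorts, built around the
question it was designed for: **which clinicopathologic factors co-occur
among oral squamous cell carcinoma (OSCC) patients who do well after
surgery?**  In an operation-centric cohort — every patient treated primarily
by surgical operation (OP) — survival is dichotomized at 36 months, each
patient becomes a transaction of `attribute=value` items, and a level-wise
Apriori engine mines the long-survivor stratum for rules such as

```
{grade = 2, clinical stage = early}  =>  {primary site = tongue, group = OP}
```

The package is aimed at biostatisticians and clinical data scientists who
want transparent, count-exact rule mining on small categorical tables —
with the mining engine, the interestingness metrics and the ranking all
inspectable — rather than a black-box toolkit call.

## What it computes

For a transaction set *D* of *N* patients, an itemset is *frequent* when
its support (fraction of transactions containing it) reaches a minimum
support threshold.  Frequent itemsets are mined level by level: single-item
counting, candidate generation by the classic apriori-gen join/prune, and
candidate counting through a hash tree whose interior nodes route item *i*
to bucket *i* mod *T*.  Every frequent itemset of size ≥ 2 is split into
body *X* and head *Y*, scored with

| metric | formula (counts) | under independence |
|---|---|---|
| confidence | n<sub>XY</sub> / n<sub>X</sub> | — |
| support | n<sub>XY</sub> / N | — |
| lift | (n<sub>XY</sub> / n<sub>X</sub>) / (n<sub>Y</sub> / N) | 1 |
| leverage | n<sub>XY</sub>/N − (n<sub>X</sub>/N)(n<sub>Y</sub>/N) | 0 |
| conviction | n<sub>X</sub>(N − n<sub>Y</sub>) / (N(n<sub>X</sub> − n<sub>XY</sub> + 1)) | ≈ 1 |

and ranked by lift (descending, stable) after a minimum-lift filter.  The
conviction shown is the Laplace-smoothed variant used by common rule-mining
toolkits; the unsmoothed textbook form is available as
`conviction_variant="standard"`.

A univariate layer (contingency tables, Pearson chi-square without
continuity correction, per-category 5-year survival percentages) covers the
descriptive side, and a synthetic-cohort generator plus a deterministic
271-patient benchmark fixture make the entire pipeline testable without
access to registry data.

## Worked example

```python
import clinrules as cr

db = cr.build_reference_fixture()          # 271 long-survivor transactions
frequent = cr.mine_frequent(db, min_support=0.09)
rules = cr.generate_rules(frequent, db)    # 134 rules, laplace conviction
report = cr.rank_rules(rules, sort_metric="lift", min_lift=1.5, top_k=10)
print(report.to_frame().to_string(index=False))
```

prints (first two of ten rows):

```
                                body  n_body                                 head  n_joint  confidence  lift  leverage  conviction
grade=02, clinical_stage_group=early      49        primary_site=tongue, group=OP       27        0.55  1.91      0.05        1.52
       primary_site=tongue, group=OP      78 grade=02, clinical_stage_group=early       27        0.35  1.91      0.05        1.23
```

Reading row 1: 49 long survivors have moderately differentiated (grade 2),
early-stage tumors; 27 of them (confidence 0.55) are also tongue-site
surgical cases.  Lift 1.91 means that combination occurs almost twice as
often as independence would predict; leverage 0.05 is the excess joint
probability; conviction 1.52 quantifies how much the rule would be
contradicted if body and head were unrelated.  Mirrored rules (rows 1–2)
share lift and leverage exactly — both are direction-free.

The `examples/` directory holds one short script per capability
(benchmark reproduction, metric walkthrough, synthetic-cohort univariate
analysis, planted-rule recovery), each printing the numbers it computes.

## Command line

```bash
clinrules simulate --seed 42 --out raw.csv      # synthetic raw cohort
clinrules ingest --input raw.csv --out cohort.csv
clinrules mine --input cohort.csv --population survived_gt36 \
    --min-support 0.09 --min-lift 1.5 --top-k 10 --out rules.tsv
clinrules univariate --input cohort.csv --out table1.tsv
clinrules fixture --out benchmark.csv           # the deterministic fixture
```

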