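# acumine

Association-rule mining and clustering of acupoint prescription databases.

## The problem

Clinical trials of acupuncture for cancer-related anorexia (CA) each report a
*prescription* — the set of acupoints (coded `ST36`, `RN12`, …) stimulated in
one treatment arm. Evidence syntheses treat these prescriptions as market-basket
*transactions* and mine them for the acupoint combinations that trialists
repeatedly choose together: which points dominate, which pairs and triples
co-occur beyond chance, and how the points group by co-usage.

`acumine` is a tested, reusable implementation of that pipeline for anyone
doing this kind of prescription-pattern synthesis:

* **frequency profiling** — per-acupoint transaction counts and proportions;
* **frequent-itemset mining** — two independent implementations, Apriori and
  FP-growth, required to agree exactly;
* **association rules** — for a rule L ⇒ R over N transactions,

  - support = supp(L ∪ R),
  - confidence = supp(L ∪ R)/supp(L),
  - expected confidence = supp(R) (the confidence under independence),
  - lift = confidence / expected confidence,

  all kept as exact rationals internally and rounded only in reports;
* **hierarchical clustering** of acupoints on their binary co-occurrence
  profiles (squared Euclidean / Jaccard; average / complete / single linkage),
  with Newick export and k-cluster cuts;
* **a constraint-reconstructed corpus**: the published CA analysis (33
  formulas from 27 controlled trials, 38 acupoints) never deposited its raw
  database, but its printed summary counts and rule metrics over-determine
  much of it. `acumine.fixture` turns every published statistic into an
  integer constraint and solves for a 33-transaction database that is
  observationally equivalent to the original with respect to every published
  number (it is *not* claimed to be the original data);
* **a synthetic generator** with planted antecedent ⇒ consequent dependencies
  and closed-form expected metrics, for testing at any scale.

Thresholds default to the study's reporting conventions: minimum support 24%,
minimum confidence 75%, applied inclusively on exact integer counts
(0.24 × 33 = 7.92, so a count of 8 is frequent).

## Worked example

Reconstruct the corpus, profile it, and mine single-consequent rules:

```sh
$ acumine fixture -o fixtures/ca33.csv
$ acumine freq fixtures/ca33.csv --top 5
item    count   proportion
ST36    24      0.727
RN12    22      0.667
SP6     14      0.424
PC6     13      0.394
RN4     13      0.394
```

Zusanli (ST36) appears in 24 of the 33 formulas and Zhongwan (RN12) in 22 —
the two workhorse points of the corpus.

```sh
$ acumine mine fixtures/ca33.csv --max-rhs-len 1 --top-rules 10 --itemsets-out itemsets.tsv
lhs       rhs   support  confidence  expected_confidence  lift
RN4       RN12  0.364    0.923       0.67                 1.385
RN4       SP6   0.333    0.846       0.42                 1.995
PC6       ST36  0.333    0.846       0.73                 1.163
SP6       RN4   0.333    0.786       0.39                 1.995
SP6       RN12  0.333    0.786       0.67                 1.179
RN12;SP6  RN4   0.303    0.909       0.39                 2.308
RN4;SP6   RN12  0.303    0.909       0.67                 1.364
RN12;RN4  SP6   0.303    0.833       0.42                 1.964
DU20      RN12  0.273    1.0         0.67                 1.5
HT7       RN12  0.273    1.0         0.67                 1.5
```

Read the first row as: Guanyuan (RN4) appears in 12/33 formulas together with
Zhongwan (RN12) (support 0.364); when RN4 is prescribed, RN12 accompanies it
92.3% of the time, 1.385× more often than RN12's 67% base rate. The strongest
association by lift is {SP6, RN12} ⇒ RN4 (2.308). Shenmen (HT7) and Baihui
(DU20) are *always* prescribed with RN12 (confidence 1.0). Without
`--max-rhs-len 1` the miner also emits multi-consequent rules such as
RN4 ⇒ {RN12, SP6}; `--algorithm fpgrowth` produces a byte-identical itemset
table.

```sh
$ acumine cluster fixtures/ca33.csv -k 6 --newick-out tree.nwk --partition-out -
k  item  cluster_id
6  ST36  1
6  RN12  2
6  SP6   3
6  RN4   3
...
```

At k = 6, the frequently-used points split into singleton clusters for the two
dominant points (ST36, RN12), an {SP6, RN4} pair, and groups of the
lower-frequency points — the same qualitative structure the published
dendrogram shows.

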