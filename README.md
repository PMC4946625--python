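# netincon

Loop inconsistency models and the design-by-treatment (DxT) interaction
framework for network meta-analysis.

A *design* is the set of treatments compared within one study. A treatment
ordering induces a *loop inconsistency model*: designs are grouped by the
earliest-ordered treatment they contain, and designs within a group are
assumed to estimate the same relative effects. The package

- enumerates designs, builds loop inconsistency models from orderings, and
  forms their unions (common refinements of design partitions);
- machine-verifies that any two distinct designs are separated by a
  constructively built witness ordering, and that the union of all loop
  models is the discrete partition — i.e. the DxT interaction model — on
  full or arbitrary observed design sets;
- translates any design partition into an identifiable contrast-level design
  matrix (basic effects versus a reference plus group-level inconsistency
  offsets, reduced by deterministic rank-revealing elimination);
- fits consistency, loop, and DxT models to contrast data by generalized
  least squares with a common heterogeneity variance τ² (exchangeable
  within-study structure), estimates τ² by a matrix method-of-moments
  generalization of DerSimonian–Laird, and performs the global Wald
  chi-square test for inconsistency;
- simulates contrast-level networks with configurable basic effects,
  heterogeneity, and per-design inconsistency offsets, including correlated
  contrasts from multi-arm studies.

## CLI

Every invocation emits one JSON run report on stdout (with `--format text`,
the human-readable rendering goes to stdout and the report to stderr).

```sh
netincon enumerate --treatments A,B,C,D
netincon loop-model --ordering C,B,D,A --format text
netincon union --treatments A,B,C,D --orderings "C,B,D,A;A,B,C,D"
netincon union --treatments A,B,C,D --orderings all
netincon verify --n 4                     # lemma + theorem, exit 1 on failure
netincon simulate --scenario triangle --omega 0.3 --tau2 0.04 \
    --studies 5 --seed 42 --out data.csv
netincon fit --data data.csv --model dxt --tau2 auto
netincon fit --data data.csv --model loop:C,B,D,A
netincon test --data data.csv --tau2 0.04
```

### Data format

CSV (UTF-8, comma, dot decimal), one row per study contrast:

```
study,design,baseline,treatment,estimate,variance
```

Within-study covariances of multi-arm studies live in a sidecar
`<stem>.cov.csv` with columns `study,t1,t2,cov`; missing off-diagonals
default to zero. `netincon simulate` writes both files.

## Library sketch

```python
from netincon import (
    enumerate_designs, loop_model, partition_union, union_over_orderings,
    distinct_orderings, verify_lemma, verify_theorem,
    build_matrix, inconsistency_df, model_contains, one_study_per_design,
    discrete_partition, single_group_partition,
    fit_gls, estimate_tau2, wald_inconsistency_test,
    scenario, simulate_network,
)

designs = enumerate_designs("ABCD")            # the 11 possible designs
l1 = loop_model(("C", "B", "D", "A"), designs)  # 3 groups
l2 = loop_model(("A", "B", "C", "D"), designs)
union = partition_union(l1, l2)                 # 6 groups
assert verify_theorem(designs)                  # union of all = discrete

data = simulate_network(scenario("triangle", omega=0.3, studies=5, seed=42))
result = wald_inconsistency_test(data, tau2=0.0)
print(result.statistic, result.df, result.p_value)
```

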