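# netphen

Group comparison of brain connectivity matrices and multi-domain
phenotype scores, built for case–control designs such as comparing a
substance-use-disorder group against non-users. The package bundles the
full statistical pipeline such a study needs once preprocessing has
produced per-subject Fisher-z connectivity matrices and a phenotype
table:

- **Preparation** — monotone transforms (`x^e`, `1/x`, `log x`),
  residualization on age, age², sex and their interactions, Fisher
  r-to-z, edge-wise >4 SD outlier screening with subject exclusion, and
  a PCA-derived general cognitive score *g*.
- **Univariate comparison** — GLM group tests (pooled two-sample *t*
  when unadjusted), pooled-SD Cohen's *d*, Benjamini–Hochberg FDR within
  explicit families, and Pearson/Spearman correlations for post-hoc
  analyses.
- **Network-based statistic (NBS)** — edge-wise *F* tests, suprathreshold
  connected components scored by *extent* (edge count) or *intensity*
  (summed *F*), and max-component permutation p-values that control the
  family-wise error rate; exhaustive label enumeration for tiny samples.
- **Graph metrics over density curves** — graphs matched across subjects
  by retaining the top 1–40% strongest positive/negative edges; global
  efficiency, degree, strength, clustering, signed (asymmetric) Louvain
  modularity and participation coefficient on the union graph; the group
  difference is the **area between group mean curves**, tested by
  permutation; block-level (module-pair) mean-FC comparisons.
- **Evidence** — interval-null JZS Bayes factors (standardized effects in
  (−0.1, 0.1) count as null-equivalent) by adaptive quadrature of the
  noncentral-*t* likelihood over a truncated Cauchy(0, √2⁄2) prior, and
  the posterior probability of association (PPA) for multiplicity-aware
  interpretation: posterior odds = BF · π/(1−π).
- **Synthetic cohorts** — a generator producing two-group cohorts with
  modular connectivity, covariate-dependent edges, a planted connected
  edge component, heavy-tailed edge outliers, an optional subject-global
  additive signal (its absence mimics global-signal-regressed data), and
  phenotype batteries loading on a shifted latent factor — so the whole
  pipeline is testable end-to-end without access to subject data.

## Worked example

```python
from scipy import stats
from netphen import (CohortSpec, simulate_cohort, build_design, residualize,
                     GroupComparison, evaluate_evidence, NetworkBasedStatistic)

spec = CohortSpec(
    n_case=40, n_control=90, n_nodes=60, n_modules=4,
    planted_edges=tuple((0, j) for j in range(1, 7)),   # 6-edge star
    effect_delta=0.08, edge_noise_sd=0.1,
    phenotype_effect=-0.6, seed=42,
)
cohort = simulate_cohort(spec)

design = build_design(cohort.phenotypes)                 # age, age², sex, interactions
rm = residualize(cohort.phenotypes["verbal_memory"], design)
res = GroupComparison(rm.values, cohort.groups, name="verbal_memory").fit()
print(res.summary())

ev = evaluate_evidence("verbal_memory", res.statistic,
                       res.n_case, res.n_control, prior_pi=0.1)
print(f"BF = {ev.bf:.2f}  PPA = {ev.ppa:.3f}  grade = {ev.grade}")

ids, stack = cohort.connectome_stack()
groups = cohort.groups.loc[ids].to_numpy()
model = NetworkBasedStatistic(stack, groups,
                              design=design.loc[ids].to_numpy(float))
thr = round(stats.f.isf(0.001, 1, len(ids) - 2), 2)      # primary threshold
fit = model.fit(threshold=thr, statistic="intensity", n_perm=5000, seed=7)
print(fit.summary().head(3).to_string(index=False))
```

Output:

```
verbal_memory: case -0.240 (0.799, n=40) vs control 0.107 (1.064, n=90); d=-0.350, t(128)=-1.841, p=0.06791
BF = 0.81  PPA = 0.083  grade = inconclusive
 component  threshold  extent  intensity  p_extent  p_intensity  nodes
         0      11.34       5  88.973347    0.0002       0.0002      6
```

The cognitive score is modestly lower in cases (*d* = −0.35) but the
evidence is inconclusive (BF between 0.3 and 3; with a 0.1 prior the
posterior probability of a real association is 8%). The NBS recovers the
planted connectivity component: 5 suprathreshold edges over 6 nodes,
whose summed *F* of 89.0 is larger than the maximum null component in
all 5,000 group-label permutations (p = 1/5001 ≈ 0.0002).

There is also a CLI (`netphen simulate|qc|compare|nbs|evidence|run-all`)
mirroring these stages; `run-all` drives the full pipeline from a YAML
config and writes CSV/JSON reports plus a provenance manifest.

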