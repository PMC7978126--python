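# Methods

This note documents the statistical models the package implements, the
choices made where conventions differ, and what the synthetic-data tests
do and do not establish.

## Preparation of measures

Every comparison operates on standardized residuals. A measure is
optionally transformed (`x^e`, `1/x`, or `log x` — declared per measure
in config, never inferred automatically, because visual transform
selection is not reproducible), regressed on the covariate design, and
the residuals are z-scored over the retained sample with both groups
pooled. Pooled scaling is what makes group means of standardized
residuals informative (they need not be 0/0). The design is intercept,
age, age², sex, age·sex and age²·sex — the full crossing of the age
terms with sex — plus any named confounders; age is centered before
squaring, which improves conditioning without changing the column space.
The group label never enters this design.

Degenerate cases are errors, not silent results: transforms reject
domain violations instead of clipping, a measure lying in the design's
span raises a named "near-zero residual variance" error, and
rank-deficient designs report exactly which columns are mutually
collinear.

Connectivity is analysed on the Fisher-z scale (`atanh r`). Edge-level
QC flags subject-edges more than 4 SD from the cross-subject edge mean
(SDs estimated in a single pass, not re-estimated after exclusions;
zero-SD edges are reported, never flagged) and excludes subjects whose
outlier-edge count exceeds a cut that scales with matrix size — 1,000
edges on a 382-parcel (72,771-edge) matrix, i.e. ≈1.4% of possible
edges, rescaled for other parcellations and overridable.

The general cognitive score *g* is the first principal component of the
z-scored battery, with per-test median imputation of missing cells
(flagged in the output) and the sign oriented so a designated anchor
test loads positively.

## Group tests and effect sizes

The group test is the two-sided *t* of the group coefficient in an OLS
fit with optional extra confounders; without confounders it is exactly
the pooled two-sample *t* (and *F* = *t*²). Cohen's *d* uses the pooled
SD, *d* = (m₁ − m₂)/s_p with s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),
case minus control — this is the definition that reproduces published
effect-size tables from their printed group summaries (no Hedges
correction, no Welch denominator). FDR is Benjamini–Hochberg, the field
default where "FDR" is unqualified, applied within explicit families so
each correction set is auditable.

## Network-based statistic

Edges are residualized against the covariate design once, up front;
group labels are then exchangeable under the null, so the permutation
scheme is simple relabeling (full Freedman–Lane is out of scope). Each
edge gets *F* = *t*² with df (1, n−2). Edges with *F* at or above the
primary threshold form a graph whose connected components are scored by
extent (edge count) and intensity (summed *F* — the raw sum, not the
exceedance over the threshold). The null distribution is the maximum
component score over permutations, which controls family-wise error at
the component level. Sampled permutations use the add-one estimator
p = (1 + #{null ≥ obs})/(1 + n_perm), unbiased against p = 0; when the
distinct label splits number no more than `n_perm` (e.g. 4+4 → 70
splits) they are enumerated exhaustively and the exact proportion is
reported. The primary threshold is user input (defaults 15, 16, 17 in
pipeline config); there is no automatic threshold selection. Intensity
comparisons against the null use a 10⁻⁹ relative tolerance so the
identity permutation is never lost to float noise.

## Graph metrics over density

Because graph metrics are density-sensitive, all subjects' graphs are
matched by edge count: at density *d*% the top k = ⌊d/100 · n_possible⌋
same-sign edges by signed magnitude are retained, ties broken by
lexicographic edge index so thresholding is reproducible. The feasible
upper bound is the floor of the cohort-minimum same-sign edge fraction,
capped at 40%; the pipeline also drops leading grid densities where
k = 0 on small matrices. Efficiency, degree and clustering are computed
on the binarized graph (the dominant convention in density-matched
designs); strength sums retained |weights|, keeping negative-graph
metrics nonnegative and comparable across signs. Global efficiency is
the mean inverse shortest-path length over ordered pairs, disconnected
pairs contributing zero.

Modularity and participation use the union of the positive and negative
thresholded graphs (density twice that of single-sign metrics).
Modularity is maximized by a Louvain scheme on the asymmetric signed
quality Q\* = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻ at resolution 1, with 10 seeded
restarts by default (best quality kept); participation is
P_i = 1 − Σ_m (k_im/k_i)² on positive weights, using each subject's own
partition — no group-template partition is imposed. The pipeline
computes modularity and participation from a single Louvain pass per
graph since they share the partition.

A metric traced over the grid forms a curve per subject; the group
difference is the signed area between group mean curves with a unit
density step, Σ_d (mean_case(d) − mean_control(d)). Because this
statistic is linear in per-subject curve sums, the permutation test
reduces to a two-sample mean comparison of subject-level areas, which
the implementation exploits for speed; p is two-sided on |area| with the
add-one estimator. Cohen's *d* and Bayes factors are computed on the
per-subject density-averaged metric. Regional (per-node) p-values are
FDR-corrected across nodes, per metric. Nodes whose curve is constant in
every subject (e.g. clustering of isolated nodes) get *d* = 0 rather
than a divide-by-zero.

Block-level summaries are unweighted means of Fisher-z edges per module
pair (within-module excluding the diagonal), per module to the rest of
the brain, and over the whole matrix, each compared through the same
residualize-and-test machinery in its own FDR family.

## Evidence: interval-null Bayes factors and PPA

The Bayes factor contrasts a Cauchy(0, √2⁄2) prior on the standardized
effect truncated to the *complement* of the null interval (default
(−0.1, 0.1)) against the same prior truncated to the interval — the
evidence ratio for "an effect big enough to matter" versus "a negligible
effect". Each marginal likelihood is an adaptive quadrature of the
noncentral-*t* density of the observed *t* over the truncated prior
(integration split at zero and at the likelihood peak; relative
tolerance 10⁻⁹), with df = n₁+n₂−2 and effective n = n₁n₂/(n₁+n₂). As
the interval shrinks this converges to the standard point-null JZS
Bayes factor, which is exposed separately and used as a cross-check. The
√2⁄2 "medium" prior scale is the default of the standard Bayes-factor
software for this test.

PPA converts BF to a posterior probability given a prior probability of
association π: posterior odds = BF·π/(1−π), PPA = odds/(1+odds). Priors
are explicit inputs, never silent defaults: the pipeline uses 0.1 for
small hypothesis-driven families and 1/m for an m-test exploratory
family, both overridable per family in config. Evidence grades follow
the conventional thresholds — BF < 0.3 substantial for the null region,
BF > 3 substantial and BF > 10 strong for the alternative, boundaries at
0.3 and 3 counted as inconclusive.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: a
modular base connectivity pattern (within-module Fisher-z 0.30, between
0.05), independent Gaussian edge noise (SD 0.10), an additive group
shift on one planted connected edge set (cases only, so control
expectations stay at base), per-SD covariate slopes added to all edges,
an optional subject-level global constant (SD 0 by default, i.e.
GSR-like data), and heavy-tailed outliers drawn as Student-t(2) deviates
scaled by 4× the edge noise SD so >4 SD events occur at a controllable
rate. Ages are Uniform(18, 70) and sex Bernoulli(0.45), matching the
sampled population's support; default group sizes are 39 cases and 92
controls, the imaging group sizes of the design this pipeline targets.
Phenotype scores load on a single latent factor (loadings 0.45–0.7
across six domains) with unique variances chosen for unit total
variance; a group shift on the factor induces correlated test deficits.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: spatial autocorrelation and correlated
edge noise, motion artefacts, non-Gaussian FC distributions,
site/scanner effects, and real covariate–outcome confounding structure.
Calibration results (type-I error of the permutation tests) transfer to
any exchangeable null; power figures are specific to the independent-
noise model and should be read as machinery checks, not study planning
numbers.

## Problem sizes used in validation

The test suite exercises the machinery at reduced but structurally
faithful sizes chosen so the whole suite runs in minutes on one core:
NBS false-positive calibration uses 200 null cohorts of 20+20 subjects
on 50 nodes with 1,000 permutations; curve-test calibration uses 500
null runs of 20+20 curves with 1,000 permutations; the planted-component
power fixture uses 8 planted edges at a standardized effect of 0.5 with
40+40 subjects at the F(α=0.001) primary threshold; pipeline determinism
runs 60+60 subjects on 100 nodes with 1,000 permutations. The measured
detection rate of the planted-component fixture (≈0.27, pre-registered
from an independent brute-force oracle run of 100 seeds) is what this
configuration yields analytically: with a per-edge standardized effect
of 0.5, each planted edge exceeds the α=0.001 threshold with probability
≈0.12, and detection essentially requires at least two exceedances among
the eight planted edges (≈0.25) — a useful reminder that component-level
power at stringent primary thresholds is modest for mid-sized effects.

## Known limitations

- Permutation inference assumes exchangeability after covariate
  residualization; heteroscedastic groups or covariate–group interactions
  violate this.
- Louvain is a heuristic: restarts reduce but do not eliminate the
  chance of suboptimal partitions; results are seed-deterministic, not
  globally optimal.
- The curve-area statistic weighs all densities equally; effects
  confined to a narrow density band dilute.
- Single imputation (per-test medians) before PCA/Bayes factors
  understates uncertainty from missingness; multiple imputation is out
  of scope.
- Weighted shortest-path efficiency variants, consensus clustering,
  TFCE-style statistics and directed networks are not implemented.
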