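# Methods

This note documents the models, conventions and numerical choices behind
`traitspace`, and what the synthetic study conditions do and do not
establish about real questionnaire data.

## Scoring and reliability

Responses are integers on each instrument's declared scale `[min, max]`.
Reverse-keyed items are mapped `v → min + max − v`, an involution on the
scale. The autism-quotient instrument is scored on the graded 1–4 scale
by default (so its range resembles the other instruments); the original
binary scoring (agree side → 1) is available as a mode. Out-of-range or
unknown responses are hard errors naming subject, item and value —
loading never imputes, because silent imputation would distort the
correlation structure every later stage consumes. Missing rows can only
be rejected (default) or listwise-deleted on request.

Cronbach's alpha is `k/(k−1) · (1 − Σσ_i²/σ_x²)` with **sample**
variances (denominator n−1) throughout; the formula is
convention-consistent, so the choice only matters if mixed, which is why
it is fixed and stated. Split-half reliability uses the odd/even item
positions (the source analysis does not state its partition; a fixed
positional split keeps the statistic reproducible) with Spearman–Brown
correction `2r/(1+r)`. The high-sensitivity prevalence helper takes the
scale threshold as configuration — the published criterion it would
mirror is external — and excludes subjects above the depression cutoff
(default 53 scale points) from the denominator.

## Synthetic cohorts

The generator is a two-level Gaussian factor model discretized to
Likert scales. Cluster factors `c1, c2 ~ N(0,1)` with correlation `b`
(default −0.4); trait `t` in cluster `k` has factor
`f_t = √w_t·c_k + √(1−w_t)·u_t` with per-trait cluster coupling `w_t`
(default 0.45; 0.65 for the hub traits conscientiousness and
neuroticism, which gives them the strongest correlations and hence the
highest graph centrality). An item is `y = λ f + σ ε` with loading
λ = 0.7 and, by default, `σ = √(1−λ²)` so continuous items have unit
variance and two same-trait items correlate at λ². Subdomains may carry
a private factor coupled to an overridden cluster, or load directly on a
*neighboring trait's* factor (`mix_with`): the aesthetic-sensitivity
subdomain of the sensitivity scale uses `mix_with="openness"`, which
places its items inside the openness item cloud — an intermixed, not
merely adjacent, planting. That distinction matters: a private
opposite-cluster factor would produce a separable blob that a linear
classifier would rightly keep.

Subject groups add mean shifts. The outer groups shift the cluster
factors by ±3.0 in opposite directions (proportions 328/296/213 of 837,
the group sizes implied by the reported per-group degrees of freedom).
The moderate group has no cluster shift but a distinct two-trait
signature (autism +5, extraversion +4 on the factor scale, roughly
halved after z-scoring by the shift-inflated trait variances). A
single-trait signature cannot work here: under correlation distance a
moderate subject's own cluster-factor tilt (variance 1) aligns half of
them with an outer group, and an autism-only spike points toward the
negative cluster that contains autism. The two-trait signature is
approximately orthogonal to the bipolar axis, which is what makes the
third group discoverable by the same clustering the outer groups use.
With these conditions the k=2 trait cut recovers the planted clusters
with ARI 1 and the k=3 subject cut reaches ARI ≥ 0.8 in 10/10 seeds,
and the within-group composite correlations come out around −0.2 in the
outer groups.

Discretization uses equiprobable normal-quantile thresholds under each
item's theoretical marginal (group-mixture mean and variance in closed
form), which keeps marginals balanced and preserves correlation signs;
`population_correlations` / `population_trait_correlations` return the
exact continuous-score correlation matrices including the group-mixture
component, so sampled correlations converge to them.

**What this does not show.** Real questionnaire data has skewed
marginals, acquiescence and method variance, partially overlapping
subdomain content, and subject heterogeneity far richer than three
shifted Gaussians. Passing recovery tests here demonstrates that the
pipeline detects the structure it targets when that structure is
present at realistic strength and sample size — not that real cohorts
contain it.

## Clustering

Distance is `1 − r` (Pearson) between profiles; constant profiles are
errors. WPGMA agglomeration updates `d((ab),c) = (d(a,c)+d(b,c))/2`
regardless of cluster sizes; ties break on the lexicographically lowest
cluster-index pair, and leaf display order is the plain left-to-right
traversal of the merge tree (no optimal-leaf reordering, matching the
source analysis's setting). Cuts undo the k−1 highest merges. Subject
clustering applies the *same* correlation distance to subjects'
11-trait z-profiles — one distance for both axes, as in a clustergram.
The subject tree is cut at k=3 (the analysis it mirrors displays three
groups; a fixed-k cut is the reproducible reading). Composites are
unweighted means of member-trait z-scores; group comparisons use the
paired t-test (df = n−1) and Pearson correlations with exact-t p-values
(df = n−2).

## Graph learning

The conditional-independence test is Fisher's z on partial correlations
computed by inverting the `{i,j}∪S` submatrix of the sample correlation
matrix — the standard test for PC-type algorithms (the source names the
algorithm and α = 0.01 but not the statistic). PC-stable freezes the
adjacency per level, so the surviving skeleton is invariant under
variable reordering; conditioning-set size is unbounded by default
(feasible at 11 nodes) with an optional cap. Note that the *set of
tests performed* is not order-invariant (the first accepting subset
ends a pair's level), and edge presence is not globally monotone in α:
a denser high-α graph enlarges the adjacency-restricted search space,
which can remove an edge a stricter run kept. Level-0 behavior is
monotone, and that is what the suite asserts.

Edge weight is the minimum |ρ̂| among the pair's test records (the
"net" pairwise association), signed by that same record; a sign
conflict across conditioning sets triggers a warning and resolves to
the minimal record. Centrality is the sum of absolute incident weights
— absolute, because signed sums would make "importance" ill-defined on
mixed-sign graphs.

## Embedding

MDS is metric stress majorization (raw stress, Guttman transform) from
a classical-scaling start; the update never increases stress, iteration
stops on relative improvement < 1e−9 or at 300 rounds, and the result
is deterministic. t-SNE runs on the squared precomputed distances with
per-point perplexity calibration (target 10), learning rate 100,
standard momentum schedule (0.5 → 0.8 at iteration 250) with adaptive
gains, and the early-exaggeration factor 80 applied for the first 99
iterations — the exaggeration value is taken at face value and the
phase length is the conventional default of the reference
implementation family, exposed as `exaggeration_phase`. Iteration caps
at 5000 but exits early once the gradient norm falls below 1e−7 after
the exaggeration phase; with a fixed init (the MDS solution) the whole
path is deterministic, no RNG is consumed. Embeddings are meaningful
only up to similarity transforms, so all comparisons (including the
overlay of an externally supplied trait correlation matrix against a
cohort's own) go through Procrustes alignment.

## Refinement

Separability is the *training* misclassification fraction of a linear
soft-margin SVM with C = 1 on the labeled union of two point sets —
linear because the criterion is linear separability, training error
because the motivating definition is a plain misclassification fraction
on the analyzed points, C = 1 because the original regularization
constant is unstated and 1 is the conventional default. Pruning matches
each target item to its nearest trait centroid (own centroid computed
excluding the item), tests each neighbor-matched subset against that
neighbor, and removes subsets with error > θ. θ defaults to 0.05,
between the error ranges of retained (≈4%) and removed (≈8–27%) sets in
the motivating analysis; it is configurable and not optimized here.
Pruning at a fixed θ is idempotent. Subdomain reassignment moves an
item to the subdomain whose centroid (excluding the item) is nearest.

## Effects and power

The factorial stage dichotomizes scores at the median by default
(`> median` → high; a fixed-threshold rule is available) — the external
"high score" criteria the source cites are not printed, and a median
split is the neutral reproducible choice. The two-way ANOVA uses
Type-II sums of squares (each main effect after the other, interaction
against the full model), the convention family of the source tool and
the one that is order-invariant under unbalanced cells; it is
implemented via statsmodels and cross-checked against a
nested-least-squares oracle. Tukey HSD uses the studentized range with
the pooled cell residual mean square. The correlation sample-size
formula is the two-sided Fisher-z form
`n = ⌈((z_{1−α/2}+z_{pow})/atanh r)² + 3⌉`; two-sided α is required to
give n = 783 at r = 0.1, α = 0.05, power 0.80, and the formula agrees
with an exact power scan.

## Pipeline

One seed drives everything through per-stage substreams
(`numpy.random.SeedSequence.spawn`), so toggling a stage does not
perturb the others and identical configurations produce byte-identical
artifacts (fixed `%.10g` float formatting, sorted JSON keys, SHA-256
hashes in the run report). Problem sizes in the shipped scripts — 10
recovery seeds, 5 embedding/refinement seeds, 50 oracle instances at
n = 10 000 — were chosen so a full reproduction runs in about a minute
on one CPU while keeping Monte-Carlo noise well inside the margins the
checks assert.

## Known limitations

- The HSPS schema fixture beyond the documented membership constraints
  is a synthetic placeholder, not the published key (clearly marked in
  `traitspace.schema`).
- The generator's Gaussian-factor model has no item-level difficulty or
  discrimination structure (no IRT), no skew, and exchangeable items
  within a subdomain — so subdomain *reassignment* between statistically
  identical subdomains is arbitrary by construction.
- PC-stable outputs an undirected skeleton only; no orientation or
  v-structure discovery is attempted, and CI tests are unadjusted for
  multiplicity (α = 0.01 is the only control).
- The separability rule tests neighbor-matched subsets, an
  operationalization of a grouping the motivating analysis reported
  only post hoc.
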