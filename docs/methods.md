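# Methods

## Clustering model

Everything in this package operates on an agglomerative hierarchy built
with **average linkage** and the **Euclidean** metric: starting from N
singleton clusters, the two clusters with the smallest mean pairwise
distance are merged until one cluster remains, producing N − 1 merges
with heights d₁ ≤ … ≤ d_m (m = N − 1). Average linkage on a metric is
reducible, so the height sequence is non-decreasing; the
`MergeSequence` constructor clamps inversions smaller than 1e−9 (pure
floating-point noise) and raises on anything larger. Ties between
candidate merges are resolved by the underlying linkage implementation;
on continuous data exact ties have probability zero, and the test suite
cross-checks the whole merge sequence against an O(N³) re-computation of
all pairwise cluster distances for N ≤ 12. No standardisation or scaling
is applied to the input — the estimators are compared on the raw
geometry, and all of them are invariant to rigid translation.

Flat partitions are recovered two ways, and the two are consistent
because heights are sorted: `cut_to_k` undoes the last k − 1 merges;
`cut_at_height(h)` applies exactly the merges with height ≤ h, giving
k = N − #{i : dᵢ ≤ h}. `cut_at_height` is monotone: a higher threshold
can only produce fewer clusters.

## The four cutoff rules

With m merge heights, the index i of a merge corresponds to m + 2 − i
clusters present just before that merge; all argmax ties break toward
the smallest index (hence the larger k), a deterministic and, on
continuous data, measure-zero choice.

**Elbow (acceleration).** k̂_E = m + 2 − argmax_{i∈[3,m]}
(dᵢ − 2dᵢ₋₁ + dᵢ₋₂), the standard second difference of the height
sequence. Needs m ≥ 3. Range [2, m − 1]: it can never report a single
cluster or all-singletons.

**Maximum difference.** k̂_D = m + 2 − argmax_{i∈[2,m]} (dᵢ − dᵢ₋₁).
Needs m ≥ 2 and never reports 1, but handles singleton clusters (a
singleton merely joins late; it does not break the rule). Equivalent
formulation, verified by a brute-force property test: among all cuts
between consecutive merge heights, pick the cut bounded by the widest
height gap.

**Mode.** The empirical distribution of jump sizes is summarised by its
mode D̂ and standard deviation σ_D (sample sd, n − 1 denominator); the
tree is cut at the height threshold D̂ + α·σ_D. The rationale: the most
common jump size reflects within-cluster merges, so a good cutoff sits
several deviations above it. The mode of a continuous sample is not
well-defined; we use the midpoint of the fullest of ⌈√m⌉ equal-width
histogram bins over [min d, max d], ties to the lowest bin, and D̂ = the
common value when all heights are equal. α defaults to 3; tuning it
would require labelled data, which defeats the purpose of an automatic
rule. The threshold interpretation (a height, then a cut) is our design
choice for making the rule return a count while staying on the
dendrogram's distance scale. The mode rule can return 1.

**Gap statistic.** For k = 1..k_max the data are clustered (average
linkage, cut to k) and the size-normalised within-cluster dispersion

  W_k = Σ_r (1 / 2n_r) Σ_{i,i′ ∈ C_r} d_{ii′}

is computed with plain Euclidean distances, the inner sum over ordered
pairs. B reference datasets — independent uniforms over the observed
range of each feature, the simple uniform construction — are clustered
identically, giving E*[log W_k] as the reference mean,
Gap(k) = E*[log W_k] − log W_k, and s_k = sd·√(1 + 1/B) (sample sd;
with B = 50 the ddof choice is immaterial). The estimate is the
smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}; if the rule never fires
below k_max the function returns k_max with an explicit `no_elbow`
diagnostic rather than failing. Defaults: k_max = 10, B = 50, both
configurable; B is a bias/variance-free Monte-Carlo size, so it only
needs to be large enough that reference noise (∝ 1/√B) is small against
the gap curvature.

## Resampling consensus

**Mixing**: L subsamples of M rows drawn without replacement (defaults
M = ⌊N/2⌋, L = 100), the base estimator applied to each, and the mode of
the L counts reported, ties toward the smaller count (conservative and
deterministic). With L = 1, M = N the wrapper reproduces the base
estimator exactly — a degenerate case kept as a regression test.
**Leave-one-out**: the same aggregation over the N subsets that each
omit one observation. A replicate on which the estimator fails (e.g.
fewer merges than the rule needs) is skipped and counted; more than 50%
failures aborts with an error. The full pairwise distance matrix is
computed once per dataset and sliced per replicate, so each replicate
costs one linkage, not one distance computation. Per-replicate estimator
parameters are inherited unchanged from the base call. Mixing the gap
statistic is supported but costly (B + 1 hierarchies per replicate);
the jump rules are the intended consensus targets.

## Synthetic generator and evaluation

The generator draws k ∈ [1,4] clusters of `points_per_cluster` (default
100) bivariate normal points at the corners (±m/2, ±m/2) of a square of
side m (default separation 6 → centers (±3, ±3)), covariance
scale_r·I₂ per cluster (default all 1; the heterogeneous preset uses
1, 1, 2, 0.5 — scales on the covariance matrix, not the standard
deviation). When k < 4 the centers are taken in the fixed order
(−3,−3), (3,3), (−3,3), (3,−3). Custom centers lift the k ≤ 4 and 2-D
restrictions.

The harness reports, per method, the mean estimate, the **success rate**
S (fraction of runs with k̂ = k) and the **error size** E (mean |k − k̂|
over the wrong runs only, defined as 0 when no run is wrong, so S = 1 ⇔
E = 0). One master seed spawns an independent substream per run and
every method sees the same data within a run, making the comparison
paired; identical seeds give bit-identical tables. The separation sweep
reruns the experiment over a grid of m values and emits a tidy
long-format table.

What the generator does *not* emulate: correlated features,
heavy-tailed or skewed noise, unequal cluster sizes, high-dimensional
data (p ≫ 2) and chaining structures. Benchmarks passing on these
Gaussian squares show the rules behave as designed in a well-separated
low-dimensional regime; they do not certify performance on real
expression matrices, which is why the 26-sample Biobase case study is
exercised separately.

## Problem sizes and numerical choices

The acceptance benchmarks use 200 simulation runs per scenario — enough
that the binomial standard error of a success rate near 0.95 is below
0.02 — except the leave-one-out benchmark, which runs 50 replications
of its N-linkage inner loop (SE ≲ 0.03). Degenerate inputs are handled
explicitly: identical points merge at height 0; all-equal heights give
σ_D = 0 and a mode threshold at that height (one cluster); a zero
dispersion falls back to log W = −∞ rather than raising inside the gap
profile. Matrix input is validated cell-by-cell and parse errors name
the offending row and column.

## Known limitations

* The jump rules cannot detect the single-cluster case (their argmax
  ranges exclude it); use the gap statistic when k = 1 is plausible.
* The mode rule without consensus resampling is unreliable on touching
  clusters; it is included for study and for its strong behaviour under
  mixing, not as a default recommendation.
* The gap statistic's uniform reference is a poor null for elongated or
  correlated data; a principal-component-aligned reference is not
  implemented.
* On clusters with strongly unequal spreads, an outlying point of a wide
  cluster can survive as a singleton high into the tree and draw the
  maximum-difference rule (and the elbow) one cluster too high; the
  consensus wrappers largely remove this failure mode.
* Optimal mixing parameters M and L are an open question; the defaults
  follow the half-sample convention.
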