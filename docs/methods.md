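# Methods

This note documents the models and procedures implemented in
`lifespan_topology`, the parameters that matter, the design choices
made where several conventions exist, and what the synthetic-data tests
do and do not establish about real imaging cohorts.

## Networks and preprocessing

The unit of analysis is a symmetric, nonnegative, zero-diagonal
connectivity matrix (90×90 in the study-shaped configuration) whose
entries are streamline counts before normalization and lie in [0, 1]
after. All entry points validate these invariants and reject violations
rather than repairing them.

**Outlier removal.** Subjects are binned by nearest-integer age
(half-up rounding) and removed when their network density is more than
3 SD (population SD) from the bin mean. Bins with fewer than two
subjects, or with zero SD, are passed through and logged: an SD-based
rule is undefined there.

**Harmonization mask.** Batch harmonization (e.g. ComBat) is treated
as an external step; the package implements only its post-processing:
entries are zeroed wherever the pre-harmonization matrix was zero, and
negative harmonized entries are clipped to zero. The mask can only
remove or shrink, never create.

**Age smoother.** Trend estimation over age uses a cubic smoothing
spline (`scipy.interpolate.make_smoothing_spline`) with the penalty
chosen by generalized cross-validation. The same smoother reports
peak/valley ages: sign changes of the fitted derivative between
consecutive integer ages, refined by root finding and rounded to
integer years. Tied ages are averaged before fitting; at least 10
distinct ages are required.

**Thresholding.** Two modes.

* *Variable density*: the per-age target is 70% of the smoothed raw
  density trend. One absolute streamline-count cutoff is chosen per
  (age bin × dataset) group by brute force over the sorted union of
  the group's weights, minimizing |mean post-threshold density −
  target| (ties resolved toward the smaller cutoff, i.e. the denser
  result). A target above the achievable density leaves the group
  unthresholded with a warning.
* *Fixed density* (default 0.10): each network keeps its own
  k = round(target × n_pairs) heaviest edges. Tie handling is
  deterministic: all edges strictly above the cutoff weight survive,
  then tied edges are admitted in descending weight order, stable by
  node-pair index, until k is reached. This makes thresholding
  monotone in the target (a higher target keeps a superset of edges)
  and density-exact whenever weights are distinct.

Weights are then rescaled to [0, 1] by dividing by the matrix maximum
(idempotent; undefined and rejected for an all-zero matrix).

## Graph metrics

Twelve organizational measures per network, computed on the normalized
weighted matrix. Conventions that the literature leaves open are fixed
as follows:

* **Path lengths** use the inverse-weight transform, length = 1/w, the
  standard distance convention for weighted connectivity data. The
  characteristic path length averages finite pairwise distances only
  and sets a `disconnected` flag when unreachable pairs exist; global
  efficiency counts unreachable pairs as zero.
* **Clustering** is the geometric-mean (Onnela) triangle intensity on
  max-normalized weights; nodes with degree < 2 score 0. **Local
  efficiency** of a node is the global efficiency of its neighborhood
  subgraph.
* **Small-worldness** is σ = (C/⟨C_null⟩)/(L/⟨L_null⟩) over
  Maslov–Sneppen rewired nulls (10 per network by default, 10 swap
  attempts per edge) that preserve the degree sequence, edge count and
  weight multiset. The literal C/L ratio has units and cannot support
  a ">1 means small-world" reading, so the null-normalized form is the
  default. A null ensemble with zero clustering or disconnected nulls
  is rejected.
* **Modularity** is the best Louvain Q over 10 seeded restarts at
  resolution γ (default 0.6). The resolution sweep compares observed Q
  across a cohort sample with Q of rewired nulls by a two-sample
  Kolmogorov–Smirnov statistic at each γ in 0.2…2 (step 0.2) and picks
  the largest statistic, breaking ties toward the smaller γ — the
  resolution at which modular structure is most non-random.
* **Core/periphery** fit maximizes the cosine-form correlation between
  the weight matrix and an ideal pattern (1 on pairs touching the
  core, 0 on periphery–periphery pairs) by greedy single-node flips
  from seeded starts, including strength-based and all-core starts;
  q ∈ [0, 1]. Exhaustive search on small graphs confirms the greedy
  optimum in tests.
* **k-core / s-core** sizes use generalized degeneracy peeling
  (repeatedly remove the minimum-degree or minimum-strength node; a
  node's core number is the running maximum of removal values), which
  is independent of tie-break order. The reported size is the node
  count at the highest nonempty level; an explicit level can be
  requested instead, since conventions differ on which level to report.
* **Betweenness** uses 1/w lengths, unnormalized counts over unordered
  pairs with endpoints excluded and equal-length multiplicities split
  fractionally. **Subgraph centrality** is Σⱼ vᵢⱼ² e^{λⱼ} over the
  eigendecomposition, computed on the binarized thresholded network by
  default (weighted available via a flag) — whether weighted or binary
  is another open convention.

## Turning points

The 11 retained metrics (the k-core is excluded: it is the one measure
without a reliable age trend) are averaged per integer age — every age
0…90 must be represented; missing years are an error rather than being
silently interpolated — and z-scored per column. Columns constant
after averaging are dropped with a warning.

The standardized 91×11 matrix is embedded in 3-D by a UMAP ensemble:
nearest neighbors 2…89 × minimum distances 0.1…1.0 in 11 even steps
(968 members), Euclidean metric. Each member's seed is a stable hash of
(nn, min_dist, global seed), so the full ensemble is reproducible and
members are independent. A reduced 2×3 grid (nn ∈ {5, 15}, min_dist ∈
{0.1, 0.5, 1.0}) is provided for fast runs.

Per member and dimension, a degree-5 polynomial is fit by least squares
over age. Gradients are the *analytic* derivative of the fitted
polynomial evaluated at integer ages (finite differences would add a
step-size choice with no benefit). Candidate turning points are
consecutive-integer sign flips of the gradient, refined to the real
root of the derivative in that interval and rounded half-up. A
candidate at age i survives the fluctuation filter iff
T < Σ_{j=i−W}^{i+W} |G_j| with the window truncated at the 0/90
boundaries (defaults W = 5 years, T = 0.8; the comparison is strict).
Raising T can only remove survivors — a property the tests sweep.

Candidates within and across dimensions are merged by single-linkage
chaining with linking distance A (default 5 years): sorted candidates
whose consecutive gaps are ≤ A form one cluster, replaced by its mean,
rounded half-up. Single linkage reproduces the canonical two-point
example (31 and 33 merge to 32) and handles chains deterministically.

Major turning points are the peaks of a Gaussian KDE over the pooled
per-member turning ages, evaluated on a 0.1-year grid padded 5 years
beyond each boundary so edge peaks register. The kernel bandwidth is a
fixed 3 years by default. Silverman's rule (available via
`bandwidth_years=None`) assumes near-unimodality and, on pooled
turning ages that form tight clusters 17–35 years apart, yields 14–20
year bandwidths that merge every cluster into one or two broad bumps
even when all members agree perfectly; 3 years absorbs the observed
±2-year member scatter while resolving clusters at least ~8 years
apart. Peaks must rise above the deeper of their two adjacent valleys
by at least 5% of the global density maximum — measuring prominence
against adjacent valleys avoids a pathology of contour-based
prominence on near-flat densities, where equal-height numerical
ripples each inherit full-height prominence. A pool concentrated on a
single age short-circuits to that age (a KDE over zero-variance data
is undefined).

Exactness and bias: applied directly to noiseless planted trajectories
(each metric treated as a dimension), fit → detect → filter → merge
recovers the planted ages exactly after rounding, provided T is below
the planted gradient mass (unit-variance curves carry windowed sums of
roughly 0.3–0.8). Through the UMAP ensemble, the embedding's nonlinear
warp introduces a systematic bias of about ±1 year near the ends of
the age range, so pipeline-level recovery is accurate to ±1–2 years,
not exact.

## Epochs

Boundary membership: epoch k covers rounded ages [b_{k−1}, b_k), with
the first epoch starting at 0 and the last closed at 90, so a subject
exactly at a boundary belongs to the later epoch. The rule is a
convention (sample sizes imply boundary ages belong to a single epoch,
but not which); it is centralized in `assign_epochs`.

* **Correlations**: Pearson r of each metric with age per epoch,
  two-sided α = 0.05. A direction change is flagged only when two
  consecutive epochs are both significant with opposite signs.
  Zero-variance metrics yield NaN r with a `degenerate` flag rather
  than being dropped. Regional correlations apply Benjamini–Hochberg
  across the 90 regions within each (metric, epoch) family.
* **LASSO**: age regressed on the 11 metrics, standardized within
  epoch (the within-epoch age-metric relationship is the estimand),
  10-fold CV with shuffled, seeded folds. The selected λ is the
  largest whose mean CV MSE is within one standard error of the
  minimum; if that model is empty, the min-MSE λ is used and the
  result flagged (`min_mse_fallback`) — regularization weakened rather
  than reporting an uninformative empty model.
* **PCA**: eigenvalues of the metric correlation matrix; retention by
  parallel analysis (default 1000 standardized random datasets of the
  same shape, 95th percentile per rank, leading run of exceedances).
  Retained loadings are varimax-rotated with Kaiser normalization;
  scores are unit-variance principal component scores carried through
  the same rotation. PCA is fit on subject-level metrics across the
  whole lifespan, not on age-averages, so epoch comparisons have
  subject-level degrees of freedom.
* **Epoch comparisons**: Levene (median-centered) per component, Welch
  one-way ANOVA, and Games–Howell post hoc tests restricted to
  consecutive epoch pairs (studentized-range reference with
  Welch–Satterthwaite df, via pingouin). Components with zero
  within-group variance are skipped with a warning.
* **DTW**: each epoch's series per component is the mean score per
  integer age (at least 3 ages required). Classic full-window dynamic
  programming with absolute-difference local cost; distances are
  z-scored within each component across the consecutive-pair set and
  summed per pair. Self-distance is exactly 0 and the recursion is
  symmetric.

## Synthetic data

`generate_metric_trajectories` plants known turning ages. The default
`smooth` shape gives each metric a polynomial mean curve whose
derivative is proportional to ∏(age − aₖ): the slope changes sign
exactly at every planted age, which is the differentiable structure the
degree-5 trajectory fit assumes. Per-metric amplitudes alternate in
sign and vary in magnitude (1.0–1.3) so the metrics are not identical;
the base curve is standardized to unit variance over the age grid so
`noise_sd` is expressed relative to the curve scale. The
`piecewise_linear` shape provides tent-like curves with explicit
per-segment slopes for degenerate-case tests. Reference conditions for
recovery experiments: turning ages {10, 30, 65, 82}, noise SD 0.3, 20
subjects per integer age.

`generate_cohort` draws stochastic-block-model count matrices: edges
Bernoulli with within/between-block probabilities solved to hit an
age-dependent target density (default declining 0.30 → 0.12 over
0–90), counts Poisson around an age-increasing mean shifted by one so
present edges are never zero — mimicking the integer, right-skewed
nature of streamline counts and the drift from dense, weak networks in
early life toward sparse, strong networks later. Ages are uniform over
integers 0–90 unless supplied, guaranteeing coverage of every age bin.

What the generator does *not* emulate: scanner/site batch effects,
spatial embedding and distance-dependent connectivity, hub topography,
head-motion artifacts, or non-Gaussian metric noise. Passing recovery
tests therefore establish the correctness and calibration of the
algorithms under the stated statistical structure, not the
reproducibility of any particular empirical finding on real cohorts.

## Problem sizes and runtime

The test suite and the acceptance script run the recovery experiment
on the reduced 2×3 ensemble (the full 968-member grid is exercised for
cardinality and is available for production runs), oracle comparisons
on graphs of up to 12 nodes (where exhaustive search is feasible),
thresholding on 200 90-node matrices, and statistical calibration with
50 parallel-analysis repeats (200 random datasets each) and 200 Welch
null repeats — sizes chosen so the whole suite completes in a few
minutes while keeping every estimate's Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

* UMAP member embeddings are only reproducible with a pinned
  `random_state`; the package always pins per-member seeds.
* The KDE peak set depends on bandwidth and prominence; both are
  exposed (`bandwidth_years`, `prominence_frac`) because no principled
  universal choice exists.
* Variable-density cutoffs are integer streamline counts chosen by
  brute force over observed weights; for continuous-weight matrices
  the "count" cutoff is simply a weight threshold.
* Games–Howell p-values are reported at numeric precision; extremely
  small values underflow to 0 and should be read as below the smallest
  printable double.
* ComBat harmonization itself, smoother-specific inference, sex-stratified
  projections and per-epoch power calculations are out of scope.
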