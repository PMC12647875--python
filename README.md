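# lifespan-topology

Tools for charting how the topology of the human structural connectome
changes across the lifespan (ages 0–90), and for locating the ages at
which that change switches direction.

The package is written for network-neuroscience researchers who have
subject-level structural connectivity matrices (90×90 symmetric
streamline counts) with age metadata, and for methodologists who want a
tested, reproducible implementation of the turning-point methodology on
synthetic data with known ground truth.

## What it does

1. **Preprocessing** — per-age-bin density outlier removal (±3 SD),
   harmonization mask post-processing (only connections present before
   harmonization are retained; negatives clipped), density-targeted
   thresholding (*variable* mode: one streamline-count cutoff per
   age × dataset group aimed at 70% of the smoothed density trend;
   *fixed* mode: every network thresholded to the same density, 10% by
   default) and max-normalization of weights to [0, 1].
2. **Graph metrics** — the 12 organizational measures on weighted
   networks: global efficiency, characteristic path length,
   small-worldness (null-normalized σ over degree- and
   weight-preserving rewired networks), average strength, modularity
   (Louvain, resolution γ selected by the largest Kolmogorov–Smirnov
   statistic against rewired nulls over γ ∈ [0.2, 2]), core/periphery
   fit, s-core and k-core sizes, local efficiency, clustering,
   betweenness and subgraph centrality.
3. **Manifold turning points** — the 11 age-predicted metrics are
   averaged per integer age, z-scored, and embedded in 3-D by an
   ensemble of UMAP parameterizations (default 88 nearest-neighbor
   values × 11 minimum distances = 968 members). Per member, each
   embedding dimension is fit with a degree-5 polynomial

   Dimension(age) = β₀ + β₁·age + … + β₅·age⁵ + ε,

   gradient sign changes are candidate turning points, small
   fluctuations are removed by requiring T < Σᵢ₋W..ᵢ₊W |Gᵢ| (defaults
   W = 5 years, T = 0.8), and candidates within A = 5 years are merged
   by averaging. **Major** turning points are the peaks of a Gaussian
   kernel density over the pooled turning points of all members.
4. **Epoch characterization** — the intervals between major turning
   points define epochs. Within/between epochs: Pearson correlations
   with direction-change detection, FDR-corrected regional
   correlations, 10-fold cross-validated LASSO age prediction with the
   one-standard-error λ rule (min-MSE fallback when the sparse model is
   empty), PCA with parallel-analysis retention (95th percentile of
   eigenvalues from 1000 random datasets) and varimax rotation, Levene
   / Welch ANOVA / Games–Howell comparisons of component scores, and
   dynamic-time-warping distances between per-age mean score
   trajectories.
5. **Synthetic cohorts** — stochastic-block-model count matrices with
   age-varying density and planted smooth metric trajectories with
   known turning ages, so every stage is testable without restricted
   imaging data.

## Worked example

```python
import numpy as np
from lifespan_topology import (
    PlantedTrajectorySpec, generate_metric_trajectories,
    EnsembleGrid, TurningPointConfig, run_turning_point_pipeline,
    assign_epochs, epoch_correlations, pca_parallel_varimax,
)

# A synthetic cohort: 11 metrics, 20 subjects per integer age 0-90,
# trajectories that change direction at ages 10, 30, 65 and 82.
spec = PlantedTrajectorySpec(turning_ages=[10, 30, 65, 82],
                             noise_sd=0.3, n_per_age=20, seed=1)
table, truth = generate_metric_trajectories(spec)

# Reduced 2x3 UMAP ensemble for speed (the full default grid has 968).
config = TurningPointConfig(grid=EnsembleGrid.small(seed=1))
tps, _ = run_turning_point_pipeline(table, config,
                                    metrics=truth["metric_names"])
print("major turning points:", tps.major)

epochs = assign_epochs(table["age"], tps.major)
corr = epoch_correlations(table, epochs, truth["metric_names"][:1])
print(corr[["epoch", "r", "significant", "direction_change"]].round(3))

pca = pca_parallel_varimax(table, truth["metric_names"], seed=1)
print("components retained:", pca.n_retained,
      "| variance explained (%):", np.round(pca.variance_explained, 2))
```

Output:

```
major turning points: [10, 31, 64, 82]
 epoch      r  significant  direction_change
     1  0.885         True             False
     2 -0.804         True              True
     3  0.948         True              True
     4 -0.611         True              True
     5  0.725         True              True
components retained: 1 | variance explained (%): [94.01]
```

Every planted turning age is recovered within one year; the epoch
correlations alternate sign across consecutive epochs exactly as the
planted direction changes dictate, and parallel analysis retains the
single real component of the rank-one planted signal.

## Command line

```bash
lifespan-topology simulate --out-dir results/synthetic --seed 1
lifespan-topology preprocess results/synthetic/cohort --mode fixed --target-density 0.10
lifespan-topology metrics results/preprocessed --out results/metrics.csv
lifespan-topology turning-points results/metrics.csv --grid small --seed 1
lifespan-topology epochs results/metrics.csv results/turning_points/major_turning_points.json
lifespan-topology run-all --seed 1 --out-dir results
```

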