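"""UMAP-ensemble manifolds and lifespan turning points.

The 11 retained metrics are averaged per integer age and standardized,
embedded into 3-D by an ensemble of UMAP parameterizations (default:
nearest neighbors 2..89 x 11 minimum distances in [0.1, 1], Euclidean
metric — 968 members), and each embedding's trajectory over age is
summarized by a degree-5 polynomial per dimension:

    Dimension(age) = b0 + b1*age + ... + b5*age^5 + eps

Turning-point candidates are the ages where the fitted gradient changes
sign; small fluctuations are removed by requiring the windowed sum of
absolute gradients to exceed a threshold T; candidates within an age
window A (within and across dimensions) are averaged into a single
turning point.  Major turning points are the peaks of a Gaussian kernel
density over the pooled turning points of all ensemble members.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleGrid",
    "InflectionFilterConfig",
    "TurningPointConfig",
    "TurningPointSet",
    "build_age_feature_matrix",
    "embed_ensemble",
    "fit_trajectory",
    "detect_candidates",
    "filter_candidates",
    "merge_candidates",
    "aggregate_major_turning_points",
    "run_turning_point_pipeline",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def build_age_feature_matrix(
    metric_table: pd.DataFrame,
    metrics: list[str] | None = None,
    age_col: str = "age_bin",
    age_range: tuple[int, int] = (0, 90),
) -> pd.DataFrame:
    """Per-integer-age means of the retained metrics, z-scored per column.

    Every integer age in ``age_range`` must be represented; missing years
    are an error (no silent interpolation).  Columns that are constant
    after age-averaging carry no information for the embedding and are
    dropped with a warning.
    """
    if metrics is None:
        from lifespan_topology.metrics import RETAINED_METRICS

        metrics = [m for m in RETAINED_METRICS if m in metric_table.columns]
    lo, hi = age_range
    present = set(int(a) for a in metric_table[age_col].unique())
    missing = [a for a in range(lo, hi + 1) if a not in present]
    if missing:
        raise ValueError(f"no subjects at integer ages: {missing}")
    means = (
        metric_table.loc[metric_table[age_col].between(lo, hi)]
        .groupby(age_col)[metrics]
        .mean()
        .sort_index()
    )
    sd = means.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(
            f"dropping zero-variance columns after age-averaging: {constant}",
            stacklevel=2,
        )
        means = means.drop(columns=constant)
        sd = sd.drop(index=constant)
    z = (means - means.mean()) / sd
    z.index.name = "age"
    return z


def _member_seed(nn: int, min_dist: float, seed: int) -> int:
    """Stable per-member seed derived from (nn, min_dist, global seed)."""
    key = f"{nn}|{min_dist:.6f}|{seed}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class EnsembleGrid:
    """The UMAP parameter ensemble.

    Defaults give 88 nearest-neighbor values (2..89) x 11 minimum
    distances evenly spaced over [0.1, 1.0] = 968 members, each embedded
    in 3 dimensions under the Euclidean metric with its own pinned seed.
    """

    nn_values: tuple[int, ...] = tuple(range(2, 90))
    min_dist_values: tuple[float, ...] = tuple(np.linspace(0.1, 1.0, 11))
    n_components: int = 3
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nn_values or not self.min_dist_values:
            raise ValueError("grid must be nonempty")
        if any(nn < 2 for nn in self.nn_values):
            raise ValueError("nearest neighbors must be >= 2")

    @property
    def size(self) -> int:
        return len(self.nn_values) * len(self.min_dist_values)

    def members(self) -> list[tuple[int, float, int]]:
        """(nearest_neighbors, min_dist, member_seed) triples."""
        return [
            (nn, float(md), _member_seed(nn, float(md), self.seed))
            for nn in self.nn_values
            for md in self.min_dist_values
        ]

    def validate_for(self, n_rows: int) -> None:
        bad = [nn for nn in self.nn_values if nn >= n_rows]
        if bad:
            raise ValueError(
                f"nearest-neighbor values {bad} are >= the number of "
                f"age rows ({n_rows})"
            )

    @classmethod
    def default(cls, seed: int = 0) -> "EnsembleGrid":
        return cls(seed=seed)

    @classmethod
    def small(cls, seed: int = 0) -> "EnsembleGrid":
        """Reduced 2x3 grid for fast runs: nn {5, 15}, min_dist {0.1, 0.5, 1.0}."""
        return cls(
            nn_values=(5, 15), min_dist_values=(0.1, 0.5, 1.0), seed=seed
        )


def embed_ensemble(
    features: pd.DataFrame, grid: EnsembleGrid
) -> list[dict]:
    """One 3-D embedding per grid member, each with a pinned seed."""
    import umap  # deferred: numba compilation is slow at import time

    x = np.asarray(features, dtype=float)
    grid.validate_for(x.shape[0])
    out = []
    for nn, md, mseed in grid.members():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = umap.UMAP(
                n_neighbors=nn,
                min_dist=md,
                n_components=grid.n_components,
                metric=grid.metric,
                random_state=mseed,
            ).fit_transform(x)
        out.append(
            {
                "n_neighbors": nn,
                "min_dist": md,
                "seed": mseed,
                "embedding": np.asarray(emb, dtype=float),
            }
        )
    return out


def fit_trajectory(
    embedding: np.ndarray, ages: np.ndarray, degree: int = 5
) -> np.ndarray:
    """Independent least-squares polynomial per embedding dimension.

    Returns an array of shape (n_dims, degree + 1) of coefficients in
    descending power order (numpy polyval convention).
    """
    embedding = np.asarray(embedding, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if degree < 2:
        raise ValueError("polynomial degree must be >= 2")
    if np.unique(ages).size < degree + 1:
        raise ValueError("need more distinct ages than the polynomial degree")
    coeffs = []
    for dim in range(embedding.shape[1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            c = np.polyfit(ages, embedding[:, dim], degree)
        coeffs.append(c)
    return np.vstack(coeffs)


def gradient_at_ages(coeffs_1d: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Analytic derivative of one fitted dimension at the given ages."""
    return np.polyval(np.polyder(coeffs_1d), np.asarray(ages, dtype=float))


def detect_candidates(
    traj: np.ndarray, ages: np.ndarray
) -> list[list[int]]:
    """Per-dimension integer ages where the fitted gradient changes sign.

    The derivative is evaluated at integer ages; each consecutive sign
    flip is refined to the derivative's real root in that interval and
    rounded to the nearest integer year.
    """
    ages = np.asarray(ages, dtype=float)
    grid = np.arange(int(ages.min()), int(ages.max()) + 1, dtype=float)
    out: list[list[int]] = []
    for coeffs in np.atleast_2d(traj):
        deriv = np.polyder(coeffs)
        if np.allclose(deriv, 0):
            logger.warning("derivative identically zero; no candidates")
            out.append([])
            continue
        g = np.polyval(deriv, grid)
        cands: list[int] = []
        roots = np.roots(deriv)
        real_roots = np.real(roots[np.abs(np.imag(roots)) < 1e-9])
        for i in range(len(grid) - 1):
            if g[i] == 0.0:
                if 0 < i and np.sign(g[i - 1]) * np.sign(g[i + 1]) < 0:
                    cands.append(int(grid[i]))
            elif g[i] * g[i + 1] < 0:
                in_iv = real_roots[
                    (real_roots >= grid[i]) & (real_roots <= grid[i + 1])
                ]
                loc = float(in_iv[0]) if in_iv.size else (grid[i] + grid[i + 1]) / 2
                cands.append(_round_half_up(loc))
        out.append(sorted(set(cands)))
    return out


@dataclass
class InflectionFilterConfig:
    """Gradient-magnitude filter for turning-point candidates.

    A candidate at age i survives iff T < sum_{j=i-W}^{i+W} |G_j|, where
    G_j is the fitted gradient at integer age j and the window is
    truncated at the age-range boundaries.
    """

    gradient_window: int = 5
    gradient_threshold: float = 0.8
    age_window: int = 5

    def __post_init__(self) -> None:
        if self.gradient_window < 1:
            raise ValueError("gradient window must be >= 1 year")
        if self.gradient_threshold < 0:
            raise ValueError("gradient threshold must be >= 0")
        if self.age_window < 1:
            raise ValueError("age window must be >= 1 year")


def filter_candidates(
    candidates: list[int],
    gradients: np.ndarray,
    cfg: InflectionFilterConfig,
    age_range: tuple[int, int] = (0, 90),
) -> list[int]:
    """Keep candidates whose windowed absolute-gradient sum exceeds T.

    ``gradients`` holds G_j at every integer age of ``age_range``.
    """
    lo, hi = age_range
    gradients = np.asarray(gradients, dtype=float)
    if gradients.size != hi - lo + 1:
        raise ValueError("gradients must cover every integer age in range")
    survivors = []
    w, t = cfg.gradient_window, cfg.gradient_threshold
    for c in candidates:
        a = max(lo, c - w) - lo
        b = min(hi, c + w) - lo
        if np.sum(np.abs(gradients[a : b + 1])) > t:
            survivors.append(c)
    return survivors


def merge_candidates(candidates, age_window: int = 5) -> list[int]:
    """Average candidates in close proximity into single turning points.

    Single-linkage chaining: sorted candidates whose consecutive gaps are
    <= the age window form one cluster (within and across dimensions);
    each cluster is replaced by its mean, rounded half-up.
    """
    if age_window < 1:
        raise ValueError("age window must be >= 1 year")
    flat = sorted(float(c) for c in candidates)
    if not flat:
        return []
    clusters: list[list[float]] = [[flat[0]]]
    for c in flat[1:]:
        if c - clusters[-1][-1] <= age_window:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    return [_round_half_up(float(np.mean(cl))) for cl in clusters]


@dataclass
class TurningPointSet:
    """Per-member turning ages, the pooled list, and the major points."""

    per_member: list[list[int]]
    pooled: list[int]
    major: list[int]
    kde_grid: np.ndarray | None = None
    kde_density: np.ndarray | None = None
    counts: dict[int, int] = field(default_factory=dict)


def aggregate_major_turning_points(
    pooled: list[int],
    prominence_frac: float = 0.05,
    bandwidth_years: float | None = 3.0,
    bw_method: str | float = "silverman",
    grid_step: float = 0.1,
    age_range: tuple[int, int] = (0, 90),
) -> TurningPointSet:
    """Major turning points = peaks of the Gaussian KDE of pooled ages.

    Local maxima on a fine age grid with prominence at least
    ``prominence_frac`` of the global maximum, rounded to integer years.
    The kernel bandwidth defaults to a fixed 3 years — wide enough to
    absorb member-to-member scatter, narrow enough to resolve distinct
    turning points; pass ``bandwidth_years=None`` to fall back to
    ``bw_method`` (e.g. Silverman's rule).  Per-age identification
    counts are reported alongside.
    """
    if not pooled:
        raise ValueError("empty pool of turning points")
    lo, hi = age_range
    pooled = [int(p) for p in pooled]
    counts: dict[int, int] = {}
    for p in pooled:
        counts[p] = counts.get(p, 0) + 1
    arr = np.asarray(pooled, dtype=float)
    if np.unique(arr).size == 1:
        age = int(arr[0])
        return TurningPointSet(
            per_member=[], pooled=pooled, major=[age], counts=counts
        )
    # Pad the grid so boundary peaks register as local maxima.
    grid = np.arange(lo - 5.0, hi + 5.0 + grid_step, grid_step)
    if bandwidth_years is not None:
        bw_method = float(bandwidth_years) / arr.std(ddof=1)
    kde = gaussian_kde(arr, bw_method=bw_method)
    dens = kde(grid)
    raw_peaks, _ = find_peaks(dens)
    # Prominence against the adjacent valleys: a peak must rise above
    # the deeper of its two neighboring minima by prominence_frac of the
    # global maximum.  (Plateau ties on a near-flat density would each
    # inherit full-height prominence under the contour definition.)
    peaks = []
    bounds = [0, *raw_peaks.tolist(), dens.size - 1]
    for k, p in enumerate(raw_peaks):
        left = dens[bounds[k] : p + 1].min()
        right = dens[p : bounds[k + 2] + 1].min()
        if dens[p] - max(left, right) >= prominence_frac * dens.max():
            peaks.append(p)
    major = sorted(
        {
            _round_half_up(float(np.clip(grid[p], lo, hi)))
            for p in peaks
        }
    )
    if not major:
        logger.warning("no KDE peak exceeds the prominence threshold")
    return TurningPointSet(
        per_member=[],
        pooled=pooled,
        major=major,
        kde_grid=grid,
        kde_density=dens,
        counts=counts,
    )


@dataclass
class TurningPointConfig:
    """End-to-end settings for the turning-point pipeline."""

    degree: int = 5
    filter: InflectionFilterConfig = field(default_factory=InflectionFilterConfig)
    grid: EnsembleGrid = field(default_factory=EnsembleGrid)
    prominence_frac: float = 0.05
    bandwidth_years: float | None = 3.0
    bw_method: str | float = "silverman"
    age_range: tuple[int, int] = (0, 90)


def turning_points_for_embedding(
    embedding: np.ndarray,
    ages: np.ndarray,
    config: TurningPointConfig,
) -> tuple[list[int], dict]:
    """detect -> filter -> merge for a single ensemble member."""
    traj = fit_trajectory(embedding, ages, degree=config.degree)
    grid_ages = np.arange(config.age_range[0], config.age_range[1] + 1, dtype=float)
    per_dim = detect_candidates(traj, ages)
    surviving: list[int] = []
    for coeffs, cands in zip(traj, per_dim):
        g = gradient_at_ages(coeffs, grid_ages)
        surviving.extend(
            filter_candidates(cands, g, config.filter, config.age_range)
        )
    merged = merge_candidates(surviving, config.filter.age_window)
    provenance = {
        "candidates_per_dim": per_dim,
        "survivors": sorted(surviving),
        "merged": merged,
    }
    return merged, provenance


def turning_points_from_trajectories(
    metric_table: pd.DataFrame,
    config: TurningPointConfig | None = None,
    metrics: list[str] | None = None,
) -> tuple[list[int], dict]:
    """detect -> filter -> merge on the metric trajectories themselves.

    Fits the per-dimension polynomials directly to the age-averaged,
    standardized metric curves (no embedding), treating each metric as
    one trajectory dimension.  On noiseless planted trajectories this
    recovers the planted turning ages exactly after rounding.
    """
    config = config or TurningPointConfig()
    features = build_age_feature_matrix(
        metric_table, metrics=metrics, age_range=config.age_range
    )
    ages = features.index.to_numpy(dtype=float)
    return turning_points_for_embedding(
        features.to_numpy(dtype=float), ages, config
    )


def run_turning_point_pipeline(
    metric_table: pd.DataFrame,
    config: TurningPointConfig | None = None,
    metrics: list[str] | None = None,
) -> tuple[TurningPointSet, dict]:
    """Feature matrix -> UMAP ensemble -> turning points -> KDE peaks.

    Returns the TurningPointSet (whose ``major`` list is the epoch
    boundary set) and a provenance dict with per-member parameters,
    seeds and candidate ages.
    """
    config = config or TurningPointConfig()
    features = build_age_feature_matrix(
        metric_table, metrics=metrics, age_range=config.age_range
    )
    ages = features.index.to_numpy(dtype=float)
    members = embed_ensemble(features, config.grid)
    per_member: list[list[int]] = []
    provenance: dict = {"members": [], "feature_columns": list(features.columns)}
    pooled: list[int] = []
    for member in members:
        merged, prov = turning_points_for_embedding(
            member["embedding"], ages, config
        )
        per_member.append(merged)
        pooled.extend(merged)
        provenance["members"].append(
            {
                "n_neighbors": member["n_neighbors"],
                "min_dist": member["min_dist"],
                "seed": member["seed"],
                **prov,
            }
        )
    tps = aggregate_major_turning_points(
        pooled,
        prominence_frac=config.prominence_frac,
        bandwidth_years=config.bandwidth_years,
        bw_method=config.bw_method,
        age_range=config.age_range,
    )
    tps.per_member = per_member
    return tps, provenance
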