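"""Synthetic cohorts with known ground truth.

Two generators stand in for restricted imaging data: piecewise-linear
metric trajectories with planted turning ages (the statistical structure
the manifold stage assumes), and stochastic-block-model streamline-count
matrices whose density and within-block intensity drift with age (dense,
weak networks in early life toward sparse, strong networks in later life).
Ground truth is always returned next to the data, never embedded in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedTrajectorySpec",
    "SyntheticCohortConfig",
    "SubjectRecord",
    "generate_metric_trajectories",
    "generate_cohort",
    "generate_toy_network",
]

#: Default planted slope patterns: one row per metric, one column per
#: segment (len(turning_ages) + 1 segments).  Signs alternate so every
#: planted turning age is a genuine direction change in most metrics,
#: with per-metric sign flips and magnitudes so the metrics are not
#: collinear.
_DEFAULT_SLOPE_SIGNS = [
    (+1, -1, +1, -1, +1),
    (-1, +1, -1, +1, -1),
    (+1, -1, -1, +1, -1),
    (-1, +1, +1, -1, +1),
    (+1, +1, -1, +1, -1),
    (-1, -1, +1, -1, +1),
    (+1, -1, +1, +1, -1),
    (-1, +1, -1, -1, +1),
    (+1, -1, -1, -1, +1),
    (-1, +1, +1, +1, -1),
    (+1, +1, -1, -1, +1),
]


@dataclass
class PlantedTrajectorySpec:
    """Planted metric trajectories with known turning ages.

    Two mean-curve shapes are available.  ``smooth`` (the default) gives
    each metric a polynomial curve whose derivative is proportional to
    prod(age - a_k) over the turning ages, so the slope changes sign
    exactly at every planted age; per-metric amplitudes alternate in
    sign and vary in magnitude so the metrics are not identical.
    ``piecewise_linear`` gives continuous piecewise-linear curves with
    the stated per-segment slopes (tent functions and their relatives).
    Subject values add i.i.d. Gaussian noise around the mean curve.
    """

    metric_names: list[str] = field(
        default_factory=lambda: [f"metric_{i:02d}" for i in range(11)]
    )
    turning_ages: list[int] = field(default_factory=lambda: [10, 30, 65, 82])
    segment_slopes: list[list[float]] | None = None
    noise_sd: float = 0.3
    n_per_age: int = 20
    seed: int = 0
    age_range: tuple[int, int] = (0, 90)
    shape: str = "smooth"

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        ages = list(self.turning_ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("turning_ages must be strictly increasing")
        if any(not (lo < a < hi) for a in ages):
            raise ValueError(
                f"turning ages must lie strictly inside [{lo}, {hi}]: {ages}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_per_age < 1:
            raise ValueError("n_per_age must be positive")
        if self.shape not in ("smooth", "piecewise_linear"):
            raise ValueError(f"unknown trajectory shape {self.shape!r}")
        n_seg = len(ages) + 1
        if self.segment_slopes is None:
            self.segment_slopes = self._default_slopes(n_seg)
        for slopes in self.segment_slopes:
            if len(slopes) != n_seg:
                raise ValueError(
                    f"each metric needs {n_seg} segment slopes, got {len(slopes)}"
                )
        if len(self.segment_slopes) != len(self.metric_names):
            raise ValueError("segment_slopes and metric_names length mismatch")

    def _default_slopes(self, n_seg: int) -> list[list[float]]:
        out = []
        for i, _name in enumerate(self.metric_names):
            signs = _DEFAULT_SLOPE_SIGNS[i % len(_DEFAULT_SLOPE_SIGNS)]
            mag = 1.0 + 0.1 * (i % 4)
            row = [mag * signs[j % len(signs)] for j in range(n_seg)]
            out.append(row)
        return out

    def mean_curve(self, metric_idx: int, ages: np.ndarray) -> np.ndarray:
        """Evaluate the noiseless mean curve of one metric at ``ages``."""
        ages = np.asarray(ages, dtype=float)
        lo, hi = self.age_range
        if self.shape == "smooth":
            # Quintic-type curve: derivative prop. to prod(age - a_k), so
            # extrema sit exactly at the planted ages.  Standardized over
            # the integer age grid, then scaled by a per-metric amplitude
            # with alternating sign.
            coeffs = np.polyint(np.poly(np.asarray(self.turning_ages, float)))
            grid = np.arange(lo, hi + 1, dtype=float)
            base = np.polyval(coeffs, grid)
            mu, sd = base.mean(), base.std()
            sd = sd if sd > 0 else 1.0
            i = metric_idx
            amp = (1.0 + 0.1 * (i % 4)) * (1.0 if i % 2 == 0 else -1.0)
            return amp * (np.polyval(coeffs, ages) - mu) / sd
        knots = np.array([lo, *self.turning_ages, hi], dtype=float)
        slopes = np.asarray(self.segment_slopes[metric_idx], dtype=float)
        # Continuous piecewise-linear curve, intercept 0 at the lower edge.
        knot_vals = np.concatenate(
            [[0.0], np.cumsum(slopes * np.diff(knots))]
        )
        return np.interp(ages, knots, knot_vals)


def generate_metric_trajectories(
    spec: PlantedTrajectorySpec,
) -> tuple[pd.DataFrame, dict]:
    """Draw a subject table from planted trajectories.

    Returns a tidy table with ``subject_id``, ``age``, ``age_bin`` and one
    column per metric, plus a ground-truth dict holding the planted
    turning ages and the noiseless mean curves.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = np.arange(lo, hi + 1)
    rows_age = np.repeat(ages, spec.n_per_age)
    n = rows_age.size
    data = {
        "subject_id": [f"synth-{i:05d}" for i in range(n)],
        "age": rows_age.astype(float),
        "age_bin": rows_age.astype(int),
    }
    curves = {}
    for j, name in enumerate(spec.metric_names):
        mean = spec.mean_curve(j, rows_age)
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        data[name] = mean + noise
        curves[name] = spec.mean_curve(j, ages).tolist()
    table = pd.DataFrame(data)
    truth = {
        "turning_ages": list(spec.turning_ages),
        "metric_names": list(spec.metric_names),
        "mean_curves": curves,
        "ages": ages.tolist(),
        "shape": spec.shape,
        "noise_sd": spec.noise_sd,
        "n_per_age": spec.n_per_age,
        "seed": spec.seed,
    }
    return table, truth


@dataclass
class SubjectRecord:
    """One cohort element: a connectivity matrix plus its metadata."""

    subject_id: str
    age: float
    sex: str
    dataset: str
    atlas: str
    matrix: np.ndarray

    @property
    def age_bin(self) -> int:
        """Nearest integer year, half-up (the age bin used throughout)."""
        return int(np.floor(self.age + 0.5))


@dataclass
class SyntheticCohortConfig:
    """Stochastic-block-model cohort of streamline-count matrices.

    ``density_curve`` maps age (years) to the target edge density of a
    subject's network; the default declines linearly from 0.30 at birth
    to 0.12 at age 90, echoing the shift from dense, weak networks early
    in life to sparse, strong networks late in life.  Within-block edge
    probability exceeds between-block probability by ``block_ratio`` so
    the networks carry planted modular structure.
    """

    n_nodes: int = 90
    age_range: tuple[int, int] = (0, 90)
    n_subjects: int = 100
    block_count: int = 5
    density_curve: object | None = None
    block_ratio: float = 4.0
    mean_count: float = 20.0
    seed: int = 0
    ages: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.block_count < 1:
            raise ValueError("block_count must be >= 1")

    def target_density(self, age: float) -> float:
        if self.density_curve is None:
            lo, hi = self.age_range
            frac = (age - lo) / max(hi - lo, 1)
            d = 0.30 - 0.18 * frac
        elif callable(self.density_curve):
            d = float(self.density_curve(age))
        else:
            d = float(self.density_curve[int(round(age))])
        if not 0.0 < d <= 1.0:
            raise ValueError(f"infeasible density {d} at age {age}")
        return d


def _sbm_matrix(
    rng: np.random.Generator, cfg: SyntheticCohortConfig, age: float
) -> np.ndarray:
    n = cfg.n_nodes
    d = cfg.target_density(age)
    labels = np.arange(n) % cfg.block_count
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    same_u = same[iu]
    f_in = same_u.mean()
    # Solve f_in*p_in + (1-f_in)*p_out = d with p_in = ratio*p_out.
    p_out = d / (f_in * cfg.block_ratio + (1.0 - f_in))
    p_in = min(cfg.block_ratio * p_out, 1.0)
    probs = np.where(same_u, p_in, p_out)
    present = rng.random(iu[0].size) < probs
    # Counts: Poisson around an age-increasing mean (weak early, strong
    # late), shifted by 1 so present edges are never zero.
    lo, hi = cfg.age_range
    lam = cfg.mean_count * (0.5 + (age - lo) / max(hi - lo, 1))
    counts = np.where(present, rng.poisson(lam, size=present.size) + 1, 0)
    m = np.zeros((n, n))
    m[iu] = counts
    m += m.T
    return m


def generate_cohort(config: SyntheticCohortConfig) -> list[SubjectRecord]:
    """Draw a cohort of SBM count matrices with age-varying density."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
        if ages.size != config.n_subjects:
            raise ValueError("ages length must equal n_subjects")
    else:
        ages = rng.integers(lo, hi + 1, size=config.n_subjects).astype(float)
    cohort = []
    for i, age in enumerate(ages):
        m = _sbm_matrix(rng, config, age)
        cohort.append(
            SubjectRecord(
                subject_id=f"sbm-{i:05d}",
                age=float(age),
                sex=["F", "M"][int(rng.integers(0, 2))],
                dataset="synthetic",
                atlas="aal90",
                matrix=m,
            )
        )
    return cohort


def generate_toy_network(
    kind: str, size: int = 4, weights: float | np.ndarray = 1.0
) -> np.ndarray:
    """Canonical small fixtures for metric oracles.

    kinds: complete, ring, star, path, two_cliques, sbm.  ``weights`` is a
    scalar applied to every edge (or, for ``sbm``, ignored: counts are
    drawn with a fixed seed).
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    w = float(weights) if np.isscalar(weights) else None
    m = np.zeros((size, size))
    if kind == "complete":
        m[:] = w
        np.fill_diagonal(m, 0.0)
    elif kind == "ring":
        for i in range(size):
            m[i, (i + 1) % size] = m[(i + 1) % size, i] = w
    elif kind == "star":
        m[0, 1:] = m[1:, 0] = w
    elif kind == "path":
        for i in range(size - 1):
            m[i, i + 1] = m[i + 1, i] = w
    elif kind == "two_cliques":
        if size % 2:
            raise ValueError("two_cliques needs an even size")
        h = size // 2
        m[:h, :h] = w
        m[h:, h:] = w
        np.fill_diagonal(m, 0.0)
    elif kind == "sbm":
        cfg = SyntheticCohortConfig(
            n_nodes=size, block_count=2, n_subjects=1, seed=12345
        )
        m = _sbm_matrix(np.random.default_rng(12345), cfg, age=45.0)
    else:
        raise ValueError(f"unknown toy network kind: {kind!r}")
    return m
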