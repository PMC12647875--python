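"""Cohort preprocessing: outliers, harmonization mask, thresholding.

Density-targeted thresholding comes in two modes.  *Variable* mode keeps
the natural age-density relationship: a smoothing spline is fit to raw
densities over age, 70% of the fitted curve becomes the per-age target,
and one streamline-count cutoff per (age bin x dataset) group is chosen
so the group's mean density lands on target.  *Fixed* mode gives every
subject the same density (10% in the reference configuration) with a
per-subject cutoff, removing total-connectivity bias from topological
comparisons.  The same spline smoother doubles as the peak/valley
detector used to describe single-metric lifespan curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq

from lifespan_topology.synthetic import SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "compute_density",
    "remove_density_outliers",
    "apply_harmonization_mask",
    "AgeSmoother",
    "fit_age_smoother",
    "compute_variable_density_targets",
    "threshold_to_density",
    "threshold_cohort_variable",
    "normalize_weights",
    "validate_matrix",
]


def validate_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("connectivity matrix needs at least 2 nodes")
    if not np.allclose(m, m.T):
        raise ValueError("connectivity matrix must be symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError("connectivity matrix must have a zero diagonal")
    if np.any(m < 0):
        raise ValueError("connectivity matrix must be nonnegative")
    return m


def compute_density(m: np.ndarray) -> float:
    """Fraction of possible node pairs with a nonzero edge."""
    m = validate_matrix(m)
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(m[iu]) / (n * (n - 1) / 2))


def remove_density_outliers(
    cohort: list[SubjectRecord], n_sd: float = 3.0
) -> tuple[list[SubjectRecord], list[str]]:
    """Drop subjects whose density is beyond ``n_sd`` SDs of their age bin.

    Bins with fewer than two subjects are passed through untouched (an SD
    is undefined there), as are bins whose SD is zero.
    """
    bins: dict[int, list[SubjectRecord]] = {}
    for rec in cohort:
        bins.setdefault(rec.age_bin, []).append(rec)
    removed: list[str] = []
    kept: list[SubjectRecord] = []
    for age_bin in sorted(bins):
        group = bins[age_bin]
        if len(group) < 2:
            kept.extend(group)
            logger.info("age bin %d has <2 subjects; passed through", age_bin)
            continue
        dens = np.array([compute_density(r.matrix) for r in group])
        mu, sd = dens.mean(), dens.std(ddof=0)
        for rec, d in zip(group, dens):
            if sd > 0 and abs(d - mu) > n_sd * sd:
                removed.append(rec.subject_id)
                logger.info(
                    "removed %s (age bin %d): density %.4f vs bin mean %.4f, sd %.4f",
                    rec.subject_id, age_bin, d, mu, sd,
                )
            else:
                kept.append(rec)
    order = {r.subject_id: i for i, r in enumerate(cohort)}
    kept.sort(key=lambda r: order[r.subject_id])
    return kept, removed


def apply_harmonization_mask(
    harmonized: np.ndarray, original: np.ndarray
) -> np.ndarray:
    """Retain only connections present before harmonization; clip negatives."""
    harmonized = np.asarray(harmonized, dtype=float)
    original = np.asarray(original, dtype=float)
    if harmonized.shape != original.shape:
        raise ValueError(
            f"shape mismatch: {harmonized.shape} vs {original.shape}"
        )
    out = np.where(original == 0, 0.0, harmonized)
    return np.clip(out, 0.0, None)


@dataclass
class AgeSmoother:
    """A fitted cubic smoothing spline over age with derivative access."""

    spline: object
    ages: np.ndarray          # integer evaluation grid
    fitted: np.ndarray        # spline values at `ages`
    sign_switch_ages: list[int]
    constant: bool = False

    def __call__(self, age) -> np.ndarray:
        return self.spline(age)

    def derivative(self, age) -> np.ndarray:
        return self.spline.derivative()(age)


def fit_age_smoother(x, y, lam: float | None = None) -> AgeSmoother:
    """Cubic smoothing spline of ``y`` over age, with peak/valley ages.

    The penalty is chosen by generalized cross-validation unless ``lam``
    is given.  Sign switches of the fitted derivative between consecutive
    integer ages are refined by root finding and reported as integer
    peak/valley ages.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    ux = np.unique(x)
    if ux.size < 10:
        raise ValueError("need at least 10 distinct ages to smooth")
    # make_smoothing_spline requires strictly increasing x: average ties.
    if ux.size < x.size:
        ymean = np.array([y[x == v].mean() for v in ux])
        xs, ys = ux, ymean
    else:
        order = np.argsort(x)
        xs, ys = x[order], y[order]
    constant = np.allclose(ys, ys[0])
    spline = make_smoothing_spline(xs, ys, lam=lam)
    ages = np.arange(int(np.floor(xs.min())), int(np.ceil(xs.max())) + 1)
    fitted = spline(ages)
    switches: list[int] = []
    if not constant:
        deriv = spline.derivative()
        g = deriv(ages.astype(float))
        for i in range(len(ages) - 1):
            if g[i] == 0 and i > 0 and np.sign(g[i - 1]) != np.sign(g[i + 1]):
                switches.append(int(ages[i]))
            elif g[i] * g[i + 1] < 0:
                root = brentq(deriv, ages[i], ages[i + 1])
                switches.append(int(np.floor(root + 0.5)))
    else:
        logger.warning("constant response: no peaks/valleys to report")
    switches = sorted(set(switches))
    return AgeSmoother(
        spline=spline, ages=ages, fitted=fitted,
        sign_switch_ages=switches, constant=constant,
    )


def compute_variable_density_targets(
    cohort: list[SubjectRecord], fraction: float = 0.7,
    lam: float | None = None,
) -> dict[int, float]:
    """70% of the smoothed raw-density trend, per integer age."""
    ages = np.array([r.age_bin for r in cohort], dtype=float)
    dens = np.array([compute_density(r.matrix) for r in cohort])
    sm = fit_age_smoother(ages, dens, lam=lam)
    targets = {}
    for a, v in zip(sm.ages, sm.fitted):
        t = fraction * float(v)
        if t <= 0:
            raise ValueError(
                f"nonpositive target density {t:.4f} at age {int(a)}; "
                "smoothed density curve dips to zero"
            )
        targets[int(a)] = min(t, 1.0)
    return targets


def _edge_order(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, stable by pair index."""
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = m[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def _keep_top_k(m: np.ndarray, k: int) -> np.ndarray:
    """Keep the k heaviest edges: all strictly above the cutoff weight,
    then tied edges in descending order (stable by node-pair index)."""
    iu, ju, w = _edge_order(m)
    k = min(k, int(np.count_nonzero(w)))
    out = np.zeros_like(m)
    if k > 0:
        out[iu[:k], ju[:k]] = w[:k]
        out += out.T
    return out


def threshold_to_density(
    group: list[np.ndarray],
    target: float,
    mode: str = "fixed",
) -> tuple[list[np.ndarray], float]:
    """Threshold matrices toward a target density.

    fixed: each matrix keeps its own top-k edges with
    k = round(target * n_pairs), so every network's density equals the
    target as closely as ties permit.

    variable: one count cutoff for the whole group, chosen by brute force
    over the sorted union of weights to minimize |mean density - target|;
    edges >= cutoff survive.
    """
    if not group:
        raise ValueError("empty group")
    if not 0.0 < target <= 1.0:
        raise ValueError("target density must be in (0, 1]")
    group = [validate_matrix(m) for m in group]
    n = group[0].shape[0]
    n_pairs = n * (n - 1) // 2
    if mode == "fixed":
        k = int(round(target * n_pairs))
        out = [_keep_top_k(m, k) for m in group]
        max_d = max(compute_density(m) for m in group)
        if target > max_d + 1e-12:
            logger.warning(
                "target density %.3f above max achievable %.3f; "
                "networks kept at their own density", target, max_d,
            )
        return out, float(k)
    if mode == "variable":
        weights = np.unique(
            np.concatenate([m[np.triu_indices(n, k=1)] for m in group])
        )
        candidates = weights[weights > 0]
        best_c, best_err = 0.0, None
        for c in candidates:
            mean_d = float(
                np.mean([
                    np.count_nonzero(m[np.triu_indices(n, k=1)] >= c) / n_pairs
                    for m in group
                ])
            )
            err = abs(mean_d - target)
            # strict < keeps the smallest cutoff among ties -> densest result
            if best_err is None or err < best_err:
                best_err, best_c = err, float(c)
        raw_mean = float(np.mean([compute_density(m) for m in group]))
        if target > raw_mean + 1e-12:
            logger.warning(
                "variable-mode target %.3f above raw mean density %.3f; "
                "group returned unthresholded", target, raw_mean,
            )
            return [m.copy() for m in group], 0.0
        out = [np.where(m >= best_c, m, 0.0) for m in group]
        return out, best_c
    raise ValueError(f"unknown mode {mode!r}")


def threshold_cohort_variable(
    cohort: list[SubjectRecord],
    targets: dict[int, float],
) -> tuple[list[SubjectRecord], dict[str, float]]:
    """Variable-density thresholding per (age bin x dataset) group."""
    groups: dict[tuple[int, str], list[SubjectRecord]] = {}
    for rec in cohort:
        groups.setdefault((rec.age_bin, rec.dataset), []).append(rec)
    cutoffs: dict[str, float] = {}
    out: dict[str, SubjectRecord] = {}
    for (age_bin, dataset), recs in groups.items():
        target = targets[age_bin]
        thresholded, cutoff = threshold_to_density(
            [r.matrix for r in recs], target, mode="variable"
        )
        cutoffs[f"{age_bin}|{dataset}"] = cutoff
        for rec, m in zip(recs, thresholded):
            out[rec.subject_id] = SubjectRecord(
                rec.subject_id, rec.age, rec.sex, rec.dataset, rec.atlas, m
            )
    return [out[r.subject_id] for r in cohort], cutoffs


def normalize_weights(m: np.ndarray) -> np.ndarray:
    """Rescale weights to [0, 1] by dividing by the matrix maximum."""
    m = validate_matrix(m)
    mx = m.max()
    if mx == 0:
        raise ValueError("cannot normalize an all-zero matrix")
    return m / mx
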