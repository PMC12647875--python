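"""Within- and between-epoch statistics.

Epochs are the age intervals between consecutive major turning points.
Inside each epoch the age-topology relationship is characterized by
Pearson correlations (with direction-change detection across epoch
boundaries and FDR-corrected regional correlations), a 10-fold
cross-validated LASSO age prediction with the one-standard-error lambda
rule, and a PCA whose component count is set by parallel analysis and
whose loadings are varimax-rotated.  Epochs are compared on their PCA
scores by Levene's test, Welch's one-way ANOVA and Games-Howell post hoc
tests, and on the shape of their per-age mean score trajectories by
dynamic time warping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "assign_epochs",
    "epoch_correlations",
    "regional_correlations",
    "LassoResult",
    "lasso_age_prediction",
    "PCAResult",
    "pca_parallel_varimax",
    "compare_epoch_scores",
    "dtw_distance",
    "dtw_epoch_trajectories",
]


def assign_epochs(ages, boundaries) -> np.ndarray:
    """Epoch index (1-based) per subject from ordered boundary ages.

    Epoch k covers rounded ages [b_{k-1}, b_k); the first epoch starts at
    0 and the last is closed at the top of the age range, so a subject
    exactly at a boundary age belongs to the later epoch.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0) or np.any(ages > 90):
        raise ValueError("ages must lie in [0, 90]")
    boundaries = sorted(float(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")
    if boundaries and (boundaries[0] <= 0 or boundaries[-1] >= 90):
        raise ValueError("boundaries must lie strictly inside (0, 90)")
    rounded = np.floor(ages + 0.5)
    return np.searchsorted(boundaries, rounded, side="right").astype(int) + 1


def epoch_correlations(
    metric_table: pd.DataFrame,
    epochs: np.ndarray,
    metrics: list[str],
    age_col: str = "age",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-epoch Pearson correlations of each metric with age.

    Direction changes are flagged where consecutive epochs are both
    significant (p < alpha) with opposite-signed correlations.  Metrics
    with zero variance inside an epoch get NaN r and a degenerate flag.
    """
    rows = []
    epochs = np.asarray(epochs)
    for ep in np.unique(epochs):
        mask = epochs == ep
        if mask.sum() < 3:
            raise ValueError(f"epoch {ep} has fewer than 3 subjects")
        age = metric_table.loc[mask, age_col].to_numpy(dtype=float)
        for metric in metrics:
            y = metric_table.loc[mask, metric].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(age) == 0:
                rows.append(
                    dict(epoch=int(ep), metric=metric, n=int(mask.sum()),
                         r=np.nan, p=np.nan, significant=False, degenerate=True)
                )
                continue
            r, p = stats.pearsonr(age, y)
            rows.append(
                dict(epoch=int(ep), metric=metric, n=int(mask.sum()),
                     r=float(r), p=float(p),
                     significant=bool(p < alpha), degenerate=False)
            )
    report = pd.DataFrame(rows)
    report["direction_change"] = False
    for metric in metrics:
        sub = report[report.metric == metric].sort_values("epoch")
        prev = None
        for idx, row in sub.iterrows():
            if (
                prev is not None
                and row.significant
                and prev.significant
                and np.sign(row.r) * np.sign(prev.r) < 0
            ):
                report.loc[idx, "direction_change"] = True
            prev = row
    return report


def regional_correlations(
    nodal_table: pd.DataFrame,
    epochs_by_subject: dict[str, int],
    metric: str,
    age_col: str = "age",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region age correlations with Benjamini-Hochberg correction.

    The BH step-up is applied across the regions within each epoch (one
    family of 90 tests per metric per epoch).
    """
    df = nodal_table.copy()
    df["epoch"] = df["subject_id"].map(epochs_by_subject)
    rows = []
    for ep, by_epoch in df.groupby("epoch"):
        regions = sorted(by_epoch["node"].unique())
        rs, ps = [], []
        for node in regions:
            sub = by_epoch[by_epoch.node == node]
            y = sub[metric].to_numpy(dtype=float)
            age = sub[age_col].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(age) == 0:
                rs.append(np.nan)
                ps.append(1.0)
                continue
            r, p = stats.pearsonr(age, y)
            rs.append(float(r))
            ps.append(float(p))
        reject, q, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        for node, r, p, qq, rej in zip(regions, rs, ps, q, reject):
            rows.append(
                dict(epoch=int(ep), node=int(node), r=r, p=p,
                     q=float(qq), significant=bool(rej))
            )
    return pd.DataFrame(rows)


@dataclass
class LassoResult:
    """One epoch's LASSO age model."""

    epoch: int
    coefficients: pd.Series
    selected_lambda: float
    lambda_min_mse: float
    rule: str                 # "one_se" or "min_mse_fallback"
    n_folds: int
    n_subjects: int


def _one_se_lambda(alphas: np.ndarray, mse_path: np.ndarray) -> tuple[float, float]:
    """Largest lambda whose mean CV MSE is within one SE of the minimum."""
    mean_mse = mse_path.mean(axis=1)
    se = mse_path.std(axis=1, ddof=1) / np.sqrt(mse_path.shape[1])
    i_min = int(np.argmin(mean_mse))
    cutoff = mean_mse[i_min] + se[i_min]
    ok = np.flatnonzero(mean_mse <= cutoff)
    lam_1se = float(alphas[ok].max())
    return lam_1se, float(alphas[i_min])


def lasso_age_prediction(
    metric_table: pd.DataFrame,
    epochs: np.ndarray,
    metrics: list[str],
    age_col: str = "age",
    folds: int = 10,
    seed: int = 0,
) -> list[LassoResult]:
    """Per-epoch LASSO of age on the (within-epoch standardized) metrics.

    The sparsity-encouraging one-standard-error lambda is used; if it
    zeroes every coefficient, the model falls back to the minimum-MSE
    lambda and is flagged, mirroring epochs where the regularization had
    to be weakened.
    """
    results = []
    epochs = np.asarray(epochs)
    for ep in np.unique(epochs):
        mask = epochs == ep
        n = int(mask.sum())
        if n <= folds:
            raise ValueError(f"epoch {ep}: need more than {folds} subjects")
        x = metric_table.loc[mask, metrics].to_numpy(dtype=float)
        y = metric_table.loc[mask, age_col].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"epoch {ep}: constant outcome")
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xz = (x - x.mean(axis=0)) / sd
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        lcv = LassoCV(cv=cv, random_state=seed).fit(xz, y)
        lam_1se, lam_min = _one_se_lambda(lcv.alphas_, lcv.mse_path_)
        model = Lasso(alpha=lam_1se).fit(xz, y)
        rule = "one_se"
        lam = lam_1se
        if np.all(model.coef_ == 0):
            logger.info(
                "epoch %d: one-SE model empty; falling back to min-MSE lambda",
                int(ep),
            )
            model = Lasso(alpha=lam_min).fit(xz, y)
            rule = "min_mse_fallback"
            lam = lam_min
        results.append(
            LassoResult(
                epoch=int(ep),
                coefficients=pd.Series(model.coef_, index=metrics),
                selected_lambda=float(lam),
                lambda_min_mse=float(lam_min),
                rule=rule,
                n_folds=folds,
                n_subjects=n,
            )
        )
    return results


@dataclass
class PCAResult:
    """Parallel-analysis-retained, varimax-rotated PCA."""

    n_retained: int
    eigenvalues: np.ndarray
    pa_thresholds: np.ndarray
    loadings: pd.DataFrame            # varimax-rotated
    scores: pd.DataFrame              # rotated component scores
    variance_explained: np.ndarray    # per retained rotated component, %
    unrotated_loadings: pd.DataFrame | None = None


def parallel_analysis_thresholds(
    n_obs: int, n_vars: int, n_iter: int = 1000,
    percentile: float = 95.0, seed: int = 0,
) -> np.ndarray:
    """Per-rank eigenvalue percentiles from standardized random data."""
    rng = np.random.default_rng(seed)
    eigs = np.empty((n_iter, n_vars))
    for i in range(n_iter):
        r = rng.standard_normal((n_obs, n_vars))
        corr = np.corrcoef(r, rowvar=False)
        eigs[i] = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return np.percentile(eigs, percentile, axis=0)


def pca_parallel_varimax(
    metric_table: pd.DataFrame,
    metrics: list[str],
    n_iter: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    n_retain: int | None = None,
) -> PCAResult:
    """PCA on standardized metrics; retention by parallel analysis.

    Observed eigenvalues of the metric correlation matrix are compared
    rank-by-rank with the ``percentile`` of eigenvalues from ``n_iter``
    standardized random datasets of the same shape; the leading run of
    components exceeding their threshold is retained, then varimax
    rotation (with Kaiser normalization) is applied to the retained
    loadings.
    """
    x = metric_table[metrics].to_numpy(dtype=float)
    n, p = x.shape
    if n < p + 1:
        raise ValueError("need at least one more subject than metrics")
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [m for m, s in zip(metrics, sd) if s == 0]
        raise ValueError(f"constant metrics cannot enter the PCA: {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    thresholds = parallel_analysis_thresholds(
        n, p, n_iter=n_iter, percentile=percentile, seed=seed
    )
    if n_retain is None:
        n_retain = 0
        while n_retain < p and eigval[n_retain] > thresholds[n_retain]:
            n_retain += 1
    if n_retain == 0:
        logger.warning("parallel analysis retains no components")
        empty = pd.DataFrame(index=metrics)
        return PCAResult(
            n_retained=0, eigenvalues=eigval, pa_thresholds=thresholds,
            loadings=empty, scores=pd.DataFrame(index=metric_table.index),
            variance_explained=np.array([]),
        )
    load = eigvec[:, :n_retain] * np.sqrt(eigval[:n_retain])
    if n_retain > 1:
        # Kaiser normalization: rotate rows scaled to unit communality.
        comm = np.sqrt((load**2).sum(axis=1))
        comm[comm == 0] = 1.0
        rot_norm, rot_t = rotate_factors(load / comm[:, None], "varimax")
        rotated = rot_norm * comm[:, None]
    else:
        rotated, rot_t = load, np.eye(1)
    # Component scores: standardized data projected on rotated axes,
    # scaled to unit variance per component before rotation.
    raw_scores = z @ eigvec[:, :n_retain] / np.sqrt(eigval[:n_retain])
    scores = raw_scores @ rot_t
    var_rot = (rotated**2).sum(axis=0) / p * 100.0
    comp_names = [f"PC{i + 1}" for i in range(n_retain)]
    return PCAResult(
        n_retained=int(n_retain),
        eigenvalues=eigval,
        pa_thresholds=thresholds,
        loadings=pd.DataFrame(rotated, index=metrics, columns=comp_names),
        scores=pd.DataFrame(
            scores, index=metric_table.index, columns=comp_names
        ),
        variance_explained=var_rot,
        unrotated_loadings=pd.DataFrame(
            load, index=metrics, columns=comp_names
        ),
    )


def compare_epoch_scores(
    scores: pd.DataFrame, epochs: np.ndarray
) -> dict[str, pd.DataFrame]:
    """Levene, Welch ANOVA, and consecutive-pair Games-Howell per PC."""
    epochs = np.asarray(epochs)
    levels = np.unique(epochs)
    if levels.size < 2:
        raise ValueError("need at least two epochs")
    for ep in levels:
        if (epochs == ep).sum() < 3:
            raise ValueError(f"epoch {ep} has fewer than 3 subjects")
    lev_rows, welch_rows, gh_rows = [], [], []
    for pc in scores.columns:
        groups = [scores.loc[epochs == ep, pc].to_numpy() for ep in levels]
        if any(np.std(g) == 0 for g in groups):
            logger.warning("%s: zero within-group variance; skipped", pc)
            continue
        w, p = stats.levene(*groups, center="median")
        lev_rows.append(dict(pc=pc, statistic=float(w), p=float(p)))
        df = pd.DataFrame({"score": scores[pc].to_numpy(), "epoch": epochs})
        wa = pg.welch_anova(data=df, dv="score", between="epoch")
        welch_rows.append(
            dict(pc=pc, F=float(wa["F"].iloc[0]),
                 ddof1=float(wa["ddof1"].iloc[0]),
                 ddof2=float(wa["ddof2"].iloc[0]),
                 p=float(wa["p_unc"].iloc[0]))
        )
        gh = pg.pairwise_gameshowell(data=df, dv="score", between="epoch")
        for _, row in gh.iterrows():
            a, b = int(row["A"]), int(row["B"])
            if abs(a - b) == 1:  # consecutive epochs only
                gh_rows.append(
                    dict(pc=pc, epoch_a=min(a, b), epoch_b=max(a, b),
                         mean_diff=float(row["diff"]), t=float(row["T"]),
                         df=float(row["df"]), p=float(row["pval"]))
                )
    return {
        "levene": pd.DataFrame(lev_rows),
        "welch": pd.DataFrame(welch_rows),
        "games_howell": pd.DataFrame(gh_rows),
    }


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic full-window dynamic time warping distance.

    Local cost is the Euclidean (absolute) distance between scalar
    points; the distance is the minimum cumulative cost over monotone
    warping paths.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("series must have length >= 2")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 1:] = cost[i, 1:]
        prev = acc[i - 1]
        for j in range(1, m):
            acc[i, j] += min(acc[i - 1, j], acc[i, j - 1], prev[j - 1])
    return float(acc[-1, -1])


@dataclass
class DTWReport:
    per_pair: pd.DataFrame       # pc, epoch_a, epoch_b, raw, standardized
    pair_sums: pd.DataFrame      # epoch_a, epoch_b, summed standardized


def dtw_epoch_trajectories(
    scores: pd.DataFrame,
    epochs: np.ndarray,
    ages: np.ndarray,
) -> DTWReport:
    """DTW distances between consecutive epochs' score trajectories.

    Each epoch's series for a PC is the mean score per integer age; raw
    DTW distances are z-scored within each PC across the consecutive-
    pair set, and the per-pair sum over PCs is reported.
    """
    epochs = np.asarray(epochs)
    ages = np.floor(np.asarray(ages, dtype=float) + 0.5).astype(int)
    levels = sorted(np.unique(epochs))
    series: dict[tuple[int, str], np.ndarray] = {}
    for ep in levels:
        mask = epochs == ep
        for pc in scores.columns:
            df = pd.DataFrame(
                {"age": ages[mask], "score": scores.loc[mask, pc].to_numpy()}
            )
            s = df.groupby("age")["score"].mean().sort_index().to_numpy()
            if s.size < 3:
                raise ValueError(
                    f"epoch {ep} spans fewer than 3 integer ages"
                )
            series[(int(ep), pc)] = s
    rows = []
    for a, b in zip(levels, levels[1:]):
        for pc in scores.columns:
            rows.append(
                dict(pc=pc, epoch_a=int(a), epoch_b=int(b),
                     raw=dtw_distance(series[(int(a), pc)], series[(int(b), pc)]))
            )
    per_pair = pd.DataFrame(rows)
    per_pair["standardized"] = per_pair.groupby("pc")["raw"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=0) if s.std(ddof=0) > 0 else s * 0.0
    )
    pair_sums = (
        per_pair.groupby(["epoch_a", "epoch_b"])["standardized"]
        .sum()
        .reset_index()
        .rename(columns={"standardized": "summed_standardized"})
    )
    return DTWReport(per_pair=per_pair, pair_sums=pair_sums)
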