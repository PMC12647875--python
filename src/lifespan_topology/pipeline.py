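"""End-to-end orchestration: simulate -> preprocess -> metrics ->
turning points -> epochs, driven by one serializable configuration with
a global seed and a manifest tying every output to the config hash."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lifespan_topology import io as lio
from lifespan_topology.epochs import (
    assign_epochs,
    compare_epoch_scores,
    dtw_epoch_trajectories,
    epoch_correlations,
    lasso_age_prediction,
    pca_parallel_varimax,
)
from lifespan_topology.manifold import (
    EnsembleGrid,
    InflectionFilterConfig,
    TurningPointConfig,
    run_turning_point_pipeline,
)
from lifespan_topology.metrics import RETAINED_METRICS, metrics_table
from lifespan_topology.preprocess import (
    compute_variable_density_targets,
    normalize_weights,
    remove_density_outliers,
    threshold_cohort_variable,
    threshold_to_density,
)
from lifespan_topology.synthetic import (
    PlantedTrajectorySpec,
    SyntheticCohortConfig,
    generate_cohort,
    generate_metric_trajectories,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults reproduce the reference analysis settings: fixed 10%
    density, gamma 0.6, degree-5 trajectories, W=5, T=0.8, A=5."""

    out_dir: str = "results"
    mode: str = "fixed"               # "fixed" or "variable"
    fixed_target: float = 0.10
    outlier_sd: float = 3.0
    normalize: bool = True
    gamma: float = 0.6
    n_null: int = 10
    degree: int = 5
    grad_window: int = 5
    grad_threshold: float = 0.8
    age_window: int = 5
    grid: str = "small"               # "default" (968 members) or "small"
    n_subjects: int = 200
    n_per_age: int = 20
    noise_sd: float = 0.3
    source: str = "trajectories"      # "trajectories" or "cohort"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError("mode must be 'fixed' or 'variable'")
        if not 0 < self.fixed_target <= 1:
            raise ValueError("fixed_target must be in (0, 1]")
        if self.grad_threshold < 0:
            raise ValueError("grad_threshold must be >= 0")
        if self.grad_window < 1 or self.age_window < 1:
            raise ValueError("windows must be >= 1 year")
        if self.degree < 2:
            raise ValueError("degree must be >= 2")

    def turning_point_config(self) -> TurningPointConfig:
        grid = (
            EnsembleGrid.default(seed=self.seed)
            if self.grid == "default"
            else EnsembleGrid.small(seed=self.seed)
        )
        return TurningPointConfig(
            degree=self.degree,
            filter=InflectionFilterConfig(
                gradient_window=self.grad_window,
                gradient_threshold=self.grad_threshold,
                age_window=self.age_window,
            ),
            grid=grid,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write a manifest of outputs and seeds."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "stages": [],
        "outputs": {},
    }

    def stage(name: str):
        logger.info("stage %s starting", name)
        manifest["stages"].append({"name": name, "started": time.time()})
        return time.time()

    def done(t0: float) -> None:
        manifest["stages"][-1]["seconds"] = round(time.time() - t0, 3)

    # --- simulate -----------------------------------------------------
    t0 = stage("simulate")
    spec = PlantedTrajectorySpec(
        noise_sd=config.noise_sd, n_per_age=config.n_per_age, seed=config.seed
    )
    metric_table, truth = generate_metric_trajectories(spec)
    lio.save_json(truth, out / "ground_truth.json")
    manifest["outputs"]["ground_truth"] = "ground_truth.json"
    if config.source == "cohort":
        cohort_cfg = SyntheticCohortConfig(
            n_subjects=config.n_subjects, seed=config.seed
        )
        cohort = generate_cohort(cohort_cfg)
    else:
        cohort = None
    done(t0)

    # --- preprocess + metrics (cohort source only) --------------------
    if cohort is not None:
        t0 = stage("preprocess")
        cohort, removed = remove_density_outliers(cohort, config.outlier_sd)
        if config.mode == "variable":
            targets = compute_variable_density_targets(cohort)
            cohort, cutoffs = threshold_cohort_variable(cohort, targets)
        else:
            matrices, cutoff = threshold_to_density(
                [r.matrix for r in cohort], config.fixed_target, mode="fixed"
            )
            for rec, m in zip(cohort, matrices):
                rec.matrix = m
            cutoffs = {"fixed": cutoff}
        if config.normalize:
            for rec in cohort:
                rec.matrix = normalize_weights(rec.matrix)
        lio.save_json(
            {"removed": removed, "cutoffs": cutoffs}, out / "preprocess.json"
        )
        manifest["outputs"]["preprocess"] = "preprocess.json"
        done(t0)

        t0 = stage("metrics")
        metric_table = metrics_table(
            cohort, gamma=config.gamma, n_null=config.n_null, seed=config.seed
        )
        done(t0)
    metric_table.to_csv(out / "metrics.csv", index=False)
    manifest["outputs"]["metrics"] = "metrics.csv"

    # --- turning points ----------------------------------------------
    t0 = stage("turning_points")
    tp_config = config.turning_point_config()
    metric_cols = [
        c for c in metric_table.columns
        if c not in ("subject_id", "age", "age_bin", "sex", "dataset")
    ]
    tps, provenance = run_turning_point_pipeline(
        metric_table, tp_config, metrics=metric_cols
    )
    lio.save_json(
        {"major": tps.major, "pooled": tps.pooled, "counts": tps.counts},
        out / "turning_points.json",
    )
    lio.save_json(provenance, out / "turning_points_provenance.json")
    manifest["outputs"]["turning_points"] = "turning_points.json"
    done(t0)

    # --- epochs -------------------------------------------------------
    t0 = stage("epochs")
    boundaries = tps.major
    epochs = assign_epochs(metric_table["age"].to_numpy(), boundaries)
    corr = epoch_correlations(metric_table, epochs, metric_cols)
    corr.to_csv(out / "epoch_correlations.csv", index=False)
    lasso = lasso_age_prediction(
        metric_table, epochs, metric_cols, seed=config.seed
    )
    lasso_df = pd.DataFrame(
        {f"epoch_{r.epoch}": r.coefficients for r in lasso}
    )
    lasso_df.to_csv(out / "lasso_coefficients.csv")
    pca = pca_parallel_varimax(metric_table, metric_cols, seed=config.seed)
    report = {
        "n_retained": pca.n_retained,
        "eigenvalues": pca.eigenvalues,
        "pa_thresholds": pca.pa_thresholds,
        "variance_explained": pca.variance_explained,
        "lasso_rules": {r.epoch: r.rule for r in lasso},
        "boundaries": boundaries,
    }
    lio.save_json(report, out / "pca_report.json")
    if pca.n_retained >= 1 and len(boundaries) >= 1:
        comp = compare_epoch_scores(pca.scores, epochs)
        comp["welch"].to_csv(out / "welch_anova.csv", index=False)
        comp["levene"].to_csv(out / "levene.csv", index=False)
        comp["games_howell"].to_csv(out / "games_howell.csv", index=False)
        dtw = dtw_epoch_trajectories(
            pca.scores, epochs, metric_table["age"].to_numpy()
        )
        dtw.per_pair.to_csv(out / "dtw_distances.csv", index=False)
        manifest["outputs"]["dtw"] = "dtw_distances.csv"
    manifest["outputs"].update(
        {
            "epoch_correlations": "epoch_correlations.csv",
            "lasso": "lasso_coefficients.csv",
            "pca_report": "pca_report.json",
        }
    )
    done(t0)

    lio.save_json(manifest, out / "manifest.json")
    return manifest
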