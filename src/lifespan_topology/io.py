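"""On-disk formats: whitespace-delimited matrices, metadata CSV, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lifespan_topology.synthetic import SubjectRecord

METADATA_COLUMNS = ["subject_id", "age", "sex", "dataset", "atlas"]


def save_matrix(m: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, m, fmt="%.10g")


def load_matrix(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {m.shape}")
    return m


def save_cohort(cohort: list[SubjectRecord], directory: str | Path) -> Path:
    """Write one matrix file per subject plus a metadata CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        save_matrix(rec.matrix, directory / f"{rec.subject_id}.txt")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age": rec.age,
                "sex": rec.sex,
                "dataset": rec.dataset,
                "atlas": rec.atlas,
            }
        )
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    meta.to_csv(directory / "metadata.csv", index=False)
    return directory


def load_cohort(directory: str | Path) -> list[SubjectRecord]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata.csv missing columns: {sorted(missing)}")
    cohort = []
    for row in meta.itertuples(index=False):
        m = load_matrix(directory / f"{row.subject_id}.txt")
        cohort.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=str(row.sex),
                dataset=str(row.dataset),
                atlas=str(row.atlas),
                matrix=m,
            )
        )
    return cohort


def save_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def load_json(path: str | Path) -> object:
    return json.loads(Path(path).read_text())


def _jsonify(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
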