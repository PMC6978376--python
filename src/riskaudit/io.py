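"""Readers and writers for the package's text interchange formats.

All formats are plain text: feature tables are comma-separated with a
header row (UTF-8, '.' decimal); class summaries, score distributions,
cohort specs and evaluation reports are JSON documents.  Writers for
stochastic artifacts embed the seed and configuration so any output can be
regenerated from its own header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cohorts import CohortSpec
from .evaluation import SubgroupComparison
from .generative import ClassSummaries, ScoreDistributions


def read_feature_table(
    path: str | Path,
    label: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a patient×feature CSV; optionally split off the label column."""
    df = pd.read_csv(path, comment="#")
    labels = None
    if label is not None:
        if label not in df.columns:
            raise ValueError(f"label column {label!r} not found in {path}")
        labels = df[label].to_numpy(dtype=int)
        df = df.drop(columns=[label])
    return df, labels


def write_feature_table(
    path: str | Path,
    features: pd.DataFrame,
    labels: np.ndarray | None = None,
    label: str = "outcome",
    header_meta: dict[str, Any] | None = None,
) -> None:
    df = features.copy()
    if labels is not None:
        df[label] = np.asarray(labels, dtype=int)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def _read_json(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_summaries(path: str | Path, summaries: ClassSummaries) -> None:
    _write_json(path, summaries.to_dict())


def read_summaries(path: str | Path) -> ClassSummaries:
    return ClassSummaries.from_dict(_read_json(path))


def write_distributions(path: str | Path, dist: ScoreDistributions) -> None:
    _write_json(path, dist.to_dict())


def read_distributions(path: str | Path) -> ScoreDistributions:
    return ScoreDistributions.from_dict(_read_json(path))


def write_cohort_spec(path: str | Path, spec: CohortSpec) -> None:
    _write_json(path, spec.to_dict())


def read_cohort_spec(path: str | Path) -> CohortSpec:
    return CohortSpec.from_dict(_read_json(path))


def write_scored_cohort(
    path: str | Path,
    scored: pd.DataFrame,
    header_meta: dict[str, Any] | None = None,
) -> None:
    """Write the per-patient audit table with a commented config header."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        scored.to_csv(fh, index_label="patient_id")


def read_scored_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="patient_id")


def write_report(path: str | Path, comparison: SubgroupComparison, meta: dict | None = None) -> None:
    """Serialize a subgroup comparison with all per-replicate metrics."""

    def clean(v: np.ndarray) -> list:
        return [None if not np.isfinite(x) else float(x) for x in v]

    payload = {
        "meta": meta or {},
        "rule": comparison.rule,
        "n_boot": comparison.n_boot,
        "subgroup_size": int(comparison.mask.sum()),
        "complement_size": int((~comparison.mask).sum()),
        "per_replicate": {
            "normalized_brier_subgroup": clean(comparison.brier_sub),
            "normalized_brier_complement": clean(comparison.brier_comp),
            "auc_subgroup": clean(comparison.auc_sub),
            "auc_complement": clean(comparison.auc_comp),
        },
        "p_values": {
            "normalized_brier": comparison.p_brier,
            "auc": comparison.p_auc,
        },
        "summary": comparison.summary().to_dict(orient="records"),
        "calibration": {
            "subgroup": comparison.calibration_sub.to_frame().to_dict(orient="list"),
            "complement": comparison.calibration_comp.to_frame().to_dict(orient="list"),
        },
    }
    _write_json(path, payload)
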