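"""Tab-separated readers/writers, structured configuration and run manifests.

All tabular artefacts are TSV with labelled rows/columns and floats printed
with 17 significant digits, which round-trips IEEE doubles bit-exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import AnalysisConfig, Cohort, ConnectivityMatrix, ParcelSphere, RegionalMap

logger = logging.getLogger("lbdgrad")

FLOAT_FMT = "%.17g"


def read_matrix(path: str | Path, modality: str = "structural") -> ConnectivityMatrix:
    """Read a region-labelled square connectivity table.

    The file must have a header row and a first column of region labels;
    symmetry is enforced within 1e-8 by averaging with the transpose.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    n = len(df.index)
    expected = (n, 2 * n) if modality == "fused" else (n, n)
    if values.shape != expected:
        raise ValueError(f"{path}: non-square body {values.shape} for {n} region labels")
    return ConnectivityMatrix(region_ids=[str(r) for r in df.index], values=values, modality=modality)


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    if matrix.modality == "fused":
        cols = [f"{r}_sc" for r in matrix.region_ids] + [f"{r}_fc" for r in matrix.region_ids]
    else:
        cols = matrix.region_ids
    df = pd.DataFrame(matrix.values, index=matrix.region_ids, columns=cols)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort table (subject_id, group, age, sex, score columns).

    Unknown group labels and missing mandatory columns are errors; empty
    score cells are kept as NaN (flagged missing, never imputed).
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    cohort = Cohort(table=df)
    n_missing = int(df[cohort.score_columns].isna().sum().sum()) if cohort.score_columns else 0
    if n_missing:
        logger.info("cohort %s: %d missing score cells retained as NaN", path, n_missing)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_regional_map(path: str | Path, name: str | None = None) -> RegionalMap:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["region_id", "value"]:
        raise ValueError(f"{path}: regional map needs columns region_id,value")
    return RegionalMap(
        region_ids=[str(r) for r in df["region_id"]],
        values=df["value"].to_numpy(dtype=float),
        name=name or Path(path).stem,
    )


def write_regional_map(rmap: RegionalMap, path: str | Path) -> None:
    pd.DataFrame({"region_id": rmap.region_ids, "value": rmap.values}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_sphere(path: str | Path) -> ParcelSphere:
    df = pd.read_csv(path, sep="\t")
    needed = ["region_id", "hemisphere", "x", "y", "z"]
    if list(df.columns) != needed:
        raise ValueError(f"{path}: parcel sphere needs columns {needed}")
    return ParcelSphere(
        region_ids=[str(r) for r in df["region_id"]],
        hemispheres=[str(h) for h in df["hemisphere"]],
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_sphere(sphere: ParcelSphere, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": sphere.region_ids,
            "hemisphere": sphere.hemispheres,
            "x": sphere.coords[:, 0],
            "y": sphere.coords[:, 1],
            "z": sphere.coords[:, 2],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Region x gene normalised expression table (regions as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_gradient_scores(region_ids, scores: np.ndarray, path: str | Path) -> None:
    cols = [f"G{k + 1}" for k in range(scores.shape[1])]
    pd.DataFrame(scores, index=region_ids, columns=cols).to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="region_id"
    )


def read_gradient_scores(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a per-subject gradient score table (region_id, G1..Gk)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(r) for r in df.index], df.to_numpy(dtype=float)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a flat key-value YAML config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return AnalysisConfig.from_dict(raw)


def write_manifest(path: str | Path, config: AnalysisConfig, stage: str, extra: dict | None = None) -> None:
    """Write a JSON run manifest recording every config field actually used."""
    from . import __version__

    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "lbdgrad": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
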