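"""Core in-memory containers shared across the pipeline.

Everything downstream operates on parcellated data: square region-by-region
connectivity matrices, per-region scalar maps, per-subject gradient score
matrices, and a cohort table. Containers are thin dataclasses around numpy
arrays / pandas frames with the invariants each stage relies on enforced at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("HC", "PD-NC", "LBD")
MODALITIES = ("structural", "functional", "fused")

SYMMETRY_TOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """A region x region connectivity weight matrix.

    ``structural`` matrices hold nonnegative streamline counts,
    ``functional`` matrices correlations in [-1, 1]. ``fused`` matrices are
    rectangular (regions x 2*regions, the horizontal concatenation of a
    structural and a functional matrix) and are exempt from the symmetry
    checks.
    """

    region_ids: list[str]
    values: np.ndarray
    modality: str = "structural"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = list(self.region_ids)
        n = len(self.region_ids)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if np.isnan(self.values).any():
            raise ValueError("connectivity matrix contains NaN")
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region labels")
        if self.modality == "fused":
            if self.values.shape != (n, 2 * n):
                raise ValueError(
                    f"fused matrix must be regions x 2*regions, got {self.values.shape}"
                )
            return
        if self.values.shape != (n, n):
            raise ValueError(f"non-square matrix body {self.values.shape} for {n} regions")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL})")
        # enforce exact symmetry by averaging with the transpose
        self.values = (self.values + self.values.T) / 2.0
        if self.modality == "structural" and (self.values < 0).any():
            raise ValueError("negative structural weights")
        if self.modality == "functional" and (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("functional weights outside [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class GradientSet:
    """Region x component gradient scores with their eigenvalues.

    Component 0 is the principal gradient (G1). ``aligned`` records whether
    the scores have been Procrustes-rotated onto a group template.
    """

    region_ids: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    aligned: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != len(self.region_ids):
            raise ValueError("scores must be region x component")
        if self.eigenvalues.shape != (self.scores.shape[1],):
            raise ValueError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in non-increasing order")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def component(self, k: int) -> np.ndarray:
        """Scores of component ``k`` (0-based; 0 = G1)."""
        return self.scores[:, k]


@dataclass
class RegionalMap:
    """One scalar per parcel (a t-map, a marker pool, an annotation axis)."""

    region_ids: list[str]
    values: np.ndarray
    name: str = "map"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids),):
            raise ValueError("one value per region required")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.region_ids, name=self.name)


@dataclass
class ParcelSphere:
    """Unit-sphere centroid and hemisphere label for every parcel.

    The substrate for spin permutations: rotations are applied to the left
    hemisphere and x-mirrored onto the right.
    """

    region_ids: list[str]
    hemispheres: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.region_ids)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be n x 3")
        if len(self.hemispheres) != n:
            raise ValueError("one hemisphere label per region required")
        bad = [h for h in self.hemispheres if h not in ("L", "R")]
        if bad:
            raise ValueError(f"hemisphere labels must be 'L' or 'R', got {sorted(set(bad))}")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.abs(norms - 1).max() > 1e-9:
            raise ValueError("centroids must lie on the unit sphere")

    def hemisphere_index(self, hemi: str) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemispheres) if h == hemi], dtype=int)


@dataclass
class Cohort:
    """Subjects with group membership, covariates and clinical scores.

    ``table`` has one row per subject with at least ``subject_id``,
    ``group``, ``age`` and ``sex`` columns; any further columns are clinical
    scores (NaN = missing, never imputed). ``matrices`` optionally maps
    subject_id -> ConnectivityMatrix.
    """

    table: pd.DataFrame
    matrices: dict[str, ConnectivityMatrix] = field(default_factory=dict)

    MANDATORY = ("subject_id", "group", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.MANDATORY if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table missing mandatory column(s): {missing}")
        bad = sorted(set(self.table["group"]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group label(s) {bad}; allowed groups are {list(GROUPS)}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.MANDATORY]

    def subjects_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "subject_id"].tolist()


@dataclass
class EffectSpec:
    """A planted group-level alteration of the latent gradient.

    regime ``expansion`` scales latent coordinates by gamma > 1 (widened
    score distribution), ``contraction`` by gamma < 1 (narrowed),
    ``reorganisation`` permutes a fraction of coordinates at unchanged
    overall spread, ``none`` leaves the template untouched. ``noise_sd``
    scales per-edge noise in all regimes.
    """

    regime: str = "none"
    gamma: float = 1.0
    reorg_fraction: float = 0.0
    noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.regime not in ("none", "expansion", "contraction", "reorganisation"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 <= self.reorg_fraction <= 1.0:
            raise ValueError("reorg_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.regime == "expansion" and not self.gamma > 1:
            raise ValueError("expansion requires gamma > 1")
        if self.regime == "contraction" and not self.gamma < 1:
            raise ValueError("contraction requires gamma < 1")
        if self.regime == "reorganisation" and not (self.reorg_fraction > 0 and self.gamma == 1):
            raise ValueError("reorganisation requires reorg_fraction > 0 and gamma = 1")
        if self.regime == "none" and self.gamma != 1:
            raise ValueError("regime 'none' requires gamma = 1")


@dataclass
class AnalysisConfig:
    """Pipeline-wide knobs.

    sparsity: fraction of weakest weights zeroed per connectivity row before
    the affinity kernel (default 0.9 = keep the top 10%; 0.8 and 0.5 are the
    replication settings). alpha: diffusion-map density-normalisation
    exponent. n_components: number of gradients retained.
    """

    n_components: int = 10
    sparsity: float = 0.9
    alpha: float = 0.5
    n_permutations: int = 1000
    seed: int = 0
    fdr_level: float = 0.05
    covariates: Sequence[str] = ("age", "sex")

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        self.covariates = list(self.covariates)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "sparsity": self.sparsity,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "fdr_level": self.fdr_level,
            "covariates": list(self.covariates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**d)
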