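"""Group comparisons of gradient distributions and regional scores.

Two complementary views of disease-related gradient change:

* distribution level — per-subject *spread* of gradient scores (SD, range,
  mean absolute deviation from the median), compared across groups with a
  Kruskal-Wallis test and Dunn post-hoc pairwise z tests;
* regional level — per-region ordinary least squares of gradient score on
  group membership with age and sex as covariates, giving an unthresholded
  t-map plus Benjamini-Hochberg q values across regions.

The two can dissociate: regional reorganisation shifts individual regions'
scores without changing the overall spread, so the t-map lights up while
the spread comparison stays null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Cohort, GradientSet, RegionalMap


def spread_stats(gradients: dict[str, GradientSet], component: int = 0) -> pd.DataFrame:
    """Per-subject spread of one component's regional scores.

    Returns a frame with columns subject_id, component, spread_sd (sample
    SD, the primary statistic), spread_range (max - min) and spread_meanabs
    (mean absolute deviation from the median).
    """
    rows = []
    for sid, grads in gradients.items():
        if not grads.aligned:
            raise ValueError(f"gradients for {sid} are not aligned to the template")
        x = grads.component(component)
        rows.append(
            {
                "subject_id": sid,
                "component": f"G{component + 1}",
                "spread_sd": float(np.std(x, ddof=1)),
                "spread_range": float(x.max() - x.min()),
                "spread_meanabs": float(np.mean(np.abs(x - np.median(x)))),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class KruskalResult:
    h: float
    p: float
    degenerate: bool
    posthoc: pd.DataFrame


def _tie_correction_sum(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> KruskalResult:
    """Kruskal-Wallis H across groups plus Dunn pairwise post-hoc tests.

    H uses the standard tie correction with a chi-square reference. Dunn z
    statistics compare mean ranks pairwise with the pooled-rank variance
    (tie-corrected); pairwise p values are Benjamini-Hochberg adjusted
    across the pairs. All values tied is reported as a degenerate result
    (H = 0, p = 1) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if np.all(values == values[0]):
        posthoc = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "z": 0.0, "p": 1.0, "q": 1.0}
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        )
        return KruskalResult(h=0.0, p=1.0, degenerate=True, posthoc=posthoc)
    h, p = stats.kruskal(*samples)

    # Dunn post-hoc: pairwise z on mean ranks with pooled tie-corrected variance
    n = values.size
    ranks = stats.rankdata(values)
    tie_sum = _tie_correction_sum(values)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ra = ranks[groups == a]
            rb = ranks[groups == b]
            var = (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))) * (1.0 / ra.size + 1.0 / rb.size)
            z = (ra.mean() - rb.mean()) / np.sqrt(var)
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))})
    posthoc = pd.DataFrame(rows)
    posthoc["q"] = multipletests(posthoc["p"], method="fdr_bh")[1]
    return KruskalResult(h=float(h), p=float(p), degenerate=False, posthoc=posthoc)


@dataclass
class GroupTMap:
    """Per-region group-contrast statistics (unthresholded t-map plus FDR)."""

    contrast: str
    region_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def t_map(self) -> RegionalMap:
        return RegionalMap(region_ids=list(self.region_ids), values=self.t, name=self.contrast)


def _design_matrix(sub: pd.DataFrame, group_b: str, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(sub)), (sub["group"] == group_b).to_numpy(dtype=float)]
    for cov in covariates:
        if cov == "sex":
            cols.append((sub["sex"] == "M").to_numpy(dtype=float))
        else:
            cols.append(sub[cov].to_numpy(dtype=float))
    return np.column_stack(cols)


def regional_model(
    scores: pd.DataFrame,
    cohort: Cohort,
    contrast: tuple[str, str],
    covariates: list[str] = ["age", "sex"],  # noqa: B006 - read-only default
) -> GroupTMap:
    """Per-region OLS of gradient score on group with covariates.

    ``scores`` is subject x region (indexed by subject_id). The t statistic
    of the group indicator (second group vs first) is returned per region,
    with two-sided p and Benjamini-Hochberg q across regions. The fit is
    vectorised across regions (identical design, many outcomes).
    """
    group_a, group_b = contrast
    table = cohort.table
    mask = table["group"].isin(contrast)
    sub = table[mask]
    if (sub["group"] == group_a).sum() == 0 or (sub["group"] == group_b).sum() == 0:
        raise ValueError(f"both groups of contrast {contrast} must be present")
    keep = ~sub[[c for c in covariates if c != "sex"]].isna().any(axis=1)
    sub = sub[keep]
    X = _design_matrix(sub, group_b, covariates)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(
            "rank-deficient design (e.g. a single-sex group or constant covariate)"
        )
    Y = scores.loc[sub["subject_id"]].to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.clip(sigma2 * XtX_inv[1, 1], 1e-300, None))
    t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    q = multipletests(p, method="fdr_bh")[1]
    return GroupTMap(
        contrast=f"{group_b} vs {group_a}",
        region_ids=list(scores.columns),
        t=t,
        p=p,
        q=q,
    )


def scores_frame(gradients: dict[str, GradientSet], component: int = 0) -> pd.DataFrame:
    """Stack one component's aligned scores into a subject x region frame."""
    data = {}
    region_ids = None
    for sid, grads in gradients.items():
        if not grads.aligned:
            raise ValueError(f"gradients for {sid} are not aligned to the template")
        if region_ids is None:
            region_ids = list(grads.region_ids)
        data[sid] = grads.component(component)
    return pd.DataFrame.from_dict(data, orient="index", columns=region_ids)
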