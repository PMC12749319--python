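"""Composite gradient difference score Gs and severity correlations.

For every patient, each region's aligned gradient value is z-scored against
the control distribution for that region and the absolute z-scores are
summed:

    Gs = sum_regions |x - mu_controls| / sigma_controls

A subject identical to the control mean in every region scores 0; larger Gs
means a more deviant overall cortical organisation. Gs is then rank-
correlated (Spearman) with clinical severity scores, optionally partialling
out covariates by residualising the rank-transformed variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GradientSet


@dataclass
class ControlNorms:
    region_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray


def control_norms(controls: dict[str, GradientSet], component: int = 0) -> ControlNorms:
    """Per-region mean and sample SD (n-1) of control gradient scores."""
    if len(controls) < 2:
        raise ValueError("need >= 2 controls for a defined sigma")
    region_ids = None
    stack = []
    for sid, grads in controls.items():
        if not grads.aligned:
            raise ValueError(f"control gradients for {sid} are not aligned")
        if region_ids is None:
            region_ids = list(grads.region_ids)
        elif list(grads.region_ids) != region_ids:
            raise ValueError("region_id mismatch across controls")
        stack.append(grads.component(component))
    X = np.asarray(stack)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sigma == 0)
    if zero.size:
        names = [region_ids[i] for i in zero]
        raise ValueError(f"zero control SD in region(s) {names}: Gs undefined there")
    return ControlNorms(region_ids=region_ids, mu=mu, sigma=sigma)


def composite_gs(scores: np.ndarray, norms: ControlNorms) -> float:
    """Sum over regions of |x - mu| / sigma against the control norms."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != norms.mu.shape:
        raise ValueError("subject score vector does not match the control norms' regions")
    return float(np.sum(np.abs(scores - norms.mu) / norms.sigma))


def cohort_gs(
    gradients: dict[str, GradientSet], norms: ControlNorms, component: int = 0
) -> pd.Series:
    """Gs for every subject, as a Series indexed by subject_id."""
    out = {}
    for sid, grads in gradients.items():
        if list(grads.region_ids) != norms.region_ids:
            raise ValueError(f"region mismatch for subject {sid}")
        out[sid] = composite_gs(grads.component(component), norms)
    return pd.Series(out, name=f"gs_G{component + 1}")


@dataclass
class SeverityCorrelation:
    rho: float
    p: float
    n: int
    adjusted_for: list[str]


def severity_correlation(
    gs: pd.Series,
    score: pd.Series,
    adjust_for: pd.DataFrame | None = None,
) -> SeverityCorrelation:
    """Spearman correlation of Gs with a clinical score.

    Missing values are removed pairwise. Unadjusted: ordinary Spearman with
    the t-approximation p value. Adjusted (partial Spearman): both variables
    are rank-transformed, residualised on the covariate columns by least
    squares (with intercept), and the Pearson correlation of the residuals
    is reported with a t-approximation p value on n - 2 - n_covariates
    degrees of freedom.
    """
    df = pd.DataFrame({"gs": gs, "score": score})
    covariates: list[str] = []
    if adjust_for is not None:
        covariates = list(adjust_for.columns)
        df = df.join(adjust_for, how="inner")
    df = df.dropna()
    n = len(df)
    if n < 5:
        raise ValueError(f"need >= 5 paired observations, got {n}")
    for col in ("gs", "score"):
        if df[col].nunique() == 1:
            raise ValueError(f"all values of {col!r} are tied: correlation undefined")
    if not covariates:
        rho, p = stats.spearmanr(df["gs"], df["score"])
        return SeverityCorrelation(rho=float(rho), p=float(p), n=n, adjusted_for=[])
    rg = stats.rankdata(df["gs"])
    rs = stats.rankdata(df["score"])
    C = df[covariates].copy()
    for col in covariates:
        if C[col].dtype == object:
            C[col] = (C[col] == C[col].iloc[0]).astype(float)
        # covariates enter on the rank scale too, so the partialling is a
        # correlation of rank residuals throughout
        C[col] = stats.rankdata(C[col].to_numpy(dtype=float))
    X = np.column_stack([np.ones(n), C.to_numpy(dtype=float)])
    resid_g = rg - X @ np.linalg.lstsq(X, rg, rcond=None)[0]
    resid_s = rs - X @ np.linalg.lstsq(X, rs, rcond=None)[0]
    # a variable fully explained by the covariates leaves only numerical
    # noise as residual; report zero partial correlation rather than the
    # correlation of rounding errors
    tol_g = 1e-8 * np.linalg.norm(rg - rg.mean())
    tol_s = 1e-8 * np.linalg.norm(rs - rs.mean())
    if np.linalg.norm(resid_g) <= tol_g or np.linalg.norm(resid_s) <= tol_s:
        rho = 0.0
    else:
        rho = float(resid_g @ resid_s / (np.linalg.norm(resid_g) * np.linalg.norm(resid_s)))
    dof = n - 2 - len(covariates)
    rho_c = min(max(rho, -0.999999999999), 0.999999999999)
    t = rho_c * np.sqrt(dof / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return SeverityCorrelation(rho=rho, p=p, n=n, adjusted_for=covariates)


def composite_cognitive_score(tasks: pd.DataFrame, invert: list[str] | None = None) -> pd.Series:
    """Average of per-task z-scores across subjects.

    ``invert`` names tasks where larger raw values mean worse performance
    (e.g. timed tasks); their z-scores are negated before averaging.
    Missing task values are ignored subject-wise (mean over available
    tasks).
    """
    invert = invert or []
    unknown = sorted(set(invert) - set(tasks.columns))
    if unknown:
        raise ValueError(f"invert names unknown task(s): {unknown}")
    z = (tasks - tasks.mean()) / tasks.std(ddof=1)
    for col in invert:
        z[col] = -z[col]
    return z.mean(axis=1, skipna=True).rename("composite_cognitive_score")
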