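"""Imaging-transcriptomics partial least squares.

A regional t-map of gradient change (Y, regions x 1) is regressed on the
region x gene expression matrix (X) by NIPALS partial least squares. The
first component (PLS1) maximises covariance between a weighted gene
combination and the t-map; its gene weights rank genes by how strongly
their regional expression tracks disease-related gradient change.

Significance is permutation-based against spin nulls of the t-map:

* component level — does PLS1 explain more variance in Y than spins of Y?
* gene level — is each gene's |PLS1 weight| larger than its own spin-null
  weight distribution? (two-sided, Benjamini-Hochberg across genes)

Term-list similarity statistics (hypergeometric overlap, rank correlation)
operate on externally supplied enrichment term lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import RegionalMap
from .nulls import SpinEnsemble, fdr

logger = logging.getLogger("lbdgrad")

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


@dataclass
class PLSResult:
    genes: list[str]
    weights: np.ndarray            # gene x component
    region_scores: np.ndarray      # region x component
    variance_explained: np.ndarray  # per component, fraction of var(Y)
    gene_p: np.ndarray | None = None
    gene_q: np.ndarray | None = None
    significant: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def pls1_weights(self) -> pd.Series:
        return pd.Series(self.weights[:, 0], index=self.genes, name="pls1_weight")


def _standardise(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0)


def _prepare(expression: pd.DataFrame, t_map: RegionalMap) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if [str(r) for r in expression.index] != list(t_map.region_ids):
        raise ValueError("expression table and t-map regions are not aligned")
    X = expression.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(expression.columns, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped[:5])
    genes = [str(g) for g, k in zip(expression.columns, keep) if k]
    Xs = _standardise(X[:, keep])
    y = t_map.values.astype(float)
    ys = (y - y.mean()) / y.std()
    return Xs, ys, genes


def _nipals(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS regression with a univariate response.

    Returns (weights, region scores, variance explained in y) per
    component. With a single y column the inner NIPALS loop converges in
    one pass (w proportional to X^T y); deflation of X and y between
    components follows the standard algorithm.
    """
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("n_components exceeds the rank the data can support")
    Xk = X.copy()
    yk = y.copy()
    ss_y = float(y @ y)
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    varexp = np.empty(n_components)
    for k in range(n_components):
        w = Xk.T @ yk
        for _ in range(NIPALS_MAX_ITER):
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("degenerate component: X^T y vanished during deflation")
            w = w / norm
            t = Xk @ w
            c = float(t @ yk) / float(t @ t)
            u = yk / c if c != 0 else yk
            w_new = Xk.T @ u
            w_new = w_new / np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xk @ w
        tt = float(t @ t)
        p_load = Xk.T @ t / tt
        c = float(t @ yk) / tt
        Xk = Xk - np.outer(t, p_load)
        yk = yk - c * t
        W[:, k] = w
        T[:, k] = t
        varexp[k] = (c**2 * tt) / ss_y
    return W, T, varexp


def pls_fit(expression: pd.DataFrame, t_map: RegionalMap, n_components: int = 3) -> PLSResult:
    """Fit PLS of the t-map on gene expression (weights only).

    Gene columns and Y are z-scored internally. Signs are fixed so PLS1
    region scores correlate positively with Y.
    """
    X, y, genes = _prepare(expression, t_map)
    W, T, varexp = _nipals(X, y, n_components)
    for k in range(W.shape[1]):
        if np.corrcoef(T[:, k], y)[0, 1] < 0:
            W[:, k] = -W[:, k]
            T[:, k] = -T[:, k]
    return PLSResult(genes=genes, weights=W, region_scores=T, variance_explained=varexp)


def _pls1_nulls(X: np.ndarray, y: np.ndarray, spins: SpinEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """PLS1 weights and variance explained for every spun Y, vectorised.

    For a univariate response the first NIPALS weight vector is exactly
    ``X^T y`` normalised, so all spins reduce to matrix products. Spinning
    permutes y's values, which leaves its mean and SD unchanged, so the
    spun responses stay z-scored.
    """
    Y = y[spins.permutations].T               # regions x n_perm
    C = X.T @ Y                               # gene x n_perm (unnormalised weights)
    norms = np.linalg.norm(C, axis=0)
    norms[norms == 0] = 1.0
    Wn = C / norms
    T = X @ Wn                                # regions x n_perm component scores
    tt = (T**2).sum(axis=0)
    ty = (T * Y).sum(axis=0)
    ss_y = float(y @ y)
    varexp = (ty**2 / tt) / ss_y
    return Wn, varexp


def pls_component_significance(
    result: PLSResult, expression: pd.DataFrame, t_map: RegionalMap, spins: SpinEnsemble
) -> float:
    """Spin-permutation p for PLS1 variance explained.

    Refits PLS1 with the t-map spun per permutation;
    p = (1 + #{null varexp >= observed}) / (n_permutations + 1).
    """
    X, y, _ = _prepare(expression, t_map)
    _, null_varexp = _pls1_nulls(X, y, spins)
    observed = result.variance_explained[0]
    return float((1.0 + np.count_nonzero(null_varexp >= observed)) / (spins.n_permutations + 1.0))


def gene_weight_significance(
    expression: pd.DataFrame,
    t_map: RegionalMap,
    spins: SpinEnsemble,
    fdr_level: float = 0.05,
    n_components: int = 3,
    null: str = "pooled",
) -> PLSResult:
    """Per-gene spin-null test of the PLS1 weights.

    Each gene's |observed PLS1 weight| is compared two-sidedly against a
    null weight distribution from spins of the t-map; p values are
    Benjamini-Hochberg adjusted across genes and the significant set
    (q < fdr_level) is reported with the observed weight sign (negative =
    down-weighted).

    ``null='pooled'`` (default) pools the null weights of all genes, which
    gives p-value resolution of about 1 / (n_genes * n_permutations) — with
    1000 spins and a per-gene null the smallest attainable p is 1/1001, and
    no single gene could ever clear a BH threshold across ~1000 genes.
    ``null='per-gene'`` compares each gene to its own null distribution.
    """
    if null not in ("pooled", "per-gene"):
        raise ValueError("null must be 'pooled' or 'per-gene'")
    result = pls_fit(expression, t_map, n_components=n_components)
    X, y, _ = _prepare(expression, t_map)
    null_w, _ = _pls1_nulls(X, y, spins)
    obs = result.weights[:, 0]
    if null == "pooled":
        pool = np.sort(np.abs(null_w).ravel())
        exceed = pool.size - np.searchsorted(pool, np.abs(obs), side="left")
        p = (1.0 + exceed) / (pool.size + 1.0)
    else:
        exceed = np.count_nonzero(np.abs(null_w) >= np.abs(obs)[:, None], axis=1)
        p = (1.0 + exceed) / (spins.n_permutations + 1.0)
    q = fdr(p)
    sig_mask = q < fdr_level
    sig = pd.DataFrame(
        {
            "gene": [g for g, m in zip(result.genes, sig_mask) if m],
            "weight": obs[sig_mask],
            "p": p[sig_mask],
            "q": q[sig_mask],
        }
    ).sort_values("q", kind="stable", ignore_index=True)
    result.gene_p = p
    result.gene_q = q
    result.significant = sig
    return result


def term_overlap(set_a, set_b, universe) -> float:
    """One-sided hypergeometric over-enrichment p of two term sets.

    p = P[overlap >= observed] when |A| terms are drawn from the universe
    and compared against the |B| marked terms.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    N, K, n = len(universe), len(set_b), len(set_a)
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rank_similarity(ranked_a: list[str], ranked_b: list[str]) -> tuple[float, float]:
    """Spearman correlation of two rankings on their shared labels.

    Rank positions are taken from each full ordering, restricted to the
    intersection of labels. Returns (rho, p).
    """
    pos_a = {lab: i for i, lab in enumerate(ranked_a)}
    pos_b = {lab: i for i, lab in enumerate(ranked_b)}
    shared = [lab for lab in ranked_a if lab in pos_b]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared labels")
    ra = [pos_a[lab] for lab in shared]
    rb = [pos_b[lab] for lab in shared]
    rho, p = stats.spearmanr(ra, rb)
    return float(rho), float(p)
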