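"""Diffusion-map connectivity gradients.

The pipeline that turns a parcellated connectome into cortical gradients:

1. ``sparsify_rows`` — per-row thresholding that keeps only the strongest
   connections (default sparsity 0.9, i.e. the top 10% of weights per row).
2. ``normalized_angle`` — pairwise similarity between the sparsified
   connectivity profiles, ``A(i, j) = 1 - arccos(cossim(x_i, x_j)) / pi``,
   mapping angular distance into [0, 1].
3. ``diffusion_embed`` — diffusion map embedding of the affinity matrix:
   density-normalise with exponent ``alpha`` (0.5 by default, approximating
   Laplace-Beltrami geometry), row-normalise to a Markov operator, and take
   the leading non-trivial eigenvectors scaled by ``lambda / (1 - lambda)``
   (the "automatic diffusion time" convention).
4. ``procrustes_align`` — orthogonal rotation of each individual's gradient
   basis onto a group template, resolving the rotation/sign indeterminacy so
   gradients are comparable across subjects.

Gradient G1 is the principal axis of inter-regional connectivity
differentiation; per-subject spread of G1 scores and per-region G1 values
are what the group comparisons consume downstream.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .datatypes import AnalysisConfig, ConnectivityMatrix, GradientSet


def sparsify_rows(matrix: ConnectivityMatrix, sparsity: float) -> ConnectivityMatrix:
    """Zero the weakest ``floor(sparsity * n)`` entries of every row.

    Rows are thresholded independently, so the result is generally not
    symmetric; the affinity kernel downstream restores symmetry. Ties at the
    cut are broken by column index: among equal values the smaller column
    index is dropped first.
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    values = matrix.values.copy()
    n_cols = values.shape[1]
    k = int(np.floor(sparsity * n_cols))
    if k == 0:
        return _bare(matrix, values)
    # stable argsort ascending: equal values ordered by column index,
    # so the smaller index falls below the cut first
    order = np.argsort(values, axis=1, kind="stable")
    rows = np.arange(values.shape[0])[:, None]
    values[rows, order[:, :k]] = 0.0
    return _bare(matrix, values)


def _bare(matrix: ConnectivityMatrix, values: np.ndarray) -> ConnectivityMatrix:
    """Clone a ConnectivityMatrix skipping validation (sparsified rows are
    intentionally asymmetric)."""
    out = ConnectivityMatrix.__new__(ConnectivityMatrix)
    out.region_ids = list(matrix.region_ids)
    out.values = values
    out.modality = matrix.modality
    return out


def normalized_angle(matrix: ConnectivityMatrix) -> np.ndarray:
    """Normalised-angle affinity between connectivity rows.

    ``A(i, j) = 1 - arccos(cossim(x_i, x_j)) / pi``: 1 for identical
    directions, 0.5 for orthogonal, 0 for antiparallel profiles.
    """
    values = matrix.values
    norms = np.linalg.norm(values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [matrix.region_ids[i] for i in zero[:5]]
        raise ValueError(
            f"all-zero connectivity row(s) for region(s) {names}: cosine similarity undefined; "
            "lower the sparsity"
        )
    unit = values / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    angle = np.arccos(cos)
    # arccos is ill-conditioned near +/-1: near-identical or near-antiparallel
    # pairs would pick up ~1e-8 error. Recompute those few pairs from chord
    # lengths obtained by direct subtraction (well-conditioned arcsin forms).
    near = np.argwhere(np.abs(cos) > 1.0 - 1e-6)
    for i, j in near:
        if cos[i, j] >= 0.0:
            chord = np.linalg.norm(unit[i] - unit[j])
            angle[i, j] = 2.0 * np.arcsin(min(chord / 2.0, 1.0))
        else:
            chord = np.linalg.norm(unit[i] + unit[j])
            angle[i, j] = np.pi - 2.0 * np.arcsin(min(chord / 2.0, 1.0))
    affinity = 1.0 - angle / np.pi
    affinity = (affinity + affinity.T) / 2.0
    np.fill_diagonal(affinity, 1.0)
    return affinity


def diffusion_embed(affinity: np.ndarray, n_components: int = 10, alpha: float = 0.5) -> GradientSet:
    """Diffusion map embedding of a symmetric nonnegative affinity matrix.

    Returns the ``n_components`` leading non-trivial eigenvectors of the
    Markov operator ``P = W / rowsum(W)`` with
    ``W = A / (d_i^alpha * d_j^alpha)``, each scaled by
    ``lambda / (1 - lambda)``. Eigenvector signs are fixed so the entry of
    largest magnitude is positive. The trivial constant eigenvector
    (eigenvalue 1) is discarded; a second unit eigenvalue means the affinity
    graph is disconnected.
    """
    A = np.asarray(affinity, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("affinity must be square")
    if np.abs(A - A.T).max() > 1e-10:
        raise ValueError("affinity must be symmetric")
    if (A < 0).any():
        raise ValueError("affinity must be nonnegative")
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < number of regions")

    d = A.sum(axis=1)
    if (d == 0).any():
        raise ValueError("affinity has an isolated region (zero degree)")
    inv_d_alpha = d ** (-alpha)
    W = A * np.outer(inv_d_alpha, inv_d_alpha)
    d2 = W.sum(axis=1)
    # P = D2^-1 W is similar to the symmetric S = D2^-1/2 W D2^-1/2
    inv_sqrt = 1.0 / np.sqrt(d2)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    # only the top n_components + 1 eigenpairs are needed
    eigvals, eigvecs = scipy.linalg.eigh(S, subset_by_index=[n - n_components - 1, n - 1])
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if abs(eigvals[0] - 1.0) > 1e-10:
        raise ValueError("leading eigenvalue is not 1: affinity is not a valid kernel")
    if n > 1 and eigvals[1] > 1.0 - 1e-10:
        raise ValueError(
            "affinity graph is disconnected (repeated unit eigenvalue); use a lower sparsity"
        )
    # eigenvectors of P from the symmetric problem; drop the trivial one
    psi = eigvecs * inv_sqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    lam = eigvals[1 : n_components + 1]
    vecs = psi[:, 1 : n_components + 1]
    scale = lam / (1.0 - lam)
    scores = vecs * scale[None, :]
    # deterministic sign: largest-magnitude entry positive
    flip = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(scores.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    return GradientSet(
        region_ids=[str(i) for i in range(n)],
        scores=scores,
        eigenvalues=lam,
        aligned=False,
    )


def embed_matrix(matrix: ConnectivityMatrix, config: AnalysisConfig) -> GradientSet:
    """Full single-subject pipeline: sparsify -> normalised angle -> embed."""
    sparse = sparsify_rows(matrix, config.sparsity)
    affinity = normalized_angle(sparse)
    grads = diffusion_embed(affinity, n_components=config.n_components, alpha=config.alpha)
    grads.region_ids = list(matrix.region_ids)
    return grads


def group_template(matrices: list[ConnectivityMatrix], config: AnalysisConfig) -> GradientSet:
    """Template gradients from the element-wise mean of control matrices."""
    if not matrices:
        raise ValueError("need at least one control matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.region_ids != first.region_ids:
            raise ValueError("region_id mismatch across control matrices")
        if m.modality != first.modality:
            raise ValueError("modality mismatch across control matrices")
    mean_values = np.mean([m.values for m in matrices], axis=0)
    mean = _bare(first, mean_values)
    return embed_matrix(mean, config)


def procrustes_align(individual: GradientSet, template: GradientSet) -> GradientSet:
    """Rotate an individual's gradients onto the template basis.

    Single-pass orthogonal Procrustes: the orthogonal matrix R (rotation or
    reflection, no scaling, no centring) minimising
    ``|individual.scores @ R - template.scores|_F``.
    """
    if individual.scores.shape != template.scores.shape:
        raise ValueError(
            f"dimension mismatch: {individual.scores.shape} vs {template.scores.shape}"
        )
    R, _ = scipy.linalg.orthogonal_procrustes(individual.scores, template.scores)
    return GradientSet(
        region_ids=list(individual.region_ids),
        scores=individual.scores @ R,
        eigenvalues=individual.eigenvalues,
        aligned=True,
    )


def fuse(structural: ConnectivityMatrix, functional: ConnectivityMatrix) -> ConnectivityMatrix:
    """Horizontally concatenate structural and functional connectivity.

    Each block is rescaled to unit Frobenius norm before concatenation so
    that neither modality dominates the fused connectivity profile.
    """
    if structural.region_ids != functional.region_ids:
        raise ValueError("region_id mismatch between structural and functional matrices")
    s = structural.values / np.linalg.norm(structural.values)
    f = functional.values / np.linalg.norm(functional.values)
    return ConnectivityMatrix(
        region_ids=list(structural.region_ids),
        values=np.hstack([s, f]),
        modality="fused",
    )


def embed_cohort(
    matrices: dict[str, ConnectivityMatrix],
    control_ids: list[str],
    config: AnalysisConfig,
) -> tuple[GradientSet, dict[str, GradientSet]]:
    """Template from controls, then per-subject aligned gradients.

    Returns the control template and a dict of aligned GradientSets keyed by
    subject id.
    """
    template = group_template([matrices[s] for s in control_ids], config)
    aligned: dict[str, GradientSet] = {}
    for sid, matrix in matrices.items():
        individual = embed_matrix(matrix, config)
        aligned[sid] = procrustes_align(individual, template)
    return template, aligned
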