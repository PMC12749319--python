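"""Gradient construction: sparsification, affinity kernel, embedding,
templating, alignment and fusion."""

import numpy as np
import pytest
from scipy import stats

from lbdgrad.datatypes import AnalysisConfig, ConnectivityMatrix
from lbdgrad.gradients import (
    diffusion_embed,
    embed_matrix,
    fuse,
    group_template,
    normalized_angle,
    procrustes_align,
    sparsify_rows,
)


def _matrix(values, modality="structural"):
    n = values.shape[0]
    return ConnectivityMatrix(
        region_ids=[f"r{i}" for i in range(n)], values=values, modality=modality
    )


def _bare_matrix(values):
    m = ConnectivityMatrix.__new__(ConnectivityMatrix)
    m.region_ids = [f"r{i}" for i in range(values.shape[0])]
    m.values = np.asarray(values, dtype=float)
    m.modality = "structural"
    return m


class TestSparsify:
    def test_zero_sparsity_is_identity(self, rng):
        v = rng.random((6, 6))
        m = _bare_matrix(v)
        np.testing.assert_array_equal(sparsify_rows(m, 0.0).values, v)

    def test_drops_smallest_per_row(self):
        # floor(0.6 * 5) = 3 smallest entries zeroed, top 2 kept
        m = _bare_matrix(np.array([[5.0, 1.0, 4.0, 2.0, 3.0]] * 5))
        out = sparsify_rows(m, 0.6)
        np.testing.assert_array_equal(out.values[0], [5.0, 0.0, 4.0, 0.0, 0.0])
        out2 = sparsify_rows(m, 0.4)
        np.testing.assert_array_equal(out2.values[0], [5.0, 0.0, 4.0, 0.0, 3.0])

    def test_tie_break_drops_smaller_column_first(self):
        m = _bare_matrix(np.full((5, 5), 2.0))
        out = sparsify_rows(m, 0.8)
        # floor(0.8*5)=4 dropped; the survivor is the largest column index
        np.testing.assert_array_equal(out.values[0], [0.0, 0.0, 0.0, 0.0, 2.0])

    def test_survivor_count(self, rng):
        v = rng.random((10, 10))
        for sparsity in (0.3, 0.5, 0.9):
            out = sparsify_rows(_bare_matrix(v), sparsity)
            kept = np.count_nonzero(out.values, axis=1)
            assert (kept == 10 - int(np.floor(sparsity * 10))).all()


class TestNormalizedAngle:
    def test_kernel_identities(self):
        # identical, orthogonal and antiparallel profiles map to 1, 0.5, 0
        rows = np.array(
            [[1.0, 1.0, 0.0, 0.0],
             [1.0, 1.0, 0.0, 0.0],
             [0.0, 0.0, 1.0, 1.0],
             [-1.0, -1.0, 0.0, 0.0]]
        )
        A = normalized_angle(_bare_matrix(rows))
        assert A[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert A[0, 2] == pytest.approx(0.5, abs=1e-12)
        assert A[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_range_symmetry_unit_diagonal(self, rng):
        A = normalized_angle(_bare_matrix(rng.random((12, 12))))
        assert A.min() >= 0.0 and A.max() <= 1.0
        np.testing.assert_array_equal(A, A.T)
        np.testing.assert_allclose(np.diag(A), 1.0)

    def test_zero_row_names_region(self):
        v = np.ones((4, 4))
        v[2] = 0.0
        with pytest.raises(ValueError, match="r2"):
            normalized_angle(_bare_matrix(v))


def _random_affinity(rng, n=30):
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


def _oracle_embedding(A, n_components, alpha):
    """Independent dense oracle: eigendecompose the Markov operator P
    directly with numpy's general eigensolver."""
    d = A.sum(1)
    W = A / (d[:, None] ** alpha * d[None, :] ** alpha)
    P = W / W.sum(1)[:, None]
    eigvals, eigvecs = np.linalg.eig(P)
    order = np.argsort(eigvals.real)[::-1]
    eigvals = eigvals.real[order]
    eigvecs = eigvecs.real[:, order]
    lam = eigvals[1 : n_components + 1]
    return eigvecs[:, 1 : n_components + 1] * (lam / (1 - lam)), lam


class TestDiffusionEmbed:
    def test_matches_dense_oracle(self, rng):
        for _ in range(50):
            A = _random_affinity(rng)
            grads = diffusion_embed(A, n_components=5, alpha=0.5)
            oracle_scores, oracle_lam = _oracle_embedding(A, 5, 0.5)
            np.testing.assert_allclose(grads.eigenvalues, oracle_lam, atol=1e-10)
            for k in range(5):
                r = np.corrcoef(grads.scores[:, k], oracle_scores[:, k])[0, 1]
                assert abs(r) > 0.999

    def test_trivial_eigenvalue_is_one(self, rng):
        A = _random_affinity(rng)
        d = A.sum(1)
        W = A / (d[:, None] ** 0.5 * d[None, :] ** 0.5)
        P = W / W.sum(1)[:, None]
        lam = np.sort(np.linalg.eigvals(P).real)[::-1]
        assert abs(lam[0] - 1.0) < 1e-10

    def test_two_block_affinity_separates_blocks(self):
        eps = 1e-3
        A = np.full((10, 10), eps)
        A[:5, :5] = 1.0
        A[5:, 5:] = 1.0
        g1 = diffusion_embed(A, n_components=2).scores[:, 0]
        assert len(set(np.sign(g1[:5]))) == 1
        assert len(set(np.sign(g1[5:]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[5])

    def test_permutation_equivariance(self, rng):
        A = _random_affinity(rng)
        perm = rng.permutation(30)
        g = diffusion_embed(A, n_components=3)
        gp = diffusion_embed(A[np.ix_(perm, perm)], n_components=3)
        np.testing.assert_allclose(gp.scores, g.scores[perm], atol=1e-8)

    def test_disconnected_affinity_rejected(self):
        A = np.zeros((8, 8))
        A[:4, :4] = 1.0
        A[4:, 4:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embed(A, n_components=2)

    def test_eigenvalues_sorted_nonincreasing(self, rng):
        g = diffusion_embed(_random_affinity(rng), n_components=6)
        assert (np.diff(g.eigenvalues) <= 1e-12).all()

    def test_sign_convention_largest_entry_positive(self, rng):
        g = diffusion_embed(_random_affinity(rng), n_components=4)
        for k in range(4):
            col = g.scores[:, k]
            assert col[np.argmax(np.abs(col))] > 0


class TestProcrustes:
    def test_identity_alignment(self, template60, small_config):
        m, _ = template60
        tpl = embed_matrix(m, small_config)
        aligned = procrustes_align(tpl, tpl)
        np.testing.assert_allclose(aligned.scores, tpl.scores, atol=1e-10)
        assert aligned.aligned

    def test_recovers_random_rotation(self, template60, small_config, rng):
        m, _ = template60
        tpl = embed_matrix(m, small_config)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
            rotated = tpl.scores @ Q
            ind = type(tpl)(
                region_ids=tpl.region_ids,
                scores=rotated,
                eigenvalues=tpl.eigenvalues,
            )
            aligned = procrustes_align(ind, tpl)
            assert np.abs(aligned.scores - tpl.scores).max() < 1e-8

    def test_preserves_frobenius_norm(self, template60, small_config, rng):
        m, _ = template60
        tpl = embed_matrix(m, small_config)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        ind = type(tpl)(
            region_ids=tpl.region_ids,
            scores=tpl.scores @ Q,
            eigenvalues=tpl.eigenvalues,
        )
        aligned = procrustes_align(ind, tpl)
        assert np.linalg.norm(aligned.scores) == pytest.approx(
            np.linalg.norm(tpl.scores), rel=1e-12
        )

    def test_dimension_mismatch_rejected(self, template60, small_config):
        m, _ = template60
        tpl = embed_matrix(m, small_config)
        bad = type(tpl)(
            region_ids=tpl.region_ids,
            scores=tpl.scores[:, :3],
            eigenvalues=tpl.eigenvalues[:3],
        )
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_align(bad, tpl)


class TestFuseAndTemplate:
    def test_fused_shape_and_block_norms(self, template60):
        m, _ = template60
        f_vals = np.clip(m.values / m.values.max() * 2 - 1, -1, 1)
        np.fill_diagonal(f_vals, 1.0)
        func = _matrix(f_vals, modality="functional")
        func.region_ids = list(m.region_ids)
        fused = fuse(m, func)
        n = m.n_regions
        assert fused.values.shape == (n, 2 * n)
        ratio = np.linalg.norm(fused.values[:, :n]) / np.linalg.norm(fused.values[:, n:])
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_self_fusion_affinity_equals_unfused(self, template60):
        m, _ = template60
        sym = _matrix(m.values)
        sym.region_ids = list(m.region_ids)
        fused = fuse(sym, _matrix_as_functional(m))
        # fusing a matrix with (a rescaled copy of) itself: cosine similarity
        # is invariant to duplicated, commonly-rescaled coordinates
        doubled = np.hstack([m.values, m.values])
        A_fused = normalized_angle(_bare_matrix_rect(doubled))
        A_plain = normalized_angle(_bare_matrix(m.values))
        np.testing.assert_allclose(A_fused, A_plain, atol=1e-10)
        assert fused.modality == "fused"

    def test_template_mean_idempotent(self, template60, small_config):
        m, _ = template60
        single = group_template([m], small_config)
        doubled = group_template([m, m], small_config)
        np.testing.assert_allclose(single.scores, doubled.scores, atol=1e-12)
        unaligned = embed_matrix(m, small_config)
        np.testing.assert_allclose(single.scores, unaligned.scores, atol=1e-12)

    def test_template_region_mismatch_rejected(self, template60, small_config):
        m, _ = template60
        other = _matrix(m.values)
        with pytest.raises(ValueError, match="region_id"):
            group_template([m, other], small_config)

    def test_template_recovers_planted_gradient(self, small_config):
        from lbdgrad.datatypes import EffectSpec
        from lbdgrad.synthetic import make_cohort

        cohort, _, latent = make_cohort(
            {"HC": 23}, {"HC": EffectSpec(regime="none")}, seed=11, n_regions=100
        )
        tpl = group_template(
            [cohort.matrices[s] for s in cohort.subjects_in("HC")], small_config
        )
        rho = stats.spearmanr(tpl.scores[:, 0], latent).statistic
        assert abs(rho) > 0.9


def _matrix_as_functional(m):
    vals = np.clip(m.values / max(m.values.max(), 1.0), -1, 1)
    np.fill_diagonal(vals, 1.0)
    out = ConnectivityMatrix(
        region_ids=list(m.region_ids), values=vals, modality="functional"
    )
    return out


def _bare_matrix_rect(values):
    m = ConnectivityMatrix.__new__(ConnectivityMatrix)
    m.region_ids = [f"r{i}" for i in range(values.shape[0])]
    m.values = np.asarray(values, dtype=float)
    m.modality = "fused"
    return m


def test_pipeline_deterministic(template60, small_config):
    m, _ = template60
    a = embed_matrix(m, small_config)
    b = embed_matrix(m, small_config)
    np.testing.assert_array_equal(a.scores, b.scores)
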