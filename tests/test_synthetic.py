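"""Properties of the synthetic cohort generator."""

import math

import numpy as np
import pytest
from scipy import stats

from lbdgrad.datatypes import EffectSpec
from lbdgrad.synthetic import (
    apply_effect,
    couple_scores,
    default_region_ids,
    draw_reorg_assignment,
    kernel_matrix,
    make_cohort,
    make_expression,
    make_parcel_sphere,
    make_smooth_map,
    make_subject,
    make_template,
)


class TestParcelSphere:
    def test_unit_norm_and_hemisphere_split(self):
        sphere = make_parcel_sphere(40, seed=2)
        assert np.abs(np.linalg.norm(sphere.coords, axis=1) - 1).max() < 1e-12
        assert sphere.hemispheres.count("L") == 20
        assert sphere.hemispheres.count("R") == 20

    def test_hemispheres_mirror_in_x(self):
        sphere = make_parcel_sphere(40, seed=2)
        left = sphere.coords[sphere.hemisphere_index("L")]
        right = sphere.coords[sphere.hemisphere_index("R")]
        np.testing.assert_allclose(left * [-1, 1, 1], right, atol=1e-12)

    def test_deterministic_and_seed_sensitive(self):
        a = make_parcel_sphere(40, seed=5)
        b = make_parcel_sphere(40, seed=5)
        c = make_parcel_sphere(40, seed=6)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.allclose(a.coords, c.coords)

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_parcel_sphere(41)


class TestTemplate:
    def test_structural_constraints(self, template60):
        m, _ = template60
        assert (m.values >= 0).all()
        assert np.diag(m.values).max() == 0.0
        np.testing.assert_array_equal(m.values, m.values.T)

    def test_functional_constraints(self):
        m, _ = make_template(30, modality="functional", seed=4)
        assert np.abs(m.values).max() <= 1.0
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_kernel_orders_near_vs_far_pairs(self, template60):
        _, latent = template60
        K = kernel_matrix(latent)
        order = np.argsort(latent)
        near = K[order[0], order[1]]
        far = K[order[0], order[-1]]
        assert near > far

    def test_latent_centred(self, template60):
        _, latent = template60
        assert abs(latent.mean()) < 1e-12


class TestEffects:
    def test_effectspec_invariants_enforced(self):
        with pytest.raises(ValueError):
            EffectSpec(regime="expansion", gamma=0.9)
        with pytest.raises(ValueError):
            EffectSpec(regime="contraction", gamma=1.1)
        with pytest.raises(ValueError):
            EffectSpec(regime="reorganisation", reorg_fraction=0.0)
        with pytest.raises(ValueError):
            EffectSpec(regime="reorganisation", reorg_fraction=0.2, gamma=1.2)

    def test_none_regime_preserves_kernel_mean(self, template60):
        _, latent = template60
        eff = EffectSpec(regime="none")
        out = apply_effect(latent, eff, np.random.default_rng(0))
        np.testing.assert_array_equal(kernel_matrix(out), kernel_matrix(latent))

    def test_reorg_moves_exactly_ceil_fraction(self):
        rng = np.random.default_rng(0)
        n, frac = 50, 0.2
        perm = draw_reorg_assignment(n, frac, rng)
        assert np.count_nonzero(perm != np.arange(n)) == math.ceil(frac * n)

    def test_subject_preserves_modality_constraints(self, template60):
        m, latent = template60
        eff = EffectSpec(regime="expansion", gamma=1.3)
        sub = make_subject(m, latent, eff, seed=9)
        assert (sub.values >= 0).all()
        np.testing.assert_array_equal(sub.values, sub.values.T)
        assert np.diag(sub.values).max() == 0.0

    def test_expansion_widens_recovered_gradient(self, template60, small_config):
        """Population spreads of aligned G1 order as contraction < none < expansion."""
        from lbdgrad.compare import spread_stats
        from lbdgrad.gradients import embed_matrix, procrustes_align

        m, latent = template60
        tpl = embed_matrix(m, small_config)
        means = {}
        for regime, gamma in [("contraction", 0.7), ("none", 1.0), ("expansion", 1.3)]:
            eff = EffectSpec(regime=regime, gamma=gamma)
            grads = {
                f"s{s}": procrustes_align(
                    embed_matrix(make_subject(m, latent, eff, seed=s), small_config), tpl
                )
                for s in range(100)
            }
            means[regime] = spread_stats(grads)["spread_sd"].mean()
        assert means["contraction"] < means["none"] < means["expansion"]


class TestCohort:
    def test_paper_group_sizes(self):
        cohort, _, _ = make_cohort(seed=0, n_regions=20)
        assert len(cohort) == 131
        counts = cohort.table["group"].value_counts()
        assert counts["HC"] == 23 and counts["PD-NC"] == 46 and counts["LBD"] == 62

    def test_same_seed_identical_table(self):
        a, _, _ = make_cohort(seed=4, n_regions=20)
        b, _, _ = make_cohort(seed=4, n_regions=20)
        assert a.table.equals(b.table)
        sid = a.table["subject_id"].iloc[0]
        np.testing.assert_array_equal(a.matrices[sid].values, b.matrices[sid].values)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            make_cohort({"HC": 0, "LBD": 3}, n_regions=20)

    def test_zero_coupling_yields_near_zero_spearman(self):
        rng = np.random.default_rng(7)
        anchors = rng.lognormal(0, 0.5, 62)
        rhos = [
            stats.spearmanr(anchors, couple_scores(anchors, 0.0, rng)).statistic
            for _ in range(50)
        ]
        assert np.abs(rhos).max() < 0.2

    def test_coupling_targets_spearman(self):
        rng = np.random.default_rng(8)
        anchors = rng.lognormal(0, 0.5, 62)
        rhos = [
            stats.spearmanr(anchors, couple_scores(anchors, 0.5, rng)).statistic
            for _ in range(50)
        ]
        assert abs(np.mean(rhos) - 0.5) < 0.05


class TestMaps:
    def test_smooth_map_zscored(self, sphere200):
        m = make_smooth_map(sphere200, 0.2, seed=1)
        assert abs(m.values.mean()) < 1e-12
        assert abs(m.values.std() - 1) < 1e-12

    def test_vanishing_smoothness_decorrelates_neighbours(self, sphere200):
        gram = np.clip(sphere200.coords @ sphere200.coords.T, -1, 1)
        geo = np.arccos(gram)
        np.fill_diagonal(geo, np.inf)
        nbr = np.argmin(geo, axis=1)
        cors = []
        for s in range(40):
            m = make_smooth_map(sphere200, 1e-4, seed=s).values
            cors.append(np.corrcoef(m, m[nbr])[0, 1])
        assert abs(np.mean(cors)) < 0.1

    def test_independent_maps_uncorrelated_on_average(self, sphere200):
        rhos = [
            stats.spearmanr(
                make_smooth_map(sphere200, 0.2, seed=2 * s).values,
                make_smooth_map(sphere200, 0.2, seed=2 * s + 1).values,
            ).statistic
            for s in range(40)
        ]
        assert abs(np.mean(rhos)) < 0.1


class TestExpression:
    def test_values_in_unit_interval(self, sphere200):
        expr = make_expression(sphere200, 20, seed=0)
        assert expr.to_numpy().min() >= 0.0 and expr.to_numpy().max() <= 1.0

    def test_full_effect_is_monotone_transform_of_target(self, sphere200):
        target = make_smooth_map(sphere200, 0.2, seed=5, name="t")
        expr = make_expression(sphere200, 5, planted={"g00003": (target, 1.0)}, seed=1)
        rho = stats.spearmanr(expr["g00003"], target.values).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_effect_leaves_genes_unrelated(self, sphere200):
        target = make_smooth_map(sphere200, 0.2, seed=6, name="t")
        expr = make_expression(
            sphere200, 50, planted={"g00001": (target, 0.0)}, seed=2
        )
        rhos = [
            abs(stats.spearmanr(expr[g], target.values).statistic) for g in expr.columns
        ]
        assert np.median(rhos) < 0.15

    def test_unknown_planted_gene_rejected(self, sphere200):
        target = make_smooth_map(sphere200, 0.2, seed=7)
        with pytest.raises(ValueError, match="not among"):
            make_expression(sphere200, 5, planted={"NOPE": (target, 1.0)}, seed=0)


def test_region_ids_cover_both_hemispheres():
    ids = default_region_ids(10)
    assert ids[0].startswith("L") and ids[-1].startswith("R")
    assert len(set(ids)) == 10
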