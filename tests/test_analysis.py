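"""Latent-space analyses: walks, archetypes, bins, LDA, mAP/q-values."""

import itertools

import numpy as np
import pytest
from scipy import stats

from morphocloud import analysis


class TestPcaLatentWalk:
    def test_map_point_zero_is_group_mean(self):
        x = np.random.default_rng(0).normal(size=(40, 6))
        walk = analysis.pca_latent_walk(x, component=0, map_points=(0,))
        assert np.allclose(walk["representations"][0], x.mean(axis=0))

    def test_walk_symmetric_about_mean(self):
        x = np.random.default_rng(1).normal(size=(30, 5))
        walk = analysis.pca_latent_walk(x, map_points=(-2, 2))
        lo, hi = walk["representations"]
        assert np.allclose((lo + hi) / 2, x.mean(axis=0))

    def test_rank1_line_retrieval_is_monotone(self):
        t = np.linspace(0, 1, 25)
        x = t[:, None] * np.array([2.0, -1.0, 3.0])
        walk = analysis.pca_latent_walk(x, map_points=(-2, -1, 0, 1, 2))
        idx = walk["nearest_index"]
        diffs = np.diff(t[idx])
        assert np.all(diffs >= 0) or np.all(diffs <= 0)

    def test_component_beyond_rank_rejected(self):
        x = np.random.default_rng(2).normal(size=(5, 3))
        with pytest.raises(ValueError, match="rank"):
            analysis.pca_latent_walk(x, component=10)


class TestArchetypes:
    def test_recovers_simplex_vertices(self):
        rng = np.random.default_rng(0)
        verts = np.eye(3) * 5
        w = rng.dirichlet([0.3] * 3, size=150)
        x = w @ verts + rng.normal(scale=0.01, size=(150, 3))
        arc = analysis.fit_archetypes(x, 3, seed=1)
        d = np.linalg.norm(arc.archetypes[:, None] - verts[None], axis=2)
        assert d.min(axis=1).max() < 0.1
        # one-to-one assignment of archetypes to vertices
        assert sorted(d.argmin(axis=1)) == [0, 1, 2]

    def test_single_archetype_is_near_mean(self):
        x = np.random.default_rng(1).normal(size=(80, 4))
        arc = analysis.fit_archetypes(x, 1, seed=2)
        assert np.linalg.norm(arc.archetypes[0] - x.mean(axis=0)) < 0.5

    def test_weight_rows_on_simplex(self):
        x = np.random.default_rng(2).normal(size=(50, 3))
        arc = analysis.fit_archetypes(x, 4, seed=3)
        assert np.abs(arc.weights.sum(axis=1) - 1).max() < 1e-8
        assert arc.weights.min() >= -1e-12

    def test_archetypes_inside_convex_hull(self):
        # archetypes are B @ X with simplex rows, hence convex combinations
        x = np.random.default_rng(3).normal(size=(60, 5))
        arc = analysis.fit_archetypes(x, 3, seed=4)
        recon = arc.mixing @ x
        assert np.allclose(recon, arc.archetypes, atol=1e-10)
        assert np.abs(arc.mixing.sum(axis=1) - 1).max() < 1e-8
        assert arc.mixing.min() >= -1e-12

    def test_deterministic_for_fixed_seed(self):
        x = np.random.default_rng(4).normal(size=(40, 3))
        a = analysis.fit_archetypes(x, 3, seed=5)
        b = analysis.fit_archetypes(x, 3, seed=5)
        assert np.array_equal(a.archetypes, b.archetypes)

    def test_more_archetypes_than_samples_rejected(self):
        with pytest.raises(ValueError):
            analysis.fit_archetypes(np.zeros((3, 2)), 4)


class TestVolumeBins:
    def test_equal_count_bins(self):
        x = np.random.default_rng(0).normal(size=(100, 4))
        v = np.arange(1.0, 101.0)
        profiles = analysis.volume_bin_profiles(x, v, n_bins=5)
        assert list(profiles["n"]) == [20] * 5

    def test_linear_representation_gives_monotone_bin_means(self):
        v = np.linspace(1, 10, 50)
        x = v[:, None] * np.array([1.0, 2.0])
        profiles = analysis.volume_bin_profiles(x, v, n_bins=5)
        means = np.stack(profiles["mean_representation"].to_list())
        assert np.all(np.diff(means[:, 0]) > 0)

    def test_single_bin_is_global_mean(self):
        x = np.random.default_rng(1).normal(size=(30, 3))
        v = np.random.default_rng(2).uniform(1, 2, size=30)
        profiles = analysis.volume_bin_profiles(x, v, n_bins=1)
        assert np.allclose(
            profiles["mean_representation"].iloc[0], x.mean(axis=0)
        )

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(ValueError):
            analysis.volume_bin_profiles(np.zeros((5, 2)), [1, 2, 0, 4, 5])


class TestLdaAxis:
    def test_separated_gaussians_axis_along_x(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(60, 5))
        b = rng.normal(size=(60, 5))
        b[:, 0] += 10
        axis, proj, examples = analysis.lda_axis(
            np.vstack([a, b]), [0] * 60 + [1] * 60
        )
        angle = np.degrees(np.arccos(abs(axis[0])))
        assert angle < 5

    def test_retrieved_examples_monotone_in_projection(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 4))
        y = (x[:, 0] > 0).astype(int)
        axis, proj, examples = analysis.lda_axis(x, y, n_examples=5)
        assert np.all(np.diff(proj[examples]) >= 0)

    def test_identical_classes_give_chance_separation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 4))
        y = np.r_[np.zeros(50), np.ones(50)]
        axis, proj, _ = analysis.lda_axis(x, y)
        auc = stats.mannwhitneyu(proj[y == 1], proj[y == 0]).statistic / (
            50 * 50
        )
        assert abs(auc - 0.5) < 0.2

    def test_single_member_class_rejected(self):
        with pytest.raises(ValueError):
            analysis.lda_axis(np.zeros((3, 2)), [0, 1, 1])


def chance_map_expectation(n_treated, n_control):
    """Exact chance-level mAP by enumerating relevance arrangements.

    Under exchangeability each arrangement of the (n_treated - 1) relevant
    items among the (n_treated + n_control - 1) ranked items is equally
    likely; the expectation of AP over arrangements is the chance mAP.
    """
    m = n_treated + n_control - 1
    g = n_treated - 1
    aps = []
    for pos in itertools.combinations(range(m), g):
        rel = np.zeros(m, dtype=bool)
        rel[list(pos)] = True
        hits = np.flatnonzero(rel)
        aps.append(np.mean((np.arange(g) + 1) / (hits + 1)))
    return float(np.mean(aps))


class TestMeanAveragePrecision:
    def test_identical_groups_match_enumerated_chance_level(self):
        n_t, n_c = 4, 4
        expect = chance_map_expectation(n_t, n_c)
        rng = np.random.default_rng(0)
        maps = [
            analysis.mean_average_precision(
                rng.normal(size=(n_t, 3)), rng.normal(size=(n_c, 3))
            )
            for _ in range(300)
        ]
        se = np.std(maps) / np.sqrt(len(maps))
        assert abs(np.mean(maps) - expect) < 4 * se

    def test_separated_groups_reach_one(self):
        rng = np.random.default_rng(1)
        treated = rng.normal(size=(10, 4)) + 100
        control = rng.normal(size=(10, 4))
        assert analysis.mean_average_precision(treated, control) == 1.0


class TestPerturbationQvalues:
    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(0)
        control = rng.normal(size=(20, 5))
        shifted = rng.normal(size=(15, 5)) + 10  # 10 sigma shift
        res = analysis.perturbation_map_qvalue(
            control, {"drug": shifted}, n_permutations=200, seed=1
        )[0]
        assert res.map_score > 0.99
        assert np.isclose(res.p_value, 1 / 201)
        assert res.q_value < 0.05 and res.significant

    def test_null_cluster_not_detected(self):
        rng = np.random.default_rng(2)
        control = rng.normal(size=(20, 5))
        same = rng.normal(size=(15, 5))
        res = analysis.perturbation_map_qvalue(
            control, {"null": same}, n_permutations=200, seed=3
        )[0]
        assert res.q_value > 0.05 and not res.significant

    def test_significance_flag_matches_inverse_q_rule(self):
        r = analysis.PerturbationResult("d", 0.5, 0.01, q_value=0.049)
        assert r.significant and 1 / r.q_value > 20
        r2 = analysis.PerturbationResult("d", 0.5, 0.2, q_value=0.051)
        assert not r2.significant and 1 / r2.q_value < 20

    def test_permutation_pvalues_superuniform_under_null(self):
        # p-values from permutation tests satisfy P(p <= t) <= t under the
        # null; check the empirical CDF over simulated null datasets
        rng = np.random.default_rng(4)
        pvals = []
        for i in range(120):
            control = rng.normal(size=(8, 3))
            treated = rng.normal(size=(8, 3))
            res = analysis.perturbation_map_qvalue(
                control, {"x": treated}, n_permutations=100, seed=1000 + i
            )[0]
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            frac = (pvals <= t).mean()
            se = np.sqrt(t * (1 - t) / len(pvals))
            assert frac <= t + 4 * se

    def test_q_monotone_and_geq_p(self):
        rng = np.random.default_rng(5)
        control = rng.normal(size=(15, 4))
        drugs = {
            "a": rng.normal(size=(10, 4)) + 8,
            "b": rng.normal(size=(10, 4)) + 0.5,
            "c": rng.normal(size=(10, 4)),
        }
        res = analysis.perturbation_map_qvalue(
            control, drugs, n_permutations=150, seed=6
        )
        for r in res:
            assert r.q_value >= r.p_value - 1e-12
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            analysis.perturbation_map_qvalue(
                np.zeros((5, 2)), {"d": np.zeros((5, 2))}, n_permutations=10
            )
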