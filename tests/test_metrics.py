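"""Benchmark metrics: oracles, calibration, z-score summary."""

import numpy as np
import pandas as pd
import pytest

from morphocloud import metrics
from morphocloud.nn import autodiff as ad


class _IdentityModel:
    """Stub whose reconstruction is the input itself."""

    def reconstruct(self, pts):
        return ad.Tensor(np.asarray(pts, dtype=float))


class _OriginModel:
    """Stub that reconstructs every cloud as all-origin points."""

    def reconstruct(self, pts):
        return ad.Tensor(np.zeros_like(np.asarray(pts, dtype=float)))


class TestReconstructionError:
    def test_identity_model_scores_zero(self):
        clouds = [np.random.default_rng(i).normal(size=(20, 3)) for i in range(3)]
        assert np.allclose(
            metrics.reconstruction_error(_IdentityModel(), clouds), 0.0
        )

    def test_origin_decoder_on_unit_sphere_equals_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(500, 3))
        sphere = v / np.linalg.norm(v, axis=1, keepdims=True)
        err = metrics.reconstruction_error(_OriginModel(), [sphere])
        # every point is at distance 1 from the origin reconstruction
        assert np.isclose(err[0], 1.0, atol=1e-12)

    def test_zero_sdf_predictor_mse_equals_mean_square_targets(self):
        class ZeroSDF:
            def predict_sdf(self, surface, queries):
                return ad.Tensor(np.zeros(len(queries)))

        class S:
            surface_points = np.zeros((10, 3))
            query_points = np.zeros((50, 3))
            sdf_values = np.linspace(-2, 2, 50)

        err = metrics.reconstruction_error(ZeroSDF(), [S()])
        assert np.isclose(err[0], np.mean(S.sdf_values**2))


class TestRotationInvarianceError:
    def test_invariant_statistic_scores_zero(self):
        def sorted_pairwise(pts):
            d = np.linalg.norm(pts[:, None, :3] - pts[None, :, :3], axis=2)
            return np.sort(d[np.triu_indices(len(pts), 1)])[:20]

        clouds = [np.random.default_rng(i).normal(size=(12, 3)) for i in range(3)]
        err = metrics.rotation_invariance_error(sorted_pairwise, clouds, 5, 0)
        assert np.all(err < 1e-10)

    def test_coordinate_mean_embedding_is_sensitive(self):
        def coord_mean(pts):
            return np.asarray(pts)[:, :3].mean(axis=0)

        cloud = np.random.default_rng(1).normal(size=(30, 3)) + [3, 0, 0]
        err = metrics.rotation_invariance_error(coord_mean, [cloud], 6, 2)
        assert err[0] > 0.1

    def test_vn_encoder_beats_coordinate_embedding_tenfold(self):
        from morphocloud.nn import vn

        enc = vn.VNEncoder(bottleneck=8, hidden_channels=(8, 8), k=6, seed=0)
        clouds = [
            np.random.default_rng(i).normal(size=(24, 3)) + [2, 0, 0]
            for i in range(4)
        ]
        vn_err = metrics.rotation_invariance_error(
            lambda p: vn.invariant_representation(enc(p)), clouds, 4, 3
        )
        base_err = metrics.rotation_invariance_error(
            lambda p: np.asarray(p).mean(axis=0), clouds, 4, 3
        )
        assert base_err.mean() > 10 * vn_err.mean()

    def test_too_few_rotations_rejected(self):
        with pytest.raises(ValueError):
            metrics.rotation_invariance_error(lambda p: p, [], 1, 0)


def brute_force_levina_bickel(x, k):
    """Independent loop-based implementation of the estimator."""
    n = len(x)
    vals = []
    for i in range(n):
        d = np.sort(np.linalg.norm(x - x[i], axis=1))[1 : k + 1]
        s = sum(np.log(d[k - 1] / d[j]) for j in range(k - 1))
        vals.append(1.0 / (s / (k - 2)))
    return float(np.mean(vals))


class TestCompactness:
    def test_matches_brute_force_oracle(self):
        x = np.random.default_rng(0).normal(size=(100, 4))
        for k in (5, 9):
            assert np.isclose(
                metrics.levina_bickel(x, k),
                brute_force_levina_bickel(x, k),
                atol=1e-9,
            )

    @pytest.mark.parametrize(
        "dim,maker",
        [
            (1, lambda rng: np.linspace(0, 1, 4000)[:, None]
             * np.array([1.0, 2.0, 3.0])
             + rng.normal(scale=1e-9, size=(4000, 3))),
            (2, lambda rng: np.column_stack(
                [rng.uniform(size=(4000, 2)), np.zeros((4000, 8))])),
            (5, lambda rng: np.column_stack(
                [rng.normal(size=(4000, 5)), np.zeros((4000, 15))])),
        ],
    )
    def test_recovers_known_manifold_dimension(self, dim, maker):
        x = maker(np.random.default_rng(dim))
        assert abs(metrics.compactness(x) - dim) <= 0.5

    def test_invalid_k_range_rejected(self):
        with pytest.raises(ValueError):
            metrics.compactness(np.zeros((10, 2)), k_min=5, k_max=20)


class TestClassificationScore:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(size=(30, 4)), rng.normal(size=(30, 4)) + 20])
        y = [0] * 30 + [1] * 30
        mean, sd = metrics.classification_score(x, y)
        assert mean == 1.0

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 6))
        y = rng.integers(0, 4, size=200)
        mean, sd = metrics.classification_score(x, y, seed=2)
        se = np.sqrt(0.25 * 0.75 / 200)
        assert abs(mean - 0.25) < 3 * se + 0.05

    def test_top_k_all_classes_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 4))
        y = rng.integers(0, 3, size=60)
        mean, _ = metrics.classification_score(x, y, top_k=3)
        assert mean == 1.0

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            metrics.classification_score(np.zeros((6, 2)), [0, 0, 0, 0, 1, 1])


class TestRegressionScore:
    def test_linear_target_perfect_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 5))
        y = x @ np.array([1.0, -2, 0.5, 0, 3])
        mean, sd = metrics.regression_score(x, y)
        assert mean > 0.999

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 5))
        y = rng.normal(size=500)
        mean, _ = metrics.regression_score(x, y)
        assert mean <= 0.05

    def test_duplicated_columns_stable(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(150, 3))
        y = x @ np.array([1.0, 2.0, -1.0]) + rng.normal(scale=0.1, size=150)
        m1, _ = metrics.regression_score(x, y)
        m2, _ = metrics.regression_score(np.hstack([x, x]), y)
        assert abs(m1 - m2) < 0.02

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            metrics.regression_score(np.zeros((10, 2)), np.ones(10))


class _LinearStubModel:
    """Decoder stub that is linear in the representation."""

    def __init__(self):
        rng = np.random.default_rng(0)
        self.A = rng.normal(size=(4, 30))

    def decoder(self, rep):
        return ad.Tensor((np.asarray(rep) @ self.A).reshape(10, 3))


class TestInterpolationMetrics:
    def test_identical_endpoints_zero_energy(self):
        model = _LinearStubModel()
        rep = np.ones(4)
        energy, avg = metrics.interpolation_metrics(
            model, [(rep, rep)], np.stack([rep, 2 * rep, 0 * rep]), steps=5
        )
        assert energy[0] == 0.0

    def test_linear_decoder_path_additivity(self):
        # for a linear decoder the summed consecutive distances equal the
        # endpoint distance regardless of the number of steps, provided the
        # displacement is small enough that the identity matching stays
        # optimal along the whole path
        model = _LinearStubModel()
        rng = np.random.default_rng(1)
        a = rng.normal(size=4)
        b = a + 0.01 * rng.normal(size=4)
        all_reps = np.stack([a, b])
        e1, _ = metrics.interpolation_metrics(model, [(a, b)], all_reps, steps=2)
        e2, _ = metrics.interpolation_metrics(model, [(a, b)], all_reps, steps=9)
        assert np.isclose(e1[0], e2[0], rtol=0.05)

    def test_interpolants_stay_near_manifold_for_dataset_pairs(self):
        model = _LinearStubModel()
        rng = np.random.default_rng(2)
        reps = rng.normal(size=(50, 4))
        a, b = reps[0], reps[1]
        _, avg = metrics.interpolation_metrics(model, [(a, b)], reps, steps=5)
        span = np.linalg.norm(a - b)
        nn_d = np.sort(
            np.linalg.norm(reps - reps[0], axis=1)
        )[1]
        assert avg[0] <= span + nn_d


class TestEfficiencyAndZscore:
    def test_parameter_count_of_linear_map(self):
        class Stub:
            params = [ad.Parameter(np.zeros((10, 10))),
                      ad.Parameter(np.zeros(10))]

        rep = metrics.efficiency_report(Stub())
        assert rep["parameter_count"] == 110
        assert set(rep) == {
            "parameter_count",
            "inference_seconds_per_sample",
            "estimated_energy",
        }

    def test_zscore_sign_flip_for_lower_better(self):
        raw = pd.DataFrame(
            {
                "model": ["a", "b"],
                "metric": ["reconstruction_error"] * 2,
                "value": [1.0, 3.0],
            }
        )
        out = metrics.zscore_summary(raw)
        assert out.loc[0, "z"] > 0 > out.loc[1, "z"]  # lower error is better

    def test_zscores_sum_to_zero(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            {
                "model": list("abcd") * 2,
                "metric": ["classification_accuracy"] * 4
                + ["compactness"] * 4,
                "value": rng.uniform(size=8),
            }
        )
        out = metrics.zscore_summary(raw)
        for _, g in out.groupby("metric"):
            assert abs(g["z"].sum()) < 1e-12

    def test_equal_values_warn_and_zero(self):
        raw = pd.DataFrame(
            {
                "model": list("abc"),
                "metric": ["compactness"] * 3,
                "value": [2.0, 2.0, 2.0],
            }
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = metrics.zscore_summary(raw)
        assert np.all(out["z"] == 0.0)
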